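"""Readers and writers for the scan's input and output formats.

Genotypes arrive either as VCF 4.x (GT field only, parsed with cyvcf2) or
as a plain TSV dialect: a header row of sample identifiers, one row per
SNP, cells holding alt-allele counts 0/1/2 or ``NA`` for a missing call.
Expression matrices and phenotype tables are TSV with the row identifier in
the first column.  All containers validate on construction; round-tripping
any container through its writer and reader reproduces it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_stats import hwe_exact_test

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "DataFormatError",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "filter_hwe",
]


class DataFormatError(ValueError):
    """A file violates the expected format; message names the location."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str = "."
    pos: int = 0  # 1-based, VCF convention
    ref: str = "."
    alt: str = "."


@dataclass
class GenotypeMatrix:
    """Samples × SNPs alt-allele counts with per-SNP metadata.

    ``calls`` is a float array with values in {0, 1, 2} and ``nan`` for
    missing genotypes.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("allele counts must lie in {0, 1, 2}")
        if len(set(s.snp_id for s in self.snps)) != len(self.snps):
            raise DataFormatError("duplicate SNP identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample identifiers")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def calls_for(self, snp_id: str) -> pd.Series:
        """Allele counts for one SNP, indexed by sample id (nan = missing)."""
        return pd.Series(
            self.calls[:, self.snp_index(snp_id)], index=self.sample_ids
        )

    def genotype_counts(
        self, snp_id: str, samples: Iterable[str] | None = None
    ) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts, optionally restricted to a
        sample subset."""
        calls = self.calls_for(snp_id)
        if samples is not None:
            calls = calls.loc[calls.index.intersection(list(samples))]
        values = calls.dropna().to_numpy()
        return (
            int((values == 0).sum()),
            int((values == 1).sum()),
            int((values == 2).sum()),
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of (already normalized) expression values."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataFormatError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if self.values.columns.duplicated().any():
            raise DataFormatError("duplicate sample identifiers")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataFormatError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]


@dataclass
class PhenotypeTable:
    """Per-sample biomarker values (and optional ICV column)."""

    values: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise DataFormatError("duplicate sample identifiers in phenotypes")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(
                f"phenotype column {name!r} not found; "
                f"available: {list(self.values.columns)}"
            )
        return self.values[name]


# ---------------------------------------------------------------------------
# genotype I/O

_TSV_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataFormatError(f"{path}:1: empty header")
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise DataFormatError(f"{path}:1: header has no sample columns")
        snps: list[SnpRecord] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} "
                    f"columns, got {len(cells)}"
                )
            row = []
            for col, cell in enumerate(cells[1:], start=2):
                if cell not in _TSV_TOKENS:
                    raise DataFormatError(
                        f"{path}:{lineno}: column {col}: invalid genotype "
                        f"cell {cell!r} (expected 0/1/2/NA)"
                    )
                row.append(_TSV_TOKENS[cell])
            snps.append(SnpRecord(snp_id=cells[0]))
            rows.append(row)
    calls = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, calls=calls)


def _read_genotypes_vcf(path: str, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise DataFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    sample_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec_no, variant in enumerate(vcf, start=1):
        alts = variant.ALT or []
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(alts) != 1:
            if multiallelic == "skip" or len(alts) == 0:
                n_skipped += 1
                logger.info(
                    "skipping multi-allelic record %d (%s)", rec_no, snp_id
                )
                continue
            if multiallelic != "split":
                raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
        # one output SNP per alt allele; phased and unphased GT are treated
        # identically (only allele counts matter)
        genotypes = variant.genotypes  # [[a1, a2, phased], ...]
        for alt_idx, alt in enumerate(alts, start=1):
            col = np.full(len(sample_ids), np.nan)
            for si, gt in enumerate(genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    continue
                col[si] = sum(1 for a in alleles if a == alt_idx)
            suffix = f"_{alt}" if len(alts) > 1 else ""
            snps.append(
                SnpRecord(
                    snp_id=snp_id + suffix,
                    chrom=str(variant.CHROM),
                    pos=int(variant.POS),
                    ref=str(variant.REF),
                    alt=str(alt),
                )
            )
            columns.append(col)
    if n_skipped:
        logger.info("skipped %d multi-allelic record(s)", n_skipped)
    calls = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, calls=calls)


def read_genotypes(
    path: str, format: str = "vcf", multiallelic: str = "skip"
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the 0/1/2/NA TSV dialect.

    VCF GT fields are mapped to alt-allele counts; ``./.`` becomes missing.
    Multi-allelic records are skipped (default) or split into one
    pseudo-SNP per alt allele, per ``multiallelic``.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path, multiallelic)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(genotypes.sample_ids) + "\n")
        for j, snp in enumerate(genotypes.snps):
            cells = [
                "NA" if not np.isfinite(v) else str(int(v))
                for v in genotypes.calls[:, j]
            ]
            fh.write(snp.snp_id + "\t" + "\t".join(cells) + "\n")


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 file (sites with placeholder
    metadata get chrom '1', ref 'A', alt 'G')."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            chrom = snp.chrom if snp.chrom != "." else "1"
            pos = snp.pos if snp.pos > 0 else j + 1
            ref = snp.ref if snp.ref != "." else "A"
            alt = snp.alt if snp.alt != "." else "G"
            gts = [
                gt_codes.get(v, "./.") for v in genotypes.calls[:, j]
            ]
            fh.write(
                f"{chrom}\t{pos}\t{snp.snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression / phenotype I/O

def _read_table(path: str, what: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse {what} TSV: {exc}") from exc
    if frame.index.hasnans:
        raise DataFormatError(f"{path}: missing row identifier")
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            raise DataFormatError(
                f"{path}: non-numeric cell in column {col!r}, "
                f"row {bad.index[0] if len(bad) else '?'}"
            )
    return frame


def read_expression(path: str, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a genes × samples expression TSV (first column = gene id).

    Set ``genes_in_rows=False`` for samples-in-rows layouts; the matrix is
    transposed on read.
    """
    frame = _read_table(path, "expression")
    if not genes_in_rows:
        frame = frame.T
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(values=frame.astype(float))


def write_expression(expression: ExpressionMatrix, path: str) -> None:
    expression.values.to_csv(path, sep="\t", index_label="gene_id")


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read a phenotype TSV (first column = sample id, named numeric
    biomarker columns)."""
    return PhenotypeTable(values=_read_table(path, "phenotype"))


def write_phenotypes(phenotypes: PhenotypeTable, path: str) -> None:
    phenotypes.values.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# HWE filtering

def filter_hwe(
    genotypes: GenotypeMatrix,
    control_samples: Iterable[str],
    alpha: float = 1e-6,
) -> GenotypeMatrix:
    """Drop SNPs deviating from Hardy-Weinberg equilibrium in controls.

    The exact conditional test is evaluated on the control samples only;
    SNPs with p < ``alpha`` are removed.  ``alpha = 0`` removes nothing.
    """
    controls = set(control_samples)
    if not controls:
        raise ValueError("empty control sample set")
    unknown = controls - set(genotypes.sample_ids)
    if unknown:
        raise ValueError(f"control samples not in genotypes: {sorted(unknown)[:5]}")
    kept = []
    for snp in genotypes.snps:
        counts = genotypes.genotype_counts(snp.snp_id, controls)
        if sum(counts) == 0 or hwe_exact_test(*counts) >= alpha:
            kept.append(snp.snp_id)
    logger.info(
        "HWE filter (alpha=%g): retained %d of %d SNPs",
        alpha, len(kept), len(genotypes.snps),
    )
    return genotypes.subset_snps(kept)
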