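"""Genome-scale orchestration of the stratified structural-break scan.

A *trio* is one (stratifier, gene, biomarker) triple: samples are split
into up to three subgroups by their genotype at a SNP (or by a precomputed
three-level label such as an APOE class), and the Chow test asks whether
the linear expression-on-biomarker relationship differs across the
subgroups.  This module scans every gene for one stratifier, adjusts the
resulting p-values for multiple testing, selects and ranks hits, scores
selections against a reference gene list by hypergeometric enrichment,
ranks SNPs by their enrichment, and summarizes rankings as true-positive
rates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import core_stats
from .core_stats import (
    MIN_GROUP_SIZE,
    EnrichmentResult,
    InsufficientDataError,
    UnfittableGroupError,
    bh_fdr,
    chow_test,
    hypergeom_enrichment,
    ols_fit,
    pearson_with_p,
)
from .data_io import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .federated import FederatedConfig, MessageLog, SiteData, federated_chow

logger = logging.getLogger(__name__)

__all__ = [
    "Stratifier",
    "TrioRecord",
    "SnpRankRecord",
    "ScanConfig",
    "stratify_by_genotype",
    "stratify_by_labels",
    "scan_genes",
    "select_genes",
    "enrich_selection",
    "rank_snps",
    "tpr_at_m",
    "adjust_by_icv",
    "records_to_frame",
]


@dataclass(frozen=True)
class Stratifier:
    """Sample → subgroup assignment derived from one genotype source.

    ``groups`` maps each retained sample to its subgroup label (alt-allele
    count 0/1/2 for SNP stratifiers, or an arbitrary ≤3-level label);
    samples with a missing genotype are listed in ``dropped_samples`` and
    never enter a fit.
    """

    source: str
    groups: dict
    dropped_samples: tuple[str, ...]

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.groups[s] for s in samples], dtype=object)

    @property
    def distinct_labels(self) -> list:
        return sorted(set(self.groups.values()), key=str)


@dataclass(frozen=True)
class TrioRecord:
    """Scan result for one (stratifier, gene, biomarker) trio.

    ``p_value``/``q_value``/``f_value`` are ``nan`` when fewer than two
    subgroups were eligible (too small, or a constant biomarker).
    ``group_sizes`` and ``per_group_pearson`` are aligned with the
    stratifier's sorted labels, padded to three slots.
    """

    stratifier_id: str
    gene_id: str
    biomarker_id: str
    f_value: float
    p_value: float
    q_value: float
    group_sizes: tuple[int, int, int]
    per_group_pearson: tuple[tuple[float, float, int], ...]

    @property
    def is_missing(self) -> bool:
        return not math.isfinite(self.p_value)


@dataclass(frozen=True)
class SnpRankRecord:
    """One SNP's position in the enrichment-based ranking."""

    snp_id: str
    enrichment_p: float  # nan when the SNP was unscannable
    overlap: int
    rank: int


@dataclass(frozen=True)
class ScanConfig:
    """Settings shared by every trio in one scan."""

    biomarker_id: str = "biomarker"
    solver: str = "federated"  # "federated" | "centralized"
    n_sites: int = 1
    federated: FederatedConfig = field(default_factory=FederatedConfig)
    seed: int = 0
    enrichment_tail: str = "greater"

    def __post_init__(self) -> None:
        if self.solver not in {"federated", "centralized"}:
            raise ValueError(f"unknown solver {self.solver!r}")


def stratify_by_genotype(genotypes: GenotypeMatrix, snp_id: str) -> Stratifier:
    """Subgroups from alt-allele counts at one SNP; missing calls dropped."""
    calls = genotypes.calls_for(snp_id)  # KeyError if absent
    groups = {s: int(v) for s, v in calls.items() if np.isfinite(v)}
    dropped = tuple(s for s, v in calls.items() if not np.isfinite(v))
    return Stratifier(source=snp_id, groups=groups, dropped_samples=dropped)


def stratify_by_labels(labels: pd.Series, source: str | None = None) -> Stratifier:
    """Subgroups from a precomputed ≤3-level label column (e.g. APOE
    e3/e3, e3/e4, e4/e4); NA labels dropped."""
    keep = labels.dropna()
    distinct = set(keep)
    if len(distinct) > 3:
        raise ValueError(
            f"stratifier column has {len(distinct)} levels; at most 3 allowed"
        )
    return Stratifier(
        source=source or str(labels.name),
        groups=dict(keep.items()),
        dropped_samples=tuple(labels.index[labels.isna()]),
    )


def _centralized_chow(x: np.ndarray, y: np.ndarray, labels: np.ndarray):
    """Closed-form counterpart of the federated trio fit (same eligibility
    rules, normal-equations solutions)."""
    eligible = []
    for lab in sorted(set(labels), key=str):
        mask = labels == lab
        if mask.sum() >= MIN_GROUP_SIZE and np.ptp(x[mask]) > 0:
            eligible.append(lab)
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"only {len(eligible)} eligible subgroup(s)"
        )
    group_fits = [ols_fit(x[labels == lab], y[labels == lab]) for lab in eligible]
    pool = np.isin(labels, eligible)
    combined = ols_fit(x[pool], y[pool])
    return chow_test(group_fits, combined)


def _aligned_samples(
    stratifier: Stratifier, biomarker: pd.Series, expression: ExpressionMatrix
) -> list[str]:
    samples = sorted(
        set(stratifier.groups)
        & set(biomarker.dropna().index)
        & set(expression.sample_ids)
    )
    n_union = len(
        set(stratifier.groups) | set(biomarker.index) | set(expression.sample_ids)
    )
    if not samples:
        raise ValueError("no samples shared by stratifier, biomarker and expression")
    logger.info(
        "sample alignment: %d retained, %d dropped", len(samples),
        n_union - len(samples),
    )
    return samples


def scan_genes(
    stratifier: Stratifier,
    biomarker: pd.Series,
    expression: ExpressionMatrix,
    config: ScanConfig,
    log: MessageLog | None = None,
) -> list[TrioRecord]:
    """Chow-test every gene against one stratifier and biomarker.

    Samples are aligned by identifier intersection across the three inputs.
    One :class:`TrioRecord` is produced per gene; Benjamini-Hochberg
    q-values are computed over the scan's non-missing p-values, and
    per-subgroup Pearson correlations are reported for downstream
    inspection.  With ``solver="federated"`` the samples are partitioned
    across ``n_sites`` institutions and every fit runs through the
    federated protocol (transcript captured in ``log`` if given).
    """
    samples = _aligned_samples(stratifier, biomarker, expression)
    labels = stratifier.labels_for(samples)
    x = biomarker.loc[samples].to_numpy(dtype=float)
    expr = expression.values[samples]

    sorted_labels = sorted(set(labels), key=str)
    if config.solver == "federated":
        # one random partition per scan, shared by every gene's four fits
        site_indices = _partition_indices(len(samples), config.n_sites, config.seed)

    rows: list[dict] = []
    for gene_id in expr.index:
        y = expr.loc[gene_id].to_numpy(dtype=float)
        try:
            if config.solver == "centralized":
                result = _centralized_chow(x, y, labels)
            else:
                sites = [
                    SiteData(f"site{i + 1}", x[idx], y[idx], labels[idx])
                    for i, idx in enumerate(site_indices)
                ]
                result = federated_chow(sites, config.federated, log)
            f_value, p_value = result.f_value, result.p_value
        except (InsufficientDataError, UnfittableGroupError) as exc:
            logger.debug("gene %s: missing p (%s)", gene_id, exc)
            f_value, p_value = math.nan, math.nan

        sizes, pearson = [], []
        for lab in sorted_labels:
            mask = labels == lab
            sizes.append(int(mask.sum()))
            try:
                pearson.append(pearson_with_p(x[mask], y[mask]))
            except (UnfittableGroupError, ValueError):
                pearson.append((math.nan, math.nan, int(mask.sum())))
        while len(sizes) < 3:
            sizes.append(0)
            pearson.append((math.nan, math.nan, 0))
        rows.append(
            dict(
                gene_id=str(gene_id),
                f_value=f_value,
                p_value=p_value,
                group_sizes=tuple(sizes[:3]),
                per_group_pearson=tuple(pearson[:3]),
            )
        )

    p = np.array([r["p_value"] for r in rows])
    q = np.full_like(p, math.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = bh_fdr(p[finite])

    return [
        TrioRecord(
            stratifier_id=stratifier.source,
            biomarker_id=config.biomarker_id,
            q_value=float(qi),
            **row,
        )
        for row, qi in zip(rows, q)
    ]


def _partition_indices(n: int, n_sites: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(c) for c in np.array_split(rng.permutation(n), n_sites)]


def select_genes(
    records: Sequence[TrioRecord],
    alpha: float | None = None,
    top_n: int | None = None,
) -> list[str]:
    """Select genes by p-value threshold or by top-N rank.

    Exactly one of ``alpha`` (keep p < alpha) and ``top_n`` (keep the N
    smallest p) must be given.  Missing-p trios never qualify; p ties are
    broken by gene identifier so the selection is deterministic.
    """
    if not records:
        raise ValueError("no records to select from")
    if (alpha is None) == (top_n is None):
        raise ValueError("give exactly one of alpha or top_n")
    scored = sorted(
        (r for r in records if not r.is_missing),
        key=lambda r: (r.p_value, r.gene_id),
    )
    if alpha is not None:
        return [r.gene_id for r in scored if r.p_value < alpha]
    if top_n > len(scored):
        warnings.warn(
            f"top_n={top_n} exceeds {len(scored)} scored genes; returning all"
        )
    return [r.gene_id for r in scored[:top_n]]


def enrich_selection(
    selected: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
    tail: str = "greater",
) -> EnrichmentResult:
    """Hypergeometric enrichment of a gene selection against a reference.

    Identifiers are matched case-insensitively; selected/reference entries
    outside the universe are dropped (and logged).
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    sel = {str(g).upper() for g in selected}
    ref = {str(g).upper() for g in reference}
    for name, s in (("selected", sel), ("reference", ref)):
        extra = s - uni
        if extra:
            logger.info(
                "%d %s gene(s) outside the universe dropped (e.g. %s)",
                len(extra), name, sorted(extra)[:3],
            )
    sel &= uni
    ref &= uni
    return hypergeom_enrichment(
        universe_size=len(uni),
        reference_size=len(ref),
        draw_size=len(sel),
        overlap=len(sel & ref),
        tail=tail,
    )


def rank_snps(
    snp_ids: Sequence[str],
    genotypes: GenotypeMatrix,
    biomarker: pd.Series,
    expression: ExpressionMatrix,
    reference: Iterable[str],
    top_n: int,
    config: ScanConfig,
) -> list[SnpRankRecord]:
    """Rank SNPs by the enrichment of their top-N scan hits.

    For each SNP: stratify by genotype, scan all genes, take the top-N
    genes by p, and score that selection against the reference list with
    the hypergeometric test (universe = all scanned genes).  SNPs are
    ranked by ascending enrichment p with lexicographic tie-breaking;
    unscannable SNPs (e.g. monomorphic) get a missing p and rank last.
    Because (M, n, N) are fixed across SNPs, equal overlap counts yield
    identical enrichment p-values.
    """
    reference = list(reference)
    universe = expression.gene_ids
    scored: list[tuple[float, str, int]] = []
    for snp_id in snp_ids:
        try:
            stratifier = stratify_by_genotype(genotypes, snp_id)
            records = scan_genes(stratifier, biomarker, expression, config)
            selection = select_genes(records, top_n=top_n)
            if not selection:
                raise InsufficientDataError("no scorable gene")
            enr = enrich_selection(
                selection, reference, universe, tail=config.enrichment_tail
            )
            scored.append((enr.p_value, snp_id, enr.overlap))
        except (InsufficientDataError, UnfittableGroupError, ValueError) as exc:
            logger.info("SNP %s unscannable (%s); ranked last", snp_id, exc)
            scored.append((math.nan, snp_id, 0))
    scored.sort(key=lambda t: (math.isnan(t[0]), t[0] if not math.isnan(t[0]) else 0.0, t[1]))
    return [
        SnpRankRecord(snp_id=sid, enrichment_p=p, overlap=k, rank=i + 1)
        for i, (p, sid, k) in enumerate(scored)
    ]


def tpr_at_m(
    ranked: Sequence[SnpRankRecord], positives: Iterable[str], m: int
) -> float:
    """Fraction of the top-``m`` ranked SNPs that are known positives."""
    if not 1 <= m <= len(ranked):
        raise ValueError(f"m={m} out of range 1..{len(ranked)}")
    pos = set(positives)
    top = sorted(ranked, key=lambda r: r.rank)[:m]
    return sum(1 for r in top if r.snp_id in pos) / m


def adjust_by_icv(volume, icv):
    """Head-size correction of a regional volume: elementwise volume/ICV."""
    volume_arr = np.asarray(volume, dtype=float)
    icv_arr = np.asarray(icv, dtype=float)
    if volume_arr.shape != icv_arr.shape:
        raise ValueError("volume and ICV must have equal length")
    if np.any(icv_arr <= 0):
        raise ValueError("non-positive ICV value: invalid phenotype")
    adjusted = volume_arr / icv_arr
    if isinstance(volume, pd.Series):
        return pd.Series(adjusted, index=volume.index, name=volume.name)
    return adjusted


def records_to_frame(records: Sequence[TrioRecord]) -> pd.DataFrame:
    """Flatten scan records into the scan's tabular output layout."""
    rows = []
    for r in records:
        row = {
            "stratifier_id": r.stratifier_id,
            "gene_id": r.gene_id,
            "biomarker_id": r.biomarker_id,
            "F": r.f_value,
            "p": r.p_value,
            "q": r.q_value,
        }
        for g in range(3):
            row[f"n_g{g + 1}"] = r.group_sizes[g]
        for g in range(3):
            row[f"r_g{g + 1}"] = r.per_group_pearson[g][0]
            row[f"p_g{g + 1}"] = r.per_group_pearson[g][1]
        rows.append(row)
    return pd.DataFrame(rows)
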