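"""Synthetic genotype-expression-biomarker datasets with planted structure.

The generator realizes the data-generating process the stratified
structural-break scan is designed to detect: an imaging biomarker drawn
from a Gaussian, biallelic genotypes drawn under Hardy-Weinberg
proportions, and gene expression that is linear in the biomarker — with a
*different* slope (and optionally intercept) in each genotype subgroup for
the planted causal (SNP, gene) pairs, and a single shared slope everywhere
else.  Pooling the subgroups dilutes or cancels the per-group correlations,
which is exactly the signature the Chow scan recovers.

Everything is driven by a :class:`SimulationSpec` and a seed; regenerating
with the same spec is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GenotypeMatrix, SnpRecord
from .federated import SiteData

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_trio_dataset",
    "partition_sites",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults encode the strong-effect three-group setting used throughout
    the package's calibration and power checks: ~100 samples per genotype
    subgroup (300 samples, allele frequency 0.5 under Hardy-Weinberg, or
    exactly equal groups with ``balanced_groups``), causal slopes
    (0.5, 0.5, 3.0), equal intercepts so detected structure is attributable
    to slopes alone, and Gaussian noise with standard deviation 0.2.
    """

    n_samples: int = 300
    allele_freq: float = 0.5
    group_intercepts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    group_slopes: tuple[float, float, float] = (0.5, 0.5, 3.0)
    noise_sd: float = 0.2
    n_genes: int = 200
    n_causal_genes: int = 1
    n_snps: int = 20
    n_causal_snps: int = 4
    missing_rate: float = 0.0
    n_sites: int = 5
    seed: int = 0
    biomarker_mean: float = 0.0
    biomarker_sd: float = 1.0
    null_slope: float = 0.5  # shared slope of non-causal genes
    balanced_groups: bool = False  # exactly n_samples/3 per genotype class

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes exceeds n_genes")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps exceeds n_snps")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def _draw_genotype_column(
    spec: SimulationSpec, rng: np.random.Generator, balanced: bool
) -> np.ndarray:
    if balanced:
        base = np.repeat([0.0, 1.0, 2.0], spec.n_samples // 3)
        extra = rng.choice([0.0, 1.0, 2.0], size=spec.n_samples - base.size)
        col = rng.permutation(np.concatenate([base, extra]))
    else:
        p = spec.allele_freq  # alt-allele frequency
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        col = rng.choice([0.0, 1.0, 2.0], size=spec.n_samples, p=probs)
    if spec.missing_rate > 0:
        col = col.copy()
        col[rng.random(spec.n_samples) < spec.missing_rate] = np.nan
    return col


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Biallelic genotypes under Hardy-Weinberg proportions.

    Each SNP is drawn independently with genotype probabilities
    (p², 2pq, q²) for alt-allele frequency q = ``allele_freq``, with
    independent missingness at ``missing_rate``.
    """
    rng = _rng(spec, stream=1)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    snps = [
        SnpRecord(snp_id=f"rs{j + 1:05d}", chrom="1", pos=1000 * (j + 1),
                  ref="A", alt="G")
        for j in range(spec.n_snps)
    ]
    calls = np.column_stack(
        [
            _draw_genotype_column(spec, rng, balanced=spec.balanced_groups)
            for _ in range(spec.n_snps)
        ]
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, calls=calls)


def simulate_trio_dataset(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Full synthetic study: genotypes, expression, biomarker, truth table.

    The first ``n_causal_snps`` SNPs are causal; ``n_causal_genes`` genes
    are assigned to them round-robin, without replacement, so every planted
    (SNP, gene) pair is unambiguous.  A causal gene's expression follows
    ``intercept[g] + slope[g] * biomarker + noise`` with ``g`` the sample's
    genotype at its causal SNP (missing genotypes fall back to the shared
    null slope); all other genes share a single slope.  The truth table has
    columns ``snp_id, gene_id``.
    """
    genotypes = simulate_genotypes(spec)
    rng = _rng(spec, stream=2)
    samples = genotypes.sample_ids
    biomarker = pd.Series(
        rng.normal(spec.biomarker_mean, spec.biomarker_sd, spec.n_samples),
        index=samples,
        name="biomarker",
    )
    gene_ids = [f"GENE{j + 1:05d}" for j in range(spec.n_genes)]

    causal_snps = genotypes.snp_ids[: spec.n_causal_snps]
    causal_genes = gene_ids[: spec.n_causal_genes]
    pairs = [
        (causal_snps[i % len(causal_snps)] if causal_snps else None, g)
        for i, g in enumerate(causal_genes)
    ]
    truth = pd.DataFrame(pairs, columns=["snp_id", "gene_id"])

    x = biomarker.to_numpy()
    values = np.empty((spec.n_genes, spec.n_samples))
    gene_to_snp = dict(zip(truth["gene_id"], truth["snp_id"]))
    intercepts = np.asarray(spec.group_intercepts)
    slopes = np.asarray(spec.group_slopes)
    for j, gene in enumerate(gene_ids):
        noise = rng.normal(0.0, spec.noise_sd, spec.n_samples)
        snp = gene_to_snp.get(gene)
        if snp is None:
            values[j] = spec.null_slope * x + noise
        else:
            g = genotypes.calls_for(snp).to_numpy()
            g_idx = np.where(np.isfinite(g), g, -1).astype(int)
            a = np.where(g_idx >= 0, intercepts[g_idx], 0.0)
            b = np.where(g_idx >= 0, slopes[g_idx], spec.null_slope)
            values[j] = a + b * x + noise
    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples)
    )
    return genotypes, expression, biomarker, truth


def partition_sites(
    x: Sequence[float],
    y: Sequence[float],
    group_labels: Sequence,
    n_sites: int,
    seed: int = 0,
) -> list[SiteData]:
    """Randomly assign samples to ``n_sites`` disjoint hypothetical
    institutions (every sample exactly once)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group_labels)
    n = x.size
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites > n:
        raise ValueError(f"cannot split {n} samples across {n_sites} sites")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [
        SiteData(
            site_id=f"site{i + 1}",
            x=x[chunk],
            y=y[chunk],
            group_labels=labels[chunk],
        )
        for i, chunk in enumerate(np.array_split(order, n_sites))
    ]
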