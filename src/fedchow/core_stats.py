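"""Closed-form statistics underlying the stratified-association scan.

This module provides the statistical primitives used everywhere else in the
package: ordinary least squares for the per-group expression-on-biomarker
lines, the generalized (multi-group) Chow structural-break F-test, the
hypergeometric enrichment probability used to score gene selections against
a reference list, Pearson correlation with its t-based p-value, the
Benjamini-Hochberg step-up FDR adjustment, and an exact conditional test of
Hardy-Weinberg equilibrium used for SNP quality filtering.

All functions are pure and operate on plain numpy arrays or scalars; the
federated protocol in :mod:`fedchow.federated` reproduces the same fits
without centralizing data and feeds its aggregated residual sums back into
:func:`chow_test`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionFit",
    "ChowResult",
    "EnrichmentResult",
    "UnfittableGroupError",
    "InsufficientDataError",
    "ols_fit",
    "chow_test",
    "hypergeom_enrichment",
    "pearson_with_p",
    "bh_fdr",
    "hwe_exact_test",
    "MIN_GROUP_SIZE",
]

#: Smallest subgroup that can support a bivariate line fit (k + 1 with k = 2).
MIN_GROUP_SIZE = 3


class UnfittableGroupError(ValueError):
    """A group's data cannot support a least-squares line (too few points or
    a constant predictor)."""


class InsufficientDataError(ValueError):
    """Not enough samples or groups to form the requested test."""


@dataclass(frozen=True)
class RegressionFit:
    """One fitted linear model: coefficients ``w``, residual sum of squares
    ``S`` and sample count ``N``.

    ``coefficients`` is ordered intercept-first.  ``n_params`` is the number
    of regression parameters ``k`` (2 for the intercept + slope models used
    throughout).
    """

    coefficients: np.ndarray
    rss: float
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.rss < -1e-9:
            raise ValueError(f"negative residual sum of squares: {self.rss}")
        object.__setattr__(self, "rss", max(float(self.rss), 0.0))

    @property
    def n_params(self) -> int:
        return self.coefficients.size

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])


@dataclass(frozen=True)
class ChowResult:
    """Generalized Chow test outcome for G subgroups against the pooled fit.

    The statistic compares the pooled residual sum ``S_C`` with the summed
    per-group residual sums ``sum_g S_g``::

        F = [ (S_C - sum_g S_g) / ((G - 1) k) ] / [ sum_g S_g / (N - G k) ]

    which under the equal-coefficients null follows an F distribution with
    ``(G - 1) k`` and ``N - G k`` degrees of freedom (``N`` the total sample
    count).  For G = 3, k = 2 the numerator degrees of freedom are 2k = 4.
    """

    f_value: float
    df_num: int
    df_den: int
    p_value: float
    group_fits: tuple[RegressionFit, ...]
    combined_fit: RegressionFit

    @property
    def n_groups(self) -> int:
        return len(self.group_fits)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of a drawn gene set against a reference.

    ``universe_size`` (M) genes total, ``reference_size`` (n) of them in the
    reference list, ``draw_size`` (N) genes selected, ``overlap`` (k) of the
    selection in the reference.
    """

    universe_size: int
    reference_size: int
    draw_size: int
    overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= min(self.reference_size, self.draw_size)):
            raise ValueError(
                f"impossible overlap {self.overlap} for reference "
                f"{self.reference_size}, draw {self.draw_size}"
            )
        if self.reference_size > self.universe_size:
            raise ValueError("reference larger than universe")
        if self.draw_size > self.universe_size:
            raise ValueError("draw larger than universe")


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Exact least-squares fit of ``y = a + b x``.

    Parameters
    ----------
    x, y
        Equal-length numeric vectors with at least :data:`MIN_GROUP_SIZE`
        points; ``x`` must not be constant.

    Raises
    ------
    UnfittableGroupError
        If the data cannot identify an intercept and slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < MIN_GROUP_SIZE:
        raise UnfittableGroupError(
            f"need at least {MIN_GROUP_SIZE} points, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise UnfittableGroupError("constant predictor: slope unidentifiable")
    design = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return RegressionFit(coefficients=coef, rss=float(resid @ resid), n_samples=x.size)


def chow_test(
    group_fits: Sequence[RegressionFit], combined_fit: RegressionFit
) -> ChowResult:
    """Generalized Chow test from per-group and pooled residual sums.

    Only the residual sums ``S``, sample counts ``N`` and the parameter
    count ``k`` enter the statistic, which is what allows the federated
    protocol to evaluate it from aggregated scalars alone.

    Raises
    ------
    InsufficientDataError
        Fewer than two groups, or non-positive denominator degrees of
        freedom.
    """
    group_fits = tuple(group_fits)
    n_groups = len(group_fits)
    if n_groups < 2:
        raise InsufficientDataError("Chow test needs at least two groups")
    k = combined_fit.n_params
    if any(f.n_params != k for f in group_fits):
        raise ValueError("all fits must share the same parameter count k")
    n_total = sum(f.n_samples for f in group_fits)
    if n_total != combined_fit.n_samples:
        raise ValueError("group sample counts do not sum to the combined count")
    df_num = (n_groups - 1) * k
    df_den = n_total - n_groups * k
    if df_den <= 0:
        raise InsufficientDataError(
            f"too few samples: {n_total} across {n_groups} groups with k={k}"
        )
    s_groups = sum(f.rss for f in group_fits)
    numerator = (combined_fit.rss - s_groups) / df_num
    if s_groups <= 0.0:
        # perfect within-group fits: any pooled lack of fit is infinitely
        # significant, none at all is a null result
        f_value = math.inf if numerator > 1e-12 else 0.0
    else:
        f_value = numerator / (s_groups / df_den)
    # floating-point (or federated-solver) residue can push the numerator
    # slightly negative; the statistic is 0 there by construction
    f_value = max(f_value, 0.0)
    p_value = float(stats.f.sf(f_value, df_num, df_den)) if math.isfinite(f_value) else 0.0
    return ChowResult(
        f_value=float(f_value),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        group_fits=group_fits,
        combined_fit=combined_fit,
    )


def hypergeom_enrichment(
    universe_size: int,
    reference_size: int,
    draw_size: int,
    overlap: int,
    tail: str = "greater",
) -> EnrichmentResult:
    """Hypergeometric enrichment probability for an observed overlap.

    ``tail`` selects the convention:

    ``"greater"``
        strictly-greater upper tail P(X > k) (default);
    ``"geq"``
        P(X >= k);
    ``"point"``
        the probability mass at the observed overlap, P(X = k).

    All three are exposed because published enrichment analyses are not
    always explicit about which quantity they report; the four parameters
    are carried in the result so any convention can be audited.
    """
    result_args = dict(
        universe_size=int(universe_size),
        reference_size=int(reference_size),
        draw_size=int(draw_size),
        overlap=int(overlap),
    )
    # EnrichmentResult.__post_init__ validates the bounds
    dist = stats.hypergeom(universe_size, reference_size, draw_size)
    if tail == "greater":
        p = dist.sf(overlap)
    elif tail == "geq":
        p = dist.sf(overlap - 1)
    elif tail == "point":
        p = dist.pmf(overlap)
    else:
        raise ValueError(f"unknown tail convention: {tail!r}")
    return EnrichmentResult(p_value=float(np.clip(p, 0.0, 1.0)), **result_args)


def pearson_with_p(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson product-moment correlation with the two-sided t-based p-value.

    Returns ``(r, p, n)``.  Raises :class:`UnfittableGroupError` for fewer
    than three pairs or a constant vector, mirroring the group-eligibility
    rule of the scan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise UnfittableGroupError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UnfittableGroupError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving; each adjusted value lies in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts that are no more probable than the observed one
    (the standard exact formulation used for genotyping QC).  Monomorphic
    sites admit a single outcome and return p = 1.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = 2 * counts[0] + counts[1]
    n_b = 2 * counts[2] + counts[1]
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0
    # attainable heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (max(n_a, n_b) - hets) // 2
    logp = (
        hets * math.log(2.0)
        + math.lgamma(n + 1)
        - np.array([math.lgamma(v + 1) for v in hom_minor])
        - np.array([math.lgamma(v + 1) for v in hets])
        - np.array([math.lgamma(v + 1) for v in hom_major])
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == counts[1])[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
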