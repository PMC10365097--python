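"""Multi-site linear regression and Chow testing without moving raw data.

The protocol mirrors how a coordinating center and ``I`` institutions would
jointly fit the four linear models a stratified structural-break test needs
(one per genotype subgroup plus the pooled model) while each institution
keeps its samples local:

1. every site reports count-level summaries (sample count, sums and sums of
   squares of its biomarker and expression values) so the coordinator can
   broadcast global standardization constants;
2. each round, every site computes its partial gradient
   ``grad_i = X_iᵀ(X_i w − y_i)`` on its own (standardized) data and sends
   only that vector; the coordinator sums the partials into the global
   gradient and sends it back;
3. each site applies the same gradient-descent update
   ``w ← w − (η / N) ∇S(w)`` locally — the coordinator never holds an
   updated coefficient vector, which prevents it from reconstructing site
   data from consecutive gradients;
4. after convergence each site reports its scalar residual sum of squares
   on the original scale; the coordinator aggregates ``S = Σ_i S_i`` and
   ``N = Σ_i N_i`` per model and evaluates the Chow F and p from those
   scalars alone.

Every message a site emits is a :class:`StatsMessage`,
:class:`GradientMessage` or :class:`ResidualMessage`; an optional
:class:`MessageLog` captures the full transcript (serializable to
newline-delimited JSON) so the privacy contract — no raw sample values ever
leave a site — can be audited mechanically.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_stats import (
    MIN_GROUP_SIZE,
    ChowResult,
    InsufficientDataError,
    RegressionFit,
    UnfittableGroupError,
    chow_test,
)

__all__ = [
    "COMBINED",
    "SiteData",
    "StatsMessage",
    "GradientMessage",
    "ResidualMessage",
    "MessageLog",
    "FederatedConfig",
    "ConvergenceWarning",
    "local_gradient",
    "aggregate_and_step",
    "federated_ols",
    "federated_chow",
]

#: Pseudo-group label for the pooled (all eligible subgroups) model.
COMBINED = "C"


class ConvergenceWarning(UserWarning):
    """Gradient descent hit the iteration cap before the norm tolerance."""


@dataclass
class SiteData:
    """One institution's local samples for a single trio.

    ``x`` holds the imaging-biomarker values, ``y`` the expression values
    and ``group_labels`` the genotype subgroup of each sample.  A site may
    hold zero samples of some subgroup.
    """

    site_id: str
    x: np.ndarray
    y: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if not (self.x.shape == self.y.shape == self.group_labels.shape):
            raise ValueError("x, y and group_labels must have equal length")

    def mask_for(self, group) -> np.ndarray:
        """Boolean mask of this site's samples belonging to ``group``.

        ``group`` is a single subgroup label, or a tuple/frozenset of labels
        for the pooled model.
        """
        if isinstance(group, (tuple, frozenset, set, list)):
            return np.isin(self.group_labels, list(group))
        return self.group_labels == group


@dataclass(frozen=True)
class StatsMessage:
    """Count-level summaries a site reports for standardization."""

    site_id: str
    group: object
    n_samples: int
    sum_x: float
    sum_xx: float
    sum_y: float
    sum_yy: float

    def to_dict(self) -> dict:
        return {
            "kind": "stats",
            "site_id": self.site_id,
            "group": str(self.group),
            "n_samples": self.n_samples,
            "sum_x": self.sum_x,
            "sum_xx": self.sum_xx,
            "sum_y": self.sum_y,
            "sum_yy": self.sum_yy,
        }


@dataclass(frozen=True)
class GradientMessage:
    """A site's partial gradient for one model in one descent round.

    The gradient vector, a residual-sum scalar (final round only) and the
    sample count are the *only* quantities a site ever emits.
    """

    site_id: str
    group: object
    gradient: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gradient", np.asarray(self.gradient, dtype=float)
        )

    def to_dict(self) -> dict:
        return {
            "kind": "gradient",
            "site_id": self.site_id,
            "group": str(self.group),
            "gradient": self.gradient.tolist(),
            "n_samples": self.n_samples,
        }


@dataclass(frozen=True)
class ResidualMessage:
    """Final-round scalar residual sum of squares from one site."""

    site_id: str
    group: object
    rss: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "kind": "residual",
            "site_id": self.site_id,
            "group": str(self.group),
            "rss": self.rss,
            "n_samples": self.n_samples,
        }


class MessageLog:
    """Transcript of every site→coordinator message, for privacy audits."""

    def __init__(self) -> None:
        self.messages: list = []

    def record(self, message) -> None:
        self.messages.append(message)

    def to_ndjson(self) -> str:
        return "\n".join(json.dumps(m.to_dict()) for m in self.messages)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_ndjson() + "\n")


@dataclass(frozen=True)
class FederatedConfig:
    """Solver settings shared by the coordinator and all sites.

    ``learning_rate`` is the step size η on standardized data; the applied
    update divides by the global sample count so the effective step is
    invariant to cohort size.  Convergence is declared when the global
    gradient norm drops below ``tolerance``.
    """

    learning_rate: float = 0.1
    max_iterations: int = 10_000
    tolerance: float = 1e-8
    n_sites: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.tolerance <= 0:
            raise ValueError("learning_rate and tolerance must be positive")
        if self.max_iterations < 1 or self.n_sites < 1:
            raise ValueError("max_iterations and n_sites must be >= 1")


def local_gradient(w: np.ndarray, site: SiteData, group) -> GradientMessage:
    """One site's partial gradient ``X_iᵀ(X_i w − y_i)`` for ``group``.

    The design matrix has an intercept column, so ``w`` has length 2.
    Sites holding no samples of the group emit a zero gradient with
    ``n_samples = 0`` (empty groups are legal, not an error).
    """
    w = np.asarray(w, dtype=float)
    mask = site.mask_for(group)
    n = int(mask.sum())
    if n == 0:
        return GradientMessage(site.site_id, group, np.zeros_like(w), 0)
    x = site.x[mask]
    y = site.y[mask]
    design = np.column_stack([np.ones(n), x])
    grad = design.T @ (design @ w - y)
    return GradientMessage(site.site_id, group, grad, n)


def aggregate_and_step(
    messages: Sequence[GradientMessage], w: np.ndarray, config: FederatedConfig
) -> np.ndarray:
    """Sum the per-site gradients and take one gradient-descent step.

    Returns the updated coefficient vector each site computes locally from
    the broadcast global gradient; the coordinator itself only ever sums.
    """
    w = np.asarray(w, dtype=float)
    grads = [np.asarray(m.gradient, dtype=float) for m in messages]
    if any(g.shape != w.shape for g in grads):
        raise ValueError("gradient length mismatch: protocol corruption")
    n_total = sum(m.n_samples for m in messages)
    if n_total == 0:
        return w.copy()
    global_grad = np.sum(grads, axis=0)
    return w - (config.learning_rate / n_total) * global_grad


def _aggregate_stats(sites: Sequence[SiteData], group, log: MessageLog | None):
    """Collect per-site count-level summaries and pool them."""
    n = 0
    sx = sxx = sy = syy = 0.0
    for site in sites:
        mask = site.mask_for(group)
        xs = site.x[mask]
        ys = site.y[mask]
        msg = StatsMessage(
            site_id=site.site_id,
            group=group,
            n_samples=int(mask.sum()),
            sum_x=float(xs.sum()),
            sum_xx=float((xs * xs).sum()),
            sum_y=float(ys.sum()),
            sum_yy=float((ys * ys).sum()),
        )
        if log is not None:
            log.record(msg)
        n += msg.n_samples
        sx += msg.sum_x
        sxx += msg.sum_xx
        sy += msg.sum_y
        syy += msg.sum_yy
    return n, sx, sxx, sy, syy


def federated_ols(
    sites: Sequence[SiteData],
    group,
    config: FederatedConfig,
    log: MessageLog | None = None,
) -> RegressionFit:
    """Fit one linear model across sites by federated gradient descent.

    The model is ``y = a + b x`` on the pooled samples of ``group`` (a
    subgroup label, or a tuple of labels for the combined model).  Inputs
    are standardized with globally aggregated first and second moments —
    count-level scalars only — and the converged coefficients and residual
    sums are reported back on the original scale, with each site
    contributing its residual-sum scalar ``S_i`` and count ``N_i``.

    Raises :class:`UnfittableGroupError` when the pooled group has fewer
    than three samples or a constant biomarker.  A fit that exhausts
    ``max_iterations`` is returned anyway with a :class:`ConvergenceWarning`
    carrying the achieved gradient norm.
    """
    n, sx, sxx, sy, syy = _aggregate_stats(sites, group, log)
    if n < MIN_GROUP_SIZE:
        raise UnfittableGroupError(
            f"group {group!r}: {n} pooled samples, need {MIN_GROUP_SIZE}"
        )
    mean_x = sx / n
    mean_y = sy / n
    var_x = max(sxx / n - mean_x**2, 0.0)
    var_y = max(syy / n - mean_y**2, 0.0)
    if var_x <= 0:
        raise UnfittableGroupError(f"group {group!r}: constant biomarker")
    sd_x = math.sqrt(var_x)
    sd_y = math.sqrt(var_y) if var_y > 0 else 1.0  # constant y: slope -> 0

    # each site standardizes locally from the broadcast global constants
    std_sites = [
        SiteData(
            site_id=s.site_id,
            x=(s.x - mean_x) / sd_x,
            y=(s.y - mean_y) / sd_y,
            group_labels=s.group_labels,
        )
        for s in sites
    ]

    w = np.zeros(2)
    grad_norm = math.inf
    for _ in range(config.max_iterations):
        messages = [local_gradient(w, s, group) for s in std_sites]
        if log is not None:
            for m in messages:
                log.record(m)
        global_grad = np.sum([m.gradient for m in messages], axis=0)
        grad_norm = float(np.linalg.norm(global_grad))
        if grad_norm < config.tolerance:
            break
        w = aggregate_and_step(messages, w, config)
    else:
        warnings.warn(
            f"group {group!r}: no convergence in {config.max_iterations} "
            f"iterations (gradient norm {grad_norm:.3e})",
            ConvergenceWarning,
        )

    # back-transform to the original scale
    slope = w[1] * sd_y / sd_x
    intercept = mean_y + w[0] * sd_y - slope * mean_x
    coef = np.array([intercept, slope])

    # final round: sites report scalar residual sums on the original scale
    rss = 0.0
    for site in sites:
        mask = site.mask_for(group)
        resid = site.y[mask] - (coef[0] + coef[1] * site.x[mask])
        msg = ResidualMessage(
            site_id=site.site_id,
            group=group,
            rss=float(resid @ resid),
            n_samples=int(mask.sum()),
        )
        if log is not None:
            log.record(msg)
        rss += msg.rss
    return RegressionFit(coefficients=coef, rss=rss, n_samples=n)


def _eligible_groups(sites: Sequence[SiteData]) -> list:
    """Subgroup labels with enough pooled samples and a non-constant
    biomarker, in deterministic (sorted) order."""
    labels = sorted({lab for s in sites for lab in np.unique(s.group_labels)},
                    key=str)
    eligible = []
    for lab in labels:
        n, sx, sxx, _, _ = _aggregate_stats(sites, lab, log=None)
        if n >= MIN_GROUP_SIZE and sxx / n - (sx / n) ** 2 > 0:
            eligible.append(lab)
    return eligible


def federated_chow(
    sites: Sequence[SiteData],
    config: FederatedConfig,
    log: MessageLog | None = None,
) -> ChowResult:
    """Full federated structural-break test for one trio.

    Fits one federated model per eligible subgroup plus the combined model
    over those subgroups' samples (four models when three subgroups are
    eligible), then evaluates the Chow F and p at the coordinator from the
    aggregated residual sums and counts alone.

    Raises :class:`InsufficientDataError` when fewer than two subgroups are
    eligible; genome-scale scans catch this and record a missing p-value.
    """
    eligible = _eligible_groups(sites)
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"only {len(eligible)} eligible subgroup(s); need at least 2"
        )
    group_fits = [federated_ols(sites, lab, config, log) for lab in eligible]
    combined_fit = federated_ols(sites, tuple(eligible), config, log)
    return chow_test(group_fits, combined_fit)
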