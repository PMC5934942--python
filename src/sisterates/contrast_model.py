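"""Standardized sister-pair contrasts, the Welch & Waxman reliability
filter, and least-squares regression of contrasts on population contrasts.

For a pair with event counts :math:`c_1, c_2`, branch length :math:`t`
(the height of the pair's ancestor, a proxy for divergence time) and
populations :math:`N_1, N_2`, the contrasts are

.. math::
    d = \\frac{c_1 - c_2}{(c_1 + c_2)/2} \\cdot \\frac{1}{\\sqrt{t}},
    \\qquad
    x = \\frac{\\ln N_1 - \\ln N_2}{\\sqrt{t}}.

Dividing the count difference by the pair mean standardizes for the
amount of data, and dividing by :math:`\\sqrt{t}` standardizes for
divergence time (contrast variance grows linearly with time under a
Poisson accumulation of events).  Pairs that diverged very recently have
noisy contrasts: such pairs show up as a negative relationship between
:math:`|d|` and :math:`\\sqrt{t}`.  The Welch & Waxman filter removes the
shallowest pair repeatedly until that relationship is no longer
significantly negative, then the analysis regresses :math:`d` on
:math:`x` by ordinary least squares with an intercept.

Both contrasts use the orientation of the input pair (member 1 minus
member 2); the same orientation is applied to numerator and predictor so
the fitted slope is meaningful regardless of how pairs are oriented,
provided the orientation is applied uniformly to d and x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "Contrast",
    "WWFilterResult",
    "standardized_difference",
    "population_contrast",
    "compute_contrasts",
    "ww_filter",
    "contrast_regression",
]

from .poisson_model import RateFit


@dataclass(frozen=True)
class Contrast:
    """One pair's standardized count contrast and population contrast."""

    pair_id: object
    d: float
    x: float
    branch_length: float

    @property
    def abs_d(self) -> float:
        return abs(self.d)

    @property
    def sqrt_bl(self) -> float:
        return math.sqrt(self.branch_length)


@dataclass(frozen=True)
class RemovedPair:
    pair_id: object
    reason: str  # zero_branch | zero_counts | ww_iteration
    branch_length: float


@dataclass(frozen=True)
class WWFilterResult:
    retained: tuple[Contrast, ...]
    removed: tuple[RemovedPair, ...]
    final_slope: float
    final_p_one_sided: float


def standardized_difference(c1: float, c2: float, branch_length: float) -> float:
    """Count difference per mean count per sqrt(branch length).

    Undefined (returns NaN) when the pair has no events or no divergence
    time; such pairs are flagged for removal rather than raising.
    """
    if branch_length <= 0 or c1 + c2 <= 0:
        return float("nan")
    return (c1 - c2) / ((c1 + c2) / 2.0) / math.sqrt(branch_length)


def population_contrast(N1: float, N2: float, branch_length: float) -> float:
    """Difference of log populations per sqrt(branch length)."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError(f"populations must be positive, got ({N1}, {N2})")
    if branch_length <= 0:
        return float("nan")
    return (math.log(N1) - math.log(N2)) / math.sqrt(branch_length)


def compute_contrasts(
    pair_ids,
    counts1,
    counts2,
    populations1,
    populations2,
    branch_lengths,
) -> list[Contrast]:
    """Vector convenience: one :class:`Contrast` per pair, NaN where undefined."""
    out = []
    for pid, c1, c2, n1, n2, bl in zip(
        pair_ids, counts1, counts2, populations1, populations2, branch_lengths
    ):
        out.append(
            Contrast(
                pair_id=pid,
                d=standardized_difference(c1, c2, bl),
                x=population_contrast(n1, n2, bl),
                branch_length=bl,
            )
        )
    return out


def _unreliability_test(contrasts: list[Contrast]) -> tuple[float, float]:
    """OLS slope of |d| on sqrt(branch length), with one-sided p.

    The one-sided p-value tests slope < 0 (shallow pairs noisier); it is
    half the two-sided OLS p when the slope is negative.
    """
    y = np.array([c.abs_d for c in contrasts])
    x = np.array([c.sqrt_bl for c in contrasts])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    p_two = float(model.pvalues[1])
    p_one = p_two / 2.0 if slope < 0 else 1.0 - p_two / 2.0
    return slope, p_one


def ww_filter(
    contrasts: list[Contrast],
    rule: str = "significance",
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> WWFilterResult:
    """Welch & Waxman reliability filter.

    Pairs with undefined contrasts (zero branch length or zero counts)
    are removed first.  Then, while the slope of |d| on sqrt(branch
    length) is negative -- significantly so under the default
    ``rule="significance"`` (one-sided p < ``alpha``), or at all under
    ``rule="slope"`` -- the pair with the smallest branch length is
    removed.  The removal log is deterministic: ties on branch length are
    broken by input order.
    """
    if rule not in {"significance", "slope"}:
        raise ValueError(f"unknown rule {rule!r}")
    removed: list[RemovedPair] = []
    retained: list[Contrast] = []
    for c in contrasts:
        if c.branch_length <= 0:
            removed.append(RemovedPair(c.pair_id, "zero_branch", c.branch_length))
        elif math.isnan(c.d):
            removed.append(RemovedPair(c.pair_id, "zero_counts", c.branch_length))
        else:
            retained.append(c)

    slope, p_one = float("nan"), float("nan")
    while True:
        if len(retained) < min_pairs:
            raise ValueError(
                f"Welch & Waxman filter left {len(retained)} pairs "
                f"(minimum {min_pairs})"
            )
        slope, p_one = _unreliability_test(retained)
        negative = slope < 0 and (rule == "slope" or p_one < alpha)
        if not negative:
            break
        idx = min(range(len(retained)), key=lambda i: retained[i].branch_length)
        victim = retained.pop(idx)
        removed.append(RemovedPair(victim.pair_id, "ww_iteration", victim.branch_length))

    return WWFilterResult(
        retained=tuple(retained),
        removed=tuple(removed),
        final_slope=slope,
        final_p_one_sided=p_one,
    )


def contrast_regression(contrasts: list[Contrast]) -> RateFit:
    """OLS of d on x with an intercept.

    Reports the slope, its standard error, the slope F statistic
    (= t squared), its p-value, and the adjusted R^2 (which can be
    negative when the fit explains less than one parameter's worth of
    variance).
    """
    clean = [c for c in contrasts if not (math.isnan(c.d) or math.isnan(c.x))]
    if len(clean) < 3:
        raise ValueError(f"need at least 3 defined contrasts, got {len(clean)}")
    d = np.array([c.d for c in clean])
    x = np.array([c.x for c in clean])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all population contrasts equal")
    model = sm.OLS(d, sm.add_constant(x)).fit()
    t_slope = float(model.tvalues[1])
    return RateFit(
        beta_hat=float(model.params[1]),
        se=float(model.bse[1]),
        statistic=t_slope**2,
        p_value=float(model.pvalues[1]),
        r2=float(model.rsquared_adj),
        n_pairs=len(clean),
        intercept=float(model.params[0]),
        method="contrast",
    )
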