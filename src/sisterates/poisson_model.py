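"""Phylogenetically controlled Poisson regression of event counts on
population size.

Model.  For sister pair :math:`j` with speaker populations
:math:`N_{j1}, N_{j2}`, the gain (or loss) counts of the two members are
taken as independent Poisson variables whose rates are power functions of
population size -- linear on a log-log scale, which keeps rates positive:

.. math:: X_{ji} \\sim \\mathrm{Poisson}(\\mu_j N_{ji}^{\\beta}),

where :math:`\\mu_j` absorbs everything the two members share: divergence
time, amount of data, and the pair's baseline rate of change.  Because
both members inherit the same :math:`\\mu_j`, conditioning on the pair
total removes it:

.. math:: X_{j1} \\mid X_{j1}+X_{j2}=n_j \\;\\sim\\;
          \\mathrm{Binomial}\\!\\big(n_j,\\;
          p_j = N_{j1}^{\\beta}/(N_{j1}^{\\beta}+N_{j2}^{\\beta})\\big).

The conditional likelihood depends only on :math:`\\beta` and the
population *ratios*, so the fit needs no divergence dates, is invariant
to rescaling all populations, and controls for phylogeny at the pair
level.  :math:`\\beta` is estimated by maximizing the summed binomial
log-likelihood; the null hypothesis :math:`\\beta=0` (an even split,
``p = 0.5``) is tested with a likelihood-ratio statistic against
:math:`\\chi^2_1`.

The reported pseudo-R^2 is deviance-based on the *full* Poisson
likelihood with the per-pair nuisance rates profiled out:
``1 - D(beta_hat)/D(0)`` where ``D`` is the Poisson deviance against the
saturated model.  (The likelihood-ratio statistic is identical under the
conditional and the profiled full likelihood; the deviance scaling only
affects the effect-size measure.)  A McFadden variant on the conditional
likelihood is available via ``r2_method``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = ["RateFit", "split_probability", "loglik", "fit"]

_BETA_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class RateFit:
    """Result of a rate-on-population regression (either engine)."""

    beta_hat: float
    se: float
    statistic: float
    p_value: float
    r2: float
    n_pairs: int
    intercept: float | None = None
    method: str = "poisson"

    def __post_init__(self) -> None:
        if self.statistic < -1e-9:
            raise ValueError(f"negative test statistic {self.statistic}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def split_probability(N1: float, N2: float, beta: float) -> float:
    """Probability that an event falls in member 1 rather than member 2.

    ``N1**beta / (N1**beta + N2**beta)``, computed in log space so that
    extreme population ratios or betas do not overflow.  Equals 0.5 when
    ``beta == 0`` or ``N1 == N2``.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError(f"populations must be positive, got ({N1}, {N2})")
    eta = beta * (math.log(N1) - math.log(N2))
    # logistic(eta), stable on both sides
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)
    return e / (1.0 + e)


def _as_arrays(
    pairs: Sequence[tuple[float, float]], counts: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    pop = np.asarray(pairs, dtype=float)
    cnt = np.asarray(counts, dtype=float)
    if pop.shape != cnt.shape or pop.ndim != 2 or pop.shape[1] != 2:
        raise ValueError("pairs and counts must both be sequences of 2-tuples")
    if np.any(pop <= 0):
        raise ValueError("populations must be positive")
    if np.any(cnt < 0) or np.any(cnt != np.round(cnt)):
        raise ValueError("counts must be non-negative integers")
    return pop[:, 0], pop[:, 1], cnt[:, 0], cnt[:, 1]


def loglik(
    beta: float,
    pairs: Sequence[tuple[float, float]],
    counts: Sequence[tuple[int, int]],
) -> float:
    """Conditional (binomial) log-likelihood of ``beta``.

    Sum over pairs of the Binomial(n_j, p_j) log-pmf at the member-1
    count; pairs with a zero total contribute nothing.
    """
    N1, N2, x1, x2 = _as_arrays(pairs, counts)
    return _loglik_arrays(beta, N1, N2, x1, x2)


def _loglik_arrays(
    beta: float, N1: np.ndarray, N2: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> float:
    n = x1 + x2
    eta = beta * (np.log(N1) - np.log(N2))
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    const = gammaln(n + 1) - gammaln(x1 + 1) - gammaln(x2 + 1)
    return float(np.sum(const + x1 * log_p + x2 * log_q))


def _poisson_deviance(
    beta: float, N1: np.ndarray, N2: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> float:
    """Deviance of the full Poisson model with per-pair rates profiled.

    With the nuisance ``mu_j`` at its MLE given beta, member i's fitted
    mean is ``(x1+x2) * w_i / (w1+w2)`` with ``w_i = N_i**beta``.
    """
    n = x1 + x2
    eta = beta * (np.log(N1) - np.log(N2))
    p = 1.0 / (1.0 + np.exp(-eta))
    fitted = np.column_stack([n * p, n * (1.0 - p)])
    obs = np.column_stack([x1, x2])
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(obs > 0, obs * np.log(obs / fitted), 0.0)
    return float(2.0 * np.sum(term - (obs - fitted)))


def fit(
    pairs: Sequence[tuple[float, float]],
    counts: Sequence[tuple[int, int]],
    r2_method: str = "deviance",
) -> RateFit:
    """Maximum-likelihood fit of the population exponent ``beta``.

    Returns the estimate, a Wald standard error from the observed
    information of the conditional likelihood, the likelihood-ratio
    statistic against ``beta = 0`` with its chi-square (1 df) p-value,
    and a pseudo-R^2 (see module docstring; ``r2_method`` is
    ``"deviance"`` or ``"mcfadden"``).
    """
    N1, N2, x1, x2 = _as_arrays(pairs, counts)
    informative = (x1 + x2) > 0
    if informative.sum() < 2:
        raise ValueError("need at least two pairs with non-zero event totals")

    def nll(beta: float) -> float:
        return -_loglik_arrays(beta, N1, N2, x1, x2)

    res = optimize.minimize_scalar(
        nll, bounds=_BETA_BOUNDS, method="bounded", options={"xatol": 1e-10}
    )
    if not res.success:
        raise RuntimeError(f"beta optimization failed: {res.message}")
    beta_hat = float(res.x)
    ll_full = _loglik_arrays(beta_hat, N1, N2, x1, x2)
    ll_null = _loglik_arrays(0.0, N1, N2, x1, x2)
    statistic = max(0.0, 2.0 * (ll_full - ll_null))
    p_value = float(stats.chi2.sf(statistic, df=1))

    h = 1e-5 * max(1.0, abs(beta_hat))
    d2 = (
        _loglik_arrays(beta_hat + h, N1, N2, x1, x2)
        - 2.0 * ll_full
        + _loglik_arrays(beta_hat - h, N1, N2, x1, x2)
    ) / h**2
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("inf")

    if r2_method == "deviance":
        d_full = _poisson_deviance(beta_hat, N1, N2, x1, x2)
        d_null = _poisson_deviance(0.0, N1, N2, x1, x2)
        r2 = 1.0 - d_full / d_null if d_null > 0 else 0.0
    elif r2_method == "mcfadden":
        r2 = 1.0 - ll_full / ll_null if ll_null != 0 else 0.0
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")

    return RateFit(
        beta_hat=beta_hat,
        se=se,
        statistic=statistic,
        p_value=p_value,
        r2=float(r2),
        n_pairs=int(len(N1)),
        method="poisson",
    )
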