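"""Discrete power-law numerics for event-severity tails.

The severity model is the zeta (discrete power-law) distribution

    p(x) = x^(-alpha) / zeta(alpha, xmin),   x = xmin, xmin+1, ...

where ``zeta(alpha, xmin)`` is the Hurwitz zeta function.  The module
provides the PMF/CDF/CCDF, maximum-likelihood estimation of the scaling
exponent ``alpha`` on a tail, and data-driven selection of the tail
threshold ``xmin`` by minimising the Kolmogorov-Smirnov distance between
the empirical tail CDF and the fitted model (the standard
Clauset-Shalizi-Newman procedure for discrete data).

On a log-log plot the model CCDF P(x) = Pr(X >= x) is asymptotically a
straight line of slope -(alpha - 1); ``alpha`` near 2.5 is the benchmark
for insurgency-type conflict-event severities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

# alpha search interval; the upper bound must exceed the steepest tails
# seen in department-level fits (alpha close to 6).
ALPHA_MIN = 1.01
ALPHA_MAX = 8.0
ALPHA_GRID_STEP = 0.01

#: absolute-accuracy contract for the Hurwitz zeta evaluations; the cephes
#: routine behind scipy.special.zeta is accurate to ~1e-15 relative, well
#: inside this bound for the (alpha, xmin) ranges used here.
ZETA_ABS_TOL = 1e-10

#: smallest tail a candidate xmin may leave (tails this small do occur in
#: sparse department-period segments); below MIN_TAIL the candidate is
#: skipped, below SMALL_TAIL the fit carries a small-sample flag.
MIN_TAIL = 4
SMALL_TAIL = 20


class DivergenceError(ValueError):
    """alpha <= 1: the zeta normalisation series diverges."""


class DomainError(ValueError):
    """Severity below the model support (x < xmin)."""


class InsufficientDataError(ValueError):
    """Not enough data to fit a tail under the minimum-tail rule."""


def hurwitz_zeta(alpha: float, xmin: int) -> float:
    """Normalising constant ``sum_{k>=xmin} k^(-alpha)``.

    Parameters
    ----------
    alpha : exponent, must exceed 1 for the series to converge.
    xmin : integer lower end of the support, >= 1.
    """
    if alpha <= 1.0:
        raise DivergenceError(f"zeta(alpha, xmin) diverges for alpha={alpha} <= 1")
    if xmin < 1:
        raise DomainError(f"xmin must be >= 1, got {xmin}")
    return float(special.zeta(alpha, xmin))


def pl_pmf(x, alpha: float, xmin: int):
    """Model probability of an event of severity exactly ``x`` (x >= xmin)."""
    x = np.asarray(x)
    if np.any(x < xmin):
        raise DomainError(f"severity below xmin={xmin}")
    out = np.power(x, -float(alpha)) / hurwitz_zeta(alpha, xmin)
    return float(out) if out.ndim == 0 else out


def pl_cdf(x, alpha: float, xmin: int):
    """Model Pr(X <= x) for integer x >= xmin."""
    x = np.asarray(x)
    if np.any(x < xmin):
        raise DomainError(f"severity below xmin={xmin}")
    z0 = hurwitz_zeta(alpha, xmin)
    out = 1.0 - special.zeta(alpha, x + 1) / z0
    return float(out) if out.ndim == 0 else out


def pl_ccdf_model(x, alpha: float, xmin: int):
    """Model Pr(X >= x) = zeta(alpha, x) / zeta(alpha, xmin).

    ``P(xmin) = 1`` and ``log P(x)`` vs ``log x`` has asymptotic slope
    ``-(alpha - 1)``.
    """
    x = np.asarray(x)
    if np.any(x < xmin):
        raise DomainError(f"severity below xmin={xmin}")
    out = special.zeta(alpha, x) / hurwitz_zeta(alpha, xmin)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted discrete power-law tail for one conflict segment.

    ``n_total`` counts every event in the segment, ``n_tail`` those with
    severity >= ``xmin`` (only these inform ``alpha``).  ``ks_stat`` is the
    KS distance between the empirical tail CDF and the fitted model,
    evaluated over the observed tail support.
    """

    alpha: float
    xmin: int
    n_total: int
    n_tail: int
    ks_stat: float
    loglik: float
    degenerate: bool = False
    small_sample: bool = False
    #: (xmin candidate, grid alpha, KS distance) triples for every candidate
    #: examined, so the threshold choice can be audited.
    profile: tuple = field(default=(), compare=False, repr=False)


def loglikelihood(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """Tail log-likelihood ``-n ln zeta(alpha, xmin) - alpha * sum(ln x)``."""
    tail = np.asarray(tail)
    n = tail.size
    return -n * np.log(hurwitz_zeta(alpha, xmin)) - alpha * float(np.sum(np.log(tail)))


def _refine_alpha(n: int, sum_log: float, xmin: int, a_lo: float, a_hi: float) -> float:
    """Maximise the tail log-likelihood on [a_lo, a_hi] (concave in alpha)."""

    def nll(a: float) -> float:
        return n * np.log(special.zeta(a, xmin)) + a * sum_log

    res = optimize.minimize_scalar(
        nll, bounds=(a_lo, a_hi), method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x)


def fit_alpha(tail, xmin: int, *, min_tail: int = MIN_TAIL) -> tuple[float, float]:
    """Discrete MLE of the scaling exponent on a tail of severities >= xmin.

    Maximises ``L(alpha) = -n ln zeta(alpha, xmin) - alpha sum(ln x_i)``
    over the (ALPHA_MIN, ALPHA_MAX] search interval: a coarse grid locates
    the optimum, then a bounded scalar search refines it (the tail
    log-likelihood is concave in alpha).

    Returns ``(alpha_hat, loglik)``.  If every tail value equals xmin the
    likelihood is increasing in alpha, the search runs to the upper bound
    and a degeneracy warning is emitted.
    """
    tail = np.asarray(tail, dtype=np.int64)
    if tail.size < min_tail:
        raise InsufficientDataError(
            f"tail of size {tail.size} below the minimum of {min_tail}"
        )
    if np.any(tail < xmin):
        raise DomainError("tail contains values below xmin")

    n = tail.size
    sum_log = float(np.sum(np.log(tail)))
    alphas = np.arange(ALPHA_MIN, ALPHA_MAX + ALPHA_GRID_STEP / 2, ALPHA_GRID_STEP)
    ll = -n * np.log(special.zeta(alphas, xmin)) - alphas * sum_log
    k = int(np.argmax(ll))
    a_lo = alphas[max(k - 1, 0)]
    a_hi = alphas[min(k + 1, alphas.size - 1)]
    alpha_hat = _refine_alpha(n, sum_log, xmin, a_lo, a_hi)
    if alpha_hat >= ALPHA_MAX - 10 * ALPHA_GRID_STEP:
        warnings.warn(
            "alpha MLE at the upper search bound; fit is degenerate "
            "(tail carries no slope information)",
            RuntimeWarning,
            stacklevel=2,
        )
    return alpha_hat, loglikelihood(tail, alpha_hat, xmin)


def ks_distance(tail, alpha: float, xmin: int) -> float:
    """KS distance sup over the observed tail support of
    ``|F_emp(x) - F_model(x)|``, both CDFs conditioned on x >= xmin."""
    tail = np.asarray(tail, dtype=np.int64)
    vals, counts = np.unique(tail, return_counts=True)
    f_emp = np.cumsum(counts) / tail.size
    f_mod = 1.0 - special.zeta(alpha, vals + 1) / special.zeta(alpha, xmin)
    return float(np.max(np.abs(f_emp - f_mod)))


def select_xmin(
    severities,
    *,
    min_tail: int = MIN_TAIL,
    refine: bool = True,
) -> PowerLawFit:
    """Joint (alpha, xmin) fit by KS minimisation over candidate thresholds.

    Every distinct observed severity is a candidate xmin (those leaving a
    tail smaller than ``min_tail`` are skipped).  For each candidate the
    exponent is fitted by MLE on the tail and the KS distance between the
    empirical and model tail CDFs is recorded; the fit with the smallest
    distance wins, ties broken towards the smallest xmin.  With
    ``refine=False`` the winning alpha is left at the coarse-grid value
    (used inside the bootstrap, where threshold selection, not the fourth
    decimal of alpha, drives the KS null distribution).
    """
    x = np.asarray(severities, dtype=np.int64)
    if x.size == 0 or np.any(x < 1):
        raise InsufficientDataError("severities must be a non-empty list of ints >= 1")

    vals, counts = np.unique(x, return_counts=True)
    n_total = int(x.size)
    # suffix statistics: tail size and sum(log x) for each candidate
    tail_n = np.cumsum(counts[::-1])[::-1]
    log_vals = np.log(vals)
    tail_slog = np.cumsum((counts * log_vals)[::-1])[::-1]
    ok = tail_n >= min_tail
    if not np.any(ok):
        raise InsufficientDataError(
            f"no candidate xmin leaves a tail of at least {min_tail} events"
        )
    cand_idx = np.nonzero(ok)[0]

    alphas = np.arange(ALPHA_MIN, ALPHA_MAX + ALPHA_GRID_STEP / 2, ALPHA_GRID_STEP)
    # zeta(alpha, u) on the full (grid x candidate) lattice in one
    # vectorised special-function call
    zeta_cand = special.zeta(alphas[:, None], vals[cand_idx][None, :].astype(np.float64))

    best = None  # (D, xmin, alpha0, idx)
    profile = []
    for pos, i in enumerate(cand_idx):
        u = int(vals[i])
        z_u = zeta_cand[:, pos]
        n_k = int(tail_n[i])
        s_k = float(tail_slog[i])
        ll = -n_k * np.log(z_u) - alphas * s_k
        a0 = float(alphas[np.argmax(ll)])
        # KS over the observed tail support
        tv = vals[i:]
        f_emp = np.cumsum(counts[i:]) / n_k
        z0 = special.zeta(a0, u)
        f_mod = 1.0 - special.zeta(a0, tv + 1) / z0
        d = float(np.max(np.abs(f_emp - f_mod)))
        profile.append((u, a0, d))
        if best is None or d < best[0] - 1e-15:
            best = (d, u, a0, i)

    d_best, xmin, a0, i = best
    n_tail = int(tail_n[i])
    s_tail = float(tail_slog[i])
    if refine:
        alpha_hat = _refine_alpha(
            n_tail, s_tail, xmin, a0 - ALPHA_GRID_STEP, a0 + ALPHA_GRID_STEP
        )
        d_best = ks_distance(x[x >= xmin], alpha_hat, xmin)
    else:
        alpha_hat = a0
    ll = -n_tail * np.log(hurwitz_zeta(alpha_hat, xmin)) - alpha_hat * s_tail

    degenerate = alpha_hat >= ALPHA_MAX - 10 * ALPHA_GRID_STEP or (
        n_tail > 0 and np.all(x[x >= xmin] == xmin)
    )
    return PowerLawFit(
        alpha=alpha_hat,
        xmin=int(xmin),
        n_total=n_total,
        n_tail=n_tail,
        ks_stat=d_best,
        loglik=ll,
        degenerate=bool(degenerate),
        small_sample=n_tail < SMALL_TAIL,
        profile=tuple(profile),
    )
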