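"""Randomisation null for segment-level exponent variation.

Does a region's (or department's) fitted exponent carry information, or
could any same-sized subset of that period's events have produced it?
For a period with N_j pooled events of which the segment contributes
n_ij, we draw 50 random subsets of size n_ij from the pool, refit each
("simulated alternative regions"), keep draws whose bootstrap P-value
clears the 0.1 acceptance threshold, and compare the actual exponent to
the draw distribution: inside the 25th-75th percentile band, and inside
mean +/- 1 SD.  Segments failing both comparisons are flagged as
genuinely distinctive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gof import GofResult, bootstrap_pvalue
from .powerlaw import InsufficientDataError, PowerLawFit, select_xmin

DEFAULT_N_DRAWS = 50


class DesignError(ValueError):
    """Invalid subsample design (e.g. segment larger than its pool)."""


@dataclass(frozen=True)
class SubsampleDesign:
    """One segment's null: draw n_segment-sized subsets from the pool."""

    period: str
    pooled: np.ndarray  # all N_j severities of the period, country-wide
    n_segment: int  # n_ij
    n_draws: int = DEFAULT_N_DRAWS
    replace: bool = False  # draw without replacement by default

    def __post_init__(self):
        object.__setattr__(self, "pooled", np.asarray(self.pooled, dtype=np.int64))
        if self.n_segment > self.pooled.size and not self.replace:
            raise DesignError(
                f"segment size {self.n_segment} exceeds pool size {self.pooled.size}"
            )
        if self.n_draws < 1:
            raise DesignError("n_draws must be >= 1")


@dataclass(frozen=True)
class SubsampleSummary:
    """Draw-distribution summary and the two comparison flags.

    Summaries are computed over *valid* draws only (bootstrap P >= 0.1);
    both flags are inclusive at their boundaries.
    """

    alpha_mean: float
    alpha_sd: float
    alpha_q25: float
    alpha_q75: float
    n_valid: int
    actual_alpha: float
    actual_p: float
    within_quartiles: bool
    within_1sd: bool
    available: bool = True

    @classmethod
    def from_stats(
        cls,
        alpha_mean: float,
        alpha_sd: float,
        alpha_q25: float,
        alpha_q75: float,
        actual_alpha: float,
        actual_p: float = float("nan"),
        n_valid: int = 0,
    ) -> "SubsampleSummary":
        """Flag logic on externally supplied summary numbers."""
        return cls(
            alpha_mean=alpha_mean,
            alpha_sd=alpha_sd,
            alpha_q25=alpha_q25,
            alpha_q75=alpha_q75,
            n_valid=n_valid,
            actual_alpha=actual_alpha,
            actual_p=actual_p,
            within_quartiles=bool(alpha_q25 <= actual_alpha <= alpha_q75),
            within_1sd=bool(abs(actual_alpha - alpha_mean) <= alpha_sd),
        )

    @classmethod
    def unavailable(cls, actual_alpha: float, actual_p: float) -> "SubsampleSummary":
        nan = float("nan")
        return cls(nan, nan, nan, nan, 0, actual_alpha, actual_p, False, False, available=False)


def draw_alternative_segments(
    design: SubsampleDesign, seed=None
) -> list[np.ndarray]:
    """The n_draws simulated alternative compositions of the segment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        rng.choice(design.pooled, size=design.n_segment, replace=design.replace)
        for _ in range(design.n_draws)
    ]


def fit_draws(
    draws: list[np.ndarray],
    *,
    n_boot: int = 1000,
    seed=None,
) -> list[tuple[PowerLawFit | None, GofResult | None]]:
    """Refit every draw from scratch (xmin re-selected, then bootstrap GOF).

    ``n_boot=0`` skips the goodness-of-fit step (every draw then counts
    as valid downstream).  Draws too small to fit yield (None, None).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[PowerLawFit | None, GofResult | None]] = []
    for d in draws:
        try:
            fit = select_xmin(d)
        except InsufficientDataError:
            out.append((None, None))
            continue
        gof = bootstrap_pvalue(d, fit, n_boot=n_boot, seed=rng) if n_boot else None
        out.append((fit, gof))
    return out


def summarize_subsamples(
    draw_results: list[tuple[PowerLawFit | None, GofResult | None]],
    actual_fit: PowerLawFit,
    actual_gof: GofResult | None,
    *,
    p_threshold: float = 0.1,
) -> SubsampleSummary:
    """Summarise valid draw exponents and set the comparison flags.

    A draw is valid when it was fittable and (if GOF was run) its
    P-value is >= ``p_threshold``.  SD is the sample (n-1) standard
    deviation; percentiles use linear interpolation.
    """
    alphas = [
        f.alpha
        for f, g in draw_results
        if f is not None and (g is None or g.p_value >= p_threshold)
    ]
    actual_p = actual_gof.p_value if actual_gof is not None else float("nan")
    if len(alphas) < 2:
        return SubsampleSummary.unavailable(actual_fit.alpha, actual_p)
    a = np.asarray(alphas)
    return SubsampleSummary.from_stats(
        alpha_mean=float(np.mean(a)),
        alpha_sd=float(np.std(a, ddof=1)),
        alpha_q25=float(np.percentile(a, 25)),
        alpha_q75=float(np.percentile(a, 75)),
        actual_alpha=actual_fit.alpha,
        actual_p=actual_p,
        n_valid=len(alphas),
    )


def subsample_analysis(
    pooled,
    n_segment: int,
    actual_fit: PowerLawFit,
    actual_gof: GofResult | None,
    *,
    period: str = "",
    n_draws: int = DEFAULT_N_DRAWS,
    n_boot: int = 1000,
    seed=None,
    replace: bool = False,
) -> tuple[SubsampleSummary, list[float]]:
    """End-to-end null for one segment.

    Returns the summary and the list of valid draw exponents (boxplot
    fodder for the period-by-period comparison figures).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = SubsampleDesign(
        period=period, pooled=np.asarray(pooled, dtype=np.int64),
        n_segment=n_segment, n_draws=n_draws, replace=replace,
    )
    draws = draw_alternative_segments(design, seed=rng)
    results = fit_draws(draws, n_boot=n_boot, seed=rng)
    summary = summarize_subsamples(results, actual_fit, actual_gof)
    valid = [
        f.alpha
        for f, g in results
        if f is not None and (g is None or g.p_value >= 0.1)
    ]
    return summary, valid


def summaries_to_frame(rows: list[tuple[str, str, SubsampleSummary]]) -> pd.DataFrame:
    """Table-style export: one row per (period, unit) segment."""
    recs = []
    for period, unit, s in rows:
        recs.append(
            dict(
                period=period, unit=unit, alpha_mean=s.alpha_mean, alpha_sd=s.alpha_sd,
                alpha_q25=s.alpha_q25, alpha_q75=s.alpha_q75, n_valid=s.n_valid,
                actual_alpha=s.actual_alpha, actual_p=s.actual_p,
                within_quartiles=s.within_quartiles, within_1sd=s.within_1sd,
            )
        )
    return pd.DataFrame(recs)
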