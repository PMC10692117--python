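"""Discrete power-law numerics: zeta normalisation, MLE, xmin selection.

Oracles are independent of the fitting code path: the zeta values come
from direct series summation with an integral tail bound, the MLE is
checked against a dense grid search of the log-likelihood, and the KS
distance against its bare definition.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special

from conflict_spectroscopy.gof import sample_discrete_pl
from conflict_spectroscopy.powerlaw import (
    DivergenceError,
    DomainError,
    InsufficientDataError,
    fit_alpha,
    hurwitz_zeta,
    ks_distance,
    pl_ccdf_model,
    pl_cdf,
    pl_pmf,
    select_xmin,
)


def zeta_series(alpha: float, xmin: int, n_terms: int = 2_000_000) -> float:
    """Series-summation oracle: direct sum plus integral tail bracket."""
    k = np.arange(xmin, xmin + n_terms, dtype=np.float64)
    head = np.sum(k**-alpha)
    # integral bounds on the remainder put the truncated sum within
    # [tail_lo, tail_hi]; we take the midpoint
    hi = (xmin + n_terms - 0.5) ** (1 - alpha) / (alpha - 1)
    lo = (xmin + n_terms) ** (1 - alpha) / (alpha - 1)
    return head + (hi + lo) / 2


class TestHurwitzZeta:
    @pytest.mark.parametrize(
        "alpha,xmin,expected",
        [
            (2.0, 1, np.pi**2 / 6),  # Basel value
            (3.0, 1, 1.2020569031595943),  # zeta(3), frozen from zeta_series
            (2.5, 3, 0.16471056195428030),  # frozen from zeta_series
        ],
    )
    def test_known_values(self, alpha, xmin, expected):
        assert hurwitz_zeta(alpha, xmin) == pytest.approx(expected, abs=1e-10)

    def test_matches_series_oracle(self):
        for alpha, xmin in [(1.5, 1), (2.0, 5), (4.5, 2), (7.9, 10)]:
            assert hurwitz_zeta(alpha, xmin) == pytest.approx(
                zeta_series(alpha, xmin), abs=1e-8
            )

    @given(
        alpha=st.floats(1.1, 6.0),
        xmin=st.integers(1, 50),
    )
    def test_telescoping_identity(self, alpha, xmin):
        lhs = hurwitz_zeta(alpha, xmin) - hurwitz_zeta(alpha, xmin + 1)
        assert lhs == pytest.approx(xmin ** (-alpha), rel=1e-9)

    def test_divergence_below_one(self):
        with pytest.raises(DivergenceError):
            hurwitz_zeta(1.0, 1)


class TestPmfCdf:
    def test_pmf_at_one_basel(self):
        assert pl_pmf(1, 2.0, 1) == pytest.approx(6 / np.pi**2, abs=1e-10)

    def test_pmf_normalises(self):
        for alpha, xmin in [(1.8, 1), (2.5, 3), (4.0, 2)]:
            xs = np.arange(xmin, xmin + 200_000)
            total = pl_pmf(xs, alpha, xmin).sum() + pl_ccdf_model(
                xmin + 200_000, alpha, xmin
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_pmf_monotone_decreasing(self):
        xs = np.arange(1, 1000)
        p = pl_pmf(xs, 2.5, 1)
        assert np.all(np.diff(p) < 0)

    def test_pmf_domain_error(self):
        with pytest.raises(DomainError):
            pl_pmf(2, 2.5, 3)

    def test_ccdf_at_xmin_is_one(self):
        for alpha, xmin in [(2.0, 1), (3.3, 7)]:
            assert pl_ccdf_model(xmin, alpha, xmin) == pytest.approx(1.0)

    def test_ccdf_value_alpha2(self):
        z = np.pi**2 / 6
        assert pl_ccdf_model(2, 2.0, 1) == pytest.approx((z - 1) / z, abs=1e-10)

    def test_ccdf_loglog_slope(self):
        # asymptotic slope of log P(x) vs log x is -(alpha - 1)
        xs = np.unique(np.logspace(2, 4, 60).astype(int))
        logp = np.log(pl_ccdf_model(xs, 2.5, 1))
        slope = np.polyfit(np.log(xs), logp, 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.02)

    def test_cdf_ccdf_complement(self):
        xs = np.arange(3, 100)
        # Pr(X <= x) + Pr(X >= x+1) = 1
        total = pl_cdf(xs, 2.2, 3) + pl_ccdf_model(xs + 1, 2.2, 3)
        assert np.allclose(total, 1.0, atol=1e-12)


def grid_argmax_loglik(tail: np.ndarray, xmin: int, step: float = 1e-4) -> float:
    """Brute-force oracle: dense grid search of the tail log-likelihood."""
    alphas = np.arange(1.01, 8.0 + step / 2, step)
    ll = -tail.size * np.log(special.zeta(alphas, xmin)) - alphas * np.sum(
        np.log(tail)
    )
    return float(alphas[np.argmax(ll)])


class TestFitAlpha:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alpha = float(rng.uniform(1.5, 5.0))
        xmin = int(rng.integers(1, 6))
        tail = sample_discrete_pl(alpha, xmin, 500, rng)
        a_hat, _ = fit_alpha(tail, xmin)
        assert a_hat == pytest.approx(grid_argmax_loglik(tail, xmin), abs=1e-4)

    def test_two_point_tail(self):
        tail = np.array([2, 4])
        a_hat, _ = fit_alpha(tail, 2, min_tail=2)
        assert a_hat == pytest.approx(grid_argmax_loglik(tail, 2), abs=1e-4)

    def test_recovery(self):
        tail = sample_discrete_pl(2.5, 2, 5000, seed=11)
        a_hat, _ = fit_alpha(tail, 2)
        assert abs(a_hat - 2.5) < 0.06

    def test_degenerate_all_at_xmin(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            a_hat, _ = fit_alpha(np.array([3, 3, 3, 3, 3]), 3)
        assert a_hat > 7.5  # likelihood increasing in alpha

    def test_insufficient_tail(self):
        with pytest.raises(InsufficientDataError):
            fit_alpha(np.array([2, 3]), 2)

    def test_continuous_hill_scale_invariance(self):
        # the continuous-ized (Hill) exponent is exactly scale-free; the
        # discrete MLE is only approximately so and is not asserted here
        x = sample_discrete_pl(2.5, 2, 2000, seed=3).astype(float)
        hill = lambda v, lo: 1 + v.size / np.sum(np.log(v / lo))
        assert hill(x, 2) == pytest.approx(hill(7 * x, 14), rel=1e-12)


def ks_brute(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """Definition-level oracle: sup over observed support of the gap
    between empirical and model tail CDFs."""
    best = 0.0
    for v in np.unique(tail):
        f_emp = np.mean(tail <= v)
        f_mod = 1.0 - special.zeta(alpha, v + 1) / special.zeta(alpha, xmin)
        best = max(best, abs(f_emp - f_mod))
    return best


class TestSelectXmin:
    def test_ks_matches_brute_force(self):
        tail = np.array([2, 2, 3, 5, 5, 8, 13, 21])
        assert ks_distance(tail, 2.7, 2) == pytest.approx(ks_brute(tail, 2.7, 2))

    def test_pure_powerlaw_recovers_xmin_one(self):
        hits = sum(
            select_xmin(sample_discrete_pl(2.5, 1, 2000, seed=100 + s)).xmin == 1
            for s in range(20)
        )
        assert hits >= 18  # >= 90% of seeds

    def test_body_plus_tail_recovers_threshold(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            body = rng.integers(1, 5, size=800)
            tail = sample_discrete_pl(2.5, 5, 1200, rng)
            f = select_xmin(np.concatenate([body, tail]))
            hits += f.xmin in (4, 5, 6)
        assert hits >= 12  # clear majority of seeds

    def test_minimises_ks_over_candidate_profile(self):
        x = sample_discrete_pl(2.2, 1, 500, seed=5)
        fit = select_xmin(x, refine=False)
        ds = [d for (_, _, d) in fit.profile]
        assert fit.ks_stat == pytest.approx(min(ds))
        # tie-break: smallest xmin among (near-)minimisers
        argmin_xmin = min(u for (u, _, d) in fit.profile if d <= min(ds) + 1e-15)
        assert fit.xmin == argmin_xmin

    def test_counts_are_consistent(self):
        x = sample_discrete_pl(2.5, 1, 300, seed=8)
        fit = select_xmin(x)
        assert fit.n_total == 300
        assert fit.n_tail == int(np.sum(x >= fit.xmin))
        assert 0 <= fit.ks_stat <= 1

    def test_small_sample_flag(self):
        x = np.array([1] * 2 + [2, 3, 5, 9])
        fit = select_xmin(x)
        assert fit.small_sample

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            select_xmin(np.array([4, 5, 6]))
        with pytest.raises(InsufficientDataError):
            select_xmin(np.array([]))
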