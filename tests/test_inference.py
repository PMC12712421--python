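"""Segmented binomial logistic regression: slopes, breakpoints, model selection."""

import numpy as np
import pandas as pd
import pytest

from fluctsel import inference as inf
from fluctsel import popgen as pg


def counts_frame(locus_id, times, alleles, derived, env=None):
    df = pd.DataFrame({
        "locus_id": locus_id, "time": times,
        "alleles_sampled": alleles, "derived_count": derived,
    })
    if env is not None:
        df["env"] = env
    return df


def noiseless_counts(freq_paths, times, alleles=200_000):
    """Counts at huge sample size so binomial noise is negligible."""
    rows = []
    for j, path in enumerate(freq_paths):
        for t in times:
            rows.append((j, t, alleles, int(round(path[t] * alleles))))
    return pd.DataFrame(rows, columns=["locus_id", "time", "alleles_sampled",
                                       "derived_count"])


class TestLogitSlope:
    def test_two_point_single_locus_equals_logit_difference(self):
        df = counts_frame([0, 0], [0, 1], [10, 10], [5, 6])
        est = inf.logit_slope(df)
        assert est.S == pytest.approx(np.log(0.6 / 0.4), abs=1e-6)

    def test_constant_frequency_gives_zero_slope(self):
        df = counts_frame([0] * 5, range(5), [100] * 5, [40] * 5)
        est = inf.logit_slope(df)
        assert est.S == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_additive_trajectory_recovers_half_s(self):
        """On dense noiseless data with h=0.5, the slope is s/2 within 5%."""
        for s in (0.01, 0.05, 0.1):
            path = pg.deterministic_trajectory(0.1, pg.FitnessParams(s, 0.5), 600)
            inside = np.nonzero((path >= 0.1) & (path <= 0.9))[0]
            df = noiseless_counts([path], inside)
            est = inf.logit_slope(df)
            assert est.S == pytest.approx(s / 2, rel=0.05)

    def test_complete_separation_flagged_non_estimable(self):
        df = counts_frame([0] * 4, range(4), [10] * 4, [0] * 4)
        est = inf.logit_slope(df)
        assert not est.estimable
        assert est.flagged_loci == [0]

    def test_separated_locus_dropped_but_others_used(self):
        df = pd.concat([
            counts_frame([0] * 4, range(4), [50] * 4, [20, 22, 25, 28]),
            counts_frame([1] * 4, range(4), [50] * 4, [50] * 4),
        ])
        est = inf.logit_slope(df)
        assert est.estimable
        assert est.n_loci == 1
        assert est.flagged_loci == [1]

    def test_matches_statsmodels_glm(self):
        """Independent check: shared-slope fit vs statsmodels GLM with locus dummies."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        times = np.arange(0, 30, 3)
        rows = []
        for j in range(4):
            p = pg.expit(-1.0 + 0.3 * j + 0.04 * times)
            y = rng.binomial(60, p)
            rows.append(counts_frame([j] * len(times), times, [60] * len(times), y))
        df = pd.concat(rows)
        est = inf.logit_slope(df)

        t = df["time"].to_numpy(float)
        dummies = pd.get_dummies(df["locus_id"]).to_numpy(float)
        X = np.column_stack([dummies, t])
        endog = np.column_stack([df["derived_count"],
                                 df["alleles_sampled"] - df["derived_count"]])
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        assert est.S == pytest.approx(fit.params[-1], abs=1e-6)
        assert est.se == pytest.approx(fit.bse[-1], rel=1e-3)
        assert est.loglik == pytest.approx(fit.llf - _binom_const(df), abs=1e-5)


def _binom_const(df):
    from scipy.special import gammaln

    y = df["derived_count"].to_numpy(float)
    m = df["alleles_sampled"].to_numpy(float)
    return float(np.sum(gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)))


def piecewise_logit_path(intercept, slopes, bounds, T):
    """Continuous piecewise-linear logit path evaluated at 0..T."""
    t = np.arange(T + 1, dtype=float)
    lp = np.full(T + 1, float(intercept))
    for lo, hi, sl in zip(bounds[:-1], bounds[1:], slopes):
        seg = np.clip(t, lo, hi)
        lp += sl * (seg - lo)
    return pg.expit(lp)


class TestSegmented:
    def test_k_zero_reduces_to_logit_slope(self):
        df = counts_frame([0] * 6, range(6), [100] * 6, [30, 35, 33, 40, 42, 44])
        est = inf.logit_slope(df)
        fit = inf.fit_segmented(df, 0)
        assert fit.n_breakpoints == 0
        assert fit.S_per_segment[0][0] == pytest.approx(est.S, abs=1e-10)
        assert fit.loglik == pytest.approx(est.loglik, abs=1e-8)

    def test_recovers_synthetic_breakpoint(self):
        """Dense noiseless piecewise series: break at 50, slopes within 10%."""
        path = piecewise_logit_path(-2.0, [0.05, -0.0125], [0, 50, 120], 120)
        df = noiseless_counts([path], np.arange(0, 121))
        fit = inf.fit_segmented(df, 1)
        assert abs(fit.breakpoint_estimates[0] - 50) <= 2
        assert fit.S_per_segment[0][0] == pytest.approx(0.05, rel=0.10)
        assert fit.S_per_segment[1][0] == pytest.approx(-0.0125, rel=0.10)

    def test_two_breakpoints_on_three_segment_series(self):
        path = piecewise_logit_path(-2.0, [0.025, -0.0125, 0.05], [0, 50, 100, 150],
                                    150)
        df = noiseless_counts([path], np.arange(0, 151))
        fit = inf.fit_segmented(df, 2)
        assert abs(fit.breakpoint_estimates[0] - 50) <= 2
        assert abs(fit.breakpoint_estimates[1] - 100) <= 2

    def test_neutral_noisy_series_slopes_near_zero(self):
        rng = np.random.default_rng(3)
        times = np.arange(0, 60, 2)
        frames = []
        for j in range(10):
            y = rng.binomial(80, 0.4, size=len(times))
            frames.append(counts_frame([j] * len(times), times, [80] * len(times), y))
        fit = inf.fit_segmented(pd.concat(frames), 1)
        for S, se in fit.S_per_segment:
            assert abs(S) < 2 * se + 1e-12

    def test_breakpoint_intervals_bracket_estimate(self):
        path = piecewise_logit_path(-1.5, [0.06, -0.02], [0, 40, 90], 90)
        df = noiseless_counts([path], np.arange(0, 91, 1), alleles=2000)
        fit = inf.fit_segmented(df, 1)
        lo, hat, hi = fit.breakpoints[0]
        assert lo <= hat <= hi

    def test_min_segment_rule_enforced(self):
        df = counts_frame([0] * 5, range(5), [50] * 5, [20, 21, 22, 23, 24])
        with pytest.raises(ValueError):
            inf.fit_segmented(df, 1)  # 5 points cannot hold 2 segments of 3


class TestSelectBreakpoints:
    def test_kmax_zero_identical_to_logit_slope(self):
        df = counts_frame([0] * 6, range(6), [100] * 6, [30, 35, 33, 40, 42, 44])
        best = inf.select_breakpoints(df, 0)
        est = inf.logit_slope(df)
        assert best.n_breakpoints == 0
        assert best.S_per_segment[0][0] == pytest.approx(est.S, abs=1e-10)

    def test_loglik_monotone_and_bic_guards_overfitting(self):
        """Log-likelihood non-decreasing in k; BIC picks the true k on clean data."""
        path = piecewise_logit_path(-2.0, [0.05, -0.02], [0, 40, 100], 100)
        rng = np.random.default_rng(1)
        times = np.arange(0, 101, 2)
        frames = []
        for j in range(6):
            y = rng.binomial(100, path[times])
            frames.append(counts_frame([j] * len(times), times, [100] * len(times), y))
        best = inf.select_breakpoints(pd.concat(frames), 3)
        lls = [best.model_scores[k][0] for k in sorted(best.model_scores)]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
        assert best.n_breakpoints == 1
        assert abs(best.breakpoint_estimates[0] - 40) <= 4


class TestInstantaneous:
    @pytest.mark.parametrize("pb,pa,expected", [
        (0.5, 0.6, 0.4),
        (0.2, 0.25, 0.3125),
        (0.37, 0.37, 0.0),
    ])
    def test_point_estimates(self, pb, pa, expected):
        est = inf.instantaneous_S(pb, pa)
        assert est.S_t == pytest.approx(expected)

    def test_boundary_before_frequency_not_estimable(self):
        assert not inf.instantaneous_S(0.0, 0.5).estimable
        assert not inf.instantaneous_S(1.0, 0.5).estimable

    def test_delta_method_standard_error(self):
        """SE against a brute-force Monte Carlo oracle."""
        rng = np.random.default_rng(0)
        nb = na = 400
        pb, pa = 0.4, 0.5
        sims = []
        for _ in range(4000):
            phb = rng.binomial(nb, pb) / nb
            pha = rng.binomial(na, pa) / na
            if 0 < phb < 1:
                sims.append((pha - phb) / (phb * (1 - phb)))
        est = inf.instantaneous_S(pb, pa, nb, na)
        assert est.se == pytest.approx(np.std(sims), rel=0.1)

    def test_dt_scaling(self):
        a = inf.instantaneous_S(0.5, 0.6, dt=10.0)
        assert a.S_t == pytest.approx(0.04)


class TestEnvironment:
    def _series(self, env_pattern, gamma=0.05, T=80, m=200_000):
        times = np.arange(T + 1)
        env = np.array([env_pattern(t) for t in times], dtype=float)
        lp = np.empty(T + 1)
        lp[0] = -1.0
        for i in range(T):
            lp[i + 1] = lp[i] + gamma * env[i]
        p = pg.expit(lp)
        y = np.rint(p * m).astype(int)
        return counts_frame([0] * (T + 1), times, [m] * (T + 1), y,
                            env=env)

    def test_constant_env_falls_back_to_plain_fit(self):
        df = self._series(lambda t: 1.0)
        fit = inf.fit_with_environment(df, 0)
        assert fit.env_flag == "constant"
        assert fit.env_interaction == (0.0, 0.0)
        plain = inf.logit_slope(df)
        assert fit.S_per_segment[0][0] == pytest.approx(plain.S, abs=1e-10)

    def test_alternating_env_recovers_interaction(self):
        """S = 0.05 when env = 1, 0 when env = 0: interaction ~ 0.05."""
        df = self._series(lambda t: float(t % 2 == 0), gamma=0.05)
        fit = inf.fit_with_environment(df, 0)
        gamma, se = fit.env_interaction
        assert gamma == pytest.approx(0.05, abs=max(2 * se, 1e-3))

    def test_env_linear_in_time_flagged(self):
        df = self._series(lambda t: 0.01 * t)
        fit = inf.fit_with_environment(df, 0)
        assert fit.env_flag == "collinear"
        assert fit.env_interaction is None


class TestSFromFit:
    def test_additive_inversion_doubles_S(self):
        fit = inf.SegmentedFit(
            n_breakpoints=0, breakpoints=[], S_per_segment=[(0.025, 0.001)],
            loglik=0.0, bic=0.0, converged=True, n_loci=1, n_obs=2,
            n_alleles=10.0, flagged_loci=[],
        )
        s = inf.s_hat_from_fit(fit, 0.5, p_ref=0.5)
        assert s[0] == pytest.approx(0.05, rel=0.03)

    def test_zero_S_maps_to_zero(self):
        fit = inf.SegmentedFit(
            n_breakpoints=0, breakpoints=[], S_per_segment=[(0.0, 0.001)],
            loglik=0.0, bic=0.0, converged=True, n_loci=1, n_obs=2,
            n_alleles=10.0, flagged_loci=[],
        )
        assert inf.s_hat_from_fit(fit, 0.15, p_ref=0.3)[0] == 0.0

    def test_rare_partially_recessive_inversion(self):
        """S=0.05 at p=0.05, h=0.15 inverts to s ~ 0.27."""
        fit = inf.SegmentedFit(
            n_breakpoints=0, breakpoints=[], S_per_segment=[(0.05, 0.001)],
            loglik=0.0, bic=0.0, converged=True, n_loci=1, n_obs=2,
            n_alleles=10.0, flagged_loci=[],
        )
        s = inf.s_hat_from_fit(fit, 0.15, p_ref=0.05)
        assert s[0] == pytest.approx(0.27, rel=0.02)

    def test_reference_frequency_from_counts(self):
        df = counts_frame([0] * 4, range(4), [100] * 4, [20, 20, 60, 60])
        fit = inf.SegmentedFit(
            n_breakpoints=1, breakpoints=[(1.0, 1.0, 2.0)],
            S_per_segment=[(0.02, 0.01), (0.02, 0.01)],
            loglik=0.0, bic=0.0, converged=True, n_loci=1, n_obs=4,
            n_alleles=400.0, flagged_loci=[],
        )
        s = inf.s_hat_from_fit(fit, 0.5, counts=df)
        # segment references are p=0.2 and p=0.6; both give s ~ 2S
        assert s == pytest.approx([0.04, 0.04], rel=0.05)


class TestJointGain:
    def test_shared_slope_se_shrinks_like_root_J(self):
        """SE from J exchangeable loci ~ single-locus SE / sqrt(J), within 2x."""
        rng = np.random.default_rng(8)
        J = 50
        times = np.arange(0, 40, 2)
        p = pg.expit(-0.5 + 0.02 * times)
        frames = []
        singles = []
        for j in range(J):
            y = rng.binomial(40, p)
            df = counts_frame([j] * len(times), times, [40] * len(times), y)
            frames.append(df)
            est = inf.logit_slope(df)
            if est.estimable:
                singles.append(est.se)
        joint = inf.logit_slope(pd.concat(frames))
        ratio = np.median(singles) / joint.se
        assert np.sqrt(J) / 2 < ratio < np.sqrt(J) * 2
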