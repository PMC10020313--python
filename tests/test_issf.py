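import numpy as np
import pandas as pd
import pytest

import dispersim as ds
from dispersim import synth
from dispersim.issf import is_low_activity, model_aic, apply_standardization, invert_standardization

from conftest import nll_bruteforce


def _fixes(times, xy=None, individual="a"):
    times = pd.to_datetime(times)
    if xy is None:
        xy = [(1000.0 * k, 0.0) for k in range(len(times))]
    return pd.DataFrame(
        {
            "individual": individual,
            "t": times,
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
        }
    )


class TestRegularizeFixes:
    def test_perfect_schedule_kept(self):
        fixes = _fixes(["2021-01-01 00:00", "2021-01-01 04:00", "2021-01-01 08:00"])
        assert len(ds.regularize_fixes(fixes)) == 3

    def test_off_schedule_fix_dropped(self):
        fixes = _fixes(["2021-01-01 00:00", "2021-01-01 04:20"])
        out = ds.regularize_fixes(fixes)
        assert len(out) == 1

    def test_within_tolerance_kept(self):
        fixes = _fixes(["2021-01-01 00:00", "2021-01-01 04:14"])
        assert len(ds.regularize_fixes(fixes)) == 2

    def test_schedule_survives_a_gap(self):
        # a missed fix at 04:00 must not disqualify the rest of the schedule
        fixes = _fixes(["2021-01-01 00:00", "2021-01-01 08:00", "2021-01-01 12:00"])
        assert len(ds.regularize_fixes(fixes)) == 3

    def test_matches_sequential_scan_oracle(self, rng):
        interval = pd.Timedelta(hours=4)
        tol = pd.Timedelta(minutes=15)
        for _ in range(20):
            n = 40
            jitter = rng.uniform(-30, 30, size=n)  # minutes
            keep_mask = rng.uniform(size=n) > 0.2
            t0 = pd.Timestamp("2021-01-01")
            times = [
                t0 + interval * k + pd.Timedelta(minutes=jitter[k])
                for k in range(n)
                if keep_mask[k]
            ]
            fixes = _fixes(times)
            got = ds.regularize_fixes(fixes)["t"].tolist()
            # independent scan: accept when the lag is close to a multiple
            kept = [times[0]]
            for t in times[1:]:
                dt = t - kept[-1]
                k = max(1, round(dt / interval))
                if abs(dt - k * interval) <= tol:
                    kept.append(t)
            assert got == kept

    def test_empty_input(self):
        out = ds.regularize_fixes(_fixes([]))
        assert len(out) == 0


class TestFixesToSteps:
    def test_collinear_fixes_give_cos_ta_one(self):
        fixes = _fixes(
            ["2021-01-01 00:00", "2021-01-01 04:00", "2021-01-01 08:00"],
            xy=[(0, 0), (1000, 0), (2000, 0)],
        )
        steps = ds.fixes_to_steps(fixes)
        assert len(steps) == 2
        assert np.isnan(steps["cos_ta"].iloc[0])
        assert steps["cos_ta"].iloc[1] == pytest.approx(1.0)

    def test_right_angle_turn(self):
        fixes = _fixes(
            ["2021-01-01 00:00", "2021-01-01 04:00", "2021-01-01 08:00"],
            xy=[(0, 0), (1000, 0), (1000, 1000)],
        )
        steps = ds.fixes_to_steps(fixes)
        assert steps["cos_ta"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_gap_breaks_heading_chain(self):
        fixes = _fixes(
            ["2021-01-01 00:00", "2021-01-01 04:00", "2021-01-01 12:00", "2021-01-01 16:00"],
            xy=[(0, 0), (1000, 0), (3000, 0), (4000, 0)],
        )
        steps = ds.fixes_to_steps(fixes)
        # the 04:00 -> 12:00 pair is not a 4-h step; the step after the gap
        # has no defined previous heading
        assert len(steps) == 2
        assert np.isnan(steps["cos_ta"].iloc[1])

    def test_zero_length_steps_dropped(self):
        fixes = _fixes(
            ["2021-01-01 00:00", "2021-01-01 04:00", "2021-01-01 08:00"],
            xy=[(0, 0), (0, 0), (1000, 0)],
        )
        steps = ds.fixes_to_steps(fixes)
        assert len(steps) == 1
        assert steps["sl"].iloc[0] == pytest.approx(1000.0)


class TestFitGamma:
    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ds.fit_gamma([1.0, -2.0, 3.0])
        with pytest.raises(ValueError):
            ds.fit_gamma([5.0])
        with pytest.raises(ValueError):
            ds.fit_gamma([5.0, 5.0, 5.0])

    def test_mle_beats_moment_matching(self, rng):
        x = rng.gamma(0.6, 1500.0, size=2000)
        fit = ds.fit_gamma(x)
        from scipy import stats

        k_mm = x.mean() ** 2 / x.var()
        theta_mm = x.var() / x.mean()
        ll_mle = stats.gamma.logpdf(x, a=fit.k, scale=fit.theta).sum()
        ll_mm = stats.gamma.logpdf(x, a=k_mm, scale=theta_mm).sum()
        assert ll_mle >= ll_mm


class TestSampleRandomSteps:
    def test_count_and_geometry(self, rng):
        gamma = ds.GammaStepLength(0.37, 6308.0)
        steps = ds.sample_random_steps((100.0, 200.0), 0.5, 24, gamma, rng)
        assert len(steps) == 24
        np.testing.assert_allclose(
            np.hypot(steps.x_end - 100.0, steps.y_end - 200.0), steps.sl
        )

    def test_uniform_angles_and_gamma_moments(self, rng):
        gamma = ds.GammaStepLength(0.37, 6308.0)
        n = 100_000
        steps = ds.sample_random_steps((0.0, 0.0), 1.234, n, gamma, rng)
        # E[cos U] = 0 with var 1/2 for U ~ U(-pi, pi)
        assert abs(steps.cos_ta.mean()) < 3 * np.sqrt(0.5 / n)
        se_sl = gamma.theta * np.sqrt(gamma.k / n)
        assert abs(steps.sl.mean() - gamma.mean) < 3 * se_sl


class TestBuildStrata:
    @pytest.fixture
    def strata(self, small_stack, rng):
        fixes = _fixes(
            pd.date_range("2021-01-01 06:00", periods=12, freq="4h"),
            xy=[(900 + 80 * k, 900 + 50 * (k % 3)) for k in range(12)],
        )
        steps = ds.fixes_to_steps(fixes)
        gamma = ds.GammaStepLength(1.0, 60.0)
        return ds.build_strata(steps, small_stack, n_random=24, gamma=gamma, rng=rng)

    def test_counts(self, strata):
        assert strata["stratum"].nunique() == 10  # first step has no heading
        assert (strata.groupby("stratum").size() == 25).all()
        assert (strata.groupby("stratum")["case"].sum() == 1).all()

    def test_low_activity_from_clock(self, strata):
        assert is_low_activity(pd.Timestamp("2021-01-01 10:00")) == 1
        assert is_low_activity(pd.Timestamp("2021-01-01 18:00")) == 0
        by_hour = strata.groupby(strata["t_start"].dt.hour)["low_activity"].unique()
        for hour, vals in by_hour.items():
            assert list(vals) == [1 if 9 <= hour < 17 else 0]

    def test_habitat_extracted_for_every_step(self, strata, small_stack):
        for name in small_stack.names:
            assert np.isfinite(strata[name]).all()


class TestStandardize:
    def test_pooled_mean_zero_sd_one(self, rng):
        frame = synth.simulate_strata(50, {"a": 0.5}, n_random=4, rng=rng)
        frame["a"] = frame["a"] * 3 + 7
        out, table = ds.standardize(frame, ["a"])
        assert abs(out["a"].mean()) < 1e-10
        assert abs(out["a"].std(ddof=0) - 1) < 1e-10
        assert table["a"][0] == pytest.approx(7, abs=0.5)

    def test_only_named_columns_touched(self, rng):
        frame = synth.simulate_strata(20, {"a": 0.5}, n_random=4, rng=rng)
        frame["low_activity"] = 1.0
        out, _ = ds.standardize(frame, ["a"])
        assert (out["low_activity"] == 1.0).all()

    def test_round_trip(self, rng):
        frame = synth.simulate_strata(20, {"a": 0.5}, n_random=4, rng=rng)
        raw = frame["a"].copy()
        out, table = ds.standardize(frame, ["a"])
        new = apply_standardization(pd.DataFrame({"a": raw}), table)
        back = invert_standardization(new, table)
        np.testing.assert_allclose(back["a"], raw, rtol=1e-12)

    def test_zero_sd_raises_with_name(self, rng):
        frame = synth.simulate_strata(20, {"a": 0.5}, n_random=4, rng=rng)
        frame["const"] = 1.0
        with pytest.raises(ValueError, match="const"):
            ds.standardize(frame, ["const"])


class TestScoresAndProbabilities:
    def test_selection_score_closed_forms(self):
        assert ds.selection_score([0.0, 0.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert ds.selection_score([1.0, 2.0], [0.0, 0.0]) == pytest.approx(1.0)
        assert ds.selection_score([np.log(2)], [1.0]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            ds.selection_score([1.0], [1.0, 2.0])

    def test_stratum_probabilities(self):
        p = ds.stratum_probabilities([0.0], np.zeros((25, 1)))
        np.testing.assert_allclose(p, 0.04)
        p = ds.stratum_probabilities([1.0], np.log([[2.0], [1.0]]))
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_overflow_guard(self):
        p = ds.stratum_probabilities([1.0], np.array([[800.0], [-800.0], [795.0]]))
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_sum_to_one_any_beta(self, rng):
        for _ in range(20):
            X = rng.normal(size=(rng.integers(2, 30), 3)) * 10
            beta = rng.normal(size=3) * 5
            assert abs(ds.stratum_probabilities(beta, X).sum() - 1) < 1e-12


class TestClogitLikelihood:
    def test_null_closed_form(self, rng):
        frame = synth.simulate_strata(40, {"a": 0.3}, n_random=24, rng=rng)
        value, _ = ds.clogit_negloglik([0.0], frame, ["a"])
        assert value == pytest.approx(40 * np.log(25), rel=1e-12)

    def test_balanced_stratum_has_zero_gradient(self):
        frame = pd.DataFrame(
            {
                "stratum": [0, 0, 0],
                "case": [1, 0, 0],
                "a": [2.0, 1.0, 3.0],  # realized value equals candidate mean
            }
        )
        _, grad = ds.clogit_negloglik([0.0], frame, ["a"])
        assert grad[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            frame = synth.simulate_strata(
                int(rng.integers(1, 6)),
                {"a": 0.5, "b": -0.2},
                n_random=int(rng.integers(1, 4)),
                rng=rng,
            )
            beta = rng.normal(size=2)
            value, _ = ds.clogit_negloglik(beta, frame, ["a", "b"])
            assert value == pytest.approx(nll_bruteforce(frame, ["a", "b"], beta), abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        frame = synth.simulate_strata(30, {"a": 0.5, "b": -0.2}, n_random=5, rng=rng)
        terms = ["a", "b", "a:b"]
        beta = np.array([0.3, -0.4, 0.1])
        _, grad = ds.clogit_negloglik(beta, frame, terms)
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            up, _ = ds.clogit_negloglik(beta + e, frame, terms)
            dn, _ = ds.clogit_negloglik(beta - e, frame, terms)
            fd = (up - dn) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestFitClogit:
    def test_duplicating_strata_keeps_estimates_doubles_loglik(self, rng):
        frame = synth.simulate_strata(200, {"a": 0.8, "b": -0.3}, n_random=9, rng=rng)
        double = pd.concat(
            [frame, frame.assign(stratum=frame["stratum"] + 10_000)], ignore_index=True
        )
        m1 = ds.fit_clogit(frame, ["a", "b"])
        m2 = ds.fit_clogit(double, ["a", "b"])
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-6)
        assert m2.loglik == pytest.approx(2 * m1.loglik, rel=1e-8)

    def test_invariance_to_standardization(self, rng):
        frame = synth.simulate_strata(400, {"a": 0.8}, n_random=9, rng=rng)
        frame["a"] = frame["a"] * 2.5 + 4.0
        m_raw = ds.fit_clogit(frame, ["a"])
        std, table = ds.standardize(frame, ["a"])
        m_std = ds.fit_clogit(std, ["a"], standardization=table)
        sd = table["a"][1]
        assert m_std.beta[0] == pytest.approx(m_raw.beta[0] * sd, abs=1e-6)
        assert m_std.beta_raw()["a"] == pytest.approx(m_raw.beta[0], abs=1e-9)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        frame = synth.simulate_strata(500, {"a": -0.5, "b": 1.0}, n_random=14, rng=rng)
        mine = ds.fit_clogit(frame, ["a", "b"])
        sm = ConditionalLogit(
            frame["case"].to_numpy(),
            frame[["a", "b"]].to_numpy(),
            groups=frame["stratum"].to_numpy(),
        ).fit(disp=0)
        np.testing.assert_allclose(mine.beta, sm.params, atol=1e-4)
        np.testing.assert_allclose(mine.se().values, sm.bse, rtol=1e-3)

    def test_stratum_constant_term_rejected(self, rng):
        frame = synth.simulate_strata(20, {"a": 0.5}, n_random=4, rng=rng)
        frame["low_activity"] = np.repeat(
            np.arange(20) % 2, 5
        ).astype(float)  # constant within stratum
        with pytest.raises(ValueError, match="low_activity"):
            ds.fit_clogit(frame, ["a", "low_activity"])

    def test_model_json_round_trip(self, rng):
        frame = synth.simulate_strata(100, {"a": 0.5}, n_random=9, rng=rng)
        m = ds.fit_clogit(
            frame,
            ["a"],
            gamma=ds.GammaStepLength(0.37, 6308.0),
            standardization={"a": (0.0, 1.0)},
        )
        back = ds.MovementModel.from_json(m.to_json())
        np.testing.assert_allclose(back.beta, m.beta)
        assert back.terms == m.terms
        assert back.gamma == m.gamma
        np.testing.assert_allclose(back.vcov.values, m.vcov.values)


class TestForwardSelect:
    def test_no_candidates_returns_base(self, rng):
        frame = synth.simulate_strata(200, {"a": 0.5}, n_random=9, rng=rng)
        model, trace = ds.forward_select(frame, ["a"], [])
        assert model.terms == ["a"]
        assert len(trace) == 1

    def test_final_aic_never_worse_than_base(self, rng):
        frame = synth.simulate_strata(
            150, {"a": 0.5, "b": -0.5}, n_random=9, rng=rng, columns=["c"]
        )
        base = ds.fit_clogit(frame, ["a", "b"])
        model, trace = ds.forward_select(frame, ["a", "b"], ["a:b", "a:c", "b:c"])
        assert model_aic(model) <= model_aic(base)
        assert (trace["aic"].diff().dropna() < 0).all()

    def test_overlapping_candidates_rejected(self, rng):
        frame = synth.simulate_strata(50, {"a": 0.5}, n_random=4, rng=rng)
        with pytest.raises(ValueError):
            ds.forward_select(frame, ["a"], ["a"])


class TestKfoldCV:
    def test_perfect_predictor_gives_rank_one(self, rng):
        # realized steps carry an overwhelmingly larger covariate value
        n, m = 60, 10
        frame = pd.DataFrame(
            {
                "stratum": np.repeat(np.arange(n), m),
                "case": np.tile([1] + [0] * (m - 1), n),
                "a": np.tile([5.0] + [0.0] * (m - 1), n) + rng.normal(0, 0.01, n * m),
            }
        )
        cv = ds.kfold_cv(frame, ["a"], k=3, reps=2, rng=rng)
        freq = cv.rank_freq
        assert freq.loc[1] > 0.95 * freq.sum()
        assert cv.rs_realized[0] < -0.5

    def test_null_model_rank_frequencies_uniform(self, rng):
        frame = synth.simulate_strata(150, {"a": 0.0}, n_random=9, rng=rng)
        cv = ds.kfold_cv(frame, ["a"], k=3, reps=3, rng=rng)
        lo, hi = cv.rs_random[1], cv.rs_random[2]
        assert lo < 0 < hi
        # realized ranks should look uniform too: no rank dominates
        freq = cv.rank_freq / cv.rank_freq.sum()
        assert freq.max() < 3.0 / 10

    def test_too_few_strata_raises(self, rng):
        frame = synth.simulate_strata(3, {"a": 0.5}, n_random=4, rng=rng)
        with pytest.raises(ValueError):
            ds.kfold_cv(frame, ["a"], k=5, reps=1, rng=rng)
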