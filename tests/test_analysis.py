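"""Kernel summaries, group statistics, consistency control, session QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pulsekernel as pk
from pulsekernel.analysis import InsufficientDataError, SessionStats


class TestKernelSummaries:
    def test_equal_weights_have_zero_slope_and_energy(self):
        w = np.full(7, 1 / np.sqrt(7))
        slope, _ = pk.kernel_slope(w)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert pk.kernel_energy(w) == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_ramp_recovers_its_rate(self):
        c = 0.07
        w = 0.5 - c * np.arange(7)
        slope, intercept = pk.kernel_slope(w)
        assert slope == pytest.approx(-c)
        assert intercept == pytest.approx(0.5 + c)

    def test_late_humped_shape_has_positive_slope(self):
        w = pk.normalize_kernel([0.1, 0.2, 0.3, 0.45, 0.55, 0.5, 0.35])
        slope, _ = pk.kernel_slope(w)
        assert slope > 0

    def test_energy_of_single_spike(self):
        assert pk.kernel_energy([1, 0, 0, 0, 0, 0, 0]) == pytest.approx(6 / 7)

    @given(
        shift=st.floats(-2, 2),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 100),
    )
    def test_energy_shift_invariance_and_summary_scale_invariance(
        self, shift, scale, seed
    ):
        w = np.random.default_rng(seed).normal(size=7)
        assert pk.kernel_energy(w + shift) == pytest.approx(pk.kernel_energy(w))
        if np.linalg.norm(w) > 1e-6:
            a = pk.summarize_kernel(pk.normalize_kernel(w))
            b = pk.summarize_kernel(pk.normalize_kernel(scale * w))
            assert a.slope == pytest.approx(b.slope)
            assert a.energy == pytest.approx(b.energy)


class TestGroupStatistics:
    def test_all_positive_slopes_give_exact_binomial_p(self):
        slopes = {"late": np.abs(np.random.default_rng(0).normal(size=20)) + 0.01,
                  "flat": np.random.default_rng(1).normal(size=20)}
        gs = pk.group_statistics(slopes)
        assert gs.sign_test_p["late"] == pytest.approx(2 * 0.5**20)

    def test_identical_groups_yield_f_zero(self):
        g = np.array([0.1, -0.2, 0.05, 0.3, -0.1, 0.15])
        gs = pk.group_statistics({"a": g, "b": g.copy(), "c": g.copy()})
        assert gs.anova_p == pytest.approx(1.0)

    def test_doubled_sd_detected_by_bartlett(self):
        detected = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            gs = pk.group_statistics(
                {"flat": rng.normal(0, 0.10, 80), "late": rng.normal(0, 0.05, 80)}
            )
            detected += gs.bartlett_p[("flat", "late")] < 0.05
        assert detected / n_rep >= 0.95

    def test_signed_rank_variant_available(self):
        rng = np.random.default_rng(5)
        slopes = {"a": rng.normal(0.1, 0.05, 30), "b": rng.normal(-0.1, 0.05, 30)}
        gs = pk.group_statistics(slopes, sign_test="signed-rank")
        assert 0 <= gs.sign_test_p["a"] <= 1

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            pk.group_statistics({"a": [0.1] * 3, "b": [0.2] * 10})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pk.group_statistics({"a": [], "b": [0.1] * 10})


class TestThresholdCorrelations:
    @staticmethod
    def _table(rng, n=40, rho=1.0):
        energy = rng.uniform(0, 0.5, n)
        thr = rho * energy + (1 - abs(rho)) * rng.normal(0, 0.1, n)
        return pd.DataFrame(
            {
                "condition": ["flat"] * n,
                "threshold": thr,
                "slope": rng.normal(0, 0.1, n),
                "energy": energy,
            }
        )

    def test_perfect_linear_association(self):
        df = self._table(np.random.default_rng(0), rho=1.0)
        res = pk.threshold_weighting_correlation(df)
        assert res["flat"]["energy"]["r"] == pytest.approx(1.0)

    def test_permuted_pairing_centers_at_zero(self):
        rng = np.random.default_rng(1)
        df = self._table(rng, rho=1.0)
        rs = []
        for _ in range(1000):
            shuf = df.copy()
            shuf["threshold"] = rng.permutation(shuf["threshold"].to_numpy())
            rs.append(pk.threshold_weighting_correlation(shuf)["flat"]["energy"]["r"])
        assert abs(np.mean(rs)) < 0.02

    def test_high_energy_observers_raise_threshold(self):
        # uniform-kernel vs concentrated-kernel observers at matched norm:
        # concentrating weight on few pulses discards evidence, raising the
        # 75% threshold along with the kernel energy
        rows = []
        for i, shape in enumerate(
            [np.ones(7), np.array([1.0, 1, 1, 1, 1, 1, 0.2]),
             np.array([1.0, 1, 1, 0.2, 0.2, 0.2, 0.2]),
             np.array([1.0, 0.7, 0.2, 0.1, 0.1, 0.1, 0.1]),
             np.array([1.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])]
        ):
            rng = np.random.default_rng(200 + i)
            trials = pk.generate_session(pk.StimulusConfig(), 4000, rng)
            kernel = 6.0 * shape / np.linalg.norm(shape)
            ch = pk.simulate_linear_choices(
                trials, pk.LinearObserver(kernel=kernel), rng
            )
            z = pk.zscore_strengths([t.net_strength for t in trials])
            fit = pk.fit_psychometric(z, ch)
            rows.append(
                {
                    "condition": "flat",
                    "threshold": fit.threshold75,
                    "slope": 0.0,
                    "energy": pk.kernel_energy(pk.normalize_kernel(kernel)),
                }
            )
        rows[0]["slope"] = 1e-6  # avoid a degenerate constant column
        df = pd.DataFrame(rows)
        res = pk.threshold_weighting_correlation(df)
        assert res["flat"]["energy"]["r"] > 0

    def test_too_few_sessions_rejected(self):
        df = self._table(np.random.default_rng(2), n=3)
        with pytest.raises(InsufficientDataError):
            pk.threshold_weighting_correlation(df)


def _observer_cohort(observer_fn, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    trials = pk.generate_session(pk.StimulusConfig(), n, rng)
    choices = observer_fn(trials, rng)
    return pk.attach_choices(trials, choices), choices


class TestConsistencyAnalysis:
    def test_perfect_integrator_aces_both_groups(self):
        trials, _ = _observer_cohort(
            lambda t, r: pk.simulate_accumulator_choices(
                t, pk.AccumulatorObserver(), r
            ),
            seed=41,
        )
        res = pk.consistency_analysis(trials)
        assert res.inconsistent_accuracy == 1.0
        assert res.consistent_accuracy == 1.0

    def test_extrema_observer_fails_inconsistent_trials(self):
        trials, _ = _observer_cohort(pk.simulate_extrema_choices, seed=43)
        res = pk.consistency_analysis(trials)
        assert res.inconsistent_accuracy == 0.0
        assert res.consistent_accuracy == 1.0

    def test_bounded_accumulator_sits_between(self):
        trials, _ = _observer_cohort(
            lambda t, r: pk.simulate_accumulator_choices(
                t, pk.AccumulatorObserver(bound=0.4, noise_sd=0.1), r
            ),
            n=8000,
            seed=47,
        )
        res = pk.consistency_analysis(trials)
        assert res.inconsistent_accuracy < res.consistent_accuracy

    def test_matched_sets_are_disjoint_and_cis_bracket_accuracy(self):
        trials, _ = _observer_cohort(pk.simulate_extrema_choices, seed=53)
        res = pk.consistency_analysis(trials)
        assert res.n_consistent == res.n_inconsistent
        lo, hi = res.consistent_ci
        assert lo <= res.consistent_accuracy <= hi

    def test_too_few_inconsistent_trials_raises(self):
        trials, _ = _observer_cohort(pk.simulate_extrema_choices, n=30, seed=59)
        with pytest.raises(InsufficientDataError):
            pk.consistency_analysis(trials, min_inconsistent=1000)


def _stats(sid, subject="M1", n=600, acc=0.95, thr=1.0):
    return SessionStats(
        session_id=sid,
        subject_id=subject,
        condition="flat",
        n_trials=n,
        strong_accuracy=acc,
        threshold=thr,
    )


class TestSessionQC:
    def test_constructed_cohort_keeps_six_of_ten(self):
        # cohort thresholds have median 1.00 and unscaled MAD 0.01; s3 sits
        # 3 MADs above the median, s8/s9 are short sessions, s1 has 80%
        # accuracy on the strongest motion values
        thrs = [1.00, 1.01, 0.99, 1.03, 0.98, 1.00, 1.01, 0.99]
        sessions = [_stats(f"s{i}", thr=t) for i, t in enumerate(thrs)]
        sessions += [_stats("s8", n=200), _stats("s9", n=200)]
        sessions[1] = _stats("s1", acc=0.80, thr=1.01)
        results = pk.session_qc(sessions)
        assert sum(r.included for r in results) == 6
        by_id = {r.session_id: r for r in results}
        assert by_id["s8"].reasons == ("too_few_trials",)
        assert by_id["s1"].reasons == ("low_strong_accuracy",)
        assert by_id["s3"].reasons == ("threshold_outlier",)

    def test_compliant_cohort_fully_included(self):
        results = pk.session_qc([_stats(f"s{i}") for i in range(5)])
        assert all(r.included for r in results)

    def test_multiple_violations_all_recorded(self):
        sessions = [_stats(f"s{i}") for i in range(4)]
        sessions.append(_stats("bad", n=100, acc=0.5))
        res = {r.session_id: r for r in pk.session_qc(sessions)}
        assert set(res["bad"].reasons) == {"too_few_trials", "low_strong_accuracy"}

    def test_order_independent(self):
        sessions = [_stats(f"s{i}", thr=1.0 + 0.05 * i) for i in range(8)]
        sessions.append(_stats("out", thr=5.0))
        a = {r.session_id: r.included for r in pk.session_qc(sessions)}
        b = {r.session_id: r.included for r in pk.session_qc(sessions[::-1])}
        assert a == b and not a["out"]

    def test_mad_rule_skipped_with_warning_for_small_subjects(self):
        sessions = [_stats("s0", subject="H1", thr=1.0), _stats("s1", subject="H1", thr=99.0)]
        with pytest.warns(UserWarning, match="MAD rule skipped"):
            results = pk.session_qc(sessions)
        assert all(r.included for r in results)
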