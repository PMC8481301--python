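"""Agreement statistics: paired TOST, Bland-Altman, repeatability, power,
and the synthetic two-device study."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eitvent as ev
from eitvent.stats import (
    P_FLOOR,
    StudyConfig,
    bland_altman,
    posthoc_power,
    repeatability_variability,
    run_study,
    tost_equivalence,
)


class TestTOST:
    def test_equivalence_declared_under_true_equality(self, rng):
        a = rng.normal(10.0, 0.5, 50)
        b = a + rng.normal(0.0, 0.1, 50)
        assert tost_equivalence(a, b, margin=1.0) < 0.05

    def test_boundary_mean_difference_gives_p_half(self, rng):
        b = rng.normal(0.0, 0.5, 5000)
        a = b + 1.0  # mean difference exactly at the margin
        # the binding one-sided t statistic is ~0 -> p ~ 0.5
        assert tost_equivalence(a, b, margin=1.0) == pytest.approx(0.5, abs=0.05)

    def test_invalid_margin_rejected(self):
        with pytest.raises(ValueError):
            tost_equivalence([1, 2, 3], [1, 2, 3], margin=0.0)

    def test_zero_variance_inside_margin_flagged_floor(self):
        p = tost_equivalence([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], margin=0.5)
        assert p == P_FLOOR

    def test_matches_statsmodels_paired_tost(self, rng):
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.1, 1.0, 30)
        ours = tost_equivalence(a, b, margin=0.8)
        theirs = sm.ttost_paired(a, b, -0.8, 0.8)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_type_i_error_at_margin_boundary(self):
        """With the true mean difference exactly at the margin, the TOST
        rejects at most alpha + 2% of the time (5000 replicates)."""
        rng = np.random.default_rng(42)
        n, margin, alpha = 20, 0.5, 0.05
        d = rng.normal(margin, 1.0, size=(5000, n))
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        se = sd / np.sqrt(n)
        from scipy import stats as sstats
        p_lower = sstats.t.sf((mean + margin) / se, n - 1)
        p_upper = sstats.t.cdf((mean - margin) / se, n - 1)
        reject = np.maximum(p_lower, p_upper) < alpha
        # cross-check the vectorised replicate against the implementation
        p_one = tost_equivalence(d[0], np.zeros(n), margin)
        assert p_one == pytest.approx(max(p_lower[0], p_upper[0]), abs=1e-12)
        assert reject.mean() <= alpha + 0.02


class TestBlandAltman:
    def test_identical_measurements_collapse_limits(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.bias == 0.0 and s.loa_lower == 0.0 and s.loa_upper == 0.0

    def test_hand_computed_example(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([2.0, 0.0, -2.0])
        s = bland_altman(a, b)
        assert s.bias == pytest.approx(0.0)
        assert s.sd_diff == pytest.approx(2.0)
        assert s.loa_lower == pytest.approx(-3.92)
        assert s.loa_upper == pytest.approx(3.92)

    def test_translation_invariance(self, rng):
        a = rng.normal(5, 1, 20)
        b = rng.normal(5, 1, 20)
        s1 = bland_altman(a, b)
        s2 = bland_altman(a + 100, b + 100)
        assert s1.bias == pytest.approx(s2.bias)
        assert s1.loa_upper == pytest.approx(s2.loa_upper)

    def test_limits_contain_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(314)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        s = bland_altman(a, b)
        inside = (s.diffs >= s.loa_lower) & (s.diffs <= s.loa_upper)
        assert 0.93 <= inside.mean() <= 0.97


class TestRepeatability:
    def test_identical_repetitions_give_zero(self):
        rec = repeatability_variability([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_array_equal(rec.values, 0.0)

    def test_hand_computed_percentage(self):
        rec = repeatability_variability([9.0], [11.0])
        assert rec.values[0] == pytest.approx(20.0)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance_and_symmetry(self, scale):
        m1 = np.array([1.0, 4.0, 9.0])
        m2 = np.array([1.5, 3.0, 10.0])
        base = repeatability_variability(m1, m2).values
        np.testing.assert_allclose(
            repeatability_variability(m1 * scale, m2 * scale).values, base,
            rtol=1e-9)
        np.testing.assert_allclose(
            repeatability_variability(m2, m1).values, base, rtol=1e-12)

    def test_zero_average_recorded_missing(self):
        rec = repeatability_variability([0.0, 1.0], [0.0, 1.0])
        assert rec.n_missing == 1
        assert np.isnan(rec.values[0])


class TestPower:
    def test_huge_margin_gives_full_power(self):
        assert posthoc_power(50, 0.05, 0.0, 1.0, margin=1e6) == pytest.approx(
            1.0, abs=1e-9)

    def test_power_increases_with_sample_size(self):
        p3 = posthoc_power(3, 0.05, 0.0, 1.0, 1.0)
        p50 = posthoc_power(50, 0.05, 0.0, 1.0, 1.0)
        assert p50 > p3

    def test_closed_form_matches_monte_carlo(self):
        """Noncentral-t power within 0.01 of 10,000-replicate simulation at
        n=50, alpha=0.05, zero true difference, sd equal to the margin."""
        n, alpha, sd, margin = 50, 0.05, 1.0, 1.0
        analytic = posthoc_power(n, alpha, 0.0, sd, margin)
        rng = np.random.default_rng(2024)
        d = rng.normal(0.0, sd, size=(10_000, n))
        mean = d.mean(axis=1)
        se = d.std(axis=1, ddof=1) / np.sqrt(n)
        from scipy import stats as sstats
        tcrit = sstats.t.ppf(1 - alpha, n - 1)
        reject = ((mean + margin) / se > tcrit) & ((mean - margin) / se < -tcrit)
        assert analytic == pytest.approx(reject.mean(), abs=0.01)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power(10, 1.5, 0.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def small_report():
    cfg = StudyConfig(n_subjects=5, refinement=1, frame_rate=10.0, seed=7)
    return run_study(cfg)


class TestRunStudy:
    def test_report_row_bookkeeping(self, small_report):
        df = small_report.measurements
        assert len(df) == 5 * 2 * 2          # subjects x devices x repetitions
        assert small_report.failures == []

    def test_identical_devices_with_shared_seeds_have_zero_bias(self, mesh2,
                                                                greit2):
        ph = ev.PhantomConfig()
        proto = ev.BreathingProtocol(frame_rate=10.0)
        sim = ev.PhantomSimulator(ph, proto, mesh=mesh2)
        seqs = ev.emulate_two_devices(ph, proto, (9, 9, 9, 9), simulator=sim)
        spiro = ev.volume_waveform(proto)
        idx_a = ev.analyze_recording(seqs[0], spiro, greit2)
        idx_b = ev.analyze_recording(seqs[1], spiro, greit2)
        for name in ev.VentilationIndices.INDEX_NAMES:
            assert getattr(idx_a, name) == getattr(idx_b, name)

    def test_equivalence_declared_for_right_fraction(self, small_report):
        """Both devices measure the same phantoms, so the right-fraction
        TOST with margin 0.1 must declare equivalence."""
        a = small_report.measurements.query(
            "device == 'A' and repetition == 1").sort_values("subject")
        b = small_report.measurements.query(
            "device == 'B' and repetition == 1").sort_values("subject")
        p = tost_equivalence(a.right_fraction.to_numpy(),
                             b.right_fraction.to_numpy(), margin=0.1)
        assert p < 0.05

    def test_agreement_summaries_cover_all_indices(self, small_report):
        for name in ev.VentilationIndices.INDEX_NAMES:
            assert name in small_report.agreement
            s = small_report.agreement[name]
            assert s.loa_lower <= s.bias <= s.loa_upper
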