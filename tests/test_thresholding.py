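import numpy as np
import pytest

import erptrials as et
from erptrials.io import ValidationError
from erptrials.thresholding import ThresholdSweep

from conftest import component_specs


class TestResidualFlatness:
    def test_zero_waveform(self):
        assert et.residual_flatness(np.zeros(10)) == 0.0

    def test_sum_of_absolutes(self):
        assert et.residual_flatness([1.0, -2.0, 3.0]) == 6.0

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=30)
        assert et.residual_flatness(2.5 * w) == pytest.approx(
            2.5 * et.residual_flatness(w))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            et.residual_flatness([])


class TestCurvatureSign:
    def test_positive_bump(self):
        bump = np.sin(np.pi * np.arange(30) / 29)
        assert et.curvature_sign(bump, rate=100.0) == 1

    def test_negative_bump(self):
        bump = -np.sin(np.pi * np.arange(30) / 29)
        assert et.curvature_sign(bump, rate=100.0) == -1

    def test_flat_line_is_zero(self):
        assert et.curvature_sign(np.zeros(30), rate=100.0) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            et.curvature_sign([1.0, 2.0], rate=100.0)


def _separable_setup():
    """Trials that either contain the template exactly or are near-flat, so
    the S distribution is bimodal and the right classification is obvious."""
    rng = np.random.default_rng(6)
    n_pre, rate = 100, 100.0
    tpl = np.sin(np.pi * np.arange(50) / 49) * 10.0
    present = np.array([True] * 12 + [False] * 8)
    rows = []
    for p in present:
        row = rng.normal(scale=0.05, size=300)
        if p:
            i0 = n_pre + 10
            row[i0:i0 + 50] += tpl
        rows.append(row)
    tm = et.TrialMatrix(np.asarray(rows), rate, n_pre, np.arange(20), (),
                        np.arange(20.0) * 2 + 2)
    spec = et.ComponentSpec("P200", 1, (0.1, 0.6), 0.35)
    template = et.Template(tpl.copy(), (0.1, 0.6), 20)
    return tm, spec, template, present


class TestThresholdSweep:
    def test_default_grid_has_five_rows_and_monotone_counts(self):
        tm, spec, template, _ = _separable_setup()
        sw = et.threshold_sweep(tm, template, spec)
        assert sw.thresholds.size == 5
        assert np.all(np.diff(sw.n_efficient) >= 0)
        assert np.all(sw.n_efficient + sw.n_residual == tm.n_trials)

    def test_empty_residual_reports_missing_not_zero(self):
        tm, spec, template, _ = _separable_setup()
        sw = et.threshold_sweep(tm, template, spec,
                                thresholds=(0.5, 0.99, 1.0))
        assert sw.n_residual[-1] == 0
        assert np.isnan(sw.flatness[-1])
        assert sw.residual_avg[-1] is None

    def test_threshold_one_efficient_average_is_grand_average(self):
        tm, spec, template, _ = _separable_setup()
        sw = et.threshold_sweep(tm, template, spec, thresholds=(0.5, 1.0))
        i0, i1 = tm.window_columns(spec.window)
        grand = tm.data[:, i0:i1].mean(axis=0)
        assert np.allclose(sw.efficient_avg[-1], grand)

    def test_unsorted_grid_rejected(self):
        tm, spec, template, _ = _separable_setup()
        with pytest.raises(ValidationError):
            et.threshold_sweep(tm, template, spec, thresholds=(0.9, 0.5))


class TestSelectOptimalThreshold:
    def _sweep(self, thresholds, flatness, curvature=None):
        n = len(thresholds)
        return ThresholdSweep(
            "P", np.asarray(thresholds, dtype=float),
            np.arange(n), np.arange(n)[::-1],
            [None] * n, [None] * n, np.asarray(flatness, dtype=float),
            curvature or [1] * n, 0)

    def test_argmin_rule(self):
        spec = et.ComponentSpec("P", 1, (0.1, 0.3), 0.2)
        thr, _ = et.select_optimal_threshold(
            self._sweep((0.5, 0.6, 0.7), [5.0, 2.0, 3.0]), spec)
        assert thr == 0.6

    def test_tie_goes_to_lowest_threshold(self):
        spec = et.ComponentSpec("P", 1, (0.1, 0.3), 0.2)
        thr, _ = et.select_optimal_threshold(
            self._sweep((0.5, 0.6), [2.0, 2.0]), spec)
        assert thr == 0.5

    def test_all_missing_is_error(self):
        spec = et.ComponentSpec("P", 1, (0.1, 0.3), 0.2)
        with pytest.raises(ValidationError):
            et.select_optimal_threshold(
                self._sweep((0.5, 0.6), [np.nan, np.nan]), spec)

    def test_reversal_candidate_reported(self):
        spec = et.ComponentSpec("P", 1, (0.1, 0.3), 0.2)
        thr, report = et.select_optimal_threshold(
            self._sweep((0.5, 0.6, 0.7), [5.0, 2.0, 3.0],
                        curvature=[1, 0, -1]), spec)
        assert report["curvature_reversal_threshold"] == 0.6
        assert report["rules_disagree"] is False

    def test_separable_groups_recovered_exactly(self):
        """With bimodal S (exact template vs near-flat trials), the chosen
        threshold splits the trials exactly as the ground truth does."""
        tm, spec, template, present = _separable_setup()
        ts = et.trial_similarity(tm, template, 0)
        grid = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
        sw = et.threshold_sweep(tm, template, spec, thresholds=grid, ts=ts)
        thr, _ = et.select_optimal_threshold(sw, spec)
        cls = et.classify_trials(ts, thr, spec.name)
        assert set(cls.efficient) == set(np.flatnonzero(present))
        # brute-force: no grid threshold classifies better
        errors = [np.sum((ts.S <= t) != present) for t in grid]
        assert np.sum((ts.S <= thr) != present) == min(errors) == 0


class TestExclusiveTrials:
    def _cls(self, name, efficient, total=6):
        eff = np.asarray(sorted(efficient), dtype=int)
        res = np.asarray(sorted(set(range(total)) - set(efficient)),
                         dtype=int)
        times = np.arange(total, dtype=float) + 1
        return et.TrialClassification(name, 0.7, eff, res, times[eff],
                                      times[res])

    def test_overlap_removed(self):
        pure = et.exclusive_trials([self._cls("A", {1, 2, 3}),
                                    self._cls("B", {3, 4})])
        assert list(pure["A"]) == [1, 2]
        assert list(pure["B"]) == [4]

    def test_identical_sets_vanish(self):
        pure = et.exclusive_trials([self._cls("A", {1, 2}),
                                    self._cls("B", {1, 2})])
        assert pure["A"].size == 0 and pure["B"].size == 0

    def test_disjoint_sets_unchanged(self):
        pure = et.exclusive_trials([self._cls("A", {0, 1}),
                                    self._cls("B", {4, 5})])
        assert list(pure["A"]) == [0, 1]
        assert list(pure["B"]) == [4, 5]

    def test_mismatched_trial_sets_rejected(self):
        with pytest.raises(ValidationError):
            et.exclusive_trials([self._cls("A", {1}, total=6),
                                 self._cls("B", {1}, total=5)])

    def test_outputs_disjoint_and_subsets(self, noisy_session):
        cfg, rec, ev, truth, tm = noisy_session
        est = et.average_epochs(tm)
        classifications = []
        for spec in component_specs(cfg):
            ts = et.trial_similarity(tm, et.extract_template(est, spec), 0)
            classifications.append(et.classify_trials(ts, 0.7, spec.name))
        pure = et.exclusive_trials(classifications)
        names = list(pure)
        for i, a in enumerate(names):
            cls = classifications[i]
            assert set(pure[a]) <= set(cls.efficient)
            for b in names[i + 1:]:
                assert set(pure[a]) & set(pure[b]) == set()


class TestReaverage:
    def test_full_set_equals_plain_average(self, noisy_session):
        tm = noisy_session[4]
        full = et.reaverage(tm, range(tm.n_trials))
        plain = et.average_epochs(tm)
        assert np.array_equal(full.mean, plain.mean)
        assert np.array_equal(full.sem, plain.sem)

    def test_singleton_is_that_trial(self, noisy_session):
        tm = noisy_session[4]
        single = et.reaverage(tm, [3])
        assert np.array_equal(single.mean, tm.data[3])
        assert np.all(single.sem == 0)

    def test_empty_set_rejected(self, noisy_session):
        with pytest.raises(ValidationError):
            et.reaverage(noisy_session[4], [])

    def test_efficient_average_sharpens_peaks(self, noisy_session):
        """Averaging only the efficient trials enlarges the component peak
        relative to the all-trials average (the whole point of selection)."""
        cfg, rec, ev, truth, tm = noisy_session
        est = et.average_epochs(tm)
        for spec in component_specs(cfg):
            ts = et.trial_similarity(tm, et.extract_template(est, spec), 0)
            sw = et.threshold_sweep(tm, et.extract_template(est, spec), spec,
                                    ts=ts)
            thr, _ = et.select_optimal_threshold(sw, spec)
            cls = et.classify_trials(ts, thr, spec.name)
            eff = et.reaverage(tm, cls.efficient)
            _, amp_all = et.component_amplitude(est, spec)
            _, amp_eff = et.component_amplitude(eff, spec)
            assert abs(amp_eff) > abs(amp_all)
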