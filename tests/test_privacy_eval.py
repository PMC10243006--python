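"""Leave-one-out attacks, ablation studies and inflection detection."""

import numpy as np
import pytest

from helpers import random_dataset, staircase_eval
from survcloak import (
    SurvivalDataset,
    ValidationError,
    ablation_study,
    curve_distance,
    detect_inflections,
    earliest_divergence,
    fit_km,
    leave_one_out_delta,
    localize_new_step,
    privacy_enhanced_curve,
    step_identifiability,
)


class TestStepIdentifiability:
    def test_distinct_event_times_all_singletons(self):
        ds = SurvivalDataset([1, 2, 3, 4, 5], [1] * 5)
        assert list(step_identifiability(fit_km(ds))) == [1, 2, 3, 4, 5]

    def test_fully_tied_events_not_singletons(self):
        ds = SurvivalDataset([3, 3, 3, 3], [1] * 4)
        assert step_identifiability(fit_km(ds)).size == 0

    def test_matches_counting_oracle(self, rng):
        for _ in range(50):
            ds = random_dataset(rng)
            curve = fit_km(ds)
            expected = sorted(
                t
                for t in set(ds.times)
                if sum(1 for T, e in zip(ds.times, ds.events) if T == t and e == 1) == 1
            )
            assert list(step_identifiability(curve)) == expected

    def test_smoothed_input_rejected(self, fixture_137):
        pc = privacy_enhanced_curve(fixture_137, "loess")
        with pytest.raises(ValidationError):
            step_identifiability(pc)


class TestDetectInflections:
    def test_linear_sequence_has_none(self):
        t = np.linspace(0, 10, 30)
        assert detect_inflections(np.column_stack([t, 1 - 0.05 * t])).size == 0

    def test_single_knee_detected_at_knee(self):
        t = np.arange(11.0)
        s = np.where(t <= 5, 1 - 0.02 * t, 0.9 - 0.1 * (t - 5))
        found = detect_inflections(np.column_stack([t, s]))
        assert found.tolist() == [5.0]

    def test_matches_exhaustive_scan_oracle(self, rng):
        t = np.linspace(0, 20, 60)
        s = np.clip(1 - t / 25 + 0.02 * rng.normal(size=60), 0, 1)
        sens = 2.5
        found = detect_inflections(np.column_stack([t, s]), sensitivity=sens)
        d2 = np.diff(s, 2)
        thr = max(sens * np.median(np.abs(d2)), 1e-12)
        expected = [
            t[i + 1]
            for i in range(1, d2.size)
            if abs(d2[i]) > thr
            and (abs(d2[i - 1]) <= thr or d2[i] * d2[i - 1] < 0)
        ]
        assert found.tolist() == expected

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            detect_inflections(np.array([[0.0, 1.0], [1.0, 0.5], [2.0, 0.2]]))


class TestCurveDistance:
    def test_identity_is_zero(self, fixture_137):
        pc = privacy_enhanced_curve(fixture_137, "loess")
        sup, l1 = curve_distance(pc, pc)
        assert sup == 0.0 and l1 == 0.0

    def test_symmetry_and_ordering(self, rng):
        a = privacy_enhanced_curve(random_dataset(rng, n=20, censor_prob=0.2), "none", unsafe_raw=True)
        b = privacy_enhanced_curve(random_dataset(rng, n=25, censor_prob=0.2), "none", unsafe_raw=True)
        sup_ab, l1_ab = curve_distance(a, b)
        sup_ba, l1_ba = curve_distance(b, a)
        assert sup_ab == sup_ba and l1_ab == l1_ba
        assert 0 <= l1_ab <= sup_ab


class TestLeaveOneOut:
    def test_raw_new_step_localises_removed_event(self, rng):
        """The release-and-join attack on raw staircases always names the
        joiner's event time when event times are distinct."""
        for _ in range(30):
            n = int(rng.integers(5, 25))
            times = rng.uniform(0, 100, n)  # continuous => distinct
            events = (rng.random(n) > 0.3).astype(int)
            if events.sum() == 0:
                continue
            ds = SurvivalDataset(times, events)
            target = int(np.nonzero(events)[0][0])
            steps = localize_new_step(fit_km(ds), fit_km(ds.drop_subject(target)))
            assert steps.tolist() == [times[target]]

    def test_earliest_divergence_is_first_event_not_removed_time(self):
        # removing the later subject perturbs the risk set at t=1 too
        ds = SurvivalDataset([1.0, 2.0], [1, 1])
        div = earliest_divergence(fit_km(ds), fit_km(ds.drop_subject(1)))
        assert div == 1.0

    def test_raw_loo_supnorm_matches_dense_grid_oracle(self, rng):
        times = rng.uniform(0, 50, 15)
        ds = SurvivalDataset(times, np.ones(15, int))
        delta = leave_one_out_delta(ds, 4, method="none", unsafe_raw=True)
        full = fit_km(ds)
        red = fit_km(ds.drop_subject(4))
        grid = np.linspace(0, 60, 5000)
        brute = max(
            abs(
                staircase_eval(full.times, full.surv, t)
                - staircase_eval(red.times, red.surv, t)
            )
            for t in np.concatenate([grid, times])
        )
        assert delta.sup_norm == pytest.approx(brute, abs=1e-12)
        assert delta.removed_time == times[4] and delta.removed_event == 1

    def test_index_out_of_range(self, fixture_137):
        with pytest.raises(ValidationError):
            leave_one_out_delta(fixture_137, 137)

    def test_smoothed_delta_records_inflections(self, fixture_137):
        idx = int(np.nonzero(fixture_137.events)[0][10])
        delta = leave_one_out_delta(fixture_137, idx, method="loess")
        assert delta.sup_norm >= delta.l1 >= 0
        assert delta.removed_event == 1
        assert isinstance(delta.inflection_times, np.ndarray)


class TestAblation:
    def test_identity_subsample(self, fixture_137):
        rep = ablation_study(fixture_137, target_n=137, seed=0, method="loess")
        assert rep.subsample_indices.tolist() == list(range(137))

    def test_seed_reproducibility(self, fixture_137):
        a = ablation_study(fixture_137, target_n=50, seed=3, method="loess")
        b = ablation_study(fixture_137, target_n=50, seed=3, method="loess")
        assert a.subsample_indices.tolist() == b.subsample_indices.tolist()
        assert a.removed_index == b.removed_index
        assert np.array_equal(a.curve_subsample.surv, b.curve_subsample.surv)
        assert np.array_equal(a.curve_reduced.surv, b.curve_reduced.surv)

    def test_target_n_too_large(self, fixture_137):
        with pytest.raises(ValidationError):
            ablation_study(fixture_137, target_n=138, seed=0)

    def test_fifty_subject_design(self, fixture_137):
        rep = ablation_study(fixture_137, target_n=50, seed=1, method="loess")
        assert rep.curve_subsample.n_input == 50
        assert rep.curve_reduced.n_input == 49
        assert rep.delta.sup_norm >= 0
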