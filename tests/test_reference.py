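"""Healthy-control reference bands, expansion labels, longitudinal pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repgvhd.errors import PairingError, ReferenceError_, ValidationError
from repgvhd.reference import (EXPANDED, HEALTHY_LIKE, ExpansionClassifier,
                               build_hc_reference, classify_sample,
                               pair_longitudinal, percent_change)


class TestReferenceBand:
    def test_individual_mean_computed_first(self):
        band = build_hc_reference([("a", 100.0), ("a", 200.0), ("b", 50.0)])
        assert band.individual_means["a"] == 150.0

    def test_p25_lands_on_order_statistic(self):
        # 9 individual means 10..90: position (9-1)*0.25 = 2 -> exactly 30
        samples = [(f"i{k}", 10.0 * k) for k in range(1, 10)]
        band = build_hc_reference(samples)
        assert band.p25 == pytest.approx(30.0)
        assert band.p75 == pytest.approx(70.0)

    def test_degenerate_all_samples_mode(self):
        band = build_hc_reference([("a", 42.0), ("a", 42.0), ("b", 42.0)],
                                  mode="all_samples")
        assert band.p25 == band.p75 == 42.0

    def test_requires_two_individuals(self):
        with pytest.raises(ReferenceError_):
            build_hc_reference([("a", 1.0), ("a", 2.0)])

    def test_duplicating_a_sample_leaves_per_individual_band_unchanged(self):
        samples = [("a", 10.0), ("a", 20.0), ("b", 30.0), ("c", 40.0)]
        band1 = build_hc_reference(samples)
        band2 = build_hc_reference(samples + [("a", 15.0), ("a", 15.0)])
        # adding samples at a's existing mean leaves the mean unchanged
        assert band1.p25 == band2.p25 and band1.p75 == band2.p75

    def test_modes_differ_when_sampling_unbalanced(self):
        samples = [("a", 10.0), ("a", 10.0), ("a", 10.0), ("b", 100.0)]
        per_ind = build_hc_reference(samples, mode="per_individual")
        pooled = build_hc_reference(samples, mode="all_samples")
        assert per_ind.p25 != pooled.p25


class TestClassification:
    @pytest.fixture
    def band(self):
        return build_hc_reference([(f"i{k}", 10.0 * k) for k in range(1, 10)])

    def test_below_threshold_is_expanded(self, band):
        assert classify_sample(29.9, band).label == EXPANDED

    def test_exactly_at_threshold_is_healthy_like(self, band):
        assert classify_sample(30.0, band).label == HEALTHY_LIKE

    def test_far_above_is_healthy_like(self, band):
        assert classify_sample(1e9, band).label == HEALTHY_LIKE

    def test_non_finite_rejected(self, band):
        with pytest.raises(ValidationError):
            classify_sample(float("nan"), band)

    def test_monotone_in_value(self, band):
        values = np.linspace(1.0, 100.0, 200)
        labels = [classify_sample(v, band).label for v in values]
        flips = [i for i in range(1, 200) if labels[i] != labels[i - 1]]
        assert len(flips) == 1  # single boundary: expanded below, healthy above
        assert labels[0] == EXPANDED and labels[-1] == HEALTHY_LIKE

    def test_classifier_fit_predict_matches_function(self, band):
        samples = [(f"i{k}", 10.0 * k) for k in range(1, 10)]
        clf = ExpansionClassifier().fit(samples)
        assert clf.threshold_ == band.p25
        np.testing.assert_array_equal(
            clf.predict([29.9, 30.0, 31.0]),
            [EXPANDED, HEALTHY_LIKE, HEALTHY_LIKE])

    def test_get_set_params_round_trip(self):
        clf = ExpansionClassifier()
        clf.set_params(mode="all_samples", percentile=10.0)
        assert clf.get_params() == {"mode": "all_samples", "percentile": 10.0}


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (200.0, 200.0, 0.0),
        (100.0, 43.73, -56.27),
        (100.0, 227.02, 127.02),
    ])
    def test_direct_arithmetic(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected, abs=1e-9)

    def test_zero_pre_undefined(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_swap_relation(self, a, b):
        # pc(a,b) == -100 * pc(b,a) / (100 + pc(b,a))
        fwd = percent_change(a, b)
        rev = percent_change(b, a)
        assert fwd == pytest.approx(-100.0 * rev / (100.0 + rev), rel=1e-9)


class TestLongitudinalPairing:
    def _samples(self, spec):
        rows = [{"subject_id": s, "timepoint": tp, "value": float(v)}
                for s, tp, v in spec]
        return pd.DataFrame(rows)

    def test_event_subject_brackets_anchor(self):
        samples = self._samples([("p1", -66, 100.0), ("p1", 9, 40.0)])
        pairs = pair_longitudinal(samples, {"p1": 0})
        assert (pairs[0].pre_timepoint, pairs[0].post_timepoint) == (-66, 9)
        assert pairs[0].percent_change == pytest.approx(-60.0)

    def test_latest_pre_earliest_post_chosen(self):
        samples = self._samples([("p1", -100, 1.0), ("p1", -10, 2.0),
                                 ("p1", 5, 3.0), ("p1", 50, 4.0)])
        p = pair_longitudinal(samples, {"p1": 0})[0]
        assert (p.pre_timepoint, p.post_timepoint) == (-10, 5)

    def test_no_pre_anchor_sample_is_error(self):
        samples = self._samples([("p1", 5, 1.0), ("p1", 9, 2.0)])
        with pytest.raises(PairingError, match="p1"):
            pair_longitudinal(samples, {"p1": 0})

    def test_control_matched_to_median_timing(self):
        # event subjects define median pre/post days (15, 45)
        samples = self._samples([
            ("e1", 10, 1.0), ("e1", 40, 1.0),
            ("e2", 20, 1.0), ("e2", 50, 1.0),
            ("c1", 10, 5.0), ("c1", 40, 6.0), ("c1", 80, 7.0),
        ])
        pairs = pair_longitudinal(samples, {"e1": 30, "e2": 40},
                                  control_subjects=["c1"])
        ctrl = [p for p in pairs if p.subject_id == "c1"][0]
        assert (ctrl.pre_timepoint, ctrl.post_timepoint) == (10, 40)

    def test_control_needs_two_timepoints(self):
        samples = self._samples([("e1", -5, 1.0), ("e1", 5, 1.0), ("c1", 10, 1.0)])
        with pytest.raises(PairingError, match="c1"):
            pair_longitudinal(samples, {"e1": 0}, control_subjects=["c1"])
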