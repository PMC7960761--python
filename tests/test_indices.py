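"""Index extraction: each sub-operation against hand-computable shapes and
closed-form oracles, plus the extraction invariants."""

import numpy as np
import pytest
from scipy.optimize import brentq

from osmoscan.curves import CurveParams, OsmoscanCurve, synth_curve
from osmoscan.errors import ParameterError, TooFewPointsError
from osmoscan.indices import (
    ExtractionConfig,
    compute_area,
    extract_indices,
    find_hyper,
    find_peak,
    find_valley,
    preprocess,
)


def _curve(osm, ei, preprocessed=False):
    return OsmoscanCurve(np.asarray(osm, float), np.asarray(ei, float), preprocessed=preprocessed)


class TestPreprocess:
    def test_duplicates_are_averaged(self):
        osm = np.concatenate(([100.0, 100.0, 150.0], np.arange(200.0, 220.0)))
        ei = np.concatenate(([0.2, 0.4, 0.3], np.full(20, 0.3)))
        out = preprocess(_curve(osm, ei), smooth_window=1)
        assert out.osmolality[0] == 100.0 and out.ei[0] == pytest.approx(0.3)
        assert out.osmolality.size == 22  # duplicates merged

    def test_identity_on_sorted_curve_without_smoothing(self):
        osm = np.arange(50.0, 90.0)
        ei = np.linspace(0.1, 0.5, osm.size)
        out = preprocess(_curve(osm, ei), smooth_window=1)
        assert np.array_equal(out.osmolality, osm) and np.allclose(out.ei, ei)

    def test_too_few_points_is_a_hard_error(self):
        with pytest.raises(TooFewPointsError):
            preprocess(_curve(np.arange(19.0), np.zeros(19)))

    def test_out_of_range_osmolalities_are_dropped(self):
        osm = np.concatenate(([-5.0, 510.0], np.arange(100.0, 125.0)))
        ei = np.concatenate(([0.9, 0.9], np.full(25, 0.3)))
        out = preprocess(_curve(osm, ei), smooth_window=1)
        assert out.osmolality.min() >= 0.0 and out.osmolality.max() <= 500.0
        assert out.osmolality.size == 25

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            preprocess(_curve(np.arange(30.0), np.zeros(30)), smooth_window=4)


class TestFindPeak:
    def test_unique_triangle_maximum(self):
        osm = np.arange(100.0, 501.0, 10.0)
        ei = 0.6 - np.abs(osm - 300.0) * 0.001
        o, e, flags = find_peak(_curve(osm, ei, preprocessed=True))
        assert (o, e) == (300.0, 0.6) and not flags

    def test_plateau_resolves_to_mean_osmolality(self):
        osm = np.arange(200.0, 401.0, 1.0)
        ei = np.where((osm >= 290) & (osm <= 310), 0.6, 0.3)
        o, e, _ = find_peak(_curve(osm, ei, preprocessed=True))
        assert o == pytest.approx(300.0) and e == 0.6

    def test_low_signal_flagged_but_returned(self):
        osm = np.arange(100.0, 400.0, 10.0)
        ei = 0.02 - np.abs(osm - 250.0) * 1e-5
        o, e, flags = find_peak(_curve(osm, ei, preprocessed=True))
        assert "LOW_SIGNAL" in flags and e < 0.05 and o == 250.0


class TestFindValley:
    def test_unique_interior_vertex(self):
        osm = np.arange(100.0, 301.0, 5.0)
        ei = 0.2 + np.abs(osm - 150.0) * 0.002
        o, e, flags = find_valley(_curve(osm, ei, preprocessed=True), o_eimax=300.0)
        assert (o, e) == (150.0, 0.2) and not flags

    def test_monotone_window_has_no_valley(self):
        osm = np.arange(100.0, 301.0, 5.0)
        ei = np.linspace(0.1, 0.6, osm.size)
        o, e, flags = find_valley(_curve(osm, ei, preprocessed=True), o_eimax=300.0)
        assert o is None and e is None and flags == {"NO_VALLEY"}


class TestFindHyper:
    def test_half_max_of_linear_descent(self):
        osm = np.arange(300.0, 501.0, 1.0)
        ei = 0.6 * (500.0 - osm) / 200.0
        o, flags = find_hyper(_curve(osm, ei, preprocessed=True), ei_max=0.6, o_eimax=300.0)
        assert o == pytest.approx(400.0, abs=1e-9) and not flags

    def test_sigmoid_descent_matches_root_finding_oracle(self):
        sigma = lambda o: 1.0 / (1.0 + np.exp((o - 420.0) / 25.0))
        osm = np.arange(300.0, 501.0, 1.0)
        ei = 0.6 * sigma(osm) / sigma(300.0)
        o, _ = find_hyper(_curve(osm, ei, preprocessed=True), ei_max=0.6, o_eimax=300.0)
        oracle = brentq(lambda x: 0.6 * sigma(x) / sigma(300.0) - 0.3, 300.0, 500.0)
        assert oracle == pytest.approx(420.41, abs=0.05)  # closed-form inversion
        assert o == pytest.approx(oracle, abs=0.1)

    def test_curve_that_never_halves_is_flagged(self):
        osm = np.arange(300.0, 501.0, 1.0)
        ei = np.full(osm.size, 0.6)
        o, flags = find_hyper(_curve(osm, ei, preprocessed=True), ei_max=0.6, o_eimax=300.0)
        assert o is None and flags == {"HYPER_NOT_REACHED"}


class TestComputeArea:
    def test_rectangle(self):
        osm = np.arange(100.0, 401.0, 1.0)
        area = compute_area(_curve(osm, np.full(osm.size, 0.5), preprocessed=True), 100.0, 400.0)
        assert area == pytest.approx(150.0)

    def test_triangle(self):
        osm = np.arange(100.0, 401.0, 1.0)
        ei = 0.6 * (osm - 100.0) / 300.0
        area = compute_area(_curve(osm, ei, preprocessed=True), 100.0, 400.0)
        assert area == pytest.approx(90.0)

    def test_interpolated_endpoints_between_samples(self):
        osm = np.arange(100.0, 401.0, 10.0)
        area = compute_area(_curve(osm, np.full(osm.size, 0.5), preprocessed=True), 105.0, 395.0)
        assert area == pytest.approx(0.5 * 290.0)

    def test_bad_bounds_rejected(self):
        osm = np.arange(100.0, 401.0, 10.0)
        c = _curve(osm, np.full(osm.size, 0.5), preprocessed=True)
        with pytest.raises(ParameterError):
            compute_area(c, 400.0, 100.0)


class TestExtractIndices:
    def test_whole_blood_preset_recovered(self, wb_curve):
        curve, truth = wb_curve
        got = extract_indices(curve)
        assert got.qc_flags == frozenset()
        assert got.o_min == pytest.approx(truth.o_min, abs=1.0)
        assert got.o_eimax == pytest.approx(truth.o_eimax, abs=1.0)
        assert got.o_hyper == pytest.approx(truth.o_hyper, abs=1.0)
        assert got.ei_min == pytest.approx(truth.ei_min, abs=0.002)
        assert got.ei_max == pytest.approx(truth.ei_max, abs=0.002)
        assert got.ei_hyper == got.ei_max / 2.0
        assert got.area == pytest.approx(truth.area, rel=0.01)

    def test_dense_fraction_has_smaller_area(self, preset_truths):
        from osmoscan.curves import preset_params

        m = extract_indices(synth_curve(preset_params("M"))[0])
        h = extract_indices(synth_curve(preset_params("H"))[0])
        assert h.area < m.area

    def test_flat_low_curve_collects_degeneracy_flags(self):
        osm = np.arange(50.0, 501.0, 5.0)
        got = extract_indices(_curve(osm, np.full(osm.size, 0.02)))
        assert {"LOW_SIGNAL", "NO_VALLEY", "HYPER_NOT_REACHED"} <= got.qc_flags
        assert got.o_min is None and got.o_hyper is None and got.area is None

    def test_extraction_is_idempotent_under_preprocessing(self):
        curve, _ = synth_curve(CurveParams(noise_sd=0.003, seed=3))
        cfg = ExtractionConfig()
        assert extract_indices(preprocess(curve, cfg.smooth_window), cfg) == extract_indices(curve, cfg)

    @pytest.mark.parametrize("k", [0.25, 0.5, 1.0, 1.5])
    def test_ei_scale_equivariance(self, k):
        """Scaling EI by k scales the EI-type indices and Area by k and
        leaves the osmolality-type indices unchanged."""
        curve, _ = synth_curve(CurveParams(grid_step=0.5))
        base = extract_indices(curve)
        scaled = extract_indices(OsmoscanCurve(curve.osmolality, curve.ei * k))
        assert scaled.o_min == pytest.approx(base.o_min, abs=0.6)
        assert scaled.o_eimax == pytest.approx(base.o_eimax, abs=0.6)
        assert scaled.o_hyper == pytest.approx(base.o_hyper, abs=0.6)
        assert scaled.ei_max == pytest.approx(base.ei_max * k, abs=1e-9)
        assert scaled.ei_min == pytest.approx(base.ei_min * k, abs=1e-9)
        assert scaled.area == pytest.approx(base.area * k, rel=1e-6)
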