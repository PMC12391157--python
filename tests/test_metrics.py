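import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pahemo.centerline import SegmentLabeling
from pahemo.engine import SteadyWSSField, WSSTimeSeriesField
from pahemo.metrics import (
    osi_field,
    segment_summary,
    summarize_case,
    tawss_field,
    wss_at_timepoint,
)


def _single_point_field(magnitudes, direction=(1.0, 0.0, 0.0), period=0.8):
    magnitudes = np.asarray(magnitudes, dtype=float)
    n = len(magnitudes)
    times = np.arange(n) * period / n
    d = np.asarray(direction) / np.linalg.norm(direction)
    vectors = magnitudes[None, :, None] * d[None, None, :]
    return WSSTimeSeriesField(
        wall_points=np.zeros((1, 3)),
        areas=np.ones(1),
        times=times,
        vectors=vectors,
    )


def _labeled_field(vectors, labels, areas=None, period=0.8):
    n_pts, n_t, _ = vectors.shape
    areas = np.ones(n_pts) if areas is None else areas
    return WSSTimeSeriesField(
        wall_points=np.zeros((n_pts, 3)),
        areas=areas,
        times=np.arange(n_t) * period / n_t,
        vectors=vectors,
        labeling=SegmentLabeling(labels=labels, areas=areas),
    )


class TestOSI:
    def test_unidirectional_shear_has_zero_osi(self):
        # magnitude 10 + 5 cos stays positive along a fixed direction
        theta = 2 * np.pi * np.arange(20) / 20
        field = _single_point_field(10 + 5 * np.cos(theta))
        assert osi_field(field).osi[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_reversing_shear_has_max_osi(self):
        theta = 2 * np.pi * np.arange(20) / 20
        field = _single_point_field(5 * np.cos(theta))
        assert osi_field(field).osi[0] == pytest.approx(0.5, abs=1e-9)

    def test_partially_reversing_analytic_value(self):
        # |1 + 2 cos| has period-mean 1/3 + 2 sqrt(3)/pi; mean vector is 1
        theta = 2 * np.pi * np.arange(4000) / 4000
        field = _single_point_field(1 + 2 * np.cos(theta))
        expected = 0.5 * (1 - 1.0 / (1.0 / 3 + 2 * np.sqrt(3) / np.pi))
        osi = osi_field(field).osi[0]
        assert osi == pytest.approx(expected, abs=1e-4)
        assert osi == pytest.approx(0.152, abs=0.001)

    def test_zero_field_warns_and_reports_zero(self):
        field = _single_point_field(np.zeros(20))
        with pytest.warns(UserWarning):
            assert osi_field(field).osi[0] == 0.0

    def test_rotating_direction_counts_as_oscillation(self):
        # constant magnitude spinning in the plane: mean vector is 0
        n = 40
        theta = 2 * np.pi * np.arange(n) / n
        vectors = np.stack(
            [np.cos(theta), np.sin(theta), np.zeros(n)], axis=1
        )[None, :, :]
        field = WSSTimeSeriesField(
            wall_points=np.zeros((1, 3)), areas=np.ones(1),
            times=np.arange(n) * 0.8 / n, vectors=vectors,
        )
        assert osi_field(field).osi[0] == pytest.approx(0.5, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_osi_bounds_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        vectors = rng.normal(size=(5, 20, 3))
        field = WSSTimeSeriesField(
            wall_points=np.zeros((5, 3)), areas=np.ones(5),
            times=np.arange(20) * 0.8 / 20, vectors=vectors,
        )
        osi = osi_field(field).osi
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vectors = rng.normal(size=(4, 20, 3))
        f1 = WSSTimeSeriesField(
            wall_points=np.zeros((4, 3)), areas=np.ones(4),
            times=np.arange(20) * 0.8 / 20, vectors=vectors,
        )
        f2 = WSSTimeSeriesField(
            wall_points=np.zeros((4, 3)), areas=np.ones(4),
            times=np.arange(20) * 0.8 / 20, vectors=2 * vectors,
        )
        np.testing.assert_allclose(osi_field(f2).osi, osi_field(f1).osi, atol=1e-12)
        np.testing.assert_allclose(tawss_field(f2), 2 * tawss_field(f1), atol=1e-12)


class TestTaWSS:
    def test_constant_field(self):
        field = _single_point_field(np.full(20, 7.5))
        assert tawss_field(field)[0] == pytest.approx(7.5, abs=1e-12)

    def test_rectified_cosine_mean(self):
        # mean of |A cos| over a period is 2A/pi
        theta = 2 * np.pi * np.arange(4000) / 4000
        field = _single_point_field(3.0 * np.cos(theta))
        assert tawss_field(field)[0] == pytest.approx(6.0 / np.pi, rel=1e-5)

    def test_dominates_mean_vector_magnitude(self):
        rng = np.random.default_rng(2)
        vectors = rng.normal(size=(10, 20, 3))
        field = WSSTimeSeriesField(
            wall_points=np.zeros((10, 3)), areas=np.ones(10),
            times=np.arange(20) * 0.8 / 20, vectors=vectors,
        )
        ta = tawss_field(field)
        mean_vec = np.linalg.norm(vectors.mean(axis=1), axis=1)
        assert np.all(ta >= mean_vec - 1e-12)


class TestTimepointSlices:
    def test_steady_series_slices_equal(self):
        field = _single_point_field(np.full(20, 4.0))
        s0 = wss_at_timepoint(field, 0)
        for i in range(1, 20):
            np.testing.assert_allclose(wss_at_timepoint(field, i), s0)

    def test_out_of_range_rejected(self):
        field = _single_point_field(np.ones(20))
        with pytest.raises(IndexError):
            wss_at_timepoint(field, 20)

    def test_peak_flow_slice_dominates_min_flow_slice(self, pa_case, fluid, rtof_waveform):
        from pahemo.engine import synthesize_wss_field
        from pahemo.flow import find_systole_diastole, fourier_decompose, reconstruct_waveform

        _, mesh, centerlines, truth = pa_case
        ff = fourier_decompose(rtof_waveform, 10)
        field = synthesize_wss_field(mesh, truth, centerlines, ff, fluid)
        inflow = reconstruct_waveform(ff, field.times)
        i_sys, i_dia = find_systole_diastole(inflow)
        w = truth.areas
        sys_avg = np.average(wss_at_timepoint(field, i_sys), weights=w)
        dia_avg = np.average(wss_at_timepoint(field, i_dia), weights=w)
        assert sys_avg > dia_avg


class TestSegmentSummary:
    def test_constant_field_every_region(self):
        labels = np.array(["MPA"] * 3 + ["LPA"] * 4 + ["RPA"] * 5)
        lab = SegmentLabeling(labels=labels, areas=np.ones(12))
        out = segment_summary(np.full(12, 2.5), lab)
        for region in ("whole", "MPA", "LPA", "RPA"):
            assert out[region] == (pytest.approx(2.5), pytest.approx(2.5))

    def test_whole_average_is_area_weighted_mix(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(["MPA", "LPA", "RPA"], 30)
        areas = rng.uniform(0.5, 2.0, 90)
        scalars = rng.uniform(0, 50, 90)
        lab = SegmentLabeling(labels=labels, areas=areas)
        out = segment_summary(scalars, lab)
        num = sum(
            out[r][0] * areas[labels == r].sum() for r in ("MPA", "LPA", "RPA")
        )
        assert out["whole"][0] == pytest.approx(num / areas.sum(), rel=1e-12)
        assert out["whole"][1] == pytest.approx(
            max(out[r][1] for r in ("MPA", "LPA", "RPA"))
        )

    def test_peak_never_below_average(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["MPA", "LPA", "RPA"], 20)
        lab = SegmentLabeling(labels=labels, areas=rng.uniform(0.1, 1, 60))
        out = segment_summary(rng.uniform(0, 9, 60), lab)
        for avg, peak in out.values():
            assert peak >= avg

    def test_missing_region_absent_not_zero(self):
        labels = np.array(["MPA"] * 10)
        lab = SegmentLabeling(labels=labels, areas=np.ones(10))
        out = segment_summary(np.ones(10), lab)
        assert "LPA" not in out and "RPA" not in out

    def test_untrimmed_extensions_rejected(self):
        labels = np.array(["MPA"] * 5 + ["extension"] * 5)
        lab = SegmentLabeling(labels=labels, areas=np.ones(10))
        with pytest.raises(ValueError, match="trim"):
            segment_summary(np.ones(10), lab)


class TestSummarizeCase:
    def _fields(self, lpa_scale=1.0):
        rng = np.random.default_rng(6)
        labels = np.repeat(["MPA", "LPA", "RPA"], 40)
        areas = np.ones(120)
        lab = SegmentLabeling(labels=labels, areas=areas)
        base = np.concatenate(
            [np.full(40, 4.0), np.full(40, 11.0 * lpa_scale), np.full(40, 7.0)]
        )
        theta = 2 * np.pi * np.arange(20) / 20
        mod = 1 + 0.6 * np.cos(theta)
        vectors = (base[:, None] * mod[None, :])[:, :, None] * np.array([1.0, 0, 0])
        pulsatile = _labeled_field(vectors, labels, areas)
        steady = SteadyWSSField(
            wall_points=np.zeros((120, 3)), areas=areas, scalars=base, labeling=lab
        )
        return steady, pulsatile, mod

    def test_schema_covers_all_regions_and_metrics(self):
        steady, pulsatile, mod = self._fields()
        summary = summarize_case(steady, pulsatile, inflow_at_timepoints=mod)
        assert set(summary.values) == {"whole", "MPA", "LPA", "RPA"}
        expected_metrics = {
            "WSS_steady_avg", "WSS_steady_peak", "taWSS_avg", "taWSS_peak",
            "WSS_systole_avg", "WSS_systole_peak", "WSS_diastole_avg",
            "WSS_diastole_peak", "OSI_avg",
        }
        for region in summary.values:
            assert expected_metrics <= set(summary.values[region])
        assert summary.metadata["systole_index"] == 0

    def test_steady_only_summary_skips_pulsatile_metrics(self):
        steady, _, _ = self._fields()
        summary = summarize_case(steady, None)
        assert "taWSS_avg" not in summary.values["whole"]
        assert "OSI_avg" not in summary.values["whole"]
        assert "WSS_steady_avg" in summary.values["whole"]

    def test_symmetric_branches_agree(self, fluid, rtof_waveform):
        from pahemo.engine import synthesize_wss_field, steady_field_from_series
        from pahemo.flow import fourier_decompose, reconstruct_waveform
        from pahemo.synthetic import default_pa_spec, make_pa_bifurcation

        spec = default_pa_spec(
            lpa_radius=0.9, rpa_radius=0.9, lpa_curvature=0.7, rpa_curvature=0.7
        )
        mesh, centerlines, truth = make_pa_bifurcation(spec)
        ff = fourier_decompose(rtof_waveform, 10)
        field = synthesize_wss_field(mesh, truth, centerlines, ff, fluid)
        inflow = reconstruct_waveform(ff, field.times)
        summary = summarize_case(None, field, inflow_at_timepoints=inflow)
        for metric, lpa_val in summary.values["LPA"].items():
            assert lpa_val == pytest.approx(summary.values["RPA"][metric], abs=1e-9)

    def test_narrowed_lpa_raises_its_steady_average(self):
        steady, pulsatile, mod = self._fields(lpa_scale=1.5)
        summary = summarize_case(steady, pulsatile, inflow_at_timepoints=mod)
        assert (
            summary.values["LPA"]["WSS_steady_avg"]
            > summary.values["RPA"]["WSS_steady_avg"]
        )
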