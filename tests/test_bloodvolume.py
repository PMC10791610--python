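"""Irradiated-blood-volume model: cylinder volumes, flow exchange, dose dilution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashear import (
    DiameterTable,
    EntryVein,
    FlowParameters,
    VesselSegment,
    blood_fraction,
    estimate,
    flow_volume,
    irradiated_volume,
    mean_blood_dose,
    polyline_lengths,
    propagate_estimates,
    ratio_uncertainty,
    replicate_stats,
    static_volume,
    total_blood_volume,
)
from flashear.bloodvolume import DataFormatError
from flashear.units import InvalidParameterError


class TestStaticVolume:
    def test_empty_trace_has_zero_volume(self):
        assert static_volume([]) == 0.0

    def test_single_thick_segment(self):
        vol = static_volume([VesselSegment("a", "thick", 10.0)])
        assert vol == pytest.approx(math.pi * 0.09**2 / 4 * 10, rel=1e-12)
        assert vol == pytest.approx(0.0636, abs=2e-4)

    def test_three_class_trace(self):
        segs = [
            VesselSegment("t1", "thick", 2.0), VesselSegment("t2", "thick", 3.0),
            VesselSegment("m1", "middle", 4.0), VesselSegment("m2", "middle", 5.0),
            VesselSegment("m3", "middle", 3.0),
        ] + [VesselSegment(f"n{i}", "thin", 3.0) for i in range(10)]
        # 0.03181 (thick, 5 mm) + 0.02356 (middle, 12 mm) + 0.03770 (thin, 30 mm)
        assert static_volume(segs) == pytest.approx(0.0931, abs=2e-4)

    def test_unknown_size_class_names_offender(self):
        with pytest.raises(DataFormatError, match="huge"):
            static_volume([VesselSegment("x", "huge", 1.0)])

    def test_explicit_diameter_overrides_class(self):
        seg = VesselSegment("a", "thin", 10.0, diameter_mm=0.09)
        assert static_volume([seg]) == pytest.approx(math.pi * 0.09**2 / 4 * 10)

    @settings(derandomize=True, max_examples=40)
    @given(length=st.floats(0.0, 50.0), c=st.floats(0.1, 5.0))
    def test_homogeneity_degree_2_in_diameter_degree_1_in_length(self, length, c):
        base = static_volume([VesselSegment("a", "thick", length)], DiameterTable())
        d2 = DiameterTable(0.09 * c, 0.05 * c, 0.04 * c)
        assert static_volume([VesselSegment("a", "thick", length)], d2) == pytest.approx(
            c**2 * base, rel=1e-9, abs=1e-15
        )
        assert static_volume([VesselSegment("a", "thick", c * length)]) == pytest.approx(
            c * base, rel=1e-9, abs=1e-15
        )

    def test_monte_carlo_voxelization_agrees_within_1pct(self, rng):
        """Analytic cylinder volumes vs per-cylinder Monte-Carlo estimation."""
        table = DiameterTable()
        for _ in range(20):
            n_seg = int(rng.integers(1, 4))
            segments, mc_total = [], 0.0
            for i in range(n_seg):
                cls = str(rng.choice(["thick", "middle", "thin"]))
                p0 = rng.uniform(0, 5, size=2)
                ang = rng.uniform(0, 2 * np.pi)
                length = float(rng.uniform(0.5, 4.0))
                p1 = p0 + length * np.array([np.cos(ang), np.sin(ang)])
                segments.append(VesselSegment(f"s{i}", cls, length))
                mc_total += _mc_cylinder_volume(p0, p1, table.diameter(cls) / 2, rng)
            assert static_volume(segments, table) == pytest.approx(mc_total, rel=0.01)


def _mc_cylinder_volume(p0, p1, radius, rng, n=200_000):
    """Monte-Carlo volume of one finite cylinder around a 2D segment axis,
    sampled in the cylinder's tight oriented bounding box."""
    axis = np.asarray(p1, float) - np.asarray(p0, float)
    length = float(np.linalg.norm(axis))
    u = axis / length
    s = rng.uniform(0.0, length, n)
    a = rng.uniform(-radius, radius, n)
    z = rng.uniform(-radius, radius, n)
    nhat = np.array([-u[1], u[0]])
    pts = np.asarray(p0) + s[:, None] * u + a[:, None] * nhat
    rel = pts - p0
    along = rel @ u
    perp2 = (rel[:, 0] - along * u[0]) ** 2 + (rel[:, 1] - along * u[1]) ** 2 + z**2
    inside = (along >= 0) & (along <= length) & (perp2 <= radius**2)
    return length * (2 * radius) ** 2 * inside.mean()


class TestPolylineLengths:
    def test_345_triangle(self):
        assert polyline_lengths([[(0, 0), (3, 4)]]) == [pytest.approx(5.0)]

    def test_axis_aligned_steps(self):
        assert polyline_lengths([[(0, 0), (1, 0), (1, 1)]]) == [pytest.approx(2.0)]

    def test_random_walk_matches_pairwise_sum(self, rng):
        pts = rng.normal(size=(100, 2))
        expected = sum(
            math.hypot(pts[i + 1, 0] - pts[i, 0], pts[i + 1, 1] - pts[i, 1])
            for i in range(99)
        )
        assert polyline_lengths([pts])[0] == pytest.approx(expected, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            polyline_lengths([[(0, 0)]])


class TestFlowVolume:
    def test_zero_time_zero_exchange(self, entry_veins):
        assert flow_volume(entry_veins, FlowParameters(2.0, 0.0)) == 0.0

    def test_conventional_exchange_through_four_veins(self, entry_veins):
        vol = flow_volume(entry_veins, FlowParameters(2.0, 550.2))
        assert vol == pytest.approx(28.0, abs=0.05)

    def test_single_middle_vein(self):
        vol = flow_volume([EntryVein("v", 0.05, "middle")], FlowParameters(2.0, 3.55))
        assert vol == pytest.approx(0.0139, abs=2e-4)

    def test_negative_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            EntryVein("v", -0.05)

    def test_thin_entry_vein_warns_but_computes(self):
        with pytest.warns(UserWarning, match="thin"):
            vol = flow_volume([EntryVein("v", 0.04, "thin")], FlowParameters(2.0, 1.0))
        assert vol > 0


class TestIrradiatedVolume:
    def test_flash930_volume_equals_static(self):
        assert irradiated_volume(0.20, 0.0) == pytest.approx(0.20)

    def test_zero(self):
        assert irradiated_volume(0.0, 0.0) == 0.0

    def test_flash9_static_plus_flow(self, entry_veins):
        flow = flow_volume(entry_veins, FlowParameters(2.0, 3.55))
        assert irradiated_volume(0.20, flow) == pytest.approx(0.38, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            irradiated_volume(-0.1, 0.0)


class TestBloodFractionAndDose:
    def test_total_blood_volume_of_study_mouse(self):
        assert total_blood_volume(19.2) == pytest.approx(1.99, abs=0.005)
        assert total_blood_volume(100.0) == pytest.approx(10.35)
        assert total_blood_volume(0.0) == 0.0

    @pytest.mark.parametrize("virr_ul, expected_pct, abs_tol", [
        (27.0, 1.4, 0.05), (0.20, 0.010, 0.0005), (0.0, 0.0, 0.0),
    ])
    def test_fractions_of_2ml_total(self, virr_ul, expected_pct, abs_tol):
        frac = blood_fraction(virr_ul, total_blood_volume(19.2))
        assert frac == pytest.approx(expected_pct, abs=abs_tol or 1e-12)

    def test_zero_total_blood_rejected(self):
        with pytest.raises(InvalidParameterError):
            blood_fraction(1.0, 0.0)

    def test_conventional_blood_dose_diluted_to_0p24(self):
        assert mean_blood_dose(33.0, 0.20, 27.0) == pytest.approx(0.24, abs=0.005)

    def test_no_exchange_gives_full_dose(self):
        assert mean_blood_dose(33.0, 0.37, 0.37) == pytest.approx(33.0)

    def test_flash9_dilution_formula(self):
        assert mean_blood_dose(33.0, 0.20, 0.37) == pytest.approx(17.8, abs=0.05)

    def test_irradiated_below_static_rejected(self):
        with pytest.raises(InvalidParameterError):
            mean_blood_dose(33.0, 1.0, 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(virr=st.floats(0.2, 100.0), extra=st.floats(0.0, 100.0))
    def test_dose_monotone_decreasing_in_irradiated_volume_and_bounded(self, virr, extra):
        d1 = mean_blood_dose(33.0, 0.2, virr)
        d2 = mean_blood_dose(33.0, 0.2, virr + extra)
        assert 0 < d2 <= d1 <= 33.0 + 1e-12


class TestCalibratedFixtureEndToEnd:
    """Timing-dependent volume chain on the calibrated trace + vein fixture."""

    def test_flash930_irradiated_volume_matches_static_within_2pct(
        self, calibrated_segments, entry_veins
    ):
        est = estimate(calibrated_segments, entry_veins, FlowParameters(2.0, 0.035))
        assert est.irradiated_volume_ul == pytest.approx(est.static_volume_ul, rel=0.02)

    def test_conventional_irradiates_100x_more_blood(self, calibrated_segments, entry_veins):
        fast = estimate(calibrated_segments, entry_veins, FlowParameters(2.0, 0.035))
        slow = estimate(calibrated_segments, entry_veins, FlowParameters(2.0, 550.2))
        assert slow.irradiated_volume_ul / fast.irradiated_volume_ul > 100

    def test_additivity_exact(self, calibrated_segments, entry_veins):
        est = estimate(calibrated_segments, entry_veins, FlowParameters(2.0, 3.55))
        assert est.irradiated_volume_ul == est.static_volume_ul + est.flow_volume_ul


class TestUncertainty:
    def test_identical_replicates_have_zero_sd(self):
        s = replicate_stats([0.2, 0.2, 0.2])
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.sem == pytest.approx(0.0, abs=1e-12)

    def test_three_replicate_sem(self):
        s = replicate_stats([0.15, 0.20, 0.25])
        assert s.mean == pytest.approx(0.20)
        assert s.sem == pytest.approx(0.029, abs=0.001)

    def test_single_replicate_sd_is_undefined_not_zero(self):
        s = replicate_stats([0.2])
        assert s.sd is None and s.sem is None and s.n == 1

    def test_ratio_propagation_matches_monte_carlo_within_5pct(self, rng):
        mu_n, sd_n, mu_d, sd_d = 0.37, 0.05, 0.20, 0.02
        analytic = ratio_uncertainty(mu_n, sd_n, mu_d, sd_d)
        draws = rng.normal(mu_n, sd_n, 100_000) / rng.normal(mu_d, sd_d, 100_000)
        assert analytic == pytest.approx(np.std(draws), rel=0.05)

    def test_propagate_estimates_across_ears(self, calibrated_segments, entry_veins):
        ests = [
            estimate(calibrated_segments, entry_veins, FlowParameters(2.0, t))
            for t in (3.4, 3.55, 3.7)
        ]
        out = propagate_estimates(ests, total_blood_ml=1.9872)
        assert out["static_volume_ul"].sd == pytest.approx(0.0, abs=1e-12)
        assert out["irradiated_volume_ul"].n == 3
        assert out["blood_fraction_pct"].mean > 0
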