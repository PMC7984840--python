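import numpy as np
import pytest

from segclock import GeometryParams
from segclock.fixtures import PlantedFieldSpec, make_planted_field, planted_phase
from segclock.observables import (
    DetectionParams,
    SegmentRecord,
    VorticityParams,
    classify_boundary,
    defect_runs,
    detect_boundary_times,
    expected_single_fraction,
    local_order,
    number_boundaries,
    score_record,
    single_double_stats,
    slice_order,
    vorticity_at_grid,
    vorticity_plane,
    vorticity_profile,
)

THREE_HALF_PI = 3 * np.pi / 2


def _cells_in_left_slab(geom, n, x0, dx, rng):
    pos = np.column_stack(
        [
            rng.uniform(x0, x0 + dx, n),
            rng.uniform(0, 2 * geom.r0, n),
            rng.uniform(0, 2 * geom.r0, n),
        ]
    )
    return pos


class TestLocalOrder:
    def test_identical_phases(self, geom, rng):
        pos = _cells_in_left_slab(geom, 40, 0.0, 11.0, rng)
        z, psi = slice_order(pos, np.full(40, 1.234), 0.0, "left", geom, 11.0)
        assert z == pytest.approx(1.0)
        assert psi == pytest.approx(1.234)

    def test_antiphase_cancellation(self, geom, rng):
        pos = _cells_in_left_slab(geom, 40, 0.0, 11.0, rng)
        theta = np.where(np.arange(40) % 2 == 0, 0.0, np.pi)
        z, _ = slice_order(pos, theta, 0.0, "left", geom, 11.0)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_rayleigh(self, geom, rng):
        pos = _cells_in_left_slab(geom, 1000, 0.0, 11.0, rng)
        z, _ = slice_order(pos, rng.uniform(0, 2 * np.pi, 1000), 0.0, "left",
                           geom, 11.0)
        assert z < 0.09

    def test_empty_slice_missing(self, geom):
        z, psi = slice_order(np.empty((0, 3)), np.empty(0), 0.0, "left", geom, 11.0)
        assert np.isnan(z) and np.isnan(psi)

    def test_gradient_high_local_order(self, geom, rng):
        """Slice-wise averaging keeps Z = 1 across a phase gradient."""
        det = DetectionParams()
        pos = _cells_in_left_slab(geom, 600, 0.0, 55.0, rng)
        theta = (THREE_HALF_PI - 2 * np.pi * pos[:, 0] / 55.0) % (2 * np.pi)
        # phases within one 11-μm slice spread over 2π/5: Zm = sinc(π/5) ≈ 0.94
        z = local_order(pos, theta, 0.0, "left", geom, det)
        assert z > 0.9
        # each internally synchronized slice gives exactly 1
        theta_flat = planted_phase(
            PlantedFieldSpec(rule="gradient", wavelength=55.0),
            np.column_stack([np.floor(pos[:, 0] / 11.0) * 11.0, pos[:, 1], pos[:, 2]]),
        )
        z2 = local_order(pos, theta_flat, 0.0, "left", geom, det)
        assert z2 == pytest.approx(1.0)

    def test_random_tissue_low_order(self, geom, rng):
        det = DetectionParams()
        pos = _cells_in_left_slab(geom, 300, 0.0, 55.0, rng)
        z = local_order(pos, rng.uniform(0, 2 * np.pi, 300), 0.0, "left", geom, det)
        assert z < 0.15

    def test_m_equals_one_degenerates_to_slice(self, geom, rng):
        det = DetectionParams(M=1)
        pos = _cells_in_left_slab(geom, 80, 0.0, 11.0, rng)
        theta = rng.uniform(0, 2 * np.pi, 80)
        assert local_order(pos, theta, 0.0, "left", geom, det) == pytest.approx(
            slice_order(pos, theta, 0.0, "left", geom, 11.0)[0]
        )


class TestBoundaryDetection:
    def test_linear_phase_crossings(self):
        # θ(t) = ω0 t reaches 3π/2 at 3/4 of the first 30-min cycle
        t = np.arange(0.0, 200.0, 1.0)
        psi1 = (2 * np.pi / 30.0 * t) % (2 * np.pi)
        taus = detect_boundary_times(t, psi1, THREE_HALF_PI, 30.0)
        expected = 22.5 + 30.0 * np.arange(len(taus))
        assert len(taus) >= 5
        assert np.abs(taus - expected).max() < 1e-9

    def test_constant_series_no_events(self):
        t = np.arange(0.0, 100.0, 1.0)
        assert len(detect_boundary_times(t, np.full(100, 1.0), THREE_HALF_PI)) == 0

    def test_jittered_double_crossing_merged(self):
        """A wiggle re-crossing ϑ within Ta/2 yields a single event."""
        t = np.arange(0.0, 60.0, 1.0)
        phase = 2 * np.pi / 30.0 * t
        phase[23] += 0.6  # early overshoot across ϑ ...
        phase[24] -= 0.5  # ... dips back below, then crosses again
        taus = detect_boundary_times(t, phase % (2 * np.pi), THREE_HALF_PI, 30.0)
        assert len(taus) == 2  # one merged event per true cycle
        assert abs(taus[0] - 22.5) < 2.0

    def test_classification_rules(self):
        det = DetectionParams()
        t = np.arange(0.0, 100.0, 1.0)
        assert classify_boundary(t, np.ones(100), 50.0, det) == "normal"
        assert classify_boundary(t, np.full(100, 0.84), 50.0, det) == "defective"
        z = np.ones(100)
        z[37] = 0.80  # one dip inside the window [35, 39]
        assert classify_boundary(t, z, 50.0, det) == "defective"
        assert classify_boundary(t, np.ones(100), 10.0, det) is None  # uncovered

    def test_classification_monotone_in_zc(self, rng):
        t = np.arange(0.0, 100.0, 1.0)
        z = rng.uniform(0.7, 1.0, 100)
        for tau in (30.0, 50.0, 70.0):
            verdicts = [
                classify_boundary(t, z, tau, DetectionParams(Zc=zc))
                for zc in (0.75, 0.85, 0.95)
            ]
            # raising Zc can only flip normal -> defective
            for a, b in zip(verdicts, verdicts[1:]):
                assert not (a == "defective" and b == "normal")

    def test_numbering_rules(self):
        # round(τ/Ta) within Δ: 8.75 -> 9; outside: 8.65 -> 8
        got = number_boundaries(np.array([262.5]), [True], Ta=30.0, Delta=0.3)
        assert list(got) == [9]
        got = number_boundaries(np.array([259.5]), [True], Ta=30.0, Delta=0.3)
        assert list(got) == [8]
        # chaining: event right after a normal numbered 11 gets 12 regardless of τ
        got = number_boundaries(
            np.array([330.0, 344.0]), [True, True], Ta=30.0, Delta=0.3
        )
        assert sorted(got) == [11, 12]
        # collision keeps the earlier event
        got = number_boundaries(
            np.array([262.5, 268.0]), [True, False, True][:2], Ta=30.0, Delta=0.3
        )
        assert 9 in got and got[9] == 262.5


class TestScoring:
    def _record(self, defective, n=20):
        return SegmentRecord.from_labels(
            "left", [j + 1 in set(defective) for j in range(n)]
        )

    def test_frs_pld_examples(self):
        rec = self._record(set(range(1, 10)) | {11, 14})
        assert rec.ald == 1
        assert rec.frs == 9  # first normal is 10
        assert rec.pld == 14
        all_normal = self._record(set())
        assert all_normal.ald is None and all_normal.pld is None
        assert all_normal.frs == 0
        mid = self._record({5, 6, 7})
        assert (mid.frs, mid.ald, mid.pld) == (0, 5, 7)

    def test_experimental_frs_convention(self):
        rec = self._record({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12})
        assert rec.frs_experimental == 10  # first normal after 9 is 11
        assert rec.frs == 10  # here conventions agree (boundary 11 first normal)

    def test_defect_runs(self):
        # N D D N D N between FRS and PLD -> runs {2, 1}
        rec = SegmentRecord.from_labels("left", [0, 1, 1, 0, 1, 0])
        assert sorted(defect_runs(rec)) == [1, 2]
        assert defect_runs(self._record(set())) == []
        rec2 = SegmentRecord.from_labels("left", [0, 1, 1, 1, 0])
        assert defect_runs(rec2) == [3]  # one all-defective span of 3

    def test_single_double_stats(self):
        left = SegmentRecord.from_labels("left", [j in (9, 11) for j in range(12)],
                                         start=10 - 9)
        # simpler explicit construction
        left = SegmentRecord("left", {j: j in (10, 12) for j in range(10, 14)})
        right = SegmentRecord("right", {j: j == 12 for j in range(10, 14)})
        ns, nt, fs = single_double_stats(left, right)
        assert (ns, nt, fs) == (1, 2, 0.5)
        ns, nt, fs = single_double_stats(left, left)
        assert fs == 0.0
        right2 = SegmentRecord("right", {j: j == 11 for j in range(10, 14)})
        assert single_double_stats(left, right2)[2] == 1.0

    def test_expected_single_fraction(self):
        assert expected_single_fraction(1.0) == 0.0
        assert expected_single_fraction(0.0) == 1.0
        assert expected_single_fraction(0.5) == pytest.approx(2 / 3)
        # Monte-Carlo oracle at p = 0.5
        rng = np.random.default_rng(1)
        L = rng.uniform(size=10**6) < 0.5
        R = rng.uniform(size=10**6) < 0.5
        nt = np.sum(L | R)
        ns = np.sum(L ^ R)
        assert ns / nt == pytest.approx(expected_single_fraction(0.5), abs=0.005)

    def test_score_record_pipeline_marks_gaps_defective(self):
        """Boundaries not claimed by a classified-normal event are defective."""
        t = np.arange(0.0, 200.0, 1.0)
        psi1 = (2 * np.pi / 30.0 * t) % (2 * np.pi)
        z = np.ones(200)
        # ruins boundary 3: τ3 ≈ 82.5, confirmation window [67.5, 71.5]
        z[(t >= 65) & (t <= 73)] = 0.5
        rec = score_record(t, psi1, z, "left", 5, DetectionParams(), Ta=30.0)
        assert rec.labels[3] is True
        assert [rec.labels[j] for j in (1, 2, 4, 5)] == [False] * 4
        assert (rec.ald, rec.pld, rec.frs) == (3, 3, 0)
        assert rec.pld >= rec.ald  # invariant whenever both defined


class TestVorticity:
    def make_vortex(self, rng, winding=1, axis="z"):
        spec = PlantedFieldSpec(
            rule="vortex", box=(110.0, 110.0, 20.0), center=(55.0, 55.0, 10.0),
            axis=axis, winding=winding,
        )
        return make_planted_field(spec, rng)

    def test_planted_vortex_detected_at_core(self, rng):
        params = VorticityParams()
        pos, th = self.make_vortex(rng)
        psi = vorticity_at_grid(pos[:, :2], th, np.array([55.0, 55.0]), params, "ccw")
        assert psi > params.psi_min
        # opposite handedness channel stays silent
        assert vorticity_at_grid(pos[:, :2], th, np.array([55.0, 55.0]), params,
                                 "cw") == 0.0

    def test_uniform_field_zero(self, rng):
        params = VorticityParams()
        spec = PlantedFieldSpec(rule="uniform", box=(110.0, 110.0, 20.0))
        pos, th = make_planted_field(spec, rng)
        assert vorticity_at_grid(pos[:, :2], th, np.array([55.0, 55.0]), params) == 0.0

    def test_empty_sector_zero(self, rng):
        params = VorticityParams()
        pos, th = self.make_vortex(rng)
        keep = ~((pos[:, 0] > 55) & (np.abs(pos[:, 1] - 55) < 8))  # carve a sector out
        assert vorticity_at_grid(pos[keep][:, :2], th[keep],
                                 np.array([55.0, 55.0]), params, "ccw") == 0.0

    def test_gradient_not_a_vortex(self, rng):
        """A linear phase gradient must not register as a vortex anywhere."""
        params = VorticityParams()
        spec = PlantedFieldSpec(rule="gradient", box=(200.0, 50.0, 20.0),
                                wavelength=55.0)
        pos, th = make_planted_field(spec, rng)
        x_grid = np.arange(20.0, 180.0, params.dx)
        u_grid = np.arange(2.0, 48.0, params.dy)
        for hand in ("ccw", "cw"):
            prof = vorticity_plane(pos[:, :2], th, x_grid, u_grid, params, hand)
            assert np.all(prof == 0.0)

    def test_mirror_swaps_handedness(self, rng):
        params = VorticityParams()
        pos, th = self.make_vortex(rng)
        mirrored = pos.copy()
        mirrored[:, 1] = 110.0 - mirrored[:, 1]
        psi_ccw = vorticity_at_grid(mirrored[:, :2], th, np.array([55.0, 55.0]),
                                    params, "ccw")
        psi_cw = vorticity_at_grid(mirrored[:, :2], th, np.array([55.0, 55.0]),
                                   params, "cw")
        assert psi_cw > params.psi_min and psi_ccw == 0.0

    def test_profile_peaks_at_planted_center(self, geom, rng):
        """ψmax(x) peaks within ±10 μm of a vortex planted in the tube."""
        from segclock.fixtures import make_u_domain_positions

        params = VorticityParams()
        pos = make_u_domain_positions(geom, 0.0015, rng)
        x_star = 150.0
        spec = PlantedFieldSpec(rule="vortex", center=(x_star, geom.r0, geom.r0),
                                axis="z", winding=1)
        th = planted_phase(spec, pos)
        prof = vorticity_profile(pos, th, geom, 0.0, "left", params)
        peak_x = prof["x"][np.argmax(prof["ccw"])]
        assert abs(peak_x - x_star) <= 10.0
        far = np.abs(prof["x"] - x_star) > 40.0
        assert np.all(prof["ccw"][far] == 0.0)

    def test_synchronized_tissue_zero_profile(self, geom, rng):
        from segclock.fixtures import make_u_domain_positions

        params = VorticityParams()
        pos = make_u_domain_positions(geom, 0.0015, rng)
        th = np.full(len(pos), THREE_HALF_PI)
        prof = vorticity_profile(pos, th, geom, 0.0, "right", params)
        assert np.all(prof["ccw"] == 0.0) and np.all(prof["cw"] == 0.0)


class TestKymograph:
    def _snapshots(self, geom, rng, rule):
        from segclock.fixtures import make_u_domain_positions, PlantedFieldSpec, planted_phase

        snaps = []
        for t in (0.0, 2.0, 4.0):
            pos = make_u_domain_positions(geom, 0.0015, rng)
            if rule == "sync":
                th = np.full(len(pos), 1.0)
            else:
                th = rng.uniform(0, 2 * np.pi, len(pos))
            snaps.append({"t": t, "xa": 0.0, "r": geom.r0,
                          "positions": pos, "theta": th})
        return snaps

    def test_sync_z_kymograph_high(self, geom, rng):
        from segclock.observables import kymograph

        kymo = kymograph(self._snapshots(geom, rng, "sync"), "Z", "left", geom)
        vals = kymo.values[np.isfinite(kymo.values)]
        assert np.all(vals >= 0.95)
        assert kymo.x_abs.shape == kymo.values.shape

    def test_random_z_kymograph_low(self, geom, rng):
        from segclock.observables import kymograph

        kymo = kymograph(self._snapshots(geom, rng, "random"), "Z", "right", geom)
        vals = kymo.values[np.isfinite(kymo.values)]
        assert np.median(vals) < 0.5
        assert np.all((vals >= 0) & (vals <= 1))
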