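"""Simulator contracts: geometry, determinism, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest

from fadyn.simulate import (
    AcquisitionSpec,
    AdhesionKinetics,
    OverlapSpec,
    VesicleFieldSpec,
    edge_distance_um,
    sample_kinetics,
    simulate_adhesion_timelapse,
    simulate_cell_mask,
    simulate_coloc_triad,
    simulate_vesicle_field,
)

from conftest import SMALL_ACQ


class TestCellMask:
    def test_ellipse_area_matches_analytic(self, ellipse_cell):
        area = ellipse_cell.sum() * 0.2**2
        assert area == pytest.approx(np.pi * 25 * 15, rel=0.02)

    def test_single_4connected_component(self, ellipse_cell):
        from scipy import ndimage as ndi

        _, n = ndi.label(ellipse_cell, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert n == 1

    def test_blob_deterministic_given_seed(self):
        a = simulate_cell_mask((128, 128), 0.25, "blob", {"mean_radius": 10}, seed=7)
        b = simulate_cell_mask((128, 128), 0.25, "blob", {"mean_radius": 10}, seed=7)
        assert np.array_equal(a, b)
        c = simulate_cell_mask((128, 128), 0.25, "blob", {"mean_radius": 10}, seed=8)
        assert not np.array_equal(a, c)

    def test_oversized_cell_raises_with_axis_name(self):
        with pytest.raises(ValueError, match="exceeds the frame"):
            simulate_cell_mask((500, 500), 0.2, "ellipse", {"semi_axes": (500.0, 10.0)})


def _one_adhesion_acq(**kw):
    defaults = dict(
        n_frames=20, frame_interval=1.0, pixel_size=0.2, image_shape=(150, 150),
        psf_sigma=0.0, background_level=0.0,
    )
    defaults.update(kw)
    return AcquisitionSpec(**defaults)


def _centered_kinetics(**kw):
    defaults = dict(
        anchor=(15.0, 15.0), axis_angle=0.0, v_assembly=0.5, v_disassembly=0.25,
        t_appear=0.0, t_halt_start=10.0, t_halt_end=15.0,
    )
    defaults.update(kw)
    return AdhesionKinetics(**defaults)


class TestAdhesionTimelapse:
    def test_distal_tip_displacement_matches_speed(self):
        acq = _one_adhesion_acq()
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (13.0, 13.0)})
        _, truth = simulate_adhesion_timelapse(cell, [_centered_kinetics()], acq, seed=0)
        tips = truth.tip_tracks
        d0 = tips[tips.frame == 0].s_distal.iloc[0]
        d10 = tips[tips.frame == 10].s_distal.iloc[0]
        assert d10 - d0 == pytest.approx(5.0)

    def test_zero_adhesions_yields_background_only(self):
        acq = _one_adhesion_acq(background_level=7.0)
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (13.0, 13.0)})
        stack, truth = simulate_adhesion_timelapse(cell, [], acq, seed=0)
        assert np.allclose(stack.data, 7.0)
        assert len(truth.tip_tracks) == 0 and len(truth.adhesions) == 0

    def test_anchor_outside_mask_raises(self):
        acq = _one_adhesion_acq()
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (5.0, 5.0)})
        with pytest.raises(ValueError, match="outside the cell mask"):
            simulate_adhesion_timelapse(cell, [_centered_kinetics(anchor=(2.0, 2.0))], acq, seed=0)

    def test_ribbon_clipped_at_cell_edge_is_flagged(self):
        acq = _one_adhesion_acq()
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (8.0, 8.0)})
        # anchor 1 um inside the edge, growing outward: must clip
        k = _centered_kinetics(anchor=(22.0, 15.0), v_assembly=0.6)
        _, truth = simulate_adhesion_timelapse(cell, [k], acq, seed=0)
        assert truth.adhesions.clipped.iloc[0]

    def test_seeded_run_bit_identical(self):
        acq = _one_adhesion_acq(poisson_scale=1.0, read_noise_sigma=2.0, psf_sigma=0.2)
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (13.0, 13.0)})
        s1, t1 = simulate_adhesion_timelapse(cell, [_centered_kinetics()], acq, seed=3)
        s2, t2 = simulate_adhesion_timelapse(cell, [_centered_kinetics()], acq, seed=3)
        assert np.array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(t1.tip_tracks, t2.tip_tracks)

    def test_halfmax_scan_reproduces_truth_tips(self):
        """Brute-force per-frame scan along the growth axis finds the rendered
        tips within one pixel of the truth table (noiseless, 1-px PSF)."""
        acq = _one_adhesion_acq(psf_sigma=0.2)
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (13.0, 13.0)})
        k = _centered_kinetics()
        stack, truth = simulate_adhesion_timelapse(cell, [k], acq, seed=0)
        from scipy.ndimage import map_coordinates

        s_grid = np.arange(-4.0, 8.0, 0.05)  # um along the axis from the anchor
        px = acq.pixel_size
        cols = (k.anchor[0] + s_grid * np.cos(k.axis_angle)) / px
        rows = (k.anchor[1] + s_grid * np.sin(k.axis_angle)) / px
        for frame in (0, 5, 12, 18):
            profile = map_coordinates(stack.frame(frame).astype(float), [rows, cols], order=1)
            half = profile.max() / 2
            above = np.flatnonzero(profile >= half)
            s_lo, s_hi = s_grid[above[0]], s_grid[above[-1]]
            row = truth.tip_tracks.query("frame == @frame").iloc[0]
            assert s_lo == pytest.approx(row.s_proximal, abs=px)
            assert s_hi == pytest.approx(row.s_distal, abs=px)

    def test_truth_tip_monotonicity(self):
        acq = SMALL_ACQ
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (40.0, 28.0)})
        kin = sample_kinetics(cell, acq.pixel_size, 5, seed=2)
        _, truth = simulate_adhesion_timelapse(cell, kin, acq, seed=2)
        for i, k in enumerate(kin):
            mine = truth.tip_tracks.query("adhesion == @i")
            growing = mine[mine.time <= k.t_halt_start]
            assert (np.diff(growing.s_distal) >= -1e-12).all()
            retracting = mine[mine.time >= k.t_halt_end]
            assert (np.diff(retracting.s_proximal) >= -1e-12).all()

    def test_noiseless_total_intensity_conserved(self):
        """With noise and PSF off, summed foreground intensity matches the
        analytic ribbon integral peak * length * width."""
        acq = _one_adhesion_acq()
        cell = simulate_cell_mask(acq.image_shape, acq.pixel_size, "ellipse", {"semi_axes": (13.0, 13.0)})
        k = _centered_kinetics()
        stack, truth = simulate_adhesion_timelapse(cell, [k], acq, seed=0)
        row = truth.tip_tracks.query("frame == 5").iloc[0]
        length_px = (row.s_distal - row.s_proximal) / acq.pixel_size
        expected = k.peak_intensity * length_px * (k.width / acq.pixel_size)
        assert float(stack.frame(5).sum()) == pytest.approx(expected, rel=0.01)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError, match="t_appear"):
            _centered_kinetics(t_appear=5.0, t_halt_start=2.0)


class TestVesicleField:
    def test_full_bias_puts_all_centres_in_band(self, ellipse_cell):
        acq = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=ellipse_cell.shape,
                              psf_sigma=0.0, background_level=0.0)
        spec = VesicleFieldSpec(n_vesicles=200, peripheral_bias=1.0, diffusion_step=0.0)
        _, truth = simulate_vesicle_field(ellipse_cell, spec, acq, seed=1)
        assert truth.vesicles.in_band.all()

    def test_unbiased_band_fraction_within_binomial_error(self, ellipse_cell):
        acq = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=ellipse_cell.shape,
                              psf_sigma=0.0, background_level=0.0)
        n = 10000
        spec = VesicleFieldSpec(n_vesicles=n, peripheral_bias=0.0, diffusion_step=0.0)
        _, truth = simulate_vesicle_field(ellipse_cell, spec, acq, seed=1)
        d = edge_distance_um(ellipse_cell, 0.2)
        band = ellipse_cell & (d < 10.0)
        p = band.sum() / ellipse_cell.sum()
        observed = truth.vesicles.in_band.mean()
        assert abs(observed - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_vesicles(self, ellipse_cell):
        acq = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=ellipse_cell.shape,
                              psf_sigma=0.0, background_level=3.0)
        stack, truth = simulate_vesicle_field(
            ellipse_cell, VesicleFieldSpec(n_vesicles=0), acq, seed=0
        )
        assert len(truth.vesicles) == 0
        assert np.allclose(stack.data, 3.0)

    def test_thin_cell_with_bias_raises(self):
        thin = simulate_cell_mask((120, 120), 0.2, "ellipse", {"semi_axes": (8.0, 8.0)})
        acq = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=(120, 120))
        with pytest.raises(ValueError, match="peripheral_bias = 0"):
            simulate_vesicle_field(thin, VesicleFieldSpec(peripheral_bias=0.5), acq, seed=0)


class TestColocTriad:
    ACQ = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=(200, 320),
                          psf_sigma=0.0, background_level=0.0)

    def test_channel_mask_is_union_of_combinations(self, ellipse_cell):
        spec = OverlapSpec(counts={"A": 100, "AB": 40, "ABC": 10})
        _, truth = simulate_coloc_triad(ellipse_cell, spec, self.ACQ, seed=0)
        assert truth.channel_masks["A"].sum() == 150
        assert truth.overlap_counts == {"A": 100, "B": 0, "C": 0, "AB": 40,
                                        "AC": 0, "BC": 0, "ABC": 10}

    def test_all_zero_spec_gives_empty_masks(self, ellipse_cell):
        _, truth = simulate_coloc_triad(ellipse_cell, OverlapSpec(counts={}), self.ACQ, seed=0)
        assert all(truth.channel_masks[c].sum() == 0 for c in "ABC")

    def test_pixel_loop_oracle_reproduces_counts_exactly(self, ellipse_cell):
        spec = OverlapSpec(counts={"A": 83, "B": 31, "C": 17, "AB": 29, "AC": 11,
                                   "BC": 7, "ABC": 13})
        _, truth = simulate_coloc_triad(ellipse_cell, spec, self.ACQ, seed=4)
        a, b, c = (truth.channel_masks[n] for n in "ABC")
        counts = dict.fromkeys(truth.overlap_counts, 0)
        for r in range(a.shape[0]):
            for cc in range(a.shape[1]):
                key = ("A" if a[r, cc] else "") + ("B" if b[r, cc] else "") + ("C" if c[r, cc] else "")
                if key:
                    counts[key] += 1
        assert counts == truth.overlap_counts

    def test_infeasible_packing_reports_required_vs_available(self):
        tiny = simulate_cell_mask((40, 40), 0.2, "ellipse", {"semi_axes": (2.0, 2.0)})
        with pytest.raises(ValueError, match="infeasible packing"):
            acq = AcquisitionSpec(n_frames=1, pixel_size=0.2, image_shape=(40, 40))
            simulate_coloc_triad(tiny, OverlapSpec(counts={"A": 10000}), acq, seed=0)


class TestSampleKinetics:
    def test_separation_and_edge_clearance(self, small_cell):
        kin = sample_kinetics(small_cell, SMALL_ACQ.pixel_size, 10, seed=3)
        assert len(kin) == 10
        pos = np.array([k.anchor for k in kin])
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0
        dmap = edge_distance_um(small_cell, SMALL_ACQ.pixel_size)
        for k in kin:
            r, c = int(round(k.anchor[1] / SMALL_ACQ.pixel_size)), int(round(k.anchor[0] / SMALL_ACQ.pixel_size))
            assert dmap[r, c] >= k.v_assembly * (k.t_halt_start - k.t_appear)

    def test_axis_points_toward_nearest_edge(self, small_cell):
        from scipy import ndimage as ndi

        kin = sample_kinetics(small_cell, SMALL_ACQ.pixel_size, 8, seed=5)
        _, (nr, nc) = ndi.distance_transform_edt(small_cell, return_indices=True)
        for k in kin:
            r = int(round(k.anchor[1] / SMALL_ACQ.pixel_size))
            c = int(round(k.anchor[0] / SMALL_ACQ.pixel_size))
            v = np.array([nc[r, c] - c, nr[r, c] - r], dtype=float)
            u = k.unit
            assert v @ u > 0
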