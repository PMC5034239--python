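"""Tracking, kymograph and turnover-metric contracts on constructed and
simulated footage."""

import numpy as np
import pytest

from fadyn.dynamics import (
    GrowthAxis,
    KymographRecord,
    adhesion_density,
    detect_adhesions,
    extract_kymograph,
    growth_axis,
    locate_tips,
    peripheral_adhesion_fraction,
    segment_events,
    track_adhesions,
    turnover_metrics,
    AdhesionTrack,
)
from fadyn.prep import label_regions
from fadyn.simulate import sample_kinetics, simulate_adhesion_timelapse
from fadyn import studies

from conftest import SMALL_ACQ


def ribbon_frame(shape=(128, 128), n=3, value=100.0, length=10, width=4):
    """n horizontal ribbons on a dark background."""
    img = np.zeros(shape)
    for i in range(n):
        r = 15 + 30 * i
        img[r : r + width, 20 : 20 + length] = value
    return img


class TestDetect:
    def test_counts_ribbons(self):
        img = ribbon_frame(n=3)
        lm = detect_adhesions(img, threshold="fixed:50", min_area=0.0, pixel_size=0.2)
        assert lm.n_labels == 3

    def test_speckle_below_min_area_ignored(self):
        img = np.zeros((64, 64))
        img[10, 10] = 100.0
        lm = detect_adhesions(img, threshold="fixed:50", min_area=0.25, pixel_size=0.2)
        assert lm.n_labels == 0

    def test_blank_frame_has_no_labels(self):
        lm = detect_adhesions(np.zeros((32, 32)), threshold="fixed:10", min_area=0.0)
        assert lm.n_labels == 0


class TestTracking:
    def test_two_stationary_ribbons_full_length_censored(self):
        frame = ribbon_frame(n=2) > 50
        maps = [label_regions(frame, pixel_size=0.2) for _ in range(60)]
        tracks = track_adhesions(maps)
        assert len(tracks) == 2
        for tr in tracks:
            assert tr.n_frames == 60 and tr.censored_start and tr.censored_end

    def test_single_frame_dropout_bridged_by_max_gap(self):
        frame = ribbon_frame(n=1) > 50
        blank = np.zeros_like(frame)
        maps = [label_regions(m, pixel_size=0.2) for m in [frame, frame, blank, frame, frame]]
        tracks = track_adhesions(maps, max_gap=1)
        assert len(tracks) == 1
        assert track_adhesions(maps, max_gap=0)[0].n_frames == 2

    def test_needs_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            track_adhesions([label_regions(np.zeros((8, 8), dtype=bool))])

    def test_staggered_lifetimes_match_truth(self, small_cell):
        kin = sample_kinetics(small_cell, SMALL_ACQ.pixel_size, 6, seed=9)
        stack, truth = simulate_adhesion_timelapse(small_cell, kin, SMALL_ACQ, seed=9)
        masks = stack.channel(0) > 50
        maps = [label_regions(m, min_area=0.15, pixel_size=SMALL_ACQ.pixel_size) for m in masks]
        tracks = [t for t in track_adhesions(maps) if t.n_frames >= 2]
        assert len(tracks) == 6
        truth_spans = sorted(zip(truth.adhesions.first_frame, truth.adhesions.last_frame))
        rec_spans = sorted((t.first_frame, t.last_frame) for t in tracks)
        for (tf, tl), (rf, rl) in zip(truth_spans, rec_spans):
            assert abs(tf - rf) <= 1 and abs(tl - rl) <= 1


class TestGrowthAxis:
    def test_recovers_angle_and_distal_sign(self, small_cell):
        kin = sample_kinetics(small_cell, SMALL_ACQ.pixel_size, 4, seed=3)
        stack, truth = simulate_adhesion_timelapse(small_cell, kin, SMALL_ACQ, seed=3)
        masks = stack.channel(0) > 50
        maps = [label_regions(m, min_area=0.15, pixel_size=SMALL_ACQ.pixel_size) for m in masks]
        tracks = [t for t in track_adhesions(maps) if t.n_frames >= 3]
        for tr in tracks:
            ax = growth_axis(tr, small_cell, length_um=10.0)
            cx, cy = ax.center_um
            k = min(kin, key=lambda k: np.hypot(k.anchor[0] - cx, k.anchor[1] - cy))
            dot = ax.unit[0] * k.unit[0] + ax.unit[1] * k.unit[1]
            assert dot > 0, "distal direction must match the truth orientation"
            assert abs(np.degrees(np.arccos(np.clip(abs(dot), 0, 1)))) < 3

    def test_isotropic_static_object_uses_fallback_or_errors(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        blob = (yy - 32) ** 2 + (xx - 32) ** 2 <= 25
        maps = [label_regions(blob, pixel_size=0.2) for _ in range(5)]
        tracks = track_adhesions(maps)
        cell = (yy - 32) ** 2 + (xx - 32) ** 2 <= 900
        with pytest.raises(ValueError, match="undefined"):
            growth_axis(tracks[0], cell)

    def test_line_near_border_flagged_clipped(self):
        frame = np.zeros((40, 200), dtype=bool)
        frame[18:22, 5:40] = True  # long ribbon near the left border
        maps = [label_regions(frame, pixel_size=0.2) for _ in range(3)]
        tracks = track_adhesions(maps)
        cell = np.ones((40, 200), dtype=bool)
        ax = growth_axis(tracks[0], cell, pixel_size=0.2, length_um=10.0)
        assert ax.clipped


class TestKymograph:
    def _axis(self, p0, p1):
        ux = np.array(p1) - np.array(p0)
        length = float(np.hypot(*ux))
        ux = ux / length
        return GrowthAxis(
            center_um=tuple((np.array(p0) + np.array(p1)) / 2),
            angle=float(np.arctan2(ux[1], ux[0])),
            unit=(float(ux[0]), float(ux[1])),
            p0_um=tuple(p0), p1_um=tuple(p1), length_um=length,
            clipped=False, fallback=False,
        )

    def test_constant_image_gives_constant_matrix(self):
        frames = np.full((4, 50, 50), 7.0)
        kymo = extract_kymograph(frames, self._axis((1.0, 5.0), (9.0, 5.0)), pixel_size=0.2)
        assert np.allclose(kymo.matrix, 7.0)

    def test_sample_count_is_length_over_pixel_plus_one(self):
        frames = np.zeros((2, 80, 80))
        kymo = extract_kymograph(frames, self._axis((2.0, 8.0), (12.0, 8.0)), pixel_size=0.2)
        assert kymo.matrix.shape[0] == 51

    def test_step_edge_matches_nearest_neighbor_oracle(self):
        frames = np.zeros((1, 60, 60))
        frames[0, :, 30:] = 100.0
        axis = self._axis((2.0, 6.0), (10.0, 6.0))  # horizontal at row 30, px=0.2
        kymo = extract_kymograph(frames, axis, pixel_size=0.2, width_avg=1)
        cols = np.round(np.linspace(10, 50, kymo.matrix.shape[0])).astype(int)
        oracle = frames[0, 30, cols]
        # bilinear and nearest agree except within 1 px of the edge
        off_edge = np.abs(cols - 30) > 1
        assert np.allclose(kymo.matrix[off_edge, 0], oracle[off_edge])

    def test_zero_length_line_rejected(self):
        frames = np.zeros((1, 20, 20))
        ax = self._axis((1.0, 1.0), (1.0 + 1e-12, 1.0))
        ax = GrowthAxis(**{**ax.__dict__, "length_um": 0.0})
        with pytest.raises(ValueError, match="zero-length"):
            extract_kymograph(frames, ax, pixel_size=0.2)


class TestLocateTips:
    def _kymo(self, matrix, step=0.2):
        n = matrix.shape[0]
        return KymographRecord(
            matrix=matrix.astype(float),
            positions_um=np.arange(n) * step,
            axis=None,
            sample_step_um=step,
            width_avg=1,
            frame_interval=1.0,
        )

    def test_plateau_edges_recovered_at_half_max(self):
        pos = np.arange(51) * 0.2
        col = np.where((pos >= 2.0) & (pos <= 6.0), 100.0, 0.0)
        kymo = self._kymo(np.tile(col[:, None], (1, 3)))
        distal, proximal = locate_tips(kymo, background_level=0.0)
        assert proximal[1] == pytest.approx(2.0, abs=0.1)
        assert distal[1] == pytest.approx(6.0, abs=0.1)

    def test_background_column_is_undefined(self):
        col_sig = np.zeros(51); col_sig[10:20] = 50.0
        matrix = np.stack([col_sig, np.zeros(51)], axis=1)
        distal, proximal = locate_tips(self._kymo(matrix), background_level=0.0)
        assert np.isfinite(distal[0]) and np.isnan(distal[1])

    def test_all_background_raises(self):
        with pytest.raises(ValueError, match="no adhesion"):
            locate_tips(self._kymo(np.zeros((51, 4))), background_level=0.0)

    def test_two_runs_keep_the_one_near_previous_tips(self):
        # frame 0: single run at 10-20; frame 1: same run + intruder at 35-45
        col0 = np.zeros(51); col0[10:21] = 100.0
        col1 = col0.copy(); col1[35:46] = 100.0
        distal, proximal = locate_tips(self._kymo(np.stack([col0, col1], axis=1)),
                                       background_level=0.0)
        assert distal[1] == pytest.approx(distal[0], abs=0.2)


class TestSegmentEvents:
    def test_assembly_then_halt(self):
        t = np.arange(19.0)
        distal = np.concatenate([np.linspace(0, 4, 9), np.full(10, 4.0)])
        proximal = np.zeros(19)
        events = segment_events(distal, proximal, t)
        kinds = [e.kind for e in events]
        assert kinds == ["assembly", "halt"]
        assert events[0].rate == pytest.approx(0.5)
        assert events[1].t_end - events[1].t_start == pytest.approx(10.0)

    def test_subthreshold_jitter_is_all_halt(self, rng):
        t = np.arange(30.0)
        distal = 5.0 + rng.uniform(-0.01, 0.01, 30)
        proximal = 1.0 + rng.uniform(-0.01, 0.01, 30)
        events = segment_events(distal, proximal, t)
        assert all(e.kind == "halt" for e in events)

    def test_events_do_not_span_undefined_gaps(self):
        t = np.arange(20.0)
        distal = np.linspace(0, 9.5, 20)
        distal[10] = np.nan
        proximal = np.zeros(20)
        events = segment_events(distal, proximal, t)
        assembly = [e for e in events if e.kind == "assembly"]
        assert len(assembly) == 2
        assert all(not (e.t_start <= 10 <= e.t_end) or 10 in (e.t_start, e.t_end)
                   for e in assembly)

    def test_recovers_simulated_rates_within_ten_percent(self, small_cell):
        kin = sample_kinetics(
            small_cell, SMALL_ACQ.pixel_size, 5, seed=21,
            v_assembly_range=(0.6, 0.6), v_disassembly_range=(0.3, 0.3),
        )
        stack, truth = simulate_adhesion_timelapse(small_cell, kin, SMALL_ACQ, seed=21)
        res = studies.recover_turnover(stack, small_cell)
        rates_a = res.per_track.assembly_rate.dropna()
        rates_d = res.per_track.disassembly_rate.dropna()
        assert len(rates_a) == 5
        assert np.all(np.abs(rates_a - 0.6) / 0.6 < 0.10)
        assert np.all(np.abs(rates_d - 0.3) / 0.3 < 0.10)


class TestTurnoverMetrics:
    def _track(self, first, last):
        tr = AdhesionTrack(track_id=0, shape=(8, 8), pixel_size=0.2)
        tr.frames = list(range(first, last + 1))
        tr.censored_start = first == 0
        return tr

    def test_arithmetic_example(self):
        from fadyn.dynamics import TurnoverEvent

        events = [
            TurnoverEvent("assembly", 0.0, 8.0, 4.0, 0.5),
            TurnoverEvent("halt", 8.0, 18.0, 0.0, 0.0),
        ]
        dyn = turnover_metrics(events, self._track(0, 17), acq_duration=60.0)
        assert dyn.assembly_rate == pytest.approx(0.5)
        assert dyn.halt_time == pytest.approx(10.0)
        assert dyn.lifespan == pytest.approx(18.0)
        assert np.isnan(dyn.disassembly_rate)  # missing, not zero

    def test_full_span_track_capped_and_censored(self):
        tr = self._track(0, 59)
        tr.censored_end = True
        dyn = turnover_metrics([], tr, acq_duration=60.0)
        assert dyn.lifespan == 60.0 and dyn.censored_start and dyn.censored_end

    def test_time_conservation_on_simulated_batch(self, small_cell):
        """assembly + disassembly + halt + undefined time covers every
        within-track interval."""
        kin = sample_kinetics(small_cell, SMALL_ACQ.pixel_size, 6, seed=13)
        stack, _ = simulate_adhesion_timelapse(small_cell, kin, SMALL_ACQ, seed=13)
        res = studies.recover_turnover(stack, small_cell)
        for tr in res.tracks:
            if tr.track_id not in res.kymographs:
                continue
            row = res.per_track.set_index("track_id").loc[tr.track_id]
            events = res.events[res.events.track_id == tr.track_id]
            covered = (events.t_end - events.t_start).sum()
            assert covered == pytest.approx(tr.last_frame - tr.first_frame, abs=1e-9)


class TestDensityAndPeriphery:
    def test_density_arithmetic(self):
        labels = np.zeros((100, 100), dtype=np.int32)
        for i in range(10):
            labels[5 * i : 5 * i + 5, :5] = i + 1
        from fadyn.prep import LabelMap

        lm = LabelMap(labels=labels, pixel_size=0.2)
        cell = np.ones((100, 100), dtype=bool)
        count, per_um2, frac = adhesion_density(lm, cell)
        assert count == 10
        assert frac == pytest.approx(250 / 10000)
        assert per_um2 == pytest.approx(10 / (10000 * 0.04))

    def test_empty_label_map(self):
        from fadyn.prep import LabelMap

        lm = LabelMap(labels=np.zeros((10, 10), dtype=np.int32), pixel_size=0.2)
        assert adhesion_density(lm, np.ones((10, 10), dtype=bool)) == (0, 0.0, 0.0)

    def test_half_covered_peripheral_region(self, ellipse_cell):
        # adhesions fill the left half of the frame entirely
        adhesions = np.zeros_like(ellipse_cell)
        adhesions[:, : ellipse_cell.shape[1] // 2] = True
        f_left = peripheral_adhesion_fraction(
            adhesions, ellipse_cell, 0.2, anchor_um=(7.0, 20.0)
        )
        none = peripheral_adhesion_fraction(
            np.zeros_like(ellipse_cell), ellipse_cell, 0.2, anchor_um=(7.0, 20.0)
        )
        assert none == 0.0
        assert 0.9 <= f_left <= 1.0  # region at the left pole sits in the filled half

    def test_region_outside_cell_rejected(self, ellipse_cell):
        with pytest.raises(ValueError):
            peripheral_adhesion_fraction(
                np.zeros_like(ellipse_cell), ellipse_cell, 0.2, anchor_um=(0.4, 0.4)
            )


class TestNoiseRobustness:
    def test_mean_rates_within_twenty_percent_at_snr_ten(self):
        m = studies.turnover_recovery_study(seed=5, n_adhesions=8, noisy=True)
        assert m.rec_track_id.notna().sum() == 8
        rel_a = abs(m.rec_assembly_rate.mean() - m.v_assembly.mean()) / m.v_assembly.mean()
        rel_d = abs(m.rec_disassembly_rate.mean() - m.v_disassembly.mean()) / m.v_disassembly.mean()
        assert rel_a < 0.20 and rel_d < 0.20
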