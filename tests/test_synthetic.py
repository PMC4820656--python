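import numpy as np
import pytest
from scipy import stats as sps

from nkscreen.layout import ChipLayout, nominal_well_rois
from nkscreen.synthetic import (
    AssayConfig,
    KillDistribution,
    OpticsModel,
    RESTING_KILL_DIST,
    SERIAL_KILL_DIST,
    preset_config,
    render_screen,
    sample_kills,
    sample_occupancy,
    simulate_assay,
    timepoint_minutes,
)


class TestKillDistribution:
    def test_validation(self):
        with pytest.raises(ValueError):
            KillDistribution([0.5, 0.4])  # does not sum to 1
        with pytest.raises(ValueError):
            KillDistribution([1.5, -0.5])

    def test_preset_anchors(self):
        # resting NK: 72% kill nothing, ~1% are serial killers
        assert RESTING_KILL_DIST.p[0] == pytest.approx(0.72)
        assert RESTING_KILL_DIST.tail(3) == pytest.approx(0.01)
        # serial assay calibration: >=3-killers commit 70% of kills,
        # >=5-killers ~22%
        assert SERIAL_KILL_DIST.mean() == pytest.approx(1.70)
        assert SERIAL_KILL_DIST.expected_share(3) == pytest.approx(0.70)
        assert SERIAL_KILL_DIST.expected_share(5) == pytest.approx(0.2176, abs=1e-3)


class TestOccupancy:
    def test_mean_targets_calibration(self, rng):
        lay = ChipLayout(subunit_rows=4, subunit_cols=4)  # 1296 wells
        cfg, _ = preset_config("resting")
        truth = sample_occupancy(lay, cfg, rng)
        n_t = (truth.cells["cell_class"] == "target").sum()
        mean = n_t / lay.n_wells
        # Poisson(3) truncated at the per-well placement capacity
        assert mean == pytest.approx(3.0, abs=0.15)

    def test_zero_et_ratio_no_nk(self, rng):
        lay = ChipLayout(subunit_rows=2, subunit_cols=2)
        cfg = AssayConfig(et_ratio=0.0)
        truth = sample_occupancy(lay, cfg, rng)
        assert (truth.cells["cell_class"] == "nk").sum() == 0

    def test_initial_dead_fraction(self, rng):
        lay = ChipLayout(subunit_rows=6, subunit_cols=6)
        cfg = AssayConfig(initial_dead_fraction=0.06)
        truth = sample_occupancy(lay, cfg, rng)
        targets = truth.cells[truth.cells["cell_class"] == "target"]
        dead0 = np.isneginf(targets["death_time_min"]).mean()
        assert dead0 == pytest.approx(0.06, abs=0.01)

    def test_cells_placed_inside_their_well(self, rng):
        lay = ChipLayout(subunit_rows=1, subunit_cols=1)
        cfg, _ = preset_config("serial_assay")
        truth = sample_occupancy(lay, cfg, rng)
        rois = {r.index.global_id(lay): r for r in nominal_well_rois(lay)}
        for row in truth.cells.itertuples():
            roi = rois[row.well_id]
            assert roi.contains(row.y_px, row.x_px)


class TestKills:
    def test_point_mass_zero_no_nk_kills(self, rng):
        lay = ChipLayout(subunit_rows=2, subunit_cols=2)
        cfg, _ = preset_config("resting")
        truth = sample_occupancy(lay, cfg, rng)
        truth = sample_kills(truth, KillDistribution([1.0]), cfg, rng)
        assert (truth.cells["killer_id"] >= 0).sum() == 0
        assert truth.nk_kill_counts().sum() == 0

    def test_kills_never_exceed_available_targets(self, rng):
        lay = ChipLayout(subunit_rows=3, subunit_cols=3)
        cfg, dist = preset_config("serial_assay")
        truth = sample_kills(sample_occupancy(lay, cfg, rng), dist, cfg, rng)
        cells = truth.cells
        killable = cells[
            (cells["cell_class"] == "target") & ~np.isneginf(cells["death_time_min"])
        ]
        per_well_killable = killable.groupby("well_id").size()
        nk = cells[cells["cell_class"] == "nk"]
        for wid, grp in nk.groupby("well_id"):
            assert grp["kill_count"].sum() <= per_well_killable.get(wid, 0)

    def test_monotone_death_and_conservation(self, resting_sim):
        truth = resting_sim.truth
        labels = resting_sim.config.timepoints
        prev = None
        n_targets = (
            truth.cells[truth.cells["cell_class"] == "target"].groupby("well_id").size()
        )
        for lab in labels:
            counts = truth.well_counts(lab)
            total = counts["n_target_live"] + counts["n_target_dead"]
            assert (total.reindex(n_targets.index, fill_value=0) == n_targets).all()
            if prev is not None:
                merged = prev.join(counts, lsuffix="_a")
                assert (merged["n_target_live"] <= merged["n_target_live_a"]).all()
            prev = counts

    def test_kill_histogram_matches_preset(self, rng):
        """GOF of realized kill counts vs the preset, no truncation active."""
        cfg, dist = preset_config("resting")
        lay = ChipLayout(subunit_rows=9, subunit_cols=9)  # 6561 wells
        truth = sample_kills(sample_occupancy(lay, cfg, rng), dist, cfg, rng)
        cells = truth.cells
        live0 = (
            cells[(cells["cell_class"] == "target") & ~np.isneginf(cells["death_time_min"])]
            .groupby("well_id").size()
        )
        nk_per_well = cells[cells["cell_class"] == "nk"].groupby("well_id").size()
        ok_wells = set(nk_per_well[nk_per_well == 1].index) & set(live0[live0 >= 3].index)
        sub = cells[(cells["cell_class"] == "nk") & cells["well_id"].isin(ok_wells)]
        assert len(sub) >= 1000
        obs = np.bincount(sub["kill_count"].astype(int), minlength=4)
        _, p = sps.chisquare(obs, dist.p * obs.sum())
        assert p > 0.01


class TestRendering:
    def test_empty_well_is_background_noise(self, small_layout, rng):
        cfg = AssayConfig(mean_targets_per_well=0.0, et_ratio=0.0)
        optics = OpticsModel(noise_sd=3.0)
        truth = sample_occupancy(small_layout, cfg, rng)
        stack = render_screen(small_layout, truth, optics, "T_0h", rng=rng)
        roi = nominal_well_rois(small_layout)[0]
        r0, c0, r1, c1 = roi.bbox
        for ch in (1, 2, 3):
            crop = stack[ch, r0:r1, c0:c1]
            assert crop.mean() == pytest.approx(optics.background, abs=1.0)
            assert crop.std() == pytest.approx(optics.noise_sd, abs=1.0)

    def test_noiseless_single_target_peak(self, small_layout, noiseless_optics, rng):
        cfg = AssayConfig(mean_targets_per_well=1.0, et_ratio=0.0, initial_dead_fraction=0.0)
        truth = sample_occupancy(small_layout, cfg, rng, noiseless_optics)
        stack = render_screen(small_layout, truth, noiseless_optics, "T_0h", rng=rng)
        targets = truth.cells[truth.cells["cell_class"] == "target"]
        for row in targets.itertuples():
            y, x = int(round(row.y_px)), int(round(row.x_px))
            peak = stack[2, y, x] - noiseless_optics.background
            assert peak == pytest.approx(
                noiseless_optics.live_green_level * row.level_scale, rel=0.01
            )

    def test_bleaching_closed_form(self, small_layout, rng):
        optics = OpticsModel(noise_sd=0.0, debris_rate_late=0.0, bleach_factor_per_screen=0.8,
                             nk_extra_bleach=1.0, level_jitter_sd=0.0)
        cfg = AssayConfig(mean_targets_per_well=1.0, et_ratio=0.0, initial_dead_fraction=0.0,
                          spontaneous_death_per_interval=0.0)
        truth = sample_occupancy(small_layout, cfg, rng, optics)
        s0 = render_screen(small_layout, truth, optics, "T_0h", rng=rng, screen_index=0)
        s2 = render_screen(small_layout, truth, optics, "T_12h", rng=rng, screen_index=2)
        g0 = s0[2] - optics.background
        g2 = s2[2] - optics.background
        assert g2.max() == pytest.approx(0.64 * g0.max(), rel=1e-6)

    def test_simulation_deterministic(self, small_layout):
        cfg, dist = preset_config("resting")
        a = simulate_assay(small_layout, cfg, dist, None, np.random.default_rng(7))
        b = simulate_assay(small_layout, cfg, dist, None, np.random.default_rng(7))
        assert a.truth.cells.equals(b.truth.cells)
        for key in a.tiles:
            np.testing.assert_array_equal(a.tiles[key], b.tiles[key])

    def test_serial_preset_doubles_targets_and_prescreens(self):
        resting, _ = preset_config("resting")
        serial, _ = preset_config("serial_assay")
        assert serial.mean_targets_per_well == 2 * resting.mean_targets_per_well
        assert serial.prescreen and serial.timepoints[0] == "T_minusNK"
        assert timepoint_minutes("T_minusNK") < 0

    def test_tile_count(self):
        lay = ChipLayout(subunit_rows=2, subunit_cols=2)
        cfg, dist = preset_config("serial_assay")
        sim = simulate_assay(lay, cfg, dist, None, np.random.default_rng(3))
        # 4 fields x (prescreen + 3 screens)
        assert len(sim.tiles) == 16
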