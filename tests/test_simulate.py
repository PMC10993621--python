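"""Simulator contracts: placement, rendering, turnover, cohort programming."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from microdyn import (
    GroupConfig,
    SimulationConfig,
    render_cell,
    simulate_cohort,
    simulate_timelapse,
)
from microdyn.simulate import CapacityError, place_somas


def small_config(**kw):
    defaults = dict(field_size_px=(256, 256), pixel_size_um=0.5, n_cells=10,
                    soma_radius_um=4.0, n_branches_per_cell=4,
                    branch_length_um=15.0, min_soma_separation_um=15.0, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPlacement:
    def test_pairwise_separation_holds(self):
        cfg = small_config(n_cells=25, min_soma_separation_um=20.0)
        xy = place_somas(cfg)
        assert xy.shape == (25, 2)
        assert pdist(xy).min() >= cfg.min_soma_separation_um  # brute-force check

    def test_single_cell_inside_bounds(self):
        cfg = small_config(n_cells=1)
        xy = place_somas(cfg)
        h_um, w_um = cfg.field_size_um
        assert 0 <= xy[0, 0] <= w_um and 0 <= xy[0, 1] <= h_um

    def test_same_seed_identical(self):
        cfg = small_config(n_cells=12)
        assert np.array_equal(place_somas(cfg), place_somas(cfg))

    def test_overpacked_field_raises_capacity_error(self):
        cfg = small_config(n_cells=60, min_soma_separation_um=40.0)
        with pytest.raises(CapacityError, match="placed only"):
            place_somas(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(min_soma_separation_um=2.0)  # < 2 * soma radius
        with pytest.raises(ValueError):
            small_config(turnover_prob=1.5)
        with pytest.raises(ValueError):
            small_config(n_frames=1)


class TestRenderCell:
    def test_no_branches_is_exactly_the_soma_disk(self):
        cfg = small_config(n_branches_per_cell=0)
        mask = render_cell((64.0, 64.0), cfg)
        r_px = cfg.soma_radius_um / cfg.pixel_size_um
        area = mask.sum()
        assert abs(area - np.pi * r_px**2) / (np.pi * r_px**2) < 0.05

    def test_branches_add_process_pixels(self):
        cfg = small_config(n_branches_per_cell=4, branch_tortuosity=0.0)
        soma_only = render_cell((64.0, 64.0), small_config(n_branches_per_cell=0))
        full = render_cell((64.0, 64.0), cfg)
        n_proc = full.sum() - soma_only.sum()
        expected = cfg.n_branches_per_cell * cfg.branch_length_um / cfg.pixel_size_um
        assert n_proc == pytest.approx(expected, rel=0.25)

    def test_straight_rays_lie_on_equally_spaced_angles(self):
        cfg = small_config(n_branches_per_cell=4, branch_tortuosity=0.0,
                           branch_length_um=20.0)
        mask = render_cell((64.0, 64.0), cfg).astype(bool)
        soma = render_cell((64.0, 64.0), small_config(n_branches_per_cell=0)).astype(bool)
        rr, cc = np.nonzero(mask & ~soma)
        ang = np.arctan2(rr - 128, cc - 128)  # px center of the 64 um point
        on_axis = np.minimum(np.abs(np.sin(2 * ang)), np.abs(np.cos(2 * ang)))
        assert np.all(on_axis < 0.2)  # every process pixel near a cardinal ray


class TestTimelapse:
    def test_zero_turnover_freezes_all_frames(self):
        cfg = small_config(turnover_prob=0.0)
        stack, gt = simulate_timelapse(cfg)
        assert all(np.array_equal(stack.frames[0], f) for f in stack.frames)
        assert gt.target_metrics["motility"] == 0.0

    def test_determinism_byte_identical(self):
        cfg = small_config(turnover_prob=0.2)
        s1, _ = simulate_timelapse(cfg)
        s2, _ = simulate_timelapse(cfg)
        assert s1.frames.tobytes() == s2.frames.tobytes()

    def test_positive_area_exactly_conserved(self):
        # the replacement rule keeps soma + active process count constant
        cfg = small_config(turnover_prob=0.3)
        stack, gt = simulate_timelapse(cfg, record_pixels=True)
        counts = np.array(gt.per_frame_pixel_counts)
        expected = gt.target_metrics["soma_px"] + gt.target_metrics["process_px"]
        assert np.all(counts == expected)

    def test_active_fraction_turnover_combination_validated(self):
        cfg = small_config(turnover_prob=0.9, active_fraction=0.9)
        with pytest.raises(ValueError, match="active_fraction"):
            simulate_timelapse(cfg)

    def test_frames_are_binary_with_timestamps(self):
        cfg = small_config()
        stack, _ = simulate_timelapse(cfg)
        assert stack.binary
        assert np.array_equal(stack.timestamps_min,
                              np.arange(cfg.n_frames) * cfg.frame_interval_min)


@pytest.fixture
def tiny_groups():
    pop = SimulationConfig(field_size_px=(256, 256), pixel_size_um=1.0,
                           n_cells=20, soma_radius_um=4.0, branch_length_um=12.0,
                           min_soma_separation_um=22.0, soma_drift_sigma_um=2.0,
                           loss_schedule={"W1": 0.3}, gain_schedule={"W1": 0.1},
                           seed=3)
    tl = SimulationConfig(field_size_px=(128, 128), pixel_size_um=0.5,
                          n_cells=5, soma_radius_um=3.0, branch_length_um=10.0,
                          min_soma_separation_um=12.0, seed=3)
    return {"g": GroupConfig(n_animals=2, population=pop, timelapse=tl)}


class TestCohort:
    def test_programmed_loss_and_gain_fractions_exact(self, tiny_groups, tmp_path):
        _, truth = simulate_cohort(tmp_path, tiny_groups, sessions=("B", "W1"))
        for animal in truth["animals"].values():
            n0 = len(animal["population"]["B"]["labels"])
            lost = animal["population"]["W1"]["lost"]
            gained = animal["population"]["W1"]["gained"]
            assert len(lost) == round(0.3 * n0)
            assert len(gained) == round(0.1 * n0)
            assert not set(lost) & set(gained)

    def test_zero_drift_zero_loss_keeps_positions(self, tmp_path):
        pop = SimulationConfig(field_size_px=(256, 256), pixel_size_um=1.0,
                               n_cells=10, soma_radius_um=4.0,
                               min_soma_separation_um=20.0,
                               soma_drift_sigma_um=0.0, seed=1)
        tl = SimulationConfig(field_size_px=(64, 64), pixel_size_um=0.5,
                              n_cells=2, soma_radius_um=3.0, branch_length_um=8.0,
                              min_soma_separation_um=10.0, seed=1)
        groups = {"g": GroupConfig(1, population=pop, timelapse=tl)}
        _, truth = simulate_cohort(tmp_path, groups, sessions=("B", "S1", "S2"))
        pop_truth = truth["animals"]["g01"]["population"]
        for s in ("S1", "S2"):
            assert pop_truth[s]["x_um"] == pop_truth["B"]["x_um"]
            assert pop_truth[s]["y_um"] == pop_truth["B"]["y_um"]

    def test_identical_groups_identical_images(self, tiny_groups, tmp_path):
        groups = {"a": tiny_groups["g"], "b": tiny_groups["g"]}
        simulate_cohort(tmp_path, groups, sessions=("B", "W1"))
        for s in ("B", "W1"):
            pa = (tmp_path / f"a01_{s}_population.tif").read_bytes()
            pb = (tmp_path / f"b01_{s}_population.tif").read_bytes()
            assert pa == pb

    def test_excess_loss_schedule_raises(self, tmp_path):
        pop = SimulationConfig(field_size_px=(256, 256), pixel_size_um=1.0,
                               n_cells=5, soma_radius_um=4.0,
                               min_soma_separation_um=20.0,
                               loss_schedule={"W1": 0.4, "W2": 0.2}, seed=0)
        tl = SimulationConfig(field_size_px=(64, 64), pixel_size_um=0.5,
                              n_cells=2, soma_radius_um=3.0, branch_length_um=8.0,
                              min_soma_separation_um=10.0, seed=0)
        groups = {"g": GroupConfig(1, population=pop, timelapse=tl)}
        with pytest.raises(ValueError, match="non-decreasing"):
            simulate_cohort(tmp_path, groups, sessions=("B", "W1", "W2"))

    def test_manifest_and_ground_truth_written(self, tiny_groups, tmp_path):
        manifest, _ = simulate_cohort(tmp_path, tiny_groups, sessions=("B", "W1"))
        assert len(manifest) == 4  # 2 animals x 2 sessions
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()

    def test_grayscale_mode_emits_noisy_images(self, tiny_groups, tmp_path):
        import tifffile

        simulate_cohort(tmp_path, tiny_groups, sessions=("B",), grayscale=True)
        img = tifffile.imread(tmp_path / "g01_B_population.tif")
        assert img.dtype == np.uint16
        assert len(np.unique(img)) > 2
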