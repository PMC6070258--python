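"""Free-energy landscapes, basin extraction, basin shifts and bend angles."""

import numpy as np
import pytest

import mdscope as m
from mdscope import modes, synthetic as syn
from mdscope.constants import BOLTZMANN_J_PER_MOL_K

KT_303 = BOLTZMANN_J_PER_MOL_K * 303.0


def _proj_from_samples(x, y):
    vals = np.stack([x, y], axis=1)
    return modes.ProjectionSeries(times_ns=np.arange(len(x)) * 0.01, values=vals)


class TestFelFromProjections:
    def test_energy_zero_at_the_density_maximum(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 5000), rng.normal(0, 1, 5000))
        fel = m.fel_from_projections(proj)
        assert fel.energy.min() == pytest.approx(0.0)
        assert (fel.energy[np.isfinite(fel.energy)] >= 0).all()

    def test_density_ratio_e_maps_to_kt(self):
        # G at P = P_max / e must equal kT (~2519 J/mol at 303 K)
        energy = -BOLTZMANN_J_PER_MOL_K * 303.0 * np.log(1 / np.e)
        assert energy == pytest.approx(2519.28, abs=0.5)
        rng = np.random.default_rng(3)
        proj = _proj_from_samples(rng.normal(0, 1, 200000), rng.normal(0, 1, 200000))
        fel = m.fel_from_projections(proj, grid=60)
        # the cell whose density is closest to P_max/e should sit near kT
        density = np.exp(-fel.energy / KT_303)
        target = np.abs(density - 1 / np.e)
        cell = np.unravel_index(np.argmin(target), density.shape)
        assert fel.energy[cell] == pytest.approx(KT_303, rel=0.02)

    def test_radial_monotonicity_for_a_symmetric_gaussian(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 50000), rng.normal(0, 1, 50000))
        fel = m.fel_from_projections(proj, grid=40)
        cx, cy = np.unravel_index(np.argmin(fel.energy), fel.energy.shape)
        ray = fel.energy[cx, cy:]
        finite = ray[np.isfinite(ray)]
        # allow small KDE noise: each step along the ray rarely decreases much
        assert (np.diff(finite) > -120).all()
        assert finite[-1] > finite[0]

    def test_degenerate_coordinate_rejected(self):
        proj = _proj_from_samples(np.zeros(500), np.random.default_rng(0).normal(0, 1, 500))
        with pytest.raises(ValueError, match="degenerate"):
            m.fel_from_projections(proj)

    def test_too_few_frames_rejected(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
        with pytest.raises(ValueError):
            m.fel_from_projections(proj)

    def test_binned_kde_agrees_with_scipy_kde(self, rng):
        from scipy.stats import gaussian_kde

        x = rng.normal(0, 1.3, 4000)
        y = rng.normal(0, 0.8, 4000)
        fel = m.fel_from_projections(_proj_from_samples(x, y), grid=50)
        kde = gaussian_kde(np.stack([x, y]))
        xc = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
        yc = 0.5 * (fel.y_edges[:-1] + fel.y_edges[1:])
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        ref = kde(np.stack([gx.ravel(), gy.ravel()])).reshape(50, 50)
        g_ref = -KT_303 * np.log(ref / ref.max())
        core = np.isfinite(fel.energy) & (g_ref < 2 * KT_303)
        assert np.abs(fel.energy[core] - g_ref[core]).mean() < 0.25 * KT_303


class TestBasins:
    def test_single_gaussian_has_one_basin_containing_the_minimum(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 20000), rng.normal(0, 1, 20000))
        fel = m.fel_from_projections(proj)
        basins = m.extract_basins(fel, threshold=KT_303)
        assert len(basins) == 1
        assert basins[0].min_energy == pytest.approx(0.0)

    def test_tiny_threshold_keeps_one_cell(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 20000), rng.normal(0, 1, 20000))
        fel = m.fel_from_projections(proj)
        basins = m.extract_basins(fel, threshold=1e-9)
        assert len(basins) == 1
        assert basins[0].n_cells == 1

    def test_no_cells_below_threshold_returns_empty_list(self, rng):
        proj = _proj_from_samples(rng.normal(0, 1, 20000), rng.normal(0, 1, 20000))
        fel = m.fel_from_projections(proj)
        fel.energy = fel.energy + 10.0
        assert m.extract_basins(fel, threshold=5.0) == []

    def test_double_well_basins_disjoint_and_occupancy_bounded(self, double_well_pair):
        free, _ = double_well_pair
        proj = modes.project_trajectory(free.trajectory, free.modes)
        fel = m.fel_from_projections(proj, (0, 1))
        basins = m.extract_basins(fel, threshold=2 * KT_303)
        assert len(basins) == 2
        all_frames = np.concatenate([b.frames for b in basins])
        assert len(np.unique(all_frames)) == len(all_frames)  # disjoint
        assert len(all_frames) <= proj.n_frames

    def test_equal_occupancy_wells_have_equal_depth(self):
        r = syn.gen_double_well(n_frames=50000, occupancy=0.5, seed=13)
        proj = modes.project_trajectory(r.trajectory, r.modes)
        fel = m.fel_from_projections(proj, (0, 1))
        basins = m.extract_basins(fel, threshold=2 * KT_303)
        assert len(basins) == 2
        assert abs(basins[0].min_energy - basins[1].min_energy) < 0.2 * KT_303

    def test_occupancy_ratio_matches_planted_boltzmann_ratio(self):
        # wide wells: separation >> kernel bandwidth
        r = syn.gen_double_well(n_frames=50000, occupancy=0.8, separation=10.0, seed=15)
        proj = modes.project_trajectory(r.trajectory, r.modes)
        fel = m.fel_from_projections(proj, (0, 1))
        basins = m.extract_basins(fel, threshold=6 * KT_303)
        ratio = basins[0].occupancy / basins[1].occupancy
        assert ratio == pytest.approx(0.8 / 0.2, rel=0.10)

    def test_deepest_basin_matches_the_majority_state(self, double_well_pair):
        free, _ = double_well_pair
        proj = modes.project_trajectory(free.trajectory, free.modes)
        fel = m.fel_from_projections(proj, (0, 1))
        deepest = m.extract_basins(fel, threshold=2 * KT_303)[0]
        states = free.meta["state"][deepest.frames]
        assert (states == "A").mean() > 0.99  # occupancy 0.8 planted in well A


class TestBasinShift:
    def test_identical_landscapes_do_not_shift(self, double_well_pair):
        free, _ = double_well_pair
        proj = modes.project_trajectory(free.trajectory, free.modes)
        fel = m.fel_from_projections(proj, (0, 1))
        np.testing.assert_allclose(
            m.basin_shift(fel, fel, threshold=2 * KT_303), 0.0, atol=1e-12
        )

    def test_translated_landscape_shifts_by_the_translation(self, rng):
        x, y = rng.normal(0, 1, 30000), rng.normal(0, 1, 30000)
        fel_a = m.fel_from_projections(_proj_from_samples(x, y))
        fel_b = m.fel_from_projections(_proj_from_samples(x - 2.0, y))
        shift = m.basin_shift(fel_a, fel_b, threshold=KT_303)
        assert shift[0] == pytest.approx(-2.0, abs=max(fel_a.cell_widths))
        assert abs(shift[1]) < max(fel_a.cell_widths)

    def test_population_shift_moves_the_deepest_basin_between_wells(self, double_well_pair):
        free, bound = double_well_pair
        p_free = modes.project_trajectory(free.trajectory, free.modes)
        p_bound = modes.project_trajectory(bound.trajectory, free.modes)  # common basis
        fel_free = m.fel_from_projections(p_free, (0, 1))
        fel_bound = m.fel_from_projections(p_bound, (0, 1))
        shift = m.basin_shift(fel_free, fel_bound, threshold=2 * KT_303)
        planted = free.meta["center_b_pc1"] - free.meta["center_a_pc1"]
        assert shift[0] == pytest.approx(planted, abs=max(fel_free.cell_widths))
        assert abs(shift[1]) < max(fel_free.cell_widths)


class TestBendAngle:
    def _traj_of_points(self, frames):
        st = syn.ca_chain_structure(3)
        return m.Trajectory(np.asarray(frames, dtype=float), 10.0, st), [
            m.select_atoms(st, f"resid {i}") for i in (1, 2, 3)
        ]

    def test_collinear_points_give_180_degrees(self):
        traj, sels = self._traj_of_points([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]])
        ang = m.bend_angle_series(traj, tuple(sels))
        assert ang[0] == pytest.approx(180.0)

    def test_right_angle_construction(self):
        traj, sels = self._traj_of_points([[[1, 0, 0], [0, 0, 0], [0, 1, 0]]])
        ang = m.bend_angle_series(traj, tuple(sels))
        assert ang[0] == pytest.approx(90.0)

    def test_coincident_points_flagged_as_nan(self):
        traj, sels = self._traj_of_points([[[0, 0, 0], [0, 0, 0], [0, 1, 0]]])
        ang = m.bend_angle_series(traj, tuple(sels))
        assert np.isnan(ang[0])

    def test_hinge_closing_by_planted_angle(self):
        open_run = syn.gen_two_domain_hinge(theta0_deg=0.0, n_frames=300, seed=31)
        # closing the elbow: rebuild with the arms 15 degrees closer
        st_open = open_run.structure
        closed_struct = syn._backbone_chain(
            len(np.unique(st_open.residue_id)),
            open_run.meta["pivot_residue"] - 1,
            arm_angle_deg=105.0,
        )
        closed = m.Trajectory(
            np.repeat(closed_struct.coords[None], 300, axis=0)
            + np.random.default_rng(0).normal(0, 0.05, (300, st_open.n_atoms, 3)),
            10.0,
            closed_struct,
        )
        tri = open_run.meta["bend_triple_residues"]
        sels_open = tuple(
            m.select_atoms(st_open, f"resid {r} and name CA") for r in tri
        )
        sels_closed = tuple(
            m.select_atoms(closed_struct, f"resid {r} and name CA") for r in tri
        )
        a_open = np.nanmean(m.bend_angle_series(open_run.trajectory, sels_open))
        a_closed = np.nanmean(m.bend_angle_series(closed, sels_closed))
        assert a_open - a_closed == pytest.approx(15.0, abs=0.5)
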