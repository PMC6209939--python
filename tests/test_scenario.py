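"""Geometry: antenna ring, antenna-count rule, rasterization, serialization."""

import numpy as np
import pytest
from scipy.constants import c as c0

from mwtomo.media import MATERIALS, DebyeMedium
from mwtomo.scenario import (
    PEC,
    CylinderTarget,
    Grid2D,
    Scenario,
    antenna_positions,
    default_single_target,
    make_grid,
    rasterize,
    suggest_num_antennas,
    symmetric_pair,
)


class TestAntennaPositions:
    def test_default_ring_eight_at_130mm(self):
        pos = antenna_positions(Scenario())
        assert pos.shape == (8, 2)
        np.testing.assert_allclose(np.hypot(pos[:, 0], pos[:, 1]), 0.065, rtol=1e-12)
        ang = np.unwrap(np.arctan2(pos[:, 1], pos[:, 0]))
        np.testing.assert_allclose(np.diff(ang), np.pi / 4, rtol=1e-12)
        # antenna 1 on the +x axis, counter-clockwise numbering
        np.testing.assert_allclose(pos[0], [0.065, 0.0], atol=1e-15)

    def test_two_antennas_are_antipodal(self):
        pos = antenna_positions(Scenario(n_antennas=2))
        np.testing.assert_allclose(pos[0], -pos[1], atol=1e-15)

    def test_sixteen_antenna_150mm_variant(self):
        pos = antenna_positions(Scenario(n_antennas=16, array_diam=0.150))
        assert pos.shape == (16, 2)
        np.testing.assert_allclose(np.hypot(pos[:, 0], pos[:, 1]), 0.075, rtol=1e-12)

    def test_rotation_invariance_as_a_set(self):
        scen = Scenario()
        pos = antenna_positions(scen)
        n = scen.n_antennas
        rot = Scenario(
            antenna_angles=tuple(2 * np.pi * (k + 1) / n for k in range(n))
        )
        pos_rot = antenna_positions(rot)
        # rotating the start angle by 2 pi / n permutes the same point set
        def key(p):
            return tuple(np.round(p, 12))

        assert {key(p) for p in pos} == {key(p) for p in pos_rot}


class TestSuggestNumAntennas:
    def test_degenerate_small_domain(self):
        assert suggest_num_antennas(MATERIALS["vacuum"], 1.0e9, 1e-9) == 1

    def test_vacuum_hand_computed(self):
        beta = 2 * np.pi * 1.0e9 / c0
        expected = int(np.ceil(2 * beta * 0.05))
        assert suggest_num_antennas(DebyeMedium(eps_inf=1.0), 1.0e9, 0.05) == expected

    def test_monotone_in_radius(self):
        bg = MATERIALS["glycerine_water_90"]
        counts = [suggest_num_antennas(bg, 1.5e9, r) for r in (0.02, 0.04, 0.08)]
        assert counts == sorted(counts)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            suggest_num_antennas(MATERIALS["vacuum"], -1e9, 0.05)
        with pytest.raises(ValueError):
            suggest_num_antennas(MATERIALS["vacuum"], 1e9, 0.0)


class TestRasterize:
    def test_no_targets_uniform_background(self):
        scen = Scenario()
        grid = make_grid(scen, 2e-3)
        pm = rasterize(scen, grid)
        bg = scen.background
        assert np.all(pm.eps_inf == bg.eps_inf)
        assert np.all(pm.sigma_s == bg.sigma_s)
        assert not pm.pec.any()

    @pytest.mark.parametrize("dx_mm, tol", [(4.0, 0.30), (2.0, 0.15), (1.0, 0.07)])
    def test_disk_cell_count_approaches_area(self, dx_mm, tol):
        # 16 mm disk: expected cell count pi * 8^2 / dx^2
        dx = dx_mm * 1e-3
        scen = Scenario().with_targets(default_single_target())
        grid = make_grid(scen, dx)
        pm = rasterize(scen, grid)
        n_target = int(np.sum(pm.eps_inf != scen.background.eps_inf))
        expected = np.pi * 8.0**2 / dx_mm**2
        assert abs(n_target - expected) / expected < tol

    def test_resolution_consistency_converges(self):
        scen = Scenario().with_targets(default_single_target())
        area_true = np.pi * 0.008**2
        errs = []
        for dx in (4e-3, 2e-3, 1e-3):
            pm = rasterize(scen, make_grid(scen, dx))
            n = int(np.sum(pm.eps_inf != scen.background.eps_inf))
            errs.append(abs(n * dx * dx - area_true) / area_true)
        assert errs[2] < errs[0]

    def test_two_disjoint_targets_differ_locally(self):
        scen1 = Scenario().with_targets(default_single_target())
        t1, t2 = symmetric_pair()
        scen2 = Scenario().with_targets(t1, t2)
        grid = make_grid(scen1, 2e-3)
        pm1 = rasterize(scen1, grid)
        pm2 = rasterize(scen2, grid)
        diff = pm1.eps_inf != pm2.eps_inf
        X, Y = grid.meshgrid()
        r2 = (X - t2.center[0]) ** 2 + (Y - t2.center[1]) ** 2
        assert diff.any()
        assert np.all(r2[diff] <= (t2.diameter / 2) ** 2)

    def test_pec_target_sets_mask(self):
        scen = Scenario().with_targets(default_single_target(medium=PEC))
        pm = rasterize(scen, make_grid(scen, 2e-3))
        assert pm.pec.sum() > 30

    def test_target_outside_wall_rejected(self):
        # inner tank is 100 mm diameter; a 16 mm target centered at 45 mm
        # would break the wall (construction already rejects ring overflow,
        # so use a scenario with a wider ring to reach rasterize's check)
        scen = Scenario(
            tank_inner_diam=0.100,
            recon_ring_diam=0.125,
            array_diam=0.130,
        ).with_targets(
            CylinderTarget(center=(0.045, 0.0), diameter=0.016, medium=MATERIALS["water"])
        )
        with pytest.raises(ValueError):
            rasterize(scen, make_grid(scen, 2e-3))


class TestScenarioValidation:
    def test_ring_must_fit_inside_array(self):
        with pytest.raises(ValueError):
            Scenario(recon_ring_diam=0.140)

    def test_array_inside_tank(self):
        with pytest.raises(ValueError):
            Scenario(array_diam=0.210)

    def test_target_inside_recon_ring(self):
        with pytest.raises(ValueError):
            Scenario().with_targets(
                CylinderTarget(center=(0.058, 0.0), diameter=0.016, medium=MATERIALS["water"])
            )

    def test_json_round_trip(self, tmp_path):
        scen = Scenario(n_antennas=16, array_diam=0.150).with_targets(
            default_single_target(), default_single_target(medium=PEC, diameter=0.012)
        )
        path = tmp_path / "scen.json"
        scen.to_json(path)
        back = Scenario.from_json(path)
        assert back.n_antennas == 16
        assert back.array_diam == pytest.approx(0.150)
        assert len(back.targets) == 2
        assert back.targets[1].is_pec
        np.testing.assert_allclose(back.targets[0].center, scen.targets[0].center)
        assert back.background == scen.background


class TestGrid2D:
    def test_index_of_center(self):
        grid = make_grid(Scenario(), 2e-3)
        i, j = grid.index_of(0.0, 0.0)
        assert grid.x_centers()[i] == pytest.approx(0.0, abs=1e-12)
        assert grid.y_centers()[j] == pytest.approx(0.0, abs=1e-12)

    def test_point_outside_raises(self):
        grid = Grid2D(nx=16, ny=16, dx=1e-3, origin=(0.0, 0.0))
        with pytest.raises(ValueError):
            grid.index_of(1.0, 0.0)
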