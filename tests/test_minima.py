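"""Minima detection, basin assignment and population-weighted free energies."""

import numpy as np
import pytest
from scipy.integrate import quad

from mdfes import (
    DEFAULT_KT,
    FreeEnergySurface,
    basin_populations,
    find_minima_grid,
    find_minima_precise,
    label_and_sort,
    minima_free_energies,
)
from mdfes.hills_io import CVMeta
from mdfes.minima import DEFAULT_DIVISIONS, MinimaSet, Minimum, _spreadsheet_label


def _surface_1d(values, lo=-2.0, hi=2.0, name="x"):
    return FreeEnergySurface(values=np.asarray(values, float), cv_meta=(CVMeta(name),),
                             grid_lo=[lo], grid_hi=[hi])


def _double_well_1d(res=256):
    x = np.linspace(-2, 2, res)
    return x, _surface_1d((x**2 - 1) ** 2)


def _four_well_2d(res):
    x = np.linspace(-2, 2, res)
    F = (x[:, None] ** 2 - 1) ** 2 + (x[None, :] ** 2 - 1) ** 2
    return x, FreeEnergySurface(values=F, cv_meta=(CVMeta("x"), CVMeta("y")),
                                grid_lo=[-2, -2], grid_hi=[2, 2])


class TestPreciseMode:
    def test_double_well_minima_and_boundary(self):
        x, f = _double_well_1d()
        minima, assignment = find_minima_precise(f)
        assert len(minima) == 2
        coords = sorted(m.cv_coords[0] for m in minima)
        sp = f.spacing(0)
        assert abs(coords[0] + 1) <= sp and abs(coords[1] - 1) <= sp
        bnodes = x[assignment.boundary_mask]
        assert np.all(np.abs(bnodes) <= 2 * sp)  # barrier sits at x = 0

    def test_single_parabola(self):
        x = np.linspace(-1, 1, 64)
        f = _surface_1d(x**2, -1, 1)
        minima, assignment = find_minima_precise(f)
        assert len(minima) == 1
        node = np.ravel_multi_index(minima[0].grid_index, f.values.shape)
        assert np.all(assignment.owner == node)
        assert not assignment.boundary_mask.any()

    @pytest.mark.parametrize("res", [64, 128, 256, 512])
    def test_four_well_count_and_coordinates(self, res):
        _, f = _four_well_2d(res)
        minima, _ = find_minima_precise(f)
        assert len(minima) == 4
        sp = f.spacing(0)
        for m in minima:
            assert all(abs(abs(c) - 1) <= sp for c in m.cv_coords)

    def test_four_well_boundaries_on_axes(self):
        _, f = _four_well_2d(128)
        _, assignment = find_minima_precise(f)
        xi = f.axis(0)
        bidx = np.argwhere(assignment.boundary_mask)
        near_axis = np.minimum(np.abs(xi[bidx[:, 0]]), np.abs(xi[bidx[:, 1]]))
        assert np.all(near_axis <= 2 * f.spacing(0))

    def test_constant_surface_rejected(self):
        f = _surface_1d(np.zeros(32))
        with pytest.raises(ValueError, match="no strict minima"):
            find_minima_precise(f)

    def test_basin_volume_stable_across_resolution(self):
        volumes = {}
        for res in (128, 256):
            _, f = _four_well_2d(res)
            _, assignment = find_minima_precise(f)
            owners, counts = np.unique(assignment.owner, return_counts=True)
            volumes[res] = np.sort(counts / counts.sum())
        assert np.abs(volumes[128] - volumes[256]).max() < 0.02


class TestGridMode:
    def test_monotone_ramp_has_single_edge_minimum(self):
        f = _surface_1d(np.linspace(0, 5, 64))
        assert len(find_minima_grid(f)) == 1  # left edge node only
        minima, _ = find_minima_precise(f)
        assert len(minima) == 1

    def test_four_well_found_and_subset_of_precise(self):
        _, f = _four_well_2d(128)
        grid = find_minima_grid(f)
        precise, _ = find_minima_precise(f)
        assert {m.grid_index for m in grid} == {m.grid_index for m in precise}

    def test_count_never_exceeds_cells(self, fw_run_small):
        from mdfes import fes_fast, normalize

        _, hills, _ = fw_run_small
        f = normalize(fes_fast(hills, resolution=96))
        grid = find_minima_grid(f, divisions=[3, 3])
        precise, _ = find_minima_precise(f)
        assert len(grid) <= 9
        assert len(grid) <= len(precise)
        assert {m.grid_index for m in grid} <= {m.grid_index for m in precise}

    def test_default_divisions_is_eight(self):
        # a 1D surface with two wells per default cell still yields 8 minima
        x = np.linspace(0, 1, 512)
        F = np.cos(32 * np.pi * x) * (1 + 0.1 * np.sin(3 * x))  # wells at (2k+1)/32, interior to cells
        f = _surface_1d(F, 0, 1)
        assert DEFAULT_DIVISIONS == 8
        assert len(find_minima_grid(f)) == 8

    def test_resolution_must_cover_divisions(self):
        f = _surface_1d(np.linspace(0, 1, 4), 0, 1)
        with pytest.raises(ValueError):
            find_minima_grid(f, divisions=8)


class TestPopulationFreeEnergies:
    @staticmethod
    def _two_gaussian_surface(res=256, a=8.0, b=6.0, wa=0.30, wb=0.22):
        x = np.linspace(-2, 2, res)
        F = -a * np.exp(-((x + 1) ** 2) / (2 * wa**2)) - b * np.exp(-((x - 1) ** 2) / (2 * wb**2))
        return x, _surface_1d(F), (a, b, wa, wb)

    def test_mirror_symmetric_basins_share_g(self):
        # even resolution: no node sits on the barrier, basins mirror exactly
        x = np.linspace(-2, 2, 256)
        f = _surface_1d((x**2 - 1) ** 2)
        _, assignment = find_minima_precise(f)
        minima = minima_free_energies(f, assignment, DEFAULT_KT)
        gs = sorted(m.g_population for m in minima)
        assert gs[0] == 0.0
        assert abs(gs[1]) < 1e-9

    def test_partition_sums_to_one(self):
        _, f, _ = self._two_gaussian_surface()
        _, assignment = find_minima_precise(f)
        p, _ = basin_populations(f, assignment, DEFAULT_KT)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_quadrature_oracle_for_two_wells(self):
        """Δg matches −kT·ln of the ratio of Boltzmann integrals computed by
        adaptive quadrature with the basin split at the barrier top."""
        _, f, (a, b, wa, wb) = self._two_gaussian_surface()
        _, assignment = find_minima_precise(f)
        minima = minima_free_energies(f, assignment, DEFAULT_KT)
        gs = sorted(m.g_population for m in minima)
        dg_pkg = gs[1] - gs[0]

        F = lambda s: -a * np.exp(-((s + 1) ** 2) / (2 * wa**2)) - b * np.exp(
            -((s - 1) ** 2) / (2 * wb**2)
        )
        xs = np.linspace(-0.5, 0.5, 20001)
        barrier = xs[np.argmax(F(xs))]
        za = quad(lambda s: np.exp(-F(s) / DEFAULT_KT), -2, barrier, limit=200)[0]
        zb = quad(lambda s: np.exp(-F(s) / DEFAULT_KT), barrier, 2, limit=200)[0]
        dg_oracle = abs(-DEFAULT_KT * np.log(min(za, zb) / max(za, zb)))
        assert abs(dg_pkg - dg_oracle) < 0.02

    def test_zero_temperature_limit_recovers_depth_difference(self):
        _, f, _ = self._two_gaussian_surface()
        _, assignment = find_minima_precise(f)
        minima = minima_free_energies(f, assignment, kT=1e-4)
        gs = sorted(m.g_population for m in minima)
        depths = sorted(m.depth for m in minima)
        assert abs((gs[1] - gs[0]) - (depths[1] - depths[0])) < 0.01

    def test_wide_shallow_basin_can_outrank_narrow_deep_one(self):
        # deeper-but-narrow right well vs shallow-but-wide left well
        x = np.linspace(-2, 2, 512)
        F = -4.0 * np.exp(-((x + 1) ** 2) / (2 * 0.5**2)) - 4.6 * np.exp(
            -((x - 1) ** 2) / (2 * 0.05**2)
        )
        f = _surface_1d(F)
        _, assignment = find_minima_precise(f)
        minima = minima_free_energies(f, assignment, DEFAULT_KT)
        deepest = min(minima, key=lambda m: m.depth)
        assert deepest.g_population > 0.0  # not the most populated state

    def test_invalid_kt(self):
        _, f, _ = self._two_gaussian_surface()
        _, assignment = find_minima_precise(f)
        with pytest.raises(ValueError):
            minima_free_energies(f, assignment, kT=0.0)


class TestLabels:
    def test_single_minimum_is_A(self):
        x = np.linspace(-1, 1, 64)
        minima, assignment = find_minima_precise(_surface_1d(x**2, -1, 1))
        labelled = minima_free_energies(_surface_1d(x**2, -1, 1), assignment, DEFAULT_KT)
        assert labelled.labels == ["A"]

    def test_equal_g_ties_broken_by_grid_index(self):
        ms = MinimaSet(
            [
                Minimum("", (30,), np.array([0.3]), 1.0, 0.5),
                Minimum("", (10,), np.array([0.1]), 1.0, 0.5),
                Minimum("", (20,), np.array([0.2]), 0.0, 0.0),
            ]
        )
        out = label_and_sort(ms)
        assert out.labels == ["C", "B", "A"]  # index 10 beats 30 at equal g

    def test_labels_extend_beyond_z(self):
        assert _spreadsheet_label(0) == "A"
        assert _spreadsheet_label(25) == "Z"
        assert _spreadsheet_label(26) == "AA"
        assert _spreadsheet_label(27) == "AB"
        # 31 wells (k/30, k = 0..30, both edge nodes included): labels A..AE
        x = np.linspace(0, 1, 1024)
        F = -np.cos(30 * 2 * np.pi * x) + 0.3 * x
        f = _surface_1d(F, 0, 1)
        _, assignment = find_minima_precise(f)
        labelled = minima_free_energies(f, assignment, DEFAULT_KT)
        labs = labelled.labels
        assert len(labs) == len(set(labs)) == 31
        assert "AE" in labs
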