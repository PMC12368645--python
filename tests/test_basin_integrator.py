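import math

import numpy as np
import pytest

from aed.basin_integrator import (
    GridSpec,
    assign_basins,
    build_grid,
    compute_dipole,
    evaluate_on_grid,
    integrate_basins,
)
from aed.density_model import AnalyticAtomSystem, total_electron_count
from aed.synthetic_fixtures import closed_form_radius, generate_atom_system

from .conftest import make_atom, make_s_wavefunction
from .oracles import trajectory_ascent_labels


def run_pipeline(system, spacing, iso=0.001, floor=1e-7):
    grid = build_grid(system, spacing=spacing, density_floor=floor)
    rho = evaluate_on_grid(system, grid)
    labels = assign_basins(rho, grid, system, density_floor=floor)
    basins = integrate_basins(labels, rho, grid, system, iso=iso)
    return grid, rho, labels, basins


class TestBuildGrid:
    def test_single_atom_box_half_width_matches_closed_form(self, single_atom_system):
        floor, pad = 1e-7, 2.0
        grid = build_grid(single_atom_system, spacing=0.1, density_floor=floor, padding=pad)
        r = math.sqrt(math.log(2.0 * (1.0 / math.pi) ** 1.5 / floor))
        half = r + pad
        lo = grid.origin
        hi = grid.origin + (np.array(grid.dims) - 1) * grid.spacing
        np.testing.assert_allclose(-lo, half, atol=0.11)
        np.testing.assert_allclose(hi, half, atol=0.11)

    def test_two_atom_box_elongated_along_separation_axis(self, two_atom_system):
        grid = build_grid(two_atom_system, spacing=0.2)
        ext = (np.array(grid.dims) - 1) * grid.spacing
        assert ext[0] == pytest.approx(ext[1] + 10.0, abs=0.5)
        assert ext[1] == pytest.approx(ext[2], abs=0.5)

    def test_non_positive_spacing_rejected(self, single_atom_system):
        with pytest.raises(ValueError, match="spacing"):
            build_grid(single_atom_system, spacing=0.0)

    def test_mirror_system_gives_mirror_grid(self):
        system = AnalyticAtomSystem(
            atoms=(make_atom(center=(-3.0, 1.0, 0.5)), make_atom(center=(4.0, -1.0, 0.0)))
        )
        mirrored = AnalyticAtomSystem(
            atoms=tuple(
                make_atom(center=a.center * np.array([-1.0, 1.0, 1.0]))
                for a in system.atoms
            )
        )
        g1 = build_grid(system, spacing=0.25)
        g2 = build_grid(mirrored, spacing=0.25)
        assert g1.dims == g2.dims
        hi1 = g1.origin[0] + (g1.dims[0] - 1) * g1.spacing
        assert g2.origin[0] == pytest.approx(-hi1, abs=1e-12)


class TestAssignBasins:
    def test_single_peak_gets_single_label(self, single_atom_system):
        _, rho, labels, _ = run_pipeline(single_atom_system, spacing=0.25)
        above = rho >= 1e-7
        assert np.all(labels[above] == 1)
        assert np.all(labels[~above] == 0)

    def test_two_equal_atoms_split_at_midplane(self, two_atom_system):
        _, rho, labels, _ = run_pipeline(two_atom_system, spacing=0.25)
        counts = np.bincount(labels.ravel())[1:]
        assert counts.shape == (2,)
        assert abs(counts[0] - counts[1]) / counts.mean() < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_trajectory_oracle(self, seed):
        """Compiled near-grid labels equal the pure-Python per-voxel walker."""
        rng = np.random.default_rng(seed)
        bundle = generate_atom_system(n_atoms=int(rng.integers(2, 5)), seed=seed + 100)
        system = bundle.system
        grid = build_grid(system, spacing=0.8)
        assert all(d <= 40 for d in grid.dims)
        rho = evaluate_on_grid(system, grid)
        labels = assign_basins(rho, grid, system)
        expected = trajectory_ascent_labels(
            rho, grid.origin, grid.spacing, system.positions, 1e-7
        )
        np.testing.assert_array_equal(labels, expected)

    def test_nucleus_outside_grid_rejected(self, single_atom_system):
        grid = GridSpec(origin=np.array([5.0, 5.0, 5.0]), spacing=0.5, dims=(4, 4, 4))
        rho = evaluate_on_grid(single_atom_system, grid)
        rho[0, 0, 0] = 1.0  # ensure a voxel above floor
        with pytest.raises(ValueError, match="outside"):
            assign_basins(rho, grid, single_atom_system)

    def test_all_below_floor_is_degenerate(self, single_atom_system):
        grid = build_grid(single_atom_system, spacing=0.5)
        rho = np.zeros(grid.dims)
        with pytest.raises(ValueError, match="degenerate"):
            assign_basins(rho, grid, single_atom_system)


class TestIntegrateBasins:
    def test_isolated_atom_volume_matches_isodensity_sphere(self, single_atom_system):
        _, _, _, basins = run_pipeline(single_atom_system, spacing=0.1)
        r = closed_form_radius(2.0, 1.0, 0.001)
        v_exact = 4.0 / 3.0 * math.pi * r**3
        assert v_exact == pytest.approx(59.8, abs=0.1)
        assert basins[0].V_i == pytest.approx(v_exact, rel=0.01)

    def test_isolated_atom_population_recovered(self, single_atom_system):
        _, _, _, basins = run_pipeline(single_atom_system, spacing=0.1)
        assert basins[0].N_i == pytest.approx(2.0, rel=0.005)

    def test_population_sum_equals_grid_total(self, two_atom_system):
        grid, rho, labels, basins = run_pipeline(two_atom_system, spacing=0.2)
        grid_total = rho[rho >= 1e-7].sum() * grid.voxel_volume
        assert sum(b.N_i for b in basins) == pytest.approx(grid_total, rel=1e-12)

    def test_envelope_volume_monotone_in_iso(self, single_atom_system):
        grid, rho, labels, _ = run_pipeline(single_atom_system, spacing=0.15)
        vols = [
            integrate_basins(labels, rho, grid, single_atom_system, iso=iso)[0].V_i
            for iso in (0.0005, 0.001, 0.002, 0.01)
        ]
        assert vols == sorted(vols, reverse=True)

    def test_envelope_clipped_population_mode(self, single_atom_system):
        grid, rho, labels, basins = run_pipeline(single_atom_system, spacing=0.15)
        clipped = integrate_basins(
            labels, rho, grid, single_atom_system, clip_populations_to_envelope=True
        )
        assert clipped[0].N_i < basins[0].N_i
        assert clipped[0].N_i == pytest.approx(basins[0].N_i, rel=0.02)

    def test_grid_convergence_cauchy(self, single_atom_system):
        """Halving h shrinks the change in N and V (Cauchy-style)."""
        results = {}
        for h in (0.4, 0.2, 0.1):
            _, _, _, basins = run_pipeline(single_atom_system, spacing=h)
            results[h] = (basins[0].N_i, basins[0].V_i)
        dn1 = abs(results[0.2][0] - results[0.4][0])
        dn2 = abs(results[0.1][0] - results[0.2][0])
        dv1 = abs(results[0.2][1] - results[0.4][1])
        dv2 = abs(results[0.1][1] - results[0.2][1])
        assert dn2 <= dn1
        assert dv2 <= dv1

    def test_non_positive_iso_rejected(self, single_atom_system):
        grid, rho, labels, _ = run_pipeline(single_atom_system, spacing=0.3)
        with pytest.raises(ValueError, match="isodensity"):
            integrate_basins(labels, rho, grid, single_atom_system, iso=0.0)


class TestComputeDipole:
    def test_neutral_spherical_atom_is_apolar(self, single_atom_system):
        grid = build_grid(single_atom_system, spacing=0.1)
        rho = evaluate_on_grid(single_atom_system, grid)
        dip = compute_dipole(single_atom_system, rho, grid)
        assert dip.magnitude < 1e-3

    def test_displaced_cloud_closed_form(self):
        """Z=2 nucleus at origin, 2e cloud at (0,0,0.1): |mu| = 0.2 au = 0.508 D."""
        from aed.basin_integrator import AU_TO_DEBYE

        cloud = AnalyticAtomSystem(atoms=(make_atom(center=(0, 0, 0.1), z=2),))
        grid = build_grid(cloud, spacing=0.05, padding=3.0)
        rho = evaluate_on_grid(cloud, grid)
        dip = compute_dipole(cloud, rho, grid, nuclei=([2.0], np.zeros((1, 3))))
        assert dip.magnitude == pytest.approx(0.2 * AU_TO_DEBYE, rel=0.01)
        assert 0.2 * AU_TO_DEBYE == pytest.approx(0.508, abs=5e-4)

    def test_two_identical_neutral_atoms_cancel(self, two_atom_system):
        grid = build_grid(two_atom_system, spacing=0.1)
        rho = evaluate_on_grid(two_atom_system, grid)
        dip = compute_dipole(two_atom_system, rho, grid)
        assert dip.magnitude < 1e-3

    def test_wavefunction_source_dipole(self):
        """Two one-electron s centers with Z=1 each: neutral, near-zero dipole."""
        wf = make_s_wavefunction([(-2.0, 0, 0), (2.0, 0, 0)], [1.0, 1.0], [1.0, 1.0])
        grid = build_grid(wf, spacing=0.15)
        rho = evaluate_on_grid(wf, grid)
        dip = compute_dipole(wf, rho, grid)
        assert dip.magnitude < 5e-3
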