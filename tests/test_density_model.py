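import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aed.density_model import (
    AnalyticAtom,
    AnalyticAtomSystem,
    GaussianPrimitive,
    MolecularOrbital,
    Wavefunction,
    evaluate_density,
    evaluate_gradient,
    total_electron_count,
)

from .conftest import make_atom, make_s_wavefunction
from .oracles import analytic_density_sum


class TestEvaluateDensity:
    def test_normalized_s_primitive_peak_value(self, h_like_wavefunction):
        """A doubly occupied normalized s primitive has rho(0) = 2 (2/pi)^{3/2}."""
        wf = make_s_wavefunction([(0, 0, 0)], [1.0], [2.0])
        rho = evaluate_density(wf, [(0.0, 0.0, 0.0)])
        assert rho[0] == pytest.approx(2.0 * (2.0 / math.pi) ** 1.5, rel=1e-14)

    def test_density_vanishes_far_from_all_centers(self, single_atom_system, h_like_wavefunction):
        far = [(50.0, 0.0, 0.0)]
        assert evaluate_density(single_atom_system, far)[0] < 1e-300
        assert evaluate_density(h_like_wavefunction, far)[0] < 1e-300

    def test_two_atom_midpoint_matches_symbolic_sum(self):
        system = AnalyticAtomSystem(
            atoms=(make_atom(center=(-5, 0, 0)), make_atom(center=(5, 0, 0)))
        )
        got = evaluate_density(system, [(0.0, 0.0, 0.0)])[0]
        expected = analytic_density_sum(
            [((-5, 0, 0), 2.0, 1.0), ((5, 0, 0), 2.0, 1.0)], (0.0, 0.0, 0.0)
        )
        assert got == pytest.approx(expected, rel=1e-14)

    def test_random_points_match_per_term_oracle(self):
        rng = np.random.default_rng(3)
        atoms = [
            (tuple(rng.uniform(-4, 4, 3)), float(rng.uniform(1, 8)), float(rng.uniform(0.5, 3)))
            for _ in range(4)
        ]
        system = AnalyticAtomSystem(
            atoms=tuple(make_atom(center=c, population=n, exponent=a) for c, n, a in atoms)
        )
        pts = rng.uniform(-6, 6, size=(25, 3))
        got = evaluate_density(system, pts)
        want = [analytic_density_sum(atoms, p) for p in pts]
        np.testing.assert_allclose(got, want, rtol=1e-13)

    def test_empty_point_list_gives_empty_result(self, single_atom_system):
        assert evaluate_density(single_atom_system, np.empty((0, 3))).shape == (0,)

    def test_non_finite_coordinates_rejected(self, single_atom_system):
        with pytest.raises(ValueError, match="non-finite"):
            evaluate_density(single_atom_system, [(np.nan, 0, 0)])

    def test_density_non_negative_with_cartesian_polynomials(self):
        """A p-type orbital density (which has nodes) never goes negative."""
        nuclei = (make_s_wavefunction([(0, 0, 0)], [1.0], [1.0]).nuclei[0],)
        prims = (
            GaussianPrimitive(center_index=1, angular_powers=(1, 0, 0), exponent=0.8),
            GaussianPrimitive(center_index=1, angular_powers=(0, 0, 0), exponent=1.2),
        )
        wf = Wavefunction(
            nuclei=nuclei,
            primitives=prims,
            orbitals=(MolecularOrbital(occupation=1.5, coefficients=np.array([0.9, -0.4])),),
            total_electrons=1.5,
        )
        pts = np.random.default_rng(0).uniform(-3, 3, size=(200, 3))
        assert np.all(evaluate_density(wf, pts) >= 0.0)


class TestEvaluateGradient:
    def test_zero_at_spherical_atom_center(self, single_atom_system):
        g = evaluate_gradient(single_atom_system, [(0.0, 0.0, 0.0)])
        np.testing.assert_allclose(g, [[0.0, 0.0, 0.0]])

    def test_spherical_atom_closed_form(self, single_atom_system):
        """For rho = N (a/pi)^{3/2} e^{-a r^2}: grad = -2 a rho r."""
        p = np.array([[1.0, 0.0, 0.0]])
        rho = evaluate_density(single_atom_system, p)[0]
        g = evaluate_gradient(single_atom_system, p)
        np.testing.assert_allclose(g, [[-2.0 * rho, 0.0, 0.0]], rtol=1e-14)

    @pytest.mark.parametrize("source_kind", ["analytic", "wavefunction"])
    def test_matches_central_finite_differences(self, source_kind):
        rng = np.random.default_rng(11)
        if source_kind == "analytic":
            source = AnalyticAtomSystem(
                atoms=tuple(
                    make_atom(
                        center=rng.uniform(-3, 3, 3),
                        population=float(rng.uniform(1, 6)),
                        exponent=float(rng.uniform(0.5, 2.0)),
                    )
                    for _ in range(3)
                )
            )
        else:
            nuclei = make_s_wavefunction(
                [(-1.5, 0, 0), (1.5, 0.5, 0)], [0.9, 1.4], [2.0, 2.0]
            ).nuclei
            prims = (
                GaussianPrimitive(center_index=1, angular_powers=(0, 0, 0), exponent=0.9),
                GaussianPrimitive(center_index=2, angular_powers=(1, 0, 1), exponent=1.4),
                GaussianPrimitive(center_index=2, angular_powers=(0, 2, 0), exponent=0.7),
            )
            c = rng.normal(size=(2, 3))
            orbs = tuple(MolecularOrbital(occupation=1.0, coefficients=c[k]) for k in range(2))
            source = Wavefunction(
                nuclei=nuclei, primitives=prims, orbitals=orbs, total_electrons=2.0
            )
        pts = rng.uniform(-2.5, 2.5, size=(20, 3))
        grad = evaluate_gradient(source, pts)
        h = 1e-5
        for ax in range(3):
            shift = np.zeros(3)
            shift[ax] = h
            fd = (
                evaluate_density(source, pts + shift)
                - evaluate_density(source, pts - shift)
            ) / (2 * h)
            scale = np.maximum(np.abs(fd), 1e-10)
            assert np.max(np.abs(grad[:, ax] - fd) / scale) < 1e-6


class TestTotalElectronCount:
    def test_analytic_sum(self):
        system = AnalyticAtomSystem(
            atoms=(make_atom(population=2.0), make_atom(center=(8, 0, 0), population=4.0))
        )
        assert total_electron_count(system) == 6.0

    def test_wavefunction_sum(self):
        wf = make_s_wavefunction([(0, 0, 0), (5, 0, 0), (0, 5, 0)], [1, 1, 1], [2, 2, 2])
        assert total_electron_count(wf) == 6.0


class TestInvariants:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_transform_leaves_density_unchanged(self, seed):
        """Rotating + translating all centers and points preserves rho."""
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-3, 3, size=(3, 3))
        pops = rng.uniform(1, 5, size=3)
        exps = rng.uniform(0.5, 2, size=3)
        pts = rng.uniform(-5, 5, size=(10, 3))
        # random rotation via QR, plus a translation
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        t = rng.uniform(-4, 4, 3)

        def build(cs):
            return AnalyticAtomSystem(
                atoms=tuple(
                    make_atom(center=c, population=float(n), exponent=float(a))
                    for c, n, a in zip(cs, pops, exps)
                )
            )

        rho0 = evaluate_density(build(centers), pts)
        rho1 = evaluate_density(build(centers @ q.T + t), pts @ q.T + t)
        np.testing.assert_allclose(rho1, rho0, rtol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            AnalyticAtom(center=np.zeros(3), population=-1.0, exponent=1.0, atomic_number=1)
        with pytest.raises(ValueError):
            GaussianPrimitive(center_index=1, angular_powers=(0, 0, 0), exponent=0.0)
        with pytest.raises(ValueError):
            MolecularOrbital(occupation=2.5, coefficients=np.ones(1))
        wf = make_s_wavefunction([(0, 0, 0)], [1.0], [2.0])
        with pytest.raises(ValueError, match="total_electrons"):
            Wavefunction(
                nuclei=wf.nuclei,
                primitives=wf.primitives,
                orbitals=wf.orbitals,
                total_electrons=3.0,
            )
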