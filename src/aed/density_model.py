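"""Molecular electron-density models.

Two density sources are supported:

* :class:`Wavefunction` — a single-determinant wavefunction expressed over
  unnormalized Cartesian Gaussian primitives (the convention of the WFX
  interchange format, in which MO coefficients absorb primitive
  normalization).  The density is the occupation-weighted sum of squared
  molecular orbitals,

  .. math:: \\rho(\\mathbf r) = \\sum_k n_k \\Big(\\sum_p c_{kp}\\,
            g_p(\\mathbf r)\\Big)^2 ,

  with primitives
  :math:`g_p(\\mathbf r) = x^{l_x} y^{l_y} z^{l_z} e^{-\\alpha r^2}`
  relative to their center.

* :class:`AnalyticAtomSystem` — a sum of spherical Gaussian "atoms"
  :math:`\\rho_A(\\mathbf r) = N_A (\\alpha_A/\\pi)^{3/2}
  e^{-\\alpha_A |\\mathbf r - \\mathbf R_A|^2}`, each of which integrates to
  exactly :math:`N_A` electrons.  These carry closed-form per-atom
  populations, isodensity radii and charge centroids and serve as the exact
  oracle for the basin-integration pipeline.

All coordinates are in bohr, densities in e/bohr^3, gradients in e/bohr^4.
Gradients are evaluated analytically; no finite differencing occurs in the
production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "NucleusSpec",
    "GaussianPrimitive",
    "MolecularOrbital",
    "Wavefunction",
    "AnalyticAtom",
    "AnalyticAtomSystem",
    "DensitySource",
    "WFX_ANGULAR_POWERS",
    "evaluate_density",
    "evaluate_gradient",
    "total_electron_count",
    "nuclear_charges_and_positions",
]

#: Map from the WFX "Primitive Types" integer to Cartesian angular powers
#: (lx, ly, lz), following the AIM/WFN ordering:
#: 1 = s; 2-4 = px, py, pz; 5-10 = dxx, dyy, dzz, dxy, dxz, dyz;
#: 11-20 = fxxx, fyyy, fzzz, fxxy, fxxz, fyyz, fxyy, fxzz, fyzz, fxyz.
WFX_ANGULAR_POWERS: dict[int, tuple[int, int, int]] = {
    1: (0, 0, 0),
    2: (1, 0, 0),
    3: (0, 1, 0),
    4: (0, 0, 1),
    5: (2, 0, 0),
    6: (0, 2, 0),
    7: (0, 0, 2),
    8: (1, 1, 0),
    9: (1, 0, 1),
    10: (0, 1, 1),
    11: (3, 0, 0),
    12: (0, 3, 0),
    13: (0, 0, 3),
    14: (2, 1, 0),
    15: (2, 0, 1),
    16: (0, 2, 1),
    17: (1, 2, 0),
    18: (1, 0, 2),
    19: (0, 1, 2),
    20: (1, 1, 1),
}

#: Densities below this magnitude are "numerically zero"; small positive
#: values are never clamped so that decay tails remain usable.
DENSITY_FLOOR_ABSOLUTE = 1e-300

_OCC_TOL = 1e-6


@dataclass(frozen=True)
class NucleusSpec:
    """A nucleus: 1-based index, element symbol, atomic number, position (bohr)."""

    index: int
    element: str
    atomic_number: int
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.atomic_number < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.atomic_number}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        object.__setattr__(self, "position", pos)

    @property
    def label(self) -> str:
        """Element+index label, e.g. ``O6``."""
        return f"{self.element}{self.index}"


@dataclass(frozen=True)
class GaussianPrimitive:
    """Unnormalized Cartesian Gaussian primitive attached to a nucleus.

    ``center_index`` is the 1-based index of the nucleus the primitive sits
    on; ``angular_powers`` are the Cartesian exponents (lx, ly, lz);
    ``exponent`` is in bohr^-2.
    """

    center_index: int
    angular_powers: tuple[int, int, int]
    exponent: float

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError(f"primitive exponent must be positive, got {self.exponent}")
        if len(self.angular_powers) != 3 or any(l < 0 for l in self.angular_powers):
            raise ValueError(f"invalid angular powers {self.angular_powers}")


@dataclass(frozen=True)
class MolecularOrbital:
    occupation: float
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupation <= 2.0:
            raise ValueError(f"occupation must lie in [0, 2], got {self.occupation}")
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )


@dataclass(frozen=True)
class Wavefunction:
    """Nuclei + primitives + occupied molecular orbitals.

    Open-shell occupations (< 2) are accepted; the density is always the
    straight occupation-weighted sum over orbitals.
    """

    nuclei: tuple[NucleusSpec, ...]
    primitives: tuple[GaussianPrimitive, ...]
    orbitals: tuple[MolecularOrbital, ...]
    total_electrons: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "primitives", tuple(self.primitives))
        object.__setattr__(self, "orbitals", tuple(self.orbitals))
        if not self.nuclei:
            raise ValueError("wavefunction must contain at least one nucleus")
        if not any(mo.occupation > 0 for mo in self.orbitals):
            raise ValueError("wavefunction must contain at least one occupied orbital")
        indices = [n.index for n in self.nuclei]
        if len(set(indices)) != len(indices):
            raise ValueError("nucleus indices must be unique")
        index_set = set(indices)
        for p in self.primitives:
            if p.center_index not in index_set:
                raise ValueError(
                    f"primitive center index {p.center_index} does not resolve to a nucleus"
                )
        nprim = len(self.primitives)
        for k, mo in enumerate(self.orbitals):
            if mo.coefficients.shape != (nprim,):
                raise ValueError(
                    f"orbital {k}: coefficient vector length {mo.coefficients.shape} "
                    f"does not match primitive count {nprim}"
                )
        occ_sum = float(sum(mo.occupation for mo in self.orbitals))
        if abs(occ_sum - self.total_electrons) > _OCC_TOL:
            raise ValueError(
                f"sum of occupations ({occ_sum}) does not match declared "
                f"total_electrons ({self.total_electrons})"
            )

    def nucleus_by_index(self, index: int) -> NucleusSpec:
        for n in self.nuclei:
            if n.index == index:
                return n
        raise KeyError(f"no nucleus with index {index}")

    def _arrays(self) -> tuple[np.ndarray, ...]:
        """Primitive data as flat arrays (centers, powers, exponents, C, occ)."""
        pos = {n.index: n.position for n in self.nuclei}
        centers = np.array([pos[p.center_index] for p in self.primitives])
        powers = np.array([p.angular_powers for p in self.primitives], dtype=np.int64)
        exps = np.array([p.exponent for p in self.primitives])
        coeff = np.array([mo.coefficients for mo in self.orbitals])
        occ = np.array([mo.occupation for mo in self.orbitals])
        return centers, powers, exps, coeff, occ


@dataclass(frozen=True)
class AnalyticAtom:
    """Spherical Gaussian atom: N_A (alpha/pi)^{3/2} exp(-alpha |r-R|^2)."""

    center: np.ndarray
    population: float
    exponent: float
    atomic_number: int

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got shape {center.shape}")
        object.__setattr__(self, "center", center)
        if self.population <= 0:
            raise ValueError(f"population must be positive, got {self.population}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be positive, got {self.exponent}")

    @property
    def peak_density(self) -> float:
        """Density at the atom center, N (alpha/pi)^{3/2}."""
        return self.population * (self.exponent / math.pi) ** 1.5


@dataclass(frozen=True)
class AnalyticAtomSystem:
    """Sum of spherical Gaussian atoms with closed-form populations."""

    atoms: tuple[AnalyticAtom, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError("analytic system must contain at least one atom")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.center for a in self.atoms])


DensitySource = Union[Wavefunction, AnalyticAtomSystem]


def _check_points(points: Sequence[Sequence[float]]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.shape == (3,):
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
    if pts.size and not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def _primitive_values(
    pts: np.ndarray, centers: np.ndarray, powers: np.ndarray, exps: np.ndarray
) -> np.ndarray:
    """Values g_p(r) for all points x primitives, shape (M, P)."""
    d = pts[:, None, :] - centers[None, :, :]  # (M, P, 3)
    r2 = np.einsum("mpi,mpi->mp", d, d)
    out = np.exp(-exps[None, :] * r2)
    for ax in range(3):
        l = powers[:, ax]
        if np.any(l > 0):
            out = out * d[:, :, ax] ** l[None, :]
    return out


def _primitive_gradients(
    pts: np.ndarray, centers: np.ndarray, powers: np.ndarray, exps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(values (M,P), gradients (M,P,3)) of all primitives at all points."""
    d = pts[:, None, :] - centers[None, :, :]
    r2 = np.einsum("mpi,mpi->mp", d, d)
    e = np.exp(-exps[None, :] * r2)
    mono = np.empty((pts.shape[0], centers.shape[0], 3))
    for ax in range(3):
        mono[:, :, ax] = d[:, :, ax] ** powers[None, :, ax]
    poly = mono[:, :, 0] * mono[:, :, 1] * mono[:, :, 2]
    vals = poly * e
    grads = np.empty_like(mono)
    for ax in range(3):
        l = powers[:, ax]
        others = poly / np.where(mono[:, :, ax] == 0.0, 1.0, mono[:, :, ax])
        # d/dx [x^l e^{-a r^2}] = (l x^{l-1} - 2 a x^{l+1}) e^{-a r^2}
        x = d[:, :, ax]
        lower = np.where(
            l[None, :] > 0, l[None, :] * x ** np.maximum(l - 1, 0)[None, :], 0.0
        )
        # at x == 0 with l > 0 the quotient form of `others` is wrong, but
        # there the whole derivative term with l>0, x=0, l-1>0 vanishes;
        # handle l == 1, x == 0 exactly via the product of the other axes
        if np.any((l == 1)):
            oth_exact = np.ones_like(poly)
            for bx in range(3):
                if bx != ax:
                    oth_exact = oth_exact * mono[:, :, bx]
            others = np.where((l[None, :] > 0) & (x == 0.0), oth_exact, others)
        grads[:, :, ax] = (lower * others - 2.0 * exps[None, :] * x * poly) * e
    return vals, grads


_CHUNK = 262_144  # points per evaluation chunk, bounds peak memory


def evaluate_density(source: DensitySource, points) -> np.ndarray:
    """Evaluate rho(r) at each point (bohr); returns densities in e/bohr^3.

    Outputs are non-negative by construction for both source kinds.
    """
    pts = _check_points(points)
    if pts.shape[0] == 0:
        return np.empty(0)
    out = np.empty(pts.shape[0])
    if isinstance(source, AnalyticAtomSystem):
        centers = source.positions
        amps = np.array([a.peak_density for a in source.atoms])
        exps = np.array([a.exponent for a in source.atoms])
        for lo in range(0, pts.shape[0], _CHUNK):
            chunk = pts[lo : lo + _CHUNK]
            d = chunk[:, None, :] - centers[None, :, :]
            r2 = np.einsum("mpi,mpi->mp", d, d)
            out[lo : lo + _CHUNK] = np.exp(-exps[None, :] * r2) @ amps
        return out
    if isinstance(source, Wavefunction):
        centers, powers, exps, coeff, occ = source._arrays()
        for lo in range(0, pts.shape[0], _CHUNK):
            chunk = pts[lo : lo + _CHUNK]
            g = _primitive_values(chunk, centers, powers, exps)
            phi = g @ coeff.T  # (m, K)
            out[lo : lo + _CHUNK] = (phi * phi) @ occ
        return out
    raise TypeError(f"unsupported density source {type(source).__name__}")


def evaluate_gradient(source: DensitySource, points) -> np.ndarray:
    """Analytic gradient of rho at each point, shape (n, 3), e/bohr^4."""
    pts = _check_points(points)
    if pts.shape[0] == 0:
        return np.empty((0, 3))
    out = np.empty((pts.shape[0], 3))
    if isinstance(source, AnalyticAtomSystem):
        centers = source.positions
        amps = np.array([a.peak_density for a in source.atoms])
        exps = np.array([a.exponent for a in source.atoms])
        for lo in range(0, pts.shape[0], _CHUNK):
            chunk = pts[lo : lo + _CHUNK]
            d = chunk[:, None, :] - centers[None, :, :]
            r2 = np.einsum("mpi,mpi->mp", d, d)
            rho_a = amps[None, :] * np.exp(-exps[None, :] * r2)
            out[lo : lo + _CHUNK] = np.einsum(
                "mp,mpi->mi", -2.0 * exps[None, :] * rho_a, d
            )
        return out
    if isinstance(source, Wavefunction):
        centers, powers, exps, coeff, occ = source._arrays()
        for lo in range(0, pts.shape[0], _CHUNK):
            chunk = pts[lo : lo + _CHUNK]
            g, dg = _primitive_gradients(chunk, centers, powers, exps)
            phi = g @ coeff.T  # (m, K)
            w = phi * occ[None, :]  # (m, K)
            for ax in range(3):
                dphi = dg[:, :, ax] @ coeff.T
                out[lo : lo + _CHUNK, ax] = 2.0 * np.einsum("mk,mk->m", w, dphi)
        return out
    raise TypeError(f"unsupported density source {type(source).__name__}")


def total_electron_count(source: DensitySource) -> float:
    """Exact electron count: sum of occupations or of analytic populations."""
    if isinstance(source, AnalyticAtomSystem):
        return float(sum(a.population for a in source.atoms))
    if isinstance(source, Wavefunction):
        return float(sum(mo.occupation for mo in source.orbitals))
    raise TypeError(f"unsupported density source {type(source).__name__}")


def nuclear_charges_and_positions(source: DensitySource) -> tuple[np.ndarray, np.ndarray]:
    """(Z array, positions (n,3) in bohr) for either source kind."""
    if isinstance(source, AnalyticAtomSystem):
        z = np.array([a.atomic_number for a in source.atoms], dtype=float)
        return z, source.positions
    if isinstance(source, Wavefunction):
        z = np.array([n.atomic_number for n in source.nuclei], dtype=float)
        pos = np.array([n.position for n in source.nuclei])
        return z, pos
    raise TypeError(f"unsupported density source {type(source).__name__}")
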