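"""Analytic multi-atom density fixtures with closed-form expectations.

Each fixture is a sum of well-separated spherical Gaussian atoms.  In that
regime every pipeline quantity has a closed form:

* population: each atom term integrates to exactly ``N_A``;
* isodensity volume: the ``rho = iso`` envelope of an isolated Gaussian atom
  is the sphere of radius ``r* = sqrt(ln(N (alpha/pi)^{3/2} / iso) / alpha)``,
  so ``V = (4/3) pi r*^3``;
* AED: ``sum(N) / sum(V)``;
* dipole: each spherical cloud's charge centroid sits on its nucleus, so
  ``mu = sum_A (Z_A - N_A) R_A`` in atomic units.

Atoms are kept separated far enough that the density of any atom at any
inter-atomic midpoint is below 1e-6 of either peak; basin boundaries then
sit in numerically empty space and the closed forms hold to quadrature
accuracy.  Overlapping-atom systems are deliberately outside the oracle
regime (basin boundaries have no closed form there) and are used only for
invariant checks.

:func:`perturb_polarization` emulates the compensating response of a moiety
to an implicit solvent: electron density shifts from donor atoms (e.g.
hydrogens) onto acceptor atoms (e.g. carbonyl oxygens), acceptor volumes
swell, donor volumes shrink, and the total moiety volume and AED stay
nearly constant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .aed_core import MoietyDefinition
from .basin_integrator import AU_TO_DEBYE, DEFAULT_ISO
from .density_model import AnalyticAtom, AnalyticAtomSystem

__all__ = [
    "FixtureBundle",
    "closed_form_radius",
    "closed_form_population_and_volume",
    "generate_atom_system",
    "perturb_polarization",
    "reflect_bundle",
]

#: Maximum allowed midpoint density relative to either atom peak.
OVERLAP_TOLERANCE = 1e-6
_MAX_RESAMPLES = 1000


def closed_form_radius(population: float, exponent: float, iso: float) -> float:
    """Isodensity radius of an isolated Gaussian atom; 0 if the peak < iso."""
    if iso <= 0:
        raise ValueError(f"isodensity value must be positive, got {iso}")
    peak = population * (exponent / math.pi) ** 1.5
    if peak <= iso:
        return 0.0
    return math.sqrt(math.log(peak / iso) / exponent)


def closed_form_population_and_volume(
    population: float, exponent: float, iso: float = DEFAULT_ISO
) -> tuple[float, float]:
    """Exact (N, V) of an isolated Gaussian atom at the given envelope."""
    if population <= 0 or exponent <= 0:
        raise ValueError("population and exponent must be positive")
    r = closed_form_radius(population, exponent, iso)
    return population, (4.0 / 3.0) * math.pi * r**3


@dataclass(frozen=True)
class FixtureBundle:
    """Analytic system + moiety + the closed-form expected pipeline outputs."""

    system: AnalyticAtomSystem
    moiety: MoietyDefinition
    expected_populations: dict[int, float]  # 1-based atom index -> N_i (e)
    expected_volumes: dict[int, float]  # 1-based atom index -> V_i (bohr^3)
    expected_aed: float  # e/bohr^3
    expected_dipole: np.ndarray  # debye, 3-vector
    iso: float
    seed: int

    @property
    def expected_total_population(self) -> float:
        return sum(self.expected_populations.values())

    @property
    def expected_total_volume(self) -> float:
        return sum(self.expected_volumes.values())

    @property
    def expected_dipole_magnitude(self) -> float:
        return float(np.linalg.norm(self.expected_dipole))

    def to_json(self, destination: Union[str, Path, IO[str], None] = None) -> str:
        payload = {
            "seed": self.seed,
            "iso": self.iso,
            "atoms": [
                {
                    "center": list(map(float, a.center)),
                    "population": a.population,
                    "exponent": a.exponent,
                    "Z": a.atomic_number,
                }
                for a in self.system.atoms
            ],
            "moiety": {
                "molecule_id": self.moiety.molecule_id,
                "moiety_atoms": sorted(self.moiety.moiety_atoms),
                "cap_atoms": sorted(self.moiety.cap_atoms),
                "chiral": self.moiety.chiral,
                "enantiomer": self.moiety.enantiomer,
            },
            "expected": {
                "populations": {str(k): v for k, v in self.expected_populations.items()},
                "volumes": {str(k): v for k, v in self.expected_volumes.items()},
                "aed": self.expected_aed,
                "dipole_debye": list(map(float, self.expected_dipole)),
            },
        }
        text = json.dumps(payload, indent=2)
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text, encoding="utf-8")
        elif destination is not None:
            destination.write(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "FixtureBundle":
        if isinstance(source, Path):
            data = json.loads(source.read_text(encoding="utf-8"))
        elif isinstance(source, str):
            data = json.loads(source)
        else:
            data = json.load(source)
        system = AnalyticAtomSystem(
            atoms=tuple(
                AnalyticAtom(
                    center=np.asarray(a["center"], dtype=float),
                    population=float(a["population"]),
                    exponent=float(a["exponent"]),
                    atomic_number=int(a["Z"]),
                )
                for a in data["atoms"]
            )
        )
        m = data["moiety"]
        moiety = MoietyDefinition(
            molecule_id=m["molecule_id"],
            moiety_atoms=frozenset(m["moiety_atoms"]),
            cap_atoms=frozenset(m.get("cap_atoms", ())),
            chiral=m.get("chiral", False),
            enantiomer=m.get("enantiomer"),
        )
        exp = data["expected"]
        return cls(
            system=system,
            moiety=moiety,
            expected_populations={int(k): v for k, v in exp["populations"].items()},
            expected_volumes={int(k): v for k, v in exp["volumes"].items()},
            expected_aed=float(exp["aed"]),
            expected_dipole=np.asarray(exp["dipole_debye"], dtype=float),
            iso=float(data["iso"]),
            seed=int(data["seed"]),
        )


def _expectations(
    system: AnalyticAtomSystem, iso: float
) -> tuple[dict[int, float], dict[int, float], float, np.ndarray]:
    pops: dict[int, float] = {}
    vols: dict[int, float] = {}
    for i, atom in enumerate(system.atoms, start=1):
        n, v = closed_form_population_and_volume(atom.population, atom.exponent, iso)
        pops[i] = n
        vols[i] = v
    total_v = sum(vols.values())
    aed = sum(pops.values()) / total_v if total_v > 0 else float("nan")
    mu_au = np.zeros(3)
    for atom in system.atoms:
        mu_au += (atom.atomic_number - atom.population) * atom.center
    return pops, vols, aed, mu_au * AU_TO_DEBYE


def _bundle_from_system(
    system: AnalyticAtomSystem,
    iso: float,
    seed: int,
    moiety: MoietyDefinition | None = None,
    molecule_id: str = "fixture",
) -> FixtureBundle:
    pops, vols, aed, dipole = _expectations(system, iso)
    if moiety is None:
        moiety = MoietyDefinition(
            molecule_id=molecule_id,
            moiety_atoms=frozenset(range(1, len(system.atoms) + 1)),
        )
    return FixtureBundle(
        system=system,
        moiety=moiety,
        expected_populations=pops,
        expected_volumes=vols,
        expected_aed=aed,
        expected_dipole=dipole,
        iso=iso,
        seed=seed,
    )


def _overlap_ok(atoms: Sequence[AnalyticAtom]) -> bool:
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            mid = (a.center + b.center) / 2.0
            limit = OVERLAP_TOLERANCE * min(a.peak_density, b.peak_density)
            for atom in (a, b):
                d2 = float(np.sum((mid - atom.center) ** 2))
                if atom.peak_density * math.exp(-atom.exponent * d2) >= limit:
                    return False
    return True


def generate_atom_system(
    n_atoms: int = 4,
    population_range: tuple[float, float] = (1.0, 10.0),
    exponent_range: tuple[float, float] = (1.0, 2.5),
    min_separation: float = 9.0,
    seed: int = 0,
    iso: float = DEFAULT_ISO,
    molecule_id: str | None = None,
) -> FixtureBundle:
    """Random well-separated Gaussian-atom system with exact expectations.

    Atom positions are resampled (up to 1000 configurations) until all
    pairwise distances reach ``min_separation`` and every midpoint overlap
    is below 1e-6 of either peak; reproducible for a fixed seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    side = 0.0 if n_atoms == 1 else min_separation * (n_atoms ** (1.0 / 3.0)) * 1.35
    for _ in range(_MAX_RESAMPLES):
        centers = rng.uniform(-side / 2.0, side / 2.0, size=(n_atoms, 3))
        if n_atoms > 1:
            deltas = centers[:, None, :] - centers[None, :, :]
            dists = np.sqrt((deltas**2).sum(axis=-1))
            iu = np.triu_indices(n_atoms, k=1)
            if dists[iu].min() < min_separation:
                continue
        pops = rng.uniform(*population_range, size=n_atoms)
        exps = rng.uniform(*exponent_range, size=n_atoms)
        atoms = tuple(
            AnalyticAtom(
                center=centers[i],
                population=float(pops[i]),
                exponent=float(exps[i]),
                atomic_number=max(1, round(float(pops[i]))),
            )
            for i in range(n_atoms)
        )
        if not _overlap_ok(atoms):
            continue
        system = AnalyticAtomSystem(atoms=atoms)
        return _bundle_from_system(
            system, iso, seed, molecule_id=molecule_id or f"fixture-{seed}"
        )
    raise RuntimeError(
        f"could not place {n_atoms} atoms with min separation {min_separation} "
        f"bohr in {_MAX_RESAMPLES} resamples"
    )


def _solve_exponent(population: float, target_volume: float, iso: float, guess: float) -> float:
    """Exponent whose closed-form envelope volume matches ``target_volume``.

    In the fixture regime (peak / iso >> e^{3/2}) the volume is strictly
    decreasing in the exponent, so the root near ``guess`` is unique.
    """
    if target_volume <= 0:
        raise ValueError("target volume must be positive")
    r_t2 = ((3.0 * target_volume) / (4.0 * math.pi)) ** (2.0 / 3.0)

    def f(alpha: float) -> float:
        peak = population * (alpha / math.pi) ** 1.5
        if peak <= iso:
            return -r_t2
        return math.log(peak / iso) / alpha - r_t2

    lo = hi = guess
    flo = fhi = f(guess)
    for _ in range(200):
        if flo > 0 and fhi < 0:
            break
        if flo <= 0:
            lo /= 1.3
            flo = f(lo)
        if fhi >= 0:
            hi *= 1.3
            fhi = f(hi)
    else:
        raise RuntimeError("could not bracket the exponent for the target volume")
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))


def perturb_polarization(
    bundle: FixtureBundle,
    transfer: float,
    swell: float,
    donor_atoms: Sequence[int],
    acceptor_atoms: Sequence[int],
) -> FixtureBundle:
    """Emulate a solvent-polarization response with compensating volumes.

    ``transfer`` electrons move in total from the donor atoms (shared
    equally) to the acceptor atoms (shared equally); total N is conserved
    exactly.  Acceptor envelope volumes grow by the fraction ``swell`` and
    donor volumes shrink by exactly the compensating amount, so the total
    moiety volume is preserved (to solver precision) and the AED moves only
    through the unchanged-N / fixed-total-V ratio.
    """
    donors = sorted(set(int(i) for i in donor_atoms))
    acceptors = sorted(set(int(i) for i in acceptor_atoms))
    n_atoms = len(bundle.system.atoms)
    for idx in donors + acceptors:
        if not 1 <= idx <= n_atoms:
            raise ValueError(f"atom index {idx} out of range 1..{n_atoms}")
    if set(donors) & set(acceptors):
        raise ValueError("donor and acceptor sets must be disjoint")
    if transfer < 0 or swell < 0:
        raise ValueError("transfer and swell must be non-negative")
    if transfer and not (donors and acceptors):
        raise ValueError("electron transfer needs non-empty donor and acceptor sets")
    if donors:
        per_donor = transfer / len(donors)
        min_pop = min(bundle.system.atoms[i - 1].population for i in donors)
        if per_donor >= min_pop:
            raise ValueError(
                f"per-donor transfer {per_donor:.4f} e exceeds the smallest donor "
                f"population {min_pop:.4f} e"
            )

    atoms = list(bundle.system.atoms)
    new_pops = [a.population for a in atoms]
    if transfer and donors and acceptors:
        per_donor = transfer / len(donors)
        per_acceptor = transfer / len(acceptors)
        for i in donors:
            new_pops[i - 1] -= per_donor
        for i in acceptors:
            new_pops[i - 1] += per_acceptor

    old_vols = {
        i: closed_form_population_and_volume(atoms[i - 1].population, atoms[i - 1].exponent, bundle.iso)[1]
        for i in range(1, n_atoms + 1)
    }
    target_vols = dict(old_vols)
    grow = sum(old_vols[i] * swell for i in acceptors)
    for i in acceptors:
        target_vols[i] = old_vols[i] * (1.0 + swell)
    if grow > 0:
        donor_total = sum(old_vols[i] for i in donors)
        if grow >= donor_total:
            raise ValueError(
                "acceptor volume growth exceeds the total donor volume available"
            )
        for i in donors:
            target_vols[i] = old_vols[i] - grow * (old_vols[i] / donor_total)

    new_atoms = []
    for i, atom in enumerate(atoms, start=1):
        pop = new_pops[i - 1]
        if target_vols[i] != old_vols[i] or pop != atom.population:
            alpha = _solve_exponent(pop, target_vols[i], bundle.iso, atom.exponent)
        else:
            alpha = atom.exponent
        new_atoms.append(replace(atom, population=pop, exponent=alpha))
    system = AnalyticAtomSystem(atoms=tuple(new_atoms))
    return _bundle_from_system(
        system, bundle.iso, bundle.seed, moiety=bundle.moiety,
    )


def jitter_exponents(bundle: FixtureBundle, factors: Sequence[float]) -> FixtureBundle:
    """Rescale each atom's exponent by a multiplicative factor.

    Emulates the residual, non-compensating part of a condition change
    (published per-moiety totals drift by ~0.1% between dielectrics):
    populations stay fixed while every envelope volume shifts slightly.
    Expected values are recomputed from the closed forms.
    """
    atoms = bundle.system.atoms
    if len(factors) != len(atoms):
        raise ValueError(f"need {len(atoms)} factors, got {len(factors)}")
    if any(f <= 0 for f in factors):
        raise ValueError("exponent factors must be positive")
    system = AnalyticAtomSystem(
        atoms=tuple(
            replace(a, exponent=a.exponent * float(f)) for a, f in zip(atoms, factors)
        )
    )
    return _bundle_from_system(system, bundle.iso, bundle.seed, moiety=bundle.moiety)


def reflect_bundle(bundle: FixtureBundle, axis: int = 0) -> FixtureBundle:
    """Mirror image of a fixture (one coordinate negated on every atom).

    The expected populations, volumes and AED are unchanged; the dipole
    component along the mirror axis flips sign.
    """
    atoms = tuple(
        replace(a, center=a.center * np.where(np.arange(3) == axis, -1.0, 1.0))
        for a in bundle.system.atoms
    )
    system = AnalyticAtomSystem(atoms=atoms)
    enantiomer = None
    if bundle.moiety.chiral:
        enantiomer = {"R": "S", "S": "R", None: "S"}[bundle.moiety.enantiomer]
    moiety = replace(bundle.moiety, enantiomer=enantiomer) if bundle.moiety.chiral else bundle.moiety
    return _bundle_from_system(system, bundle.iso, bundle.seed, moiety=moiety)
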