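import math

import numpy as np
import pytest

from aed.density_model import (
    AnalyticAtom,
    AnalyticAtomSystem,
    GaussianPrimitive,
    MolecularOrbital,
    NucleusSpec,
    Wavefunction,
)

#: Normalization constant of an s Gaussian with unit exponent,
#: (2 alpha / pi)^{3/4} at alpha = 1.
S_NORM = (2.0 / math.pi) ** 0.75


def make_atom(center=(0.0, 0.0, 0.0), population=2.0, exponent=1.0, z=None):
    return AnalyticAtom(
        center=np.asarray(center, dtype=float),
        population=population,
        exponent=exponent,
        atomic_number=z if z is not None else max(1, round(population)),
    )


@pytest.fixture
def single_atom_system():
    """One Gaussian atom: N=2, alpha=1, at the origin."""
    return AnalyticAtomSystem(atoms=(make_atom(),))


@pytest.fixture
def two_atom_system():
    """Two identical N=2, alpha=1 atoms 10 bohr apart on x."""
    return AnalyticAtomSystem(
        atoms=(make_atom(center=(-5.0, 0.0, 0.0)), make_atom(center=(5.0, 0.0, 0.0)))
    )


def make_s_wavefunction(centers, exponents, occupations):
    """One normalized s orbital per center, occupation-weighted."""
    nuclei = tuple(
        NucleusSpec(index=i + 1, element="H", atomic_number=1, position=np.asarray(c, float))
        for i, c in enumerate(centers)
    )
    prims = tuple(
        GaussianPrimitive(center_index=i + 1, angular_powers=(0, 0, 0), exponent=a)
        for i, a in enumerate(exponents)
    )
    orbitals = []
    for k, occ in enumerate(occupations):
        coeff = np.zeros(len(prims))
        coeff[k] = (2.0 * exponents[k] / math.pi) ** 0.75
        orbitals.append(MolecularOrbital(occupation=occ, coefficients=coeff))
    return Wavefunction(
        nuclei=nuclei,
        primitives=prims,
        orbitals=tuple(orbitals),
        total_electrons=float(sum(occupations)),
    )


@pytest.fixture
def h_like_wavefunction():
    """Single nucleus, one normalized s primitive, occupation 1."""
    return make_s_wavefunction([(0.0, 0.0, 0.0)], [1.0], [1.0])


MINIMAL_WFX = """<Title>
 hydrogen-like single-Gaussian test case
</Title>
<Number of Nuclei>
 1
</Number of Nuclei>
<Number of Primitives>
 1
</Number of Primitives>
<Nuclear Cartesian Coordinates>
 0.0 0.0 0.0
</Nuclear Cartesian Coordinates>
<Atomic Numbers>
 1
</Atomic Numbers>
<Primitive Centers>
 1
</Primitive Centers>
<Primitive Types>
 1
</Primitive Types>
<Primitive Exponents>
 1.0
</Primitive Exponents>
<Molecular Orbital Occupation Numbers>
 1.0
</Molecular Orbital Occupation Numbers>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
 7.127054703549901E-01
</Molecular Orbital Primitive Coefficients>
"""


@pytest.fixture
def minimal_wfx_text():
    return MINIMAL_WFX
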