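"""AED aggregation and bioisosterism classification.

The average electron density of a moiety is the ratio of its total basin
electron population to its total envelope volume,

.. math:: \\mathrm{AED} = \\frac{\\sum_{i \\in \\mathrm{moiety}} N_i}
                                {\\sum_{i \\in \\mathrm{moiety}} V_i}

in e/bohr^3.  Capping atoms (the methyl group that closes each moiety into
a neutral molecule) are excluded from both sums by construction of the
moiety definition; they are listed explicitly rather than perceived from
connectivity.

Two moieties are scored by the percent difference of their AEDs relative
to a reference (conventionally the carboxylic acid group); experimentally
validated nonclassical bioisosteres of carboxylic acid span differences
from as small as 0.15% up to about 35%, which is used as the inclusive
default decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .basin_integrator import BasinResult

__all__ = [
    "MoietyDefinition",
    "AEDRecord",
    "compute_aed",
    "aed_percent_difference",
    "classify_bioisostere",
    "BIOISOSTERE_THRESHOLD_PERCENT",
]

#: Upper AED percent difference reached by experimentally validated
#: nonclassical carboxylic-acid bioisosteres.
BIOISOSTERE_THRESHOLD_PERCENT = 35.0


@dataclass(frozen=True)
class MoietyDefinition:
    """Atom-index subset of a molecule whose basins are aggregated into AED.

    ``cap_atoms`` are excluded from the AED sums; ``enantiomer`` annotates
    chiral moieties with "R" or "S".
    """

    molecule_id: str
    moiety_atoms: frozenset[int]
    cap_atoms: frozenset[int] = frozenset()
    chiral: bool = False
    enantiomer: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "moiety_atoms", frozenset(self.moiety_atoms))
        object.__setattr__(self, "cap_atoms", frozenset(self.cap_atoms))
        if not self.moiety_atoms:
            raise ValueError("moiety must contain at least one atom")
        overlap = self.moiety_atoms & self.cap_atoms
        if overlap:
            raise ValueError(f"atoms {sorted(overlap)} are both moiety and cap atoms")
        if self.enantiomer is not None and self.enantiomer not in ("R", "S"):
            raise ValueError(f"enantiomer must be 'R' or 'S', got {self.enantiomer!r}")

    @property
    def entry_id(self) -> str:
        """Dataset entry id, with the _R/_S suffix for enantiomers."""
        if self.enantiomer:
            return f"{self.molecule_id}_{self.enantiomer}"
        return self.molecule_id


@dataclass(frozen=True)
class AEDRecord:
    """AED (e/bohr^3) of one moiety under one condition, with its sums."""

    molecule_id: str
    condition: str
    aed: float
    total_n: float
    total_v: float
    dipole: Optional[float] = None  # debye, whole-molecule

    def __post_init__(self) -> None:
        if self.total_v <= 0:
            raise ValueError("total moiety volume must be positive")
        expected = self.total_n / self.total_v
        if abs(self.aed - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError("AED must equal total_n / total_v")


def compute_aed(
    basins: Iterable[BasinResult],
    moiety: MoietyDefinition,
    condition: str = "gas",
    dipole: Optional[float] = None,
) -> AEDRecord:
    """Aggregate basin results over the moiety atoms into an AED record.

    Every moiety atom must carry a basin result; cap atoms and any other
    atoms contribute nothing.
    """
    by_index = {b.atom_index: b for b in basins}
    missing = sorted(i for i in moiety.moiety_atoms if i not in by_index)
    if missing:
        raise KeyError(
            f"moiety {moiety.molecule_id}: no basin result for atom indices {missing}"
        )
    total_n = float(sum(by_index[i].N_i for i in moiety.moiety_atoms))
    total_v = float(sum(by_index[i].V_i for i in moiety.moiety_atoms))
    if total_v == 0:
        raise ValueError(
            f"moiety {moiety.molecule_id}: total envelope volume is zero "
            "(isodensity envelope contains no voxels)"
        )
    return AEDRecord(
        molecule_id=moiety.entry_id,
        condition=condition,
        aed=total_n / total_v,
        total_n=total_n,
        total_v=total_v,
        dipole=dipole,
    )


def aed_percent_difference(record: AEDRecord, reference: AEDRecord) -> float:
    """100 * |AED - AED_ref| / AED_ref."""
    if reference.aed <= 0:
        raise ValueError(f"reference AED must be positive, got {reference.aed}")
    if record.aed <= 0:
        raise ValueError(f"AED must be positive, got {record.aed}")
    return 100.0 * abs(record.aed - reference.aed) / reference.aed


def classify_bioisostere(
    delta_percent: float, threshold: float = BIOISOSTERE_THRESHOLD_PERCENT
) -> bool:
    """True when the AED percent difference is within the (inclusive) threshold."""
    if delta_percent < 0:
        raise ValueError(f"percent difference must be non-negative, got {delta_percent}")
    return delta_percent <= threshold
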