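"""Cross-condition analysis of AED results.

A :class:`ConditionTable` arranges AED (and optionally dipole) values as a
dense molecules x conditions matrix.  On top of it this module provides

* the coefficient of determination between AED vectors from two conditions
  or solvation models (squared Pearson correlation, identical to the OLS
  R^2 of a single-predictor fit),
* a per-molecule sensitivity report: the largest relative AED spread across
  conditions, 100 * (max - min) / min by default, or the spread relative to
  a chosen reference condition,
* dataset enumeration with R/S enantiomer expansion for chiral moieties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .aed_core import AEDRecord

__all__ = [
    "ConditionTable",
    "SensitivityReport",
    "compute_r2",
    "build_condition_table",
    "sensitivity_report",
    "enumerate_dataset",
]


@dataclass(frozen=True)
class ConditionTable:
    """Dense molecules x conditions matrices of AED and (optional) dipoles."""

    molecule_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    aed: np.ndarray
    dipole: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecule_ids", tuple(self.molecule_ids))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        aed = np.asarray(self.aed, dtype=float)
        object.__setattr__(self, "aed", aed)
        shape = (len(self.molecule_ids), len(self.conditions))
        if aed.shape != shape:
            raise ValueError(f"AED matrix shape {aed.shape} does not match {shape}")
        if np.any(np.isnan(aed)):
            raise ValueError("AED matrix contains missing cells")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("molecule ids must be unique")
        if self.dipole is not None:
            dip = np.asarray(self.dipole, dtype=float)
            if dip.shape != shape:
                raise ValueError("dipole matrix shape does not match the AED matrix")
            object.__setattr__(self, "dipole", dip)

    def column(self, condition: str) -> np.ndarray:
        return self.aed[:, self.conditions.index(condition)]


def compute_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the OLS fit of y on x.

    For a single predictor this equals the squared Pearson correlation, so
    it is symmetric in x and y and invariant under affine rescaling of
    either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("degenerate input: x has zero variance")
    if np.ptp(y) == 0 or np.var(y) == 0:
        raise ValueError("degenerate input: y has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


def build_condition_table(records: Iterable[AEDRecord]) -> ConditionTable:
    """Arrange AED records into a dense table; duplicates or missing
    (molecule, condition) cells are reported by name."""
    records = list(records)
    molecule_ids = sorted({r.molecule_id for r in records})
    conditions = sorted({r.condition for r in records})
    seen: dict[tuple[str, str], AEDRecord] = {}
    for r in records:
        key = (r.molecule_id, r.condition)
        if key in seen:
            raise ValueError(f"duplicate record for molecule {key[0]!r}, condition {key[1]!r}")
        seen[key] = r
    missing = [
        (m, c) for m in molecule_ids for c in conditions if (m, c) not in seen
    ]
    if missing:
        named = ", ".join(f"({m}, {c})" for m, c in missing)
        raise ValueError(f"missing cells in condition table: {named}")
    aed = np.array(
        [[seen[(m, c)].aed for c in conditions] for m in molecule_ids]
    )
    dipoles = [[seen[(m, c)].dipole for c in conditions] for m in molecule_ids]
    has_dip = all(d is not None for row in dipoles for d in row)
    return ConditionTable(
        molecule_ids=tuple(molecule_ids),
        conditions=tuple(conditions),
        aed=aed,
        dipole=np.array(dipoles, dtype=float) if has_dip else None,
    )


@dataclass(frozen=True)
class SensitivityReport:
    """Per-molecule AED spread across conditions, in percent, plus summary."""

    per_molecule: dict[str, float]
    mean_delta_percent: float
    max_delta_percent: float
    max_molecule_id: str


def sensitivity_report(
    table: ConditionTable, reference_condition: Optional[str] = None
) -> SensitivityReport:
    """Largest relative AED change per molecule across conditions.

    Default metric: 100 * (max - min) / min over the molecule's row.  With
    ``reference_condition``, the metric is the largest 100 * |AED_c -
    AED_ref| / AED_ref over the other conditions.
    """
    if len(table.conditions) < 2:
        raise ValueError("sensitivity analysis needs at least two conditions")
    deltas: dict[str, float] = {}
    for i, mol in enumerate(table.molecule_ids):
        row = table.aed[i]
        if reference_condition is None:
            lo = row.min()
            if lo <= 0:
                raise ValueError(f"molecule {mol}: non-positive AED in table")
            deltas[mol] = float(100.0 * (row.max() - lo) / lo)
        else:
            ref = row[table.conditions.index(reference_condition)]
            if ref <= 0:
                raise ValueError(f"molecule {mol}: non-positive reference AED")
            deltas[mol] = float(100.0 * np.max(np.abs(row - ref)) / ref)
    max_mol = max(deltas, key=deltas.get)
    return SensitivityReport(
        per_molecule=deltas,
        mean_delta_percent=float(np.mean(list(deltas.values()))),
        max_delta_percent=deltas[max_mol],
        max_molecule_id=max_mol,
    )


def enumerate_dataset(moieties: Iterable[tuple[str, bool]]) -> list[str]:
    """Expand a moiety list into dataset entries.

    Achiral moieties contribute one entry; chiral moieties contribute two,
    suffixed ``_R`` and ``_S``.  Entry count = n_achiral + 2 * n_chiral.
    """
    entries: list[str] = []
    seen: set[str] = set()
    for mol_id, chiral in moieties:
        if mol_id in seen:
            raise ValueError(f"duplicate moiety id {mol_id!r}")
        seen.add(mol_id)
        if chiral:
            entries.append(f"{mol_id}_R")
            entries.append(f"{mol_id}_S")
        else:
            entries.append(mol_id)
    return entries
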