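"""File formats: WFX wavefunctions, analytic-system and moiety JSON specs,
basin-result CSV tables, and Gaussian cube volumetric output.

The WFX dialect implemented here is the tagged-text AIM interchange format:
every section is delimited by ``<Tag Name>`` / ``</Tag Name>`` lines, with
whitespace-separated numeric payloads.  Coordinates are stored in bohr.  The
parser is deliberately strict: a missing mandatory section, an array-length
mismatch, or a non-numeric token is reported as :class:`WfxFormatError` with
enough context (tag name, counts, line number) to locate the defect.

On-disk units are bohr and atomic units throughout, except dipole moments,
which are reported in debye.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .density_model import (
    WFX_ANGULAR_POWERS,
    AnalyticAtom,
    AnalyticAtomSystem,
    GaussianPrimitive,
    MolecularOrbital,
    NucleusSpec,
    Wavefunction,
)

__all__ = [
    "WfxFormatError",
    "BasinTableRow",
    "parse_wfx",
    "write_wfx",
    "parse_analytic_spec",
    "write_analytic_spec",
    "parse_moiety_json",
    "write_basin_table",
    "read_basin_table",
    "write_cube",
]


class WfxFormatError(ValueError):
    """Raised when a WFX stream violates the tagged format."""


_ELEMENTS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe"
).split()


def element_symbol(z: int) -> str:
    if 1 <= z <= len(_ELEMENTS):
        return _ELEMENTS[z - 1]
    return f"Z{z}"


MANDATORY_WFX_TAGS = (
    "Number of Nuclei",
    "Nuclear Cartesian Coordinates",
    "Atomic Numbers",
    "Primitive Centers",
    "Primitive Types",
    "Primitive Exponents",
    "Molecular Orbital Occupation Numbers",
    "Molecular Orbital Primitive Coefficients",
)

_TAG_RE = re.compile(r"^\s*<(/?)([^<>/][^<>]*)>\s*$")


def _read_sections(stream: IO[str]) -> dict[str, tuple[list[str], int]]:
    """Map tag name -> (payload lines, 1-based line number of the open tag).

    Nested tags (``<MO Number>`` inside the coefficient section) are kept
    verbatim in the enclosing payload.
    """
    sections: dict[str, tuple[list[str], int]] = {}
    open_tag: str | None = None
    open_line = 0
    payload: list[str] = []
    depth = 0
    for lineno, raw in enumerate(stream, start=1):
        m = _TAG_RE.match(raw)
        if m and open_tag is None:
            if m.group(1):
                raise WfxFormatError(
                    f"line {lineno}: closing tag </{m.group(2)}> without opening tag"
                )
            open_tag, open_line, payload, depth = m.group(2), lineno, [], 0
            continue
        if m and open_tag is not None:
            closing, name = m.group(1) == "/", m.group(2)
            if closing and name == open_tag and depth == 0:
                sections[open_tag] = (payload, open_line)
                open_tag = None
                continue
            depth += -1 if closing else 1
            payload.append(raw.rstrip("\n"))
            continue
        if open_tag is not None:
            payload.append(raw.rstrip("\n"))
    if open_tag is not None:
        raise WfxFormatError(f"unterminated section <{open_tag}> opened at line {open_line}")
    return sections


def _numeric_tokens(
    tag: str, payload: list[str], start_line: int, kind=float, strip_subtags: bool = False
) -> list:
    values = []
    subtag_depth = 0
    for offset, line in enumerate(payload):
        if strip_subtags:
            m = _TAG_RE.match(line)
            if m:
                subtag_depth += -1 if m.group(1) else 1
                continue
            if subtag_depth > 0:
                continue
        for tok in line.split():
            try:
                values.append(kind(tok))
            except ValueError as exc:
                raise WfxFormatError(
                    f"<{tag}>: non-numeric token {tok!r} at line "
                    f"{start_line + 1 + offset}"
                ) from exc
    return values


def parse_wfx(source: Union[str, Path, IO[str]]) -> Wavefunction:
    """Parse a WFX stream, path, or literal text into a :class:`Wavefunction`.

    All mandatory sections must be present; array lengths are cross-checked
    (3 x nuclei coordinates, equal-length primitive arrays, n_mo x n_prim
    molecular-orbital coefficients).
    """
    if isinstance(source, Path):
        stream: IO[str] = open(source, "r", encoding="utf-8")
    elif isinstance(source, str):
        stream = io.StringIO(source)
    else:
        stream = source
    try:
        sections = _read_sections(stream)
    finally:
        if isinstance(source, (str, Path)) and hasattr(stream, "close"):
            stream.close()

    for tag in MANDATORY_WFX_TAGS:
        if tag not in sections:
            raise WfxFormatError(f"missing mandatory section <{tag}>")

    def ints(tag: str, strip_subtags=False) -> list[int]:
        payload, line = sections[tag]
        return _numeric_tokens(tag, payload, line, int, strip_subtags)

    def floats(tag: str, strip_subtags=False) -> list[float]:
        payload, line = sections[tag]
        return _numeric_tokens(tag, payload, line, float, strip_subtags)

    (n_nuc,) = ints("Number of Nuclei") or (0,)
    coords = floats("Nuclear Cartesian Coordinates")
    if len(coords) != 3 * n_nuc:
        raise WfxFormatError(
            f"<Nuclear Cartesian Coordinates>: expected {3 * n_nuc} values "
            f"(3 x {n_nuc} nuclei), found {len(coords)}"
        )
    atomic_numbers = ints("Atomic Numbers")
    if len(atomic_numbers) != n_nuc:
        raise WfxFormatError(
            f"<Atomic Numbers>: expected {n_nuc} values, found {len(atomic_numbers)}"
        )

    centers = ints("Primitive Centers")
    types = ints("Primitive Types")
    exponents = floats("Primitive Exponents")
    n_prim = len(exponents)
    if not (len(centers) == len(types) == n_prim):
        raise WfxFormatError(
            "primitive arrays disagree in length: "
            f"{len(centers)} centers, {len(types)} types, {n_prim} exponents"
        )

    occupations = floats("Molecular Orbital Occupation Numbers")
    n_mo = len(occupations)
    coeffs = floats("Molecular Orbital Primitive Coefficients", strip_subtags=True)
    if len(coeffs) != n_mo * n_prim:
        raise WfxFormatError(
            f"<Molecular Orbital Primitive Coefficients>: expected "
            f"{n_mo} MOs x {n_prim} primitives = {n_mo * n_prim} values, "
            f"found {len(coeffs)}"
        )

    coord_arr = np.array(coords).reshape(n_nuc, 3)
    nuclei = tuple(
        NucleusSpec(
            index=i + 1,
            element=element_symbol(atomic_numbers[i]),
            atomic_number=atomic_numbers[i],
            position=coord_arr[i],
        )
        for i in range(n_nuc)
    )
    primitives = []
    for c, t, a in zip(centers, types, exponents):
        if t not in WFX_ANGULAR_POWERS:
            raise WfxFormatError(f"<Primitive Types>: unsupported type {t} (supported: 1-20)")
        primitives.append(
            GaussianPrimitive(center_index=c, angular_powers=WFX_ANGULAR_POWERS[t], exponent=a)
        )
    coeff_arr = np.array(coeffs).reshape(n_mo, n_prim)
    orbitals = tuple(
        MolecularOrbital(occupation=occupations[k], coefficients=coeff_arr[k])
        for k in range(n_mo)
    )
    return Wavefunction(
        nuclei=nuclei,
        primitives=primitives,
        orbitals=orbitals,
        total_electrons=float(sum(occupations)),
    )


_WFX_TYPE_BY_POWERS = {v: k for k, v in WFX_ANGULAR_POWERS.items()}


def write_wfx(wf: Wavefunction, destination: Union[str, Path, IO[str], None] = None) -> str:
    """Serialize a wavefunction to WFX text; optionally write it to a path/stream."""
    out = io.StringIO()

    def section(tag: str, lines: Iterable[str]) -> None:
        out.write(f"<{tag}>\n")
        for line in lines:
            out.write(line + "\n")
        out.write(f"</{tag}>\n")

    section("Title", ["generated by aed-tool"])
    section("Number of Nuclei", [f" {len(wf.nuclei)}"])
    section("Number of Primitives", [f" {len(wf.primitives)}"])
    section(
        "Nuclear Cartesian Coordinates",
        [
            " ".join(f"{x: .16E}" for x in n.position)
            for n in wf.nuclei
        ],
    )
    section("Atomic Numbers", [f" {n.atomic_number}" for n in wf.nuclei])
    section(
        "Primitive Centers",
        [" ".join(str(p.center_index) for p in wf.primitives)],
    )
    section(
        "Primitive Types",
        [" ".join(str(_WFX_TYPE_BY_POWERS[p.angular_powers]) for p in wf.primitives)],
    )
    section(
        "Primitive Exponents",
        [" ".join(f"{p.exponent: .16E}" for p in wf.primitives)],
    )
    section(
        "Molecular Orbital Occupation Numbers",
        [f" {mo.occupation: .16E}" for mo in wf.orbitals],
    )
    mo_lines: list[str] = []
    for k, mo in enumerate(wf.orbitals, start=1):
        mo_lines.append("<MO Number>")
        mo_lines.append(f" {k}")
        mo_lines.append("</MO Number>")
        coeffs = [f"{c: .16E}" for c in mo.coefficients]
        for lo in range(0, len(coeffs), 5):
            mo_lines.append(" ".join(coeffs[lo : lo + 5]))
    section("Molecular Orbital Primitive Coefficients", mo_lines)

    text = out.getvalue()
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    elif destination is not None:
        destination.write(text)
    return text


def parse_analytic_spec(source: Union[str, Path, IO[str]]) -> AnalyticAtomSystem:
    """Parse a JSON analytic-system spec: {"atoms": [{center, population, exponent, Z}]}."""
    if isinstance(source, Path):
        data = json.loads(source.read_text(encoding="utf-8"))
    elif isinstance(source, str):
        data = json.loads(source)
    else:
        data = json.load(source)
    atoms_raw = data.get("atoms")
    if not atoms_raw:
        raise ValueError("analytic spec must contain a non-empty 'atoms' list")
    atoms = []
    for i, a in enumerate(atoms_raw):
        try:
            atoms.append(
                AnalyticAtom(
                    center=np.asarray(a["center"], dtype=float),
                    population=float(a["population"]),
                    exponent=float(a["exponent"]),
                    atomic_number=int(a.get("Z", round(float(a["population"])))),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"atom {i}: invalid analytic-atom entry ({exc})") from exc
    return AnalyticAtomSystem(atoms=tuple(atoms))


def write_analytic_spec(
    system: AnalyticAtomSystem, destination: Union[str, Path, IO[str], None] = None
) -> str:
    payload = {
        "atoms": [
            {
                "center": list(map(float, a.center)),
                "population": a.population,
                "exponent": a.exponent,
                "Z": a.atomic_number,
            }
            for a in system.atoms
        ]
    }
    text = json.dumps(payload, indent=2)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    elif destination is not None:
        destination.write(text)
    return text


def parse_moiety_json(source: Union[str, Path, IO[str]]):
    """Parse a moiety definition JSON into :class:`aed.aed_core.MoietyDefinition`."""
    from .aed_core import MoietyDefinition

    if isinstance(source, Path):
        data = json.loads(source.read_text(encoding="utf-8"))
    elif isinstance(source, str):
        data = json.loads(source)
    else:
        data = json.load(source)
    return MoietyDefinition(
        molecule_id=str(data["molecule_id"]),
        moiety_atoms=frozenset(int(i) for i in data["moiety_atoms"]),
        cap_atoms=frozenset(int(i) for i in data.get("cap_atoms", ())),
        chiral=bool(data.get("chiral", False)),
        enantiomer=data.get("enantiomer"),
    )


@dataclass(frozen=True)
class BasinTableRow:
    """One per-atom basin record in a result table."""

    molecule_id: str
    condition: str
    atom_label: str
    N_i: float
    V_i: float

    def __post_init__(self) -> None:
        if self.N_i < 0 or self.V_i < 0:
            raise ValueError("basin populations and volumes must be non-negative")


_LABEL_INDEX_RE = re.compile(r"(\d+)\s*$")


def _atom_sort_key(label: str) -> tuple[int, str]:
    m = _LABEL_INDEX_RE.search(label)
    return (int(m.group(1)) if m else 0, label)


BASIN_TABLE_COLUMNS = ["molecule_id", "condition", "atom_label", "N_i", "V_i"]


def write_basin_table(
    rows: Iterable[BasinTableRow], destination: Union[str, Path, IO[str]]
) -> pd.DataFrame:
    """Write basin rows as CSV, 6 decimal places, sorted by
    (molecule, condition, atom index)."""
    frame = pd.DataFrame(
        [(r.molecule_id, r.condition, r.atom_label, r.N_i, r.V_i) for r in rows],
        columns=BASIN_TABLE_COLUMNS,
    )
    frame["_k"] = frame["atom_label"].map(_atom_sort_key)
    frame = (
        frame.sort_values(["molecule_id", "condition", "_k"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    frame.to_csv(destination, index=False, float_format="%.6f")
    return frame


def read_basin_table(source: Union[str, Path, IO[str]]) -> list[BasinTableRow]:
    frame = pd.read_csv(source, dtype={"molecule_id": str, "condition": str})
    return [
        BasinTableRow(
            molecule_id=row.molecule_id,
            condition=row.condition,
            atom_label=row.atom_label,
            N_i=float(row.N_i),
            V_i=float(row.V_i),
        )
        for row in frame.itertuples()
    ]


def write_cube(
    densities: np.ndarray,
    grid,
    source,
    destination: Union[str, Path, IO[str]],
    comment: str = "electron density",
) -> None:
    """Write volumetric data as a Gaussian cube file (z-fastest ordering).

    ``grid`` is a :class:`aed.basin_integrator.GridSpec`; ``source`` supplies
    the nuclei written into the header.
    """
    from .density_model import nuclear_charges_and_positions

    densities = np.asarray(densities, dtype=float)
    if tuple(densities.shape) != tuple(grid.dims):
        raise ValueError(
            f"density array shape {densities.shape} does not match grid dims {tuple(grid.dims)}"
        )
    if grid.spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {grid.spacing}")
    z, pos = nuclear_charges_and_positions(source)
    lines = [comment, "cube written by aed-tool (bohr, e/bohr^3)"]
    ox, oy, oz = grid.origin
    lines.append(f"{len(z):5d} {ox: .6f} {oy: .6f} {oz: .6f}")
    h = grid.spacing
    nx, ny, nz = grid.dims
    lines.append(f"{nx:5d} {h: .6f} {0.0: .6f} {0.0: .6f}")
    lines.append(f"{ny:5d} {0.0: .6f} {h: .6f} {0.0: .6f}")
    lines.append(f"{nz:5d} {0.0: .6f} {0.0: .6f} {h: .6f}")
    for zi, p in zip(z, pos):
        lines.append(
            f"{int(zi):5d} {float(zi): .6f} {p[0]: .6f} {p[1]: .6f} {p[2]: .6f}"
        )
    body = densities.reshape(nx * ny, nz)
    for row in body:
        for lo in range(0, nz, 6):
            lines.append(" ".join(f"{v: .5E}" for v in row[lo : lo + 6]))
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
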