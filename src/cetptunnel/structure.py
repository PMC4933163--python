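"""Core structural types and fixed-column PDB I/O.

Atoms carry coordinates in Ångström, a residue identity, and a van der
Waals radius used by every clearance / volume / surface computation in the
package.  Radii default to the Bondi set; the Kyte–Doolittle hydropathy
scale is bundled for the tunnel-wall chemistry profile.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "HydropathyScale",
    "PDBParseError",
    "BONDI_RADII",
    "KYTE_DOOLITTLE",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "write_pdb_models",
    "assign_vdw_radii",
    "hydropathy",
    "load_radius_table",
]

#: Bondi van der Waals radii (Å), the de-facto standard hard-sphere set.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "LI": 1.82, "B": 1.92, "C": 1.70, "N": 1.55,
    "O": 1.52, "F": 1.47, "NE": 1.54, "NA": 2.27, "MG": 1.73, "SI": 2.10,
    "P": 1.80, "S": 1.80, "CL": 1.75, "AR": 1.88, "K": 2.75, "CA": 2.31,
    "ZN": 1.39, "SE": 1.90, "BR": 1.85, "I": 1.98, "FE": 1.52,
}

#: Kyte–Doolittle hydropathy: +4.5 (ILE, most hydrophobic) to -4.5 (ARG).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records; message names the line."""


@dataclass
class Atom:
    """A single atom record.

    ``position`` is a length-3 float array in Å; ``vdw_radius`` must be
    positive once assigned (reading a PDB assigns it from the element
    table immediately).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if not self.residue_name:
            raise ValueError(f"atom {self.serial}: empty residue name")


ResidueKey = tuple[str, int, str]  # (chain, residue_seq, residue_name)


@dataclass
class Structure:
    """An ordered collection of atoms with a residue index.

    The residue index partitions the atoms exactly: every atom belongs to
    the residue keyed by its (chain, residue_seq, residue_name) triple.
    """

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residue_index(self) -> dict[ResidueKey, list[int]]:
        index: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            index.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(i)
        return index

    def centroid(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError("empty structure has no centroid")
        return self.coords().mean(axis=0)

    def copy(self) -> "Structure":
        return Structure([replace(a, position=a.position.copy()) for a in self.atoms])

    def atom_by_name(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom named {name!r} in structure")


class HydropathyScale:
    """Residue-code → hydropathy mapping covering the 20 standard amino acids.

    Lookup of an unknown three-letter code raises ``KeyError`` rather than
    returning a silent default.
    """

    def __init__(self, values: Mapping[str, float] | None = None):
        self._values = dict(KYTE_DOOLITTLE if values is None else values)
        missing = set(KYTE_DOOLITTLE) - set(self._values)
        if missing:
            raise ValueError(f"scale must cover the 20 standard residues; missing {sorted(missing)}")

    def value(self, residue_name: str) -> float:
        try:
            return self._values[residue_name.upper()]
        except KeyError:
            raise KeyError(f"unknown residue code {residue_name!r}") from None

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._values


def hydropathy(scale: HydropathyScale, residue_name: str) -> float:
    """Pure lookup of the hydropathy value of a three-letter residue code."""
    return scale.value(residue_name)


def _guess_element(name: str) -> str:
    """Infer the element from an atom name when columns 77-78 are blank."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if len(stripped) >= 2 and two in BONDI_RADII and two not in ("CA",):
        # two-letter match, but bare "CA" in a protein is a calcium trap:
        # an alpha-carbon name is far more common, so prefer carbon there.
        return two
    return stripped[0].upper()


def _open_text(stream: TextIO | str | Path, mode: str = "r"):
    if isinstance(stream, (str, Path)):
        return open(stream, mode), True
    return stream, False


def read_pdb(
    stream: TextIO | str | Path,
    radius_table: Mapping[str, float] | None = None,
) -> Structure:
    """Parse fixed-column ATOM/HETATM records into a :class:`Structure`.

    Records other than ATOM/HETATM/TER/END (and MODEL/ENDMDL wrappers) are
    ignored.  Alternate locations other than blank/'A' are skipped.  Each
    atom's vdW radius is assigned from ``radius_table`` (Bondi by default);
    an element absent from the table is an error, as is a malformed
    coordinate field (the error names the offending line).
    """
    table = BONDI_RADII if radius_table is None else radius_table
    handle, close = _open_text(stream)
    try:
        atoms: list[Atom] = []
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated {record} record")
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                residue_seq = int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
            name = line[12:16].strip()
            residue_name = line[17:20].strip()
            chain = line[21]
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(name)
            if element not in table:
                raise PDBParseError(
                    f"line {lineno}: element {element!r} (atom {name!r}) has no vdW radius in the table"
                )
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=residue_name,
                    residue_seq=residue_seq,
                    chain=chain,
                    position=np.array([x, y, z]),
                    vdw_radius=table[element],
                )
            )
        return Structure(atoms)
    finally:
        if close:
            handle.close()


def read_pdb_models(
    stream: TextIO | str | Path,
    radius_table: Mapping[str, float] | None = None,
) -> list[Structure]:
    """Split a multi-model PDB on MODEL/ENDMDL and parse each model.

    A file without MODEL records yields a single structure.
    """
    handle, close = _open_text(stream)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    blocks: list[list[str]] = []
    current: list[str] = []
    seen_model = False
    for line in text.splitlines(keepends=True):
        record = line[:6].strip()
        if record == "MODEL":
            seen_model = True
            current = []
        elif record == "ENDMDL":
            blocks.append(current)
            current = []
        else:
            current.append(line)
    if not seen_model:
        blocks = [text.splitlines(keepends=True)]
    elif current and any(l[:6].strip() in ("ATOM", "HETATM") for l in current):
        blocks.append(current)
    return [read_pdb(io.StringIO("".join(block)), radius_table) for block in blocks]


def _format_atom_name(name: str, element: str) -> str:
    # Standard convention: element columns 13-14; one-letter elements with
    # short names get a leading space.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _atom_line(a: Atom) -> str:
    for label, v in (("x", a.position[0]), ("y", a.position[1]), ("z", a.position[2])):
        if abs(v) >= 1e5 or len(f"{v:8.3f}") > 8:
            raise ValueError(f"atom {a.serial}: {label}-coordinate {v} overflows the 8-column field")
    name = _format_atom_name(a.name, a.element)
    return (
        f"ATOM  {a.serial:>5d} {name} {a.residue_name:>3s} {a.chain}"
        f"{a.residue_seq:>4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_pdb(structure: Structure, stream: TextIO | str | Path) -> None:
    """Write fixed-column ATOM records (3-decimal coordinates) plus END.

    Round-trips through :func:`read_pdb`.  An empty structure or a
    coordinate that overflows the 8-column field is an error.
    """
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    handle, close = _open_text(stream, "w")
    try:
        for a in structure.atoms:
            handle.write(_atom_line(a))
        handle.write("END\n")
    finally:
        if close:
            handle.close()


def write_pdb_models(models: Iterable[Structure], stream: TextIO | str | Path) -> None:
    """Write structures as a MODEL/ENDMDL multi-model PDB (e.g. a trajectory)."""
    models = list(models)
    if not models:
        raise ValueError("no models to write")
    handle, close = _open_text(stream, "w")
    try:
        for i, m in enumerate(models, start=1):
            if len(m) == 0:
                raise ValueError(f"model {i} is empty")
            handle.write(f"MODEL {i:>8d}\n")
            for a in m.atoms:
                handle.write(_atom_line(a))
            handle.write("ENDMDL\n")
        handle.write("END\n")
    finally:
        if close:
            handle.close()


def assign_vdw_radii(
    structure: Structure, table: Mapping[str, float] | None = None
) -> Structure:
    """Set every atom's vdW radius from its element (in place; returns it).

    Elements missing from the table raise a single error listing the
    offending atoms.
    """
    table = BONDI_RADII if table is None else table
    missing = [(a.serial, a.name, a.element) for a in structure.atoms if a.element not in table]
    if missing:
        shown = ", ".join(f"#{s} {n} ({e})" for s, n, e in missing[:10])
        more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
        raise KeyError(f"no vdW radius for atoms: {shown}{more}")
    for a in structure.atoms:
        a.vdw_radius = table[a.element]
    return structure


def load_radius_table(stream: TextIO | str | Path) -> dict[str, float]:
    """Read a two-column (element, radius-Å) whitespace-separated text file."""
    handle, close = _open_text(stream)
    try:
        table: dict[str, float] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'ELEMENT RADIUS', got {line!r}")
            radius = float(parts[1])
            if not radius > 0 or not math.isfinite(radius):
                raise ValueError(f"line {lineno}: radius must be positive and finite")
            table[parts[0].upper()] = radius
        return table
    finally:
        if close:
            handle.close()
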