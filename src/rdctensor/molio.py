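"""Molecular structure and coupling-table I/O.

This module owns the package's canonical data types: :class:`Atom`,
:class:`Conformer`, :class:`CouplingRecord` and :class:`RDCDataset`, and the
readers/writers for the two plain-text formats everything else consumes:

* standard XYZ (count line, comment line, ``element x y z`` rows, with an
  optional trailing label column) for conformer geometries, and
* a whitespace/TAB-delimited coupling table with a header row naming columns
  from ``atom1 atom2 type J sigJ T sigT D sigD include``, ``#`` comments and
  the literal string ``NA`` as missing-value sentinel.

Units are fixed package-wide: Å for coordinates, Hz for couplings,
kcal/mol for relative energies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Conformer",
    "CouplingRecord",
    "RDCDataset",
    "CouplingType",
    "MolIOError",
    "XYZParseError",
    "UnknownElementError",
    "TableParseError",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "read_rdc_table",
    "write_rdc_table",
]


class MolIOError(ValueError):
    """Base class for structure/table parsing problems."""


class XYZParseError(MolIOError):
    """Malformed XYZ file (bad count line, short file, bad coordinate)."""


class UnknownElementError(MolIOError):
    """Element symbol not present in the periodic table."""


class TableParseError(MolIOError):
    """Malformed coupling or population table."""


#: Recognized coupling classes.  ``CH`` is a rigid one-bond C-H pair,
#: ``CH2`` a diastereotopic methylene proton treated as an independent rigid
#: pair, ``CH3`` a rotating methyl group (axis-averaged), ``CC`` a carbon-
#: carbon pair and ``generic`` anything the caller parameterizes directly.
CouplingType = ("CH", "CH2", "CH3", "CC", "generic")


def atomic_weight(element: str) -> float:
    """Standard atomic weight (u) for an element symbol.

    Raises
    ------
    UnknownElementError
        if the symbol is not in the periodic table.
    """
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    try:
        w = pt.GetAtomicWeight(element.capitalize())
    except Exception:
        w = 0.0
    if not w or w <= 0:
        raise UnknownElementError(f"unknown element symbol: {element!r}")
    return float(w)


@dataclass(frozen=True)
class Atom:
    """A named atom: label, element symbol, atomic mass (u), coordinates (Å)."""

    label: str
    element: str
    mass: float
    xyz: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float).reshape(3))
        if self.mass <= 0:
            raise ValueError(f"atom {self.label}: mass must be positive, got {self.mass}")


@dataclass(frozen=True)
class Conformer:
    """An ordered collection of atoms with an optional relative energy (kcal/mol)."""

    id: str
    atoms: tuple[Atom, ...]
    e_rel: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if len(self.atoms) < 1:
            raise ValueError("a conformer needs at least one atom")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate atom labels in conformer {self.id!r}: {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å, atom order preserved."""
        return np.array([a.xyz for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def atom(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(f"no atom labelled {label!r} in conformer {self.id!r}")

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        """Copy of this conformer with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = tuple(replace(a, xyz=c.copy()) for a, c in zip(self.atoms, coords))
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class CouplingRecord:
    """One atom-pair coupling measurement.

    Holds any of the scalar coupling J, total coupling T and dipolar coupling
    D (all Hz) with their experimental errors.  At least D, or the (J, T)
    pair from which D = (T - J)/2 follows, must be present.
    """

    atom1: str
    atom2: str
    ctype: str = "CH"
    J: float | None = None
    sigJ: float | None = None
    T: float | None = None
    sigT: float | None = None
    D: float | None = None
    sigD: float | None = None
    include: bool = True

    def __post_init__(self) -> None:
        if self.ctype not in CouplingType:
            raise ValueError(f"unknown coupling type {self.ctype!r}; expected one of {CouplingType}")
        if self.D is None and not (self.J is not None and self.T is not None):
            raise ValueError(
                f"record {self.atom1}-{self.atom2}: needs D, or both J and T"
            )
        for name in ("sigJ", "sigT", "sigD"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"record {self.atom1}-{self.atom2}: {name} must be > 0, got {v}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.atom1, self.atom2)


@dataclass
class RDCDataset:
    """An ordered list of coupling records plus free-form provenance metadata."""

    records: list[CouplingRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def included(self) -> list[CouplingRecord]:
        """Records that enter design matrices."""
        return [r for r in self.records if r.include]


# ---------------------------------------------------------------------------
# XYZ


def _parse_xyz_text(text: str, conf_id: str) -> Conformer:
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise XYZParseError(f"malformed atom-count line: {lines[0]!r}") from exc
    body = [l for l in lines[2:] if l.strip()]
    if len(body) != n:
        raise XYZParseError(
            f"count line declares {n} atoms but {len(body)} atom rows found"
        )
    atoms: list[Atom] = []
    counts: dict[str, int] = {}
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {i}: expected 'element x y z [label]', got {line!r}")
        el = parts[0]
        try:
            xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError as exc:
            raise XYZParseError(f"line {i}: coordinate parse failure in {line!r}") from exc
        mass = atomic_weight(el)
        if len(parts) >= 5:
            label = parts[4]
        else:
            counts[el] = counts.get(el, 0) + 1
            label = f"{el}{counts[el]}"
        atoms.append(Atom(label=label, element=el, mass=mass, xyz=xyz))
    return Conformer(id=conf_id, atoms=tuple(atoms))


def read_xyz(path, conf_id: str | None = None) -> Conformer:
    """Read a standard XYZ file into a :class:`Conformer`.

    Atom labels are taken verbatim from an optional fifth column; with bare
    ``element x y z`` rows they are auto-generated as element+index
    (``C1, C2, ..., H1, ...``).  Masses are filled from the standard
    atomic-weight table.
    """
    with open(path) as fh:
        text = fh.read()
    if conf_id is None:
        conf_id = str(path)
    return _parse_xyz_text(text, conf_id)


def write_xyz(conf: Conformer, path, comment: str = "") -> None:
    """Write a conformer as extended XYZ (label in a fifth column)."""
    buf = io.StringIO()
    buf.write(f"{len(conf)}\n{comment}\n")
    for a in conf.atoms:
        x, y, z = a.xyz
        buf.write(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}  {a.label}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_pdb(path, conf_id: str | None = None) -> Conformer:
    """Read the first MODEL of a PDB file (element, atom name, coordinates only).

    Occupancy and altlocs are ignored; atom names become labels.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise MolIOError(f"no model in PDB file {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                el = at.element.name
                atoms.append(
                    Atom(
                        label=at.name,
                        element=el,
                        mass=atomic_weight(el),
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    return Conformer(id=conf_id or str(path), atoms=tuple(atoms))


# ---------------------------------------------------------------------------
# RDC tables

_TABLE_COLUMNS = ("atom1", "atom2", "type", "J", "sigJ", "T", "sigT", "D", "sigD", "include")
_NUMERIC = ("J", "sigJ", "T", "sigT", "D", "sigD")
_NA = "NA"


def read_rdc_table(path_or_buf) -> RDCDataset:
    """Read a coupling table into an :class:`RDCDataset`.

    The format is whitespace/TAB-delimited with a header row naming columns
    from ``atom1 atom2 type J sigJ T sigT D sigD include``; ``#`` starts a
    comment; missing values are the literal ``NA``.  ``atom1`` and ``atom2``
    are mandatory; ``include`` defaults to true.
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()

    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            rows.append((lineno, line.split()))
    if not rows:
        raise TableParseError("no header row found")

    _, header = rows[0]
    unknown = [c for c in header if c not in _TABLE_COLUMNS]
    if unknown:
        raise TableParseError(f"unknown columns in header: {unknown}")
    for mandatory in ("atom1", "atom2"):
        if mandatory not in header:
            raise TableParseError(f"missing mandatory column {mandatory!r}")

    records: list[CouplingRecord] = []
    for lineno, parts in rows[1:]:
        if len(parts) != len(header):
            raise TableParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        cell = dict(zip(header, parts))
        kwargs: dict = {"atom1": cell["atom1"], "atom2": cell["atom2"]}
        if "type" in cell and cell["type"] != _NA:
            kwargs["ctype"] = cell["type"]
        for col in _NUMERIC:
            v = cell.get(col, _NA)
            if v != _NA:
                try:
                    kwargs[col] = float(v)
                except ValueError as exc:
                    raise TableParseError(
                        f"line {lineno}: non-numeric value {v!r} in column {col!r}"
                    ) from exc
        inc = cell.get("include", "true").lower()
        kwargs["include"] = inc in ("true", "1", "yes")
        try:
            records.append(CouplingRecord(**kwargs))
        except ValueError as exc:
            raise TableParseError(f"line {lineno}: {exc}") from exc
    return RDCDataset(records=records)


def write_rdc_table(ds: RDCDataset, path) -> None:
    """Write a dataset in the canonical column order, re-readable losslessly.

    Couplings are written at 0.01 Hz resolution (errors at 0.001 Hz); absent
    fields become ``NA``.
    """
    def fmt(v: float | None, prec: int) -> str:
        return _NA if v is None else f"{v:.{prec}f}"

    out = io.StringIO()
    out.write("\t".join(_TABLE_COLUMNS) + "\n")
    for r in ds.records:
        row = [
            r.atom1,
            r.atom2,
            r.ctype,
            fmt(r.J, 2),
            fmt(r.sigJ, 3),
            fmt(r.T, 2),
            fmt(r.sigT, 3),
            fmt(r.D, 2),
            fmt(r.sigD, 3),
            "true" if r.include else "false",
        ]
        out.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(out.getvalue())
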