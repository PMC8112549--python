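"""Structure data model, PDB/mmCIF I/O, and atom selection.

The in-memory model is a small chain -> residue -> atom hierarchy with author
residue numbering preserved verbatim (catalytic residues are cited by author
numbers, e.g. D10, H983 of SpCas9).  gemmi does the heavy lifting for both
PDB and mmCIF parsing/writing; this module adapts its hierarchy to the
package's own types and applies a deterministic altloc policy.

Coordinates are Cartesian angstroms throughout; no unit conversion happens
anywhere in the package.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import gemmi
import numpy as np

from mgforge.errors import (
    AtomLookupError,
    CapacityError,
    FormatError,
    ParseError,
    SelectionError,
)

# Residue-name tables used to assign a molecule class.  Author numbering and
# names are never altered, so classification is purely name-based.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "DI", "I",
}
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
ION_NAMES = {
    "MG", "ZN", "MN", "CA", "NA", "K", "FE", "FE2", "NI", "CO", "CU", "CD",
    "CL", "BR", "IOD", "SR", "CS", "LI",
}


def molecule_class(res_name: str) -> str:
    """Classify a residue name as protein / nucleic / water / ion / other."""
    name = res_name.strip().upper()
    if name in WATER_NAMES:
        return "water"
    if name in AMINO_ACIDS:
        return "protein"
    if name in NUCLEOTIDES:
        return "nucleic"
    if name in ION_NAMES:
        return "ion"
    return "other"


@dataclass
class Atom:
    """A single atom: name, element, position (angstrom), occupancy, altloc."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.occupancy, self.altloc, self.serial, self.b_iso)


@dataclass
class Residue:
    """One residue identified by (chain_id, seq_num, icode) with ordered atoms."""

    seq_num: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def mol_class(self) -> str:
        return molecule_class(self.res_name)

    def atom(self, name: str) -> Atom:
        """Look up one atom by name; raises AtomLookupError if absent."""
        for a in self.atoms:
            if a.name == name:
                return a
        raise AtomLookupError(
            f"residue {self.res_name} {self.seq_num}{self.icode}: no atom named {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.seq_num, self.res_name,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class Chain:
    """Ordered residues sharing one chain id."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_num: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        raise AtomLookupError(f"chain {self.chain_id}: no residue {seq_num}{icode}")

    def has_residue(self, seq_num: int, icode: str = "") -> bool:
        return any(r.seq_num == seq_num and r.icode == icode for r in self.residues)

    @property
    def mol_class(self) -> str:
        """Majority molecule class over residues (ties: first seen)."""
        counts: dict[str, int] = {}
        for r in self.residues:
            counts[r.mol_class] = counts.get(r.mol_class, 0) + 1
        if not counts:
            return "other"
        return max(counts, key=lambda k: counts[k])

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """Hierarchical atom model: chains -> residues -> atoms."""

    id: str = ""
    chains: list[Chain] = field(default_factory=list)

    # -- hierarchy access ---------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise AtomLookupError(f"structure {self.id!r}: no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        """All atomic coordinates as an (N, 3) array, hierarchy order."""
        pts = [a.coords for _, _, a in self.iter_atoms()
               if not (heavy_only and a.is_hydrogen)]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts)

    def copy(self) -> "Structure":
        return Structure(self.id, [c.copy() for c in self.chains])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t to every atom in place."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, _, a in self.iter_atoms():
            a.coords = R @ a.coords + t

    def renumber_serials(self) -> None:
        for i, (_, _, a) in enumerate(self.iter_atoms(), start=1):
            a.serial = i

    # -- convenience lookups used by the site-analysis modules --------------
    def get_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue:
        return self.chain(chain_id).residue(seq_num, icode)

    def get_atom(self, chain_id: str, seq_num: int, atom_name: str,
                 icode: str = "") -> Atom:
        return self.get_residue(chain_id, seq_num, icode).atom(atom_name)


@dataclass(frozen=True)
class DomainSpec:
    """A named domain as inclusive (chain_id, start, end) author-number ranges.

    Labels follow the SpCas9 convention (REC1, REC2, REC3, HNH, RuvC, PI, BH)
    but any user label is accepted.
    """

    label: str
    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(c), int(s), int(e)) for c, s, e in self.segments)
        object.__setattr__(self, "segments", segs)
        for chain_id, start, end in segs:
            if start > end:
                raise ValueError(f"domain {self.label}: segment {chain_id}:{start}-{end} has start > end")
        # Overlap check within the same chain.
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain_id, start, end in segs:
            by_chain.setdefault(chain_id, []).append((start, end))
        for chain_id, ranges in by_chain.items():
            ranges.sort()
            for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"domain {self.label}: overlapping segments on chain {chain_id}"
                    )

    def contains(self, chain_id: str, seq_num: int) -> bool:
        return any(c == chain_id and s <= seq_num <= e for c, s, e in self.segments)

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c, _, _ in self.segments:
            if c not in seen:
                seen.append(c)
        return seen


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

class Selection:
    """Composable predicate over (chain, residue, atom).

    Build from the factory classmethods and combine with ``&``, ``|`` and
    ``~``::

        sel = Selection.mol_class("nucleic") | Selection.element("MG")
    """

    def __init__(self, predicate: Callable[[Chain, Residue, Atom], bool],
                 description: str = "<custom>") -> None:
        self._predicate = predicate
        self.description = description

    def __call__(self, chain: Chain, residue: Residue, atom: Atom) -> bool:
        return bool(self._predicate(chain, residue, atom))

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(lambda c, r, a: self(c, r, a) and other(c, r, a),
                         f"({self.description} AND {other.description})")

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(lambda c, r, a: self(c, r, a) or other(c, r, a),
                         f"({self.description} OR {other.description})")

    def __invert__(self) -> "Selection":
        return Selection(lambda c, r, a: not self(c, r, a),
                         f"(NOT {self.description})")

    def __repr__(self) -> str:
        return f"Selection[{self.description}]"

    # -- factories ----------------------------------------------------------
    @classmethod
    def all(cls) -> "Selection":
        return cls(lambda c, r, a: True, "all")

    @classmethod
    def none(cls) -> "Selection":
        return cls(lambda c, r, a: False, "none")

    @classmethod
    def chain(cls, *chain_ids: str) -> "Selection":
        ids = set(chain_ids)
        return cls(lambda c, r, a: c.chain_id in ids, f"chain {sorted(ids)}")

    @classmethod
    def res_range(cls, start: int, end: int) -> "Selection":
        return cls(lambda c, r, a: start <= r.seq_num <= end,
                   f"resi {start}-{end}")

    @classmethod
    def res_name(cls, *names: str) -> "Selection":
        up = {n.upper() for n in names}
        return cls(lambda c, r, a: r.res_name.upper() in up, f"resn {sorted(up)}")

    @classmethod
    def atom_name(cls, *names: str) -> "Selection":
        nm = set(names)
        return cls(lambda c, r, a: a.name in nm, f"name {sorted(nm)}")

    @classmethod
    def element(cls, *symbols: str) -> "Selection":
        el = {s.upper() for s in symbols}
        return cls(lambda c, r, a: a.element.upper() in el,
                   f"element {sorted(el)}")

    @classmethod
    def mol_class(cls, *classes: str) -> "Selection":
        cl = set(classes)
        return cls(lambda c, r, a: r.mol_class in cl, f"class {sorted(cl)}")

    @classmethod
    def domain(cls, spec: DomainSpec) -> "Selection":
        return cls(lambda c, r, a: spec.contains(c.chain_id, r.seq_num),
                   f"domain {spec.label}")

    @classmethod
    def heavy(cls) -> "Selection":
        return cls(lambda c, r, a: not a.is_hydrogen, "heavy")


def select_atoms(structure: Structure, selection: Selection,
                 known_chains_check: bool = True) -> Structure:
    """Return a new Structure containing exactly the atoms matching ``selection``.

    Hierarchy and ordering are preserved; empty chains/residues are dropped.
    The input structure is untouched.  Selecting on a chain id absent from the
    structure yields an empty result plus a warning, not an error.
    """
    out = Structure(id=structure.id)
    for c in structure.chains:
        new_chain = Chain(c.chain_id)
        for r in c.residues:
            kept = [a.copy() for a in r.atoms if selection(c, r, a)]
            if kept:
                new_chain.residues.append(Residue(r.seq_num, r.res_name, kept, r.icode))
        if new_chain.residues:
            out.chains.append(new_chain)
    if known_chains_check and out.n_atoms == 0 and structure.n_atoms > 0:
        warnings.warn(
            f"selection {selection.description!r} matched no atoms in "
            f"structure {structure.id!r}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise FormatError(f"unknown structure format {fmt!r} (expected pdb/mmcif/auto)")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise FormatError(f"cannot infer format from suffix {suffix!r} of {path}")


def _validate_pdb_records(path: Path) -> None:
    """Cheap pre-check so truncated ATOM records fail loudly with a line number.

    gemmi is deliberately lenient; a silent mis-parse of a clipped coordinate
    field would poison downstream geometry, so reject short records up front.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.rstrip("\n\r")
            if rec[:6].strip() in ("ATOM", "HETATM") and len(rec) < 54:
                raise ParseError(
                    f"{path}: line {lineno}: truncated {rec[:6].strip()} record "
                    f"({len(rec)} columns, need >= 54)")


def _from_gemmi(gst: gemmi.Structure, keep_altlocs: bool) -> Structure:
    """Convert the first model of a gemmi structure to the package hierarchy.

    Altloc policy: per (residue, atom name), keep the highest-occupancy
    conformer; ties broken by altloc code alphabetical order.  This gives a
    deterministic single-conformer model for geometry work.
    """
    out = Structure(id=gst.name or "")
    if len(gst) == 0:
        return out
    model = gst[0]
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(
                seq_num=gres.seqid.num,
                res_name=gres.name,
                icode=(gres.seqid.icode or "").strip(),
            )
            if keep_altlocs:
                chosen = list(gres)
            else:
                best: dict[str, gemmi.Atom] = {}
                for ga in gres:
                    prev = best.get(ga.name)
                    if prev is None:
                        best[ga.name] = ga
                        continue
                    key_new = (-ga.occ, ga.altloc or "")
                    key_old = (-prev.occ, prev.altloc or "")
                    if key_new < key_old:
                        best[ga.name] = ga
                # preserve file order of the surviving atoms
                chosen = [ga for ga in gres if best.get(ga.name) is ga]
            for ga in chosen:
                res.atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=(ga.altloc or "").strip("\x00"),
                    serial=ga.serial,
                    b_iso=ga.b_iso,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.id or "model"
    model = gemmi.Model("1")
    for c in structure.chains:
        gchain = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.res_name
            gres.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
            cls = r.mol_class
            gres.het_flag = "A" if cls in ("protein", "nucleic") else "H"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.altloc = a.altloc or "\x00"
                ga.serial = a.serial
                ga.b_iso = a.b_iso
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    return gst


def read_structure(path: str | Path, format: str = "auto",
                   keep_altlocs: bool = False) -> Structure:
    """Read a PDB or mmCIF file into the package hierarchy.

    Parameters
    ----------
    path : file to read.
    format : "pdb", "mmcif" or "auto" (infer from suffix).
    keep_altlocs : keep all alternate conformers instead of applying the
        highest-occupancy single-conformer policy.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        _validate_pdb_records(path)
    try:
        if fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st = _from_gemmi(gst, keep_altlocs=keep_altlocs)
    if not st.id:
        st.id = path.stem
    return st


def write_structure(structure: Structure, path: str | Path,
                    format: str = "auto", renumber: bool = False) -> None:
    """Write a structure as PDB or mmCIF.

    PDB fixed columns cap residue numbers at 9999 and serials at 99999; with
    ``renumber=True`` serials are regenerated, otherwise an overflow raises
    :class:`CapacityError`.  Output re-reads to the same coordinates at PDB
    precision (3 decimals).
    """
    path = Path(path)
    if structure.n_atoms == 0:
        raise SelectionError("refusing to write an empty structure")
    fmt = _detect_format(path, format)
    st = structure.copy()
    if renumber:
        st.renumber_serials()
    if fmt == "pdb":
        for _, r, _ in ((c, r, a) for c, r, a in st.iter_atoms()):
            if r.seq_num > 9999 or r.seq_num < -999:
                raise CapacityError(
                    f"residue number {r.seq_num} exceeds PDB fixed columns; "
                    "renumber the structure first")
        for _, _, a in st.iter_atoms():
            if a.serial > 99999:
                raise CapacityError(
                    f"atom serial {a.serial} exceeds PDB fixed columns; "
                    "pass renumber=True")
        if all(a.serial == 0 for _, _, a in st.iter_atoms()):
            st.renumber_serials()
    gst = _to_gemmi(st)
    if fmt == "pdb":
        gst.write_pdb(str(path))
    else:
        doc = gst.make_mmcif_document()
        doc.write_file(str(path))
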