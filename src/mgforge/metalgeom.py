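"""Metal-site detection and coordination-geometry analysis.

Mg2+ in nuclease active sites is octahedrally coordinated by N/O donors —
carboxylate oxygens (Asp/Glu), amide oxygens (Asn), imidazole nitrogens
(His), water oxygens, and non-bridging phosphate oxygens — at roughly 2.0 A.
This module finds the ions, enumerates their donor shells, scores how close
a shell is to an ideal octahedron (90 deg cis / 180 deg trans angles), and
tabulates the distances that characterize one- and two-metal sites:
ligand-to-ion, ion-to-ion, and His-CA-to-scissile-phosphorus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from mgforge.errors import AtomLookupError, GeometryError
from mgforge.structio import Atom, Residue, Structure

#: protein backbone atom names (never ligand donors in shell classification)
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

#: elements counted as inner-sphere donors; carbon is never a ligand
DONOR_ELEMENTS = {"N", "O", "S"}

FIRST_SHELL_CUTOFF = 2.6   # A; encloses ~1.8-2.1 A Mg-donor bonds with margin
SECOND_SHELL_CUTOFF = 6.0  # A from the ion; H-bond reach of first-shell donors


@dataclass(frozen=True)
class AtomRef:
    """Stable reference to one atom: (chain, residue number, icode, atom name)."""

    chain_id: str
    seq_num: int
    atom_name: str
    icode: str = ""

    def resolve(self, structure: Structure) -> Atom:
        return structure.get_atom(self.chain_id, self.seq_num, self.atom_name, self.icode)

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.seq_num}{self.icode}/{self.atom_name}"


@dataclass
class CatalyticResidue:
    """A catalytic residue and the side-chain atoms it donates to the ion(s)."""

    chain_id: str
    seq_num: int
    ligand_atoms: tuple[str, ...]
    icode: str = ""


@dataclass
class MetalSiteDefinition:
    """Definition of a one- or two-metal active site.

    ``ions`` are (label, element) with an optional explicit residue
    reference; unresolved ions are located by element search.  Defaults for
    the two canonical SpCas9 sites are provided by :func:`hnh_site` and
    :func:`ruvc_site`.
    """

    site_name: str
    ions: list[tuple[str, str, tuple[str, int] | None]]
    catalytic_residues: list[CatalyticResidue]
    water_slots_per_ion: int = 2
    scissile: "object | None" = None  # basescreen.ScissileSite, bound late

    def __post_init__(self) -> None:
        if self.site_name == "RuvC_two_metal" and len(self.ions) != 2:
            raise ValueError("a two-metal site needs exactly 2 ions")


def hnh_site(protein_chain: str = "A", d839: int = 839, n863: int = 863,
             scissile=None) -> MetalSiteDefinition:
    """Default one-metal HNH-like site: Asp and Asn side-chain oxygens."""
    return MetalSiteDefinition(
        site_name="HNH_one_metal",
        ions=[("A", "MG", None)],
        catalytic_residues=[
            CatalyticResidue(protein_chain, d839, ("OD1", "OD2")),
            CatalyticResidue(protein_chain, n863, ("OD1",)),
        ],
        scissile=scissile,
    )


def ruvc_site(protein_chain: str = "A", d10: int = 10, e762: int = 762,
              h983: int = 983, d986: int = 986, scissile=None) -> MetalSiteDefinition:
    """Default two-metal RuvC-like site: three carboxylates plus one His Nd1."""
    return MetalSiteDefinition(
        site_name="RuvC_two_metal",
        ions=[("A", "MG", None), ("B", "MG", None)],
        catalytic_residues=[
            CatalyticResidue(protein_chain, d10, ("OD1", "OD2")),
            CatalyticResidue(protein_chain, e762, ("OE1", "OE2")),
            CatalyticResidue(protein_chain, h983, ("ND1",)),
            CatalyticResidue(protein_chain, d986, ("OD1", "OD2")),
        ],
        scissile=scissile,
    )


@dataclass
class Ligand:
    ref: AtomRef
    distance: float
    ligand_class: str  # carboxylate O | amide O | imidazole N | water O | phosphate O | other


@dataclass
class CoordinationShell:
    metal: AtomRef
    ligands: list[Ligand]

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


@dataclass
class GeometryScore:
    """Octahedricity of a coordination shell.

    ``angular_deviation`` is the RMS over ligand-pair angles of the absolute
    difference from the ideal angle (90 cis / 180 trans) under the best
    vertex assignment; a perfect octahedron scores 0.
    """

    angular_deviation: float
    distance_spread: float
    complete: bool
    best_assignment: tuple[int, ...] | None = None


@dataclass
class DistanceTable:
    rows: list[tuple[str, AtomRef, AtomRef, float]] = field(default_factory=list)

    def add(self, label: str, a: AtomRef, b: AtomRef, distance: float) -> None:
        self.rows.append((label, a, b, float(distance)))

    def value(self, label: str) -> float:
        for lab, _, _, d in self.rows:
            if lab == label:
                return d
        raise KeyError(f"no distance row labeled {label!r}")

    def labels(self) -> list[str]:
        return [lab for lab, _, _, _ in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(lab, str(a), str(b), d) for lab, a, b, d in self.rows],
            columns=["label", "atom_a", "atom_b", "distance_A"],
        )


# ---------------------------------------------------------------------------
# Ion location and shell detection
# ---------------------------------------------------------------------------

def find_metal_ions(structure: Structure, element: str = "MG") -> list[AtomRef]:
    """All ions of the element, in chain/sequence order."""
    el = element.upper()
    refs = []
    for c in structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if a.element.upper() == el:
                    refs.append(AtomRef(c.chain_id, r.seq_num, a.name, r.icode))
    return refs


def _classify_ligand(residue: Residue, atom: Atom) -> str:
    cls = residue.mol_class
    name = residue.res_name.upper()
    if cls == "water":
        return "water O"
    if cls == "nucleic":
        return "phosphate O" if atom.name in ("OP1", "OP2", "O1P", "O2P",
                                              "O5'", "O3'", "P") else "other"
    if name in ("ASP", "GLU") and atom.name in ("OD1", "OD2", "OE1", "OE2"):
        return "carboxylate O"
    if name in ("ASN", "GLN") and atom.name in ("OD1", "OE1"):
        return "amide O"
    if name == "HIS" and atom.name in ("ND1", "NE2"):
        return "imidazole N"
    return "other"


def coordination_shell(structure: Structure, metal: AtomRef,
                       cutoff: float = FIRST_SHELL_CUTOFF) -> CoordinationShell:
    """All N/O/S donor heavy atoms within ``cutoff`` of the metal.

    Ligands are classified by residue chemistry and sorted by distance
    (ties broken by atom serial).  Verified against an all-pairs scan in the
    test suite; the k-d tree is an implementation detail.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    center = metal.resolve(structure).coords
    entries = []  # (distance, serial, Ligand)
    refs, coords, serials = [], [], []
    for c in structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if a.element.upper() not in DONOR_ELEMENTS:
                    continue
                refs.append((c, r, a))
                coords.append(a.coords)
                serials.append(a.serial)
    if refs:
        tree = cKDTree(np.array(coords))
        for i in tree.query_ball_point(center, cutoff):
            c, r, a = refs[i]
            ref = AtomRef(c.chain_id, r.seq_num, a.name, r.icode)
            if ref == metal:
                continue
            d = float(np.linalg.norm(a.coords - center))
            entries.append((d, serials[i], Ligand(ref, d, _classify_ligand(r, a))))
    entries.sort(key=lambda e: (e[0], e[1]))
    return CoordinationShell(metal=metal, ligands=[e[2] for e in entries])


# ---------------------------------------------------------------------------
# Octahedricity
# ---------------------------------------------------------------------------

#: unit vectors of the ideal octahedron vertices
OCTAHEDRON_VERTICES = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
], dtype=float)

#: ideal inter-vertex angle: 180 for opposite vertices, else 90
_IDEAL_ANGLE = np.degrees(np.arccos(np.clip(
    OCTAHEDRON_VERTICES @ OCTAHEDRON_VERTICES.T, -1, 1)))


def _pair_angles(vectors: np.ndarray) -> np.ndarray:
    """Matrix of ligand-metal-ligand angles in degrees."""
    unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return np.degrees(np.arccos(np.clip(unit @ unit.T, -1.0, 1.0)))


def _three_pairings(n: int = 6):
    """All 15 partitions of 6 indices into 3 unordered trans pairs."""
    idx = list(range(n))

    def rec(remaining):
        if not remaining:
            yield []
            return
        first = remaining[0]
        for k in remaining[1:]:
            rest = [i for i in remaining[1:] if i != k]
            for tail in rec(rest):
                yield [(first, k)] + tail

    yield from rec(idx)


def octahedricity(shell: CoordinationShell, structure: Structure) -> GeometryScore:
    """Score how octahedral a coordination shell is.

    For six ligands the score minimizes, over all assignments of ligands to
    octahedron vertices, the RMS of |observed angle - ideal angle| across
    all 15 ligand pairs (equivalently: over the 15 ways of choosing the
    three trans pairs).  For other coordination numbers each observed angle
    is matched to the nearer of 90/180 and the shell is flagged incomplete.
    """
    n = shell.coordination_number
    if n < 2:
        raise GeometryError(f"octahedricity needs >= 2 ligands, got {n}")
    center = shell.metal.resolve(structure).coords
    vecs = np.array([lig.ref.resolve(structure).coords - center for lig in shell.ligands])
    dists = np.linalg.norm(vecs, axis=1)
    spread = float(np.std(dists))
    angles = _pair_angles(vecs)

    if n == 6:
        iu = np.triu_indices(6, k=1)
        best = None
        best_pairing = None
        for pairing in _three_pairings():
            trans = set(tuple(sorted(p)) for p in pairing)
            ideal = np.where(
                [(min(i, j), max(i, j)) in trans for i, j in zip(*iu)], 180.0, 90.0)
            dev = angles[iu] - ideal
            rms = float(np.sqrt(np.mean(dev ** 2)))
            if best is None or rms < best:
                best = rms
                best_pairing = tuple(i for p in pairing for i in p)
        return GeometryScore(angular_deviation=best, distance_spread=spread,
                             complete=True, best_assignment=best_pairing)

    iu = np.triu_indices(n, k=1)
    obs = angles[iu]
    dev = np.minimum(np.abs(obs - 90.0), np.abs(obs - 180.0))
    rms = float(np.sqrt(np.mean(dev ** 2))) if obs.size else 0.0
    return GeometryScore(angular_deviation=rms, distance_spread=spread, complete=False)


def octahedricity_bruteforce(shell: CoordinationShell, structure: Structure) -> float:
    """Independent 6!-permutation oracle for the six-ligand score.

    Assigns ligands to the six ideal vertices in every order, scoring each
    assignment by the RMS deviation of pair angles from the vertex-pair
    ideals; returns the minimum.  Exponentially slower than
    :func:`octahedricity` but shares no code path with it.
    """
    if shell.coordination_number != 6:
        raise GeometryError("brute-force oracle requires exactly 6 ligands")
    center = shell.metal.resolve(structure).coords
    vecs = np.array([lig.ref.resolve(structure).coords - center for lig in shell.ligands])
    angles = _pair_angles(vecs)
    iu = np.triu_indices(6, k=1)
    best = np.inf
    for perm in permutations(range(6)):
        ideal = np.array([_IDEAL_ANGLE[perm[i], perm[j]] for i, j in zip(*iu)])
        rms = np.sqrt(np.mean((angles[iu] - ideal) ** 2))
        best = min(best, float(rms))
    return best


# ---------------------------------------------------------------------------
# Site tables and shell classification
# ---------------------------------------------------------------------------

def _resolve_ions(structure: Structure, site: MetalSiteDefinition) -> list[tuple[str, AtomRef]]:
    """Resolve the site's ions to atoms, assigning A/B labels.

    For two-metal sites ion A is the one nearer the His Nd1 donor if the
    site defines one (the His points its imidazole at ion A), otherwise
    nearer the scissile pro-Rp oxygen; ties break on lower atom serial.
    """
    explicit = all(ref is not None for _, _, ref in site.ions)
    found: list[AtomRef] = []
    if explicit:
        for _, element, ref in site.ions:
            chain_id, seq = ref
            res = structure.get_residue(chain_id, seq)
            hit = next((AtomRef(chain_id, seq, a.name, res.icode)
                        for a in res.atoms if a.element.upper() == element.upper()), None)
            if hit is None:
                raise AtomLookupError(f"no {element} atom in residue {chain_id}:{seq}")
            found.append(hit)
    else:
        elements = {el.upper() for _, el, _ in site.ions}
        for el in elements:
            found.extend(find_metal_ions(structure, el))
        if len(found) < len(site.ions):
            raise AtomLookupError(
                f"site {site.site_name}: found {len(found)} ions, need {len(site.ions)}")
        found = found[:len(site.ions)] if explicit else found
    if len(found) > len(site.ions):
        found = found[:len(site.ions)]

    labels = [label for label, _, _ in site.ions]
    if len(found) == 2:
        anchor = None
        for cres in site.catalytic_residues:
            if "ND1" in cres.ligand_atoms:
                try:
                    anchor = structure.get_atom(cres.chain_id, cres.seq_num, "ND1",
                                                cres.icode).coords
                except AtomLookupError:
                    anchor = None
                break
        if anchor is None and site.scissile is not None:
            anchor = site.scissile.pro_rp.resolve(structure).coords
        if anchor is not None:
            def sort_key(ref: AtomRef):
                a = ref.resolve(structure)
                return (float(np.linalg.norm(a.coords - anchor)), a.serial)
            found = sorted(found, key=sort_key)
    return list(zip(labels, found))


def site_distance_table(structure: Structure, site: MetalSiteDefinition) -> DistanceTable:
    """Characteristic distances of a metal site.

    Rows: ion-ion (two-metal sites), each defined ligand atom to its nearest
    ion, and CA-to-scissile-P for every His among the catalytic residues (if
    the site carries a scissile reference).
    """
    table = DistanceTable()
    ions = _resolve_ions(structure, site)
    ion_atoms = {label: ref.resolve(structure) for label, ref in ions}

    if len(ions) == 2:
        (la, ra), (lb, rb) = ions
        d = float(np.linalg.norm(ion_atoms[la].coords - ion_atoms[lb].coords))
        table.add(f"Mg{la}-Mg{lb}", ra, rb, d)

    for cres in site.catalytic_residues:
        try:
            residue = structure.get_residue(cres.chain_id, cres.seq_num, cres.icode)
        except AtomLookupError as exc:
            raise AtomLookupError(
                f"site {site.site_name}: cannot resolve residue "
                f"{cres.chain_id}:{cres.seq_num}") from exc
        for atom_name in cres.ligand_atoms:
            if not residue.has_atom(atom_name):
                continue
            lig = residue.atom(atom_name)
            lig_ref = AtomRef(cres.chain_id, cres.seq_num, atom_name, cres.icode)
            label_ion, dmin = None, np.inf
            for label, ref in ions:
                d = float(np.linalg.norm(lig.coords - ion_atoms[label].coords))
                if d < dmin:
                    label_ion, dmin = (label, ref), d
            table.add(f"{residue.res_name}{cres.seq_num}:{atom_name}-Mg{label_ion[0]}",
                      lig_ref, label_ion[1], dmin)

    if site.scissile is not None:
        p_ref = site.scissile.p_atom
        p = p_ref.resolve(structure)
        for cres in site.catalytic_residues:
            residue = structure.get_residue(cres.chain_id, cres.seq_num, cres.icode)
            if residue.res_name.upper() == "HIS" and residue.has_atom("CA"):
                ca = residue.atom("CA")
                ca_ref = AtomRef(cres.chain_id, cres.seq_num, "CA", cres.icode)
                table.add(f"HIS{cres.seq_num}:CA-P",
                          ca_ref, p_ref, float(np.linalg.norm(ca.coords - p.coords)))
    return table


def classify_shells(structure: Structure, site: MetalSiteDefinition,
                    first_cutoff: float = FIRST_SHELL_CUTOFF,
                    second_cutoff: float = SECOND_SHELL_CUTOFF,
                    ) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Split residues into first and second coordination shells.

    First shell: protein residues with a side-chain N/O/S within
    ``first_cutoff`` of any site ion.  Second shell: remaining protein
    residues with a side-chain N/O/S within ``second_cutoff`` of any ion or
    of any first-shell ligand atom.  Returns two sets of (chain_id, seq_num).
    """
    ions = _resolve_ions(structure, site)
    ion_coords = [ref.resolve(structure).coords for _, ref in ions]

    def side_chain_donors(r: Residue):
        for a in r.atoms:
            if a.element.upper() in DONOR_ELEMENTS and a.name not in BACKBONE_NAMES:
                yield a

    first: set[tuple[str, int]] = set()
    first_ligand_coords: list[np.ndarray] = []
    for c in structure.chains:
        for r in c.residues:
            if r.mol_class != "protein":
                continue
            for a in side_chain_donors(r):
                if any(np.linalg.norm(a.coords - ic) <= first_cutoff for ic in ion_coords):
                    first.add((c.chain_id, r.seq_num))
                    first_ligand_coords.append(a.coords)
    anchors = ion_coords + first_ligand_coords
    second: set[tuple[str, int]] = set()
    for c in structure.chains:
        for r in c.residues:
            if r.mol_class != "protein" or (c.chain_id, r.seq_num) in first:
                continue
            for a in side_chain_donors(r):
                if any(np.linalg.norm(a.coords - x) <= second_cutoff for x in anchors):
                    second.add((c.chain_id, r.seq_num))
                    break
    return first, second
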