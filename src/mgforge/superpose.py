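"""Optimal rigid superposition (Kabsch), RMSD, and domain-restricted alignment.

Used to register template structures into a common frame before transferring
domain coordinates.  Reflections are always forbidden (determinant forced to
+1): biomolecules are chiral, so an improper "superposition" is never valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mgforge.errors import GeometryError, PairingError
from mgforge.structio import DomainSpec, Structure

logger = logging.getLogger(__name__)

#: default atom subset per molecule class for domain alignment
BACKBONE_ATOMS = {"protein": ("CA",), "nucleic": ("P",)}


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform x -> R x + t (rotation then translation, angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("Transform needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix determinant != +1 (reflection?)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array (or a single 3-vector)."""
        pts = np.asarray(coords, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        Rt = self.rotation.T
        return Transform(Rt, -Rt @ self.translation)

    def to_flat(self) -> list[float]:
        """Serialize as 12 numbers: row-major rotation, then translation."""
        return [*self.rotation.reshape(9).tolist(), *self.translation.tolist()]

    @classmethod
    def from_flat(cls, values) -> "Transform":
        v = np.asarray(list(values), float)
        if v.shape != (12,):
            raise ValueError("expected 12 numbers (9 rotation + 3 translation)")
        return cls(v[:9].reshape(3, 3), v[9:])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class SuperpositionResult:
    """Outcome of a least-squares superposition."""

    transform: Transform
    rmsd: float
    n_pairs: int
    pairing: list[tuple] | None = None


def _check_not_collinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    # rank < 2 => all points on one line (or coincident): rotation under-determined
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise GeometryError("points are collinear or coincident; superposition is under-determined")


def kabsch(ref_coords, mob_coords) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference points.

    Returns the proper rotation + translation minimizing the RMSD of
    ``transform.apply(mob_coords)`` against ``ref_coords``, and that minimal
    RMSD.  Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(ref_coords, float)
    Q = np.asarray(mob_coords, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("coordinate lists must be equal-length (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 atom pairs for superposition, got {n}")
    _check_not_collinear(P)
    _check_not_collinear(Q)

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    # force a proper rotation: flip the axis of least singular value if needed
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    transform = Transform(R, t)
    moved = transform.apply(Q)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_pairs=n)


def _match_atoms(mobile: Structure, reference: Structure,
                 domain: DomainSpec | None,
                 atom_names: tuple[str, ...] | None):
    """Pair atoms by (chain_id, seq_num, icode, atom_name).

    Returns (ref_coords, mob_coords, pairing keys, unmatched residue keys).
    """
    def collect(s: Structure) -> dict:
        table = {}
        for c in s.chains:
            for r in c.residues:
                if domain is not None and not domain.contains(c.chain_id, r.seq_num):
                    continue
                for a in r.atoms:
                    if a.is_hydrogen:
                        continue
                    if atom_names is None:
                        use = a.name in BACKBONE_ATOMS.get(r.mol_class, ())
                        if r.mol_class in ("ion", "water", "other"):
                            use = True
                    else:
                        use = a.name in atom_names
                    if use:
                        table[(c.chain_id, r.seq_num, r.icode, a.name)] = a
        return table

    ref_table = collect(reference)
    mob_table = collect(mobile)
    keys = [k for k in ref_table if k in mob_table]
    unmatched = sorted(set(ref_table) ^ set(mob_table))
    ref_pts = np.array([ref_table[k].coords for k in keys]) if keys else np.zeros((0, 3))
    mob_pts = np.array([mob_table[k].coords for k in keys]) if keys else np.zeros((0, 3))
    return ref_pts, mob_pts, keys, unmatched


def align_by_domain(mobile: Structure, reference: Structure,
                    domain: DomainSpec | None = None,
                    atom_subset: tuple[str, ...] | None = None) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` using atoms of one domain.

    Atoms are paired by (chain_id, seq_num, icode, atom_name); residues
    present in only one structure are skipped (their count is logged).  The
    default subset is CA for protein residues and P for nucleic residues —
    robust to side-chain differences between templates.  The returned
    transform maps mobile coordinates into the reference frame.
    """
    if domain is not None:
        missing = [cid for cid in domain.chain_ids() if not mobile.has_chain(cid)]
        if missing:
            raise GeometryError(
                f"domain {domain.label}: chain(s) {missing} absent from mobile structure")
    ref_pts, mob_pts, keys, unmatched = _match_atoms(mobile, reference, domain, atom_subset)
    if unmatched:
        logger.info("align_by_domain: %d unmatched atom keys skipped", len(unmatched))
    if len(keys) < 3:
        label = domain.label if domain is not None else "<all>"
        raise GeometryError(
            f"domain {label}: only {len(keys)} matched atom pairs (need >= 3); "
            f"first unmatched: {unmatched[:5]}")
    result = kabsch(ref_pts, mob_pts)
    result.pairing = keys
    return result


def rmsd_between(a: Structure, b: Structure,
                 domain: DomainSpec | None = None,
                 atom_subset: tuple[str, ...] | None = None,
                 fit: bool = False) -> float:
    """RMSD between matched atoms of two structures, in angstrom.

    By default measures in the current frames (no refitting); ``fit=True``
    superposes first and returns the minimized RMSD.  Pairing follows the
    same (chain, seq, icode, atom name) rule as :func:`align_by_domain`, but
    any number >= 1 of pairs is accepted.
    """
    ref_pts, mob_pts, keys, _ = _match_atoms(b, a, domain, atom_subset)
    if len(keys) == 0:
        raise PairingError("no atom pairs matched between the two structures")
    if fit:
        if len(keys) < 3:
            raise GeometryError("fit=True needs >= 3 matched pairs")
        return kabsch(ref_pts, mob_pts).rmsd
    return float(np.sqrt(np.mean(np.sum((ref_pts - mob_pts) ** 2, axis=1))))


def rmsd_all_atom(a: Structure, b: Structure, fit: bool = False) -> float:
    """All-heavy-atom RMSD with name-based pairing across the whole structure."""
    def collect(s):
        return {(c.chain_id, r.seq_num, r.icode, at.name): at.coords
                for c, r, at in s.iter_atoms() if not at.is_hydrogen}
    ta, tb = collect(a), collect(b)
    keys = [k for k in ta if k in tb]
    if not keys:
        raise PairingError("no atom pairs matched between the two structures")
    A = np.array([ta[k] for k in keys])
    B = np.array([tb[k] for k in keys])
    if fit:
        return kabsch(B, A).rmsd
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
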