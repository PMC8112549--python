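"""Scissile-phosphate location and general-base candidate screening.

In the two-metal (RuvC-type) mechanism the non-target strand (NTS) is cut at
the phosphodiester linkage between nucleotide positions -3 and -4, counted
-1, -2, ... moving 5'-ward from the PAM-proximal nucleotide (blunt cleavage
3 bp from the PAM).  A general (Lewis) base — a histidine imidazole — must
sit close enough to the scissile phosphorus to activate a water nucleophile:
the screen evaluates every His by (i) its CA-to-P distance against a
reference distance of 7.8 A (the known one-metal general base geometry) and
(ii) whether its Nd1 lone pair points toward the phosphorus.  The in-line
check measures the nucleophile-P-leaving-group angle, ideally 180 degrees
for phosphoryl transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mgforge.errors import GeometryError, SiteError
from mgforge.metalgeom import AtomRef
from mgforge.structio import Structure

#: CA-to-scissile-P distance of the canonical one-metal general base, angstrom
REFERENCE_CA_P_DISTANCE = 7.8
DEFAULT_SCREEN_RADIUS = 10.0      # A; admits candidates near 9.6 A with margin
DEFAULT_ORIENTATION_THRESHOLD = 60.0  # deg; "points toward" tolerance


@dataclass
class ScissileSite:
    """The cleaved backbone linkage on one strand.

    The P atom belongs to the 3'-side nucleotide (position -3); O3' of the
    5'-side nucleotide (position -4) is the leaving group; pro_rp is the
    attack-facing non-bridging oxygen.
    """

    strand_chain_id: str
    position_3p: int        # seq_num of the -3 nucleotide (owns the P)
    position_5p: int        # seq_num of the -4 nucleotide (donates O3')
    p_atom: AtomRef
    pro_rp: AtomRef
    o5_prime: AtomRef
    o3_prime: AtomRef


@dataclass
class BaseCandidate:
    chain_id: str
    seq_num: int
    res_name: str
    d_ca_p: float
    orientation_angle: float
    passes: bool


@dataclass
class ScreenReport:
    site: ScissileSite
    reference_distance: float
    radius: float
    orientation_threshold: float
    candidates: list[BaseCandidate] = field(default_factory=list)

    def passing(self) -> list[BaseCandidate]:
        return [c for c in self.candidates if c.passes]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _pro_rp_name(p: np.ndarray, o5: np.ndarray, o3: np.ndarray,
                 op1: np.ndarray | None, op2: np.ndarray | None) -> str:
    """Pick the pro-Rp non-bridging oxygen geometrically.

    Convention: looking along the O5'->O3' bridging axis, pro-Rp is the
    non-bridging oxygen on the side where (O5'-P) x (O3'-P) points, i.e.
    det[O5'-P, O3'-P, OP-P] > 0.  Computed from coordinates rather than
    trusting OP1/OP2 naming, which deposition software does not guarantee.
    """
    if op1 is None and op2 is None:
        raise SiteError("scissile phosphate has no non-bridging oxygens (OP1/OP2)")
    normal = np.cross(o5 - p, o3 - p)
    best_name, best_dot = None, -np.inf
    for name, xyz in (("OP1", op1), ("OP2", op2)):
        if xyz is None:
            continue
        d = float(np.dot(normal, xyz - p))
        if d > best_dot:
            best_name, best_dot = name, d
    return best_name


def locate_scissile_phosphate(structure: Structure, strand_chain_id: str,
                              pam_position: int | None = None,
                              explicit_positions: tuple[int, int] | None = None,
                              ) -> ScissileSite:
    """Locate the cleaved linkage on a strand.

    Either ``pam_position`` (author seq number of the PAM-proximal
    nucleotide; the cut is then between offsets -3 and -4 moving 5'-ward
    along the chain) or ``explicit_positions`` = (seq of the 5'-side
    nucleotide, seq of the 3'-side nucleotide) must be given.
    """
    chain = structure.chain(strand_chain_id)
    nucs = [r for r in chain.residues if r.mol_class == "nucleic"]
    if len(nucs) < 5:
        raise SiteError(
            f"strand {strand_chain_id} has {len(nucs)} nucleotides; need >= 5")
    if explicit_positions is not None:
        seq5, seq3 = explicit_positions
        try:
            res5 = next(r for r in nucs if r.seq_num == seq5)
            res3 = next(r for r in nucs if r.seq_num == seq3)
        except StopIteration:
            raise SiteError(
                f"positions {explicit_positions} absent on strand {strand_chain_id}")
    elif pam_position is not None:
        idx = next((i for i, r in enumerate(nucs) if r.seq_num == pam_position), None)
        if idx is None:
            raise SiteError(f"PAM-proximal position {pam_position} absent on "
                            f"strand {strand_chain_id}")
        # -1 is the PAM-proximal nucleotide itself; -k = idx - (k-1)
        i3, i5 = idx - 2, idx - 3
        if i5 < 0:
            raise SiteError("strand too short 5'-ward of the PAM for a -3/-4 cut")
        res3, res5 = nucs[i3], nucs[i5]
    else:
        raise SiteError("either pam_position or explicit_positions is required")

    for name in ("P", "O5'"):
        if not res3.has_atom(name):
            raise SiteError(f"nucleotide {strand_chain_id}:{res3.seq_num} lacks {name}")
    if not res5.has_atom("O3'"):
        raise SiteError(f"nucleotide {strand_chain_id}:{res5.seq_num} lacks O3'")

    p = res3.atom("P").coords
    o5 = res3.atom("O5'").coords
    o3 = res5.atom("O3'").coords
    op1 = res3.atom("OP1").coords if res3.has_atom("OP1") else None
    op2 = res3.atom("OP2").coords if res3.has_atom("OP2") else None
    rp_name = _pro_rp_name(p, o5, o3, op1, op2)
    return ScissileSite(
        strand_chain_id=strand_chain_id,
        position_3p=res3.seq_num,
        position_5p=res5.seq_num,
        p_atom=AtomRef(strand_chain_id, res3.seq_num, "P", res3.icode),
        pro_rp=AtomRef(strand_chain_id, res3.seq_num, rp_name, res3.icode),
        o5_prime=AtomRef(strand_chain_id, res3.seq_num, "O5'", res3.icode),
        o3_prime=AtomRef(strand_chain_id, res5.seq_num, "O3'", res5.icode),
    )


def screen_general_bases(structure: Structure, site: ScissileSite,
                         radius: float = DEFAULT_SCREEN_RADIUS,
                         orientation_threshold: float = DEFAULT_ORIENTATION_THRESHOLD,
                         reference_distance: float = REFERENCE_CA_P_DISTANCE,
                         ) -> ScreenReport:
    """Evaluate every His near the scissile phosphorus as a general base.

    A candidate passes iff its CA is within ``radius`` of the P atom and the
    angle between the Cg->Nd1 bond direction and the Nd1->P direction is at
    most ``orientation_threshold`` (imidazole pointing at the phosphorus).
    Candidates are ranked by CA-P distance, ties broken by residue number.
    """
    p = site.p_atom.resolve(structure).coords
    report = ScreenReport(site=site, reference_distance=reference_distance,
                          radius=radius, orientation_threshold=orientation_threshold)
    for c in structure.chains:
        for r in c.residues:
            if r.res_name.upper() != "HIS" or not r.has_atom("CA"):
                continue
            d = float(np.linalg.norm(r.atom("CA").coords - p))
            if d > radius:
                continue
            if r.has_atom("ND1") and r.has_atom("CG"):
                nd1 = r.atom("ND1").coords
                angle = _angle_deg(nd1 - r.atom("CG").coords, p - nd1)
            else:
                angle = 180.0  # cannot orient without the imidazole
            report.candidates.append(BaseCandidate(
                chain_id=c.chain_id, seq_num=r.seq_num, res_name=r.res_name,
                d_ca_p=d, orientation_angle=angle,
                passes=(d <= radius and angle <= orientation_threshold)))
    report.candidates.sort(key=lambda cand: (cand.d_ca_p, cand.seq_num))
    return report


@dataclass
class InlineGeometry:
    nucleophile_p_distance: float
    inline_angle: float            # nucleophile-P-O3'(leaving), degrees
    deviation_from_inline: float   # |180 - inline_angle|


def inline_attack_geometry(structure: Structure, site: ScissileSite,
                           nucleophile: AtomRef) -> InlineGeometry:
    """In-line attack geometry for a candidate water nucleophile.

    Ideal phosphoryl transfer places nucleophile, phosphorus and the O3'
    leaving group on a line (angle 180 at P).
    """
    try:
        nuc = nucleophile.resolve(structure).coords
        p = site.p_atom.resolve(structure).coords
        leaving = site.o3_prime.resolve(structure).coords
    except Exception as exc:
        raise GeometryError(f"in-line geometry atoms unresolvable: {exc}") from exc
    angle = _angle_deg(nuc - p, leaving - p)
    return InlineGeometry(
        nucleophile_p_distance=float(np.linalg.norm(nuc - p)),
        inline_angle=angle,
        deviation_from_inline=abs(180.0 - angle),
    )
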