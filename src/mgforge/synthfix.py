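"""Synthetic fixtures: metal sites, template triplets, duplexes.

Every fixture is a geometric scaffold built from standard residue and atom
nomenclature (ASP/ASN/GLU/HIS side-chain donors, HOH waters, DT/DC
nucleotides, MG ions) so that downstream code paths treat synthetic and
experimental structures identically.  Mimic residues are chemically
minimal: only the atoms needed for ligation, screening and stub geometry
are present.

Design values mirror the catalytic architecture of one- and two-metal
nuclease sites: octahedral Mg2+ coordination at 2.0 A, a two-metal site
with the ions 3.3 A apart sharing the scissile pro-Rp oxygen and bridged by
two carboxylates, candidate general-base histidines with CA 7.3 and 9.6 A
from the scissile phosphorus (and the one-metal general base at 7.8 A), a
scissile linkage between strand positions -3 and -4 from the PAM-proximal
nucleotide.  All planted quantities are recorded in the fixture manifest so
oracle tests never re-derive them from the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mgforge.metalgeom import CatalyticResidue, MetalSiteDefinition
from mgforge.structio import Atom, Chain, Residue, Structure

# Frozen two-metal geometry (see docs/methods.md for the derivation):
TWO_METAL_SEPARATION = 3.3   # A, designed Mg-Mg distance
LIGAND_DISTANCE = 2.0        # A, designed metal-donor distance
SHELL_PHASE_A = np.radians(60.0)  # equatorial phase of ion A's shell
SHELL_PHASE_B = np.radians(61.0)  # equatorial phase of ion B's shell
HIS_CA_DISTANCES = (7.3, 9.6)     # A, candidate general bases (982/985 mimics)
HNH_BASE_CA_DISTANCE = 7.8        # A, one-metal general base (840 mimic)


@dataclass
class FixtureManifest:
    """Ground truth for a generated fixture, sufficient for oracle tests."""

    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, set):
                return sorted(o)
            return str(o)
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "parameters": self.parameters,
             "ground_truth": self.ground_truth, "files": self.files},
            indent=2, default=default, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _res(chain: Chain, seq: int, name: str, atoms: list[tuple[str, str, np.ndarray]]) -> Residue:
    r = Residue(seq, name, [Atom(n, el, xyz) for n, el, xyz in atoms])
    chain.residues.append(r)
    return r


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# One-metal (HNH-like) octahedral site
# ---------------------------------------------------------------------------

def make_octahedral_site(d0: float = LIGAND_DISTANCE, sigma: float = 0.0,
                         seed: int = 0) -> tuple[Structure, FixtureManifest]:
    """One Mg2+ with six O donors at octahedral vertices at ``d0`` angstrom.

    Ligands: Asp839 Od1, Asn863 Od1, two waters, and one non-bridging
    phosphate oxygen from each of two consecutive nucleotides of a 5-nt
    strand (the scissile phosphate and its 3' neighbor).  A His840 mimic
    sits in the second shell with CA 7.8 A from the scissile P, imidazole
    pointing at it.  ``sigma`` adds seeded Gaussian noise to the six ligand
    atoms only.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    rng = np.random.default_rng(seed)
    s = d0 / LIGAND_DISTANCE  # all designed lengths scale with d0

    vertices = {
        "+x": np.array([d0, 0.0, 0.0]),   # OP1 of DT3 (scissile pro-Rp)
        "-x": np.array([-d0, 0.0, 0.0]),  # water 1
        "+y": np.array([0.0, d0, 0.0]),   # OD1 of ASP 839
        "-y": np.array([0.0, -d0, 0.0]),  # OP1 of DT4
        "+z": np.array([0.0, 0.0, d0]),   # OD1 of ASN 863
        "-z": np.array([0.0, 0.0, -d0]),  # water 2
    }
    noise = {k: rng.normal(0.0, sigma, 3) if sigma > 0 else np.zeros(3)
             for k in vertices}
    lig = {k: vertices[k] + noise[k] for k in vertices}

    st = Structure(id=f"octahedral-site-seed{seed}")
    prot = Chain("A")
    st.chains.append(prot)

    od1 = lig["+y"]
    _res(prot, 839, "ASP", [
        ("OD1", "O", od1),
        ("CG", "C", od1 + np.array([0, 1.3, 0]) * s),
        ("OD2", "O", od1 + np.array([1.1, 1.9, 0]) * s),
        ("CB", "C", od1 + np.array([0, 2.8, 0]) * s),
        ("CA", "C", od1 + np.array([0, 4.3, 0]) * s),
    ])
    # His840 mimic: second shell, imidazole pointing at the scissile P
    p3 = np.array([d0 + 1.48, 0.0, 0.0])
    u840 = _unit([0.2, 0.55, 0.81])
    ca840 = p3 + HNH_BASE_CA_DISTANCE * u840
    _res(prot, 840, "HIS", [
        ("CA", "C", ca840),
        ("CB", "C", ca840 - 1.5 * u840),
        ("CG", "C", ca840 - 3.0 * u840),
        ("ND1", "N", ca840 - 4.38 * u840),
    ])
    od1n = lig["+z"]
    _res(prot, 863, "ASN", [
        ("OD1", "O", od1n),
        ("CG", "C", od1n + np.array([0, 0, 1.3]) * s),
        ("ND2", "N", od1n + np.array([1.1, 0, 1.9]) * s),
        ("CB", "C", od1n + np.array([0, 0, 2.8]) * s),
        ("CA", "C", od1n + np.array([0, 0, 4.3]) * s),
    ])

    # 5-nt target strand, 5'->3' seq 1..5; PAM-proximal is seq 5, so the
    # scissile linkage (-3/-4) is P of seq 3 bridging to O3' of seq 2.
    nuc = Chain("T")
    st.chains.append(nuc)
    p4 = np.array([0.0, -(d0 + 1.48), 0.0])
    _res(nuc, 1, "DT", [
        ("P", "P", np.array([8.2, -2.2, -3.6])),
        ("O5'", "O", np.array([7.4, -1.9, -3.1])),
        ("O3'", "O", np.array([8.9, -2.6, -4.2])),
    ])
    _res(nuc, 2, "DT", [
        ("O3'", "O", p3 + 1.6 * np.array([0.33, -0.47, -0.82])),
        ("C3'", "C", p3 + 3.0 * np.array([0.33, -0.47, -0.82])),
    ])
    _res(nuc, 3, "DT", [
        ("P", "P", p3),
        ("OP1", "O", lig["+x"]),
        ("OP2", "O", p3 + 1.48 * np.array([0.33, 0.94, 0.0])),
        ("O5'", "O", p3 + 1.6 * np.array([0.33, -0.47, 0.82])),
        ("O3'", "O", p4 + 1.6 * np.array([0.47, -0.33, -0.82])),
    ])
    _res(nuc, 4, "DT", [
        ("P", "P", p4),
        ("OP1", "O", lig["-y"]),
        ("OP2", "O", p4 + 1.48 * np.array([-0.94, -0.33, 0.0])),
        ("O5'", "O", p4 + 1.6 * np.array([0.47, -0.33, 0.82])),
    ])
    _res(nuc, 5, "DT", [
        ("P", "P", np.array([2.0, -6.0, 1.0])),
        ("O5'", "O", np.array([2.5, -6.3, 1.5])),
        ("O3'", "O", np.array([1.5, -5.5, 0.5])),
    ])

    wat = Chain("W")
    st.chains.append(wat)
    _res(wat, 1, "HOH", [("O", "O", lig["-x"])])
    _res(wat, 2, "HOH", [("O", "O", lig["-z"])])

    ion = Chain("M")
    st.chains.append(ion)
    _res(ion, 1, "MG", [("MG", "MG", np.zeros(3))])
    st.renumber_serials()

    site = MetalSiteDefinition(
        site_name="HNH_one_metal",
        ions=[("A", "MG", ("M", 1))],
        catalytic_residues=[
            CatalyticResidue("A", 839, ("OD1", "OD2")),
            CatalyticResidue("A", 863, ("OD1",)),
        ],
    )
    manifest = FixtureManifest(
        kind="octahedral_site", seed=seed,
        parameters={"d0": d0, "sigma": sigma},
        ground_truth={
            "ion": ["M", 1, "MG"],
            "ligands": {
                "ASP839:OD1": lig["+y"].tolist(),
                "ASN863:OD1": lig["+z"].tolist(),
                "DT3:OP1": lig["+x"].tolist(),
                "DT4:OP1": lig["-y"].tolist(),
                "HOH1:O": lig["-x"].tolist(),
                "HOH2:O": lig["-z"].tolist(),
            },
            "designed_distance": d0,
            "ligand_distances": {k: float(np.linalg.norm(v)) for k, v in lig.items()},
            "first_shell": [["A", 839], ["A", 863]],
            "second_shell_his": ["A", 840],
            "his840_ca_p": HNH_BASE_CA_DISTANCE,
            "scissile": {"chain": "T", "pam_position": 5,
                         "position_3p": 3, "position_5p": 2},
            "n_atoms": st.n_atoms,
        },
    )
    return st, manifest


def octahedral_site_definition() -> MetalSiteDefinition:
    """Site definition matching :func:`make_octahedral_site`."""
    return MetalSiteDefinition(
        site_name="HNH_one_metal",
        ions=[("A", "MG", ("M", 1))],
        catalytic_residues=[
            CatalyticResidue("A", 839, ("OD1", "OD2")),
            CatalyticResidue("A", 863, ("OD1",)),
        ],
    )


# ---------------------------------------------------------------------------
# Two-metal (RuvC-like) site
# ---------------------------------------------------------------------------

def _octa_equatorial(center: np.ndarray, axis: np.ndarray, phase: float,
                     radius: float) -> list[np.ndarray]:
    """Four equatorial vertices of an octahedron with one axis along ``axis``."""
    a = _unit(axis)
    u = _unit([-a[1], a[0], 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return [center + radius * (np.cos(phase + k * np.pi / 2) * u +
                               np.sin(phase + k * np.pi / 2) * v)
            for k in range(4)]


def make_two_metal_site(seed: int = 0, d_sep: float = TWO_METAL_SEPARATION,
                        d0: float = LIGAND_DISTANCE, sigma: float = 0.0,
                        his_ca_distances: tuple[float, float] = HIS_CA_DISTANCES,
                        ) -> tuple[Structure, FixtureManifest]:
    """Two Mg2+ ions ``d_sep`` apart with full shared-ligand octahedral shells.

    Architecture: the scissile pro-Rp oxygen bridges both ions (a vertex of
    both shells); the D10 and E762 carboxylate mimics each bridge with one
    oxygen per ion; H983's Nd1 coordinates ion A; D986 coordinates ion B;
    two waters complete each shell.  H982/H985 mimics sit off the site with
    CA at the configured distances from the scissile P, imidazoles pointing
    at it.  The designed geometry satisfies every default coordination
    restraint exactly, so the inter-ion spacing is an emergent property of
    the bridging-ligand network, not of any ion-ion term.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros(3)
    B = np.array([d_sep, 0.0, 0.0])
    rho = np.sqrt(d0 ** 2 - d_sep ** 2 / 4.0)
    pro_rp = np.array([d_sep / 2.0, rho, 0.0])  # 2.0 A from both ions

    # shell vertices (index 0 = anti-bridge axial vertex, 1..4 equatorial)
    va = [A - 2.0 * _unit(pro_rp - A)] + _octa_equatorial(A, pro_rp - A, SHELL_PHASE_A, d0)
    vb = [B - 2.0 * _unit(pro_rp - B)] + _octa_equatorial(B, pro_rp - B, SHELL_PHASE_B, d0)

    # the two closest disjoint cross-shell vertex pairs become the D10 and
    # E762 bridging carboxylates (same-residue pairs, bite ~2.0 A)
    cross = sorted((float(np.linalg.norm(p - q)), i, j)
                   for i, p in enumerate(va) for j, q in enumerate(vb))
    used_i: set[int] = set()
    used_j: set[int] = set()
    bridges: list[tuple[int, int]] = []
    for _, i, j in cross:
        if len(bridges) == 2:
            break
        if i not in used_i and j not in used_j:
            bridges.append((i, j))
            used_i.add(i)
            used_j.add(j)
    (d10_a, d10_b), (e762_a, e762_b) = bridges
    rest_a = [i for i in range(5) if i not in used_i]
    rest_b = [j for j in range(5) if j not in used_j]
    # H983's Nd1 takes the free A vertex with the largest y (so the imidazole
    # points past the phosphate, failing the general-base orientation screen,
    # as a metal-coordinating His should); waters take the rest.
    nd1_a = max(rest_a, key=lambda i: va[i][1])
    water_a = [i for i in rest_a if i != nd1_a]
    d986_b = min(rest_b, key=lambda j: vb[j][1])
    water_b = [j for j in rest_b if j != d986_b]

    noise = (lambda: rng.normal(0.0, sigma, 3)) if sigma > 0 else (lambda: np.zeros(3))
    center = (A + B) / 2.0

    st = Structure(id=f"two-metal-site-seed{seed}")
    prot = Chain("A")
    st.chains.append(prot)

    od1, od2 = va[d10_a] + noise(), vb[d10_b] + noise()
    mid = (od1 + od2) / 2.0
    w = _unit(mid - center)
    _res(prot, 10, "ASP", [
        ("OD1", "O", od1), ("OD2", "O", od2),
        ("CG", "C", mid + 1.2 * w), ("CB", "C", mid + 2.7 * w),
        ("CA", "C", mid + 4.2 * w),
    ])
    oe1, oe2 = va[e762_a] + noise(), vb[e762_b] + noise()
    mid = (oe1 + oe2) / 2.0
    w = _unit(mid - center)
    _res(prot, 762, "GLU", [
        ("OE1", "O", oe1), ("OE2", "O", oe2),
        ("CD", "C", mid + 1.2 * w), ("CG", "C", mid + 2.7 * w),
        ("CB", "C", mid + 4.2 * w), ("CA", "C", mid + 5.7 * w),
    ])

    # scissile phosphate: P bonded to the bridging pro-Rp oxygen, the rest of
    # the group fanning away from the site (+y)
    p = pro_rp + np.array([0.0, 1.48, 0.0])
    o5p = p + 1.6 * np.array([0.0, 0.47, -0.88])
    o3p = p + 1.6 * np.array([0.60, 0.47, 0.65])   # O3' of the -4 nucleotide
    op2 = p + 1.48 * np.array([-0.55, 0.72, 0.42])

    # general-base candidate mimics, imidazole chain collinear with CA->P
    u982 = _unit([0.0, -0.2, 0.98])
    u985 = _unit([0.0, 0.37, -0.93])
    d982, d985 = his_ca_distances
    ca982 = p + d982 * u982
    ca985 = p + d985 * u985
    _res(prot, 982, "HIS", [
        ("CA", "C", ca982), ("CB", "C", ca982 - 1.5 * u982),
        ("CG", "C", ca982 - 3.0 * u982), ("ND1", "N", ca982 - 4.38 * u982),
    ])
    nd1 = va[nd1_a] + noise()
    w = _unit(nd1 - A)
    _res(prot, 983, "HIS", [
        ("ND1", "N", nd1), ("CG", "C", nd1 + 1.38 * w),
        ("CB", "C", nd1 + 2.88 * w), ("CA", "C", nd1 + 4.38 * w),
    ])
    _res(prot, 985, "HIS", [
        ("CA", "C", ca985), ("CB", "C", ca985 - 1.5 * u985),
        ("CG", "C", ca985 - 3.0 * u985), ("ND1", "N", ca985 - 4.38 * u985),
    ])
    od1_986 = vb[d986_b] + noise()
    w = _unit(od1_986 - B)
    _res(prot, 986, "ASP", [
        ("OD1", "O", od1_986), ("CG", "C", od1_986 + 1.3 * w),
        ("OD2", "O", od1_986 + 2.55 * w), ("CB", "C", od1_986 + 1.3 * w + 1.5 * _unit([w[1], -w[0] if abs(w[0]) > 1e-9 else 1.0, 0.3])),
        ("CA", "C", od1_986 + 4.3 * w),
    ])

    # non-target strand, 5'->3' seq 1..5; PAM-proximal seq 5 => cut between
    # seq 3 (-3, owns the scissile P) and seq 2 (-4, donates O3')
    nuc = Chain("C")
    st.chains.append(nuc)
    _res(nuc, 1, "DC", [
        ("P", "P", np.array([6.2, 5.0, 2.0])),
        ("O5'", "O", np.array([5.8, 4.8, 1.8])),
        ("O3'", "O", np.array([6.6, 5.3, 2.3])),
    ])
    _res(nuc, 2, "DC", [
        ("P", "P", np.array([5.0, 4.5, 1.5])),
        ("O5'", "O", np.array([4.5, 4.2, 1.2])),
        ("O3'", "O", o3p),
        ("C3'", "C", o3p + 1.4 * np.array([0.60, 0.47, 0.65])),
    ])
    _res(nuc, 3, "DC", [
        ("P", "P", p),
        ("OP1", "O", pro_rp + noise()),
        ("OP2", "O", op2),
        ("O5'", "O", o5p),
    ])
    _res(nuc, 4, "DC", [
        ("P", "P", np.array([0.2, 6.6, -2.6])),
        ("O5'", "O", np.array([-0.2, 6.9, -2.2])),
        ("O3'", "O", np.array([0.6, 6.3, -3.1])),
    ])
    _res(nuc, 5, "DC", [
        ("P", "P", np.array([-1.2, 7.4, -2.8])),
        ("O5'", "O", np.array([-1.6, 7.7, -2.4])),
        ("O3'", "O", np.array([-0.8, 7.1, -3.3])),
    ])

    wat = Chain("W")
    st.chains.append(wat)
    water_positions = [va[i] + noise() for i in water_a] + [vb[j] + noise() for j in water_b]
    for k, pos in enumerate(water_positions, start=1):
        _res(wat, k, "HOH", [("O", "O", pos)])

    ion = Chain("M")
    st.chains.append(ion)
    _res(ion, 1, "MG", [("MG", "MG", A)])
    _res(ion, 2, "MG", [("MG", "MG", B)])
    st.renumber_serials()

    manifest = FixtureManifest(
        kind="two_metal_site", seed=seed,
        parameters={"d_sep": d_sep, "d0": d0, "sigma": sigma,
                    "his_ca_distances": list(his_ca_distances)},
        ground_truth={
            "ions": {"A": ["M", 1], "B": ["M", 2]},
            "designed_separation": d_sep,
            "designed_distance": d0,
            "bridging_pro_rp": pro_rp.tolist(),
            "shell_A": ["DC3:OP1", "ASP10:OD1", "GLU762:OE1", "HIS983:ND1",
                        "HOH:O", "HOH:O"],
            "shell_B": ["DC3:OP1", "ASP10:OD2", "GLU762:OE2", "ASP986:OD1",
                        "HOH:O", "HOH:O"],
            "first_shell": [["A", 10], ["A", 762], ["A", 983], ["A", 986]],
            "his_ca_p": {"982": d982, "985": d985,
                         "983": float(np.linalg.norm(nd1 + 4.38 * _unit(nd1 - A) - p))},
            "scissile": {"chain": "C", "pam_position": 5,
                         "position_3p": 3, "position_5p": 2},
            "n_atoms": st.n_atoms,
        },
    )
    return st, manifest


def two_metal_site_definition() -> MetalSiteDefinition:
    """Site definition matching :func:`make_two_metal_site`."""
    return MetalSiteDefinition(
        site_name="RuvC_two_metal",
        ions=[("A", "MG", ("M", 1)), ("B", "MG", ("M", 2))],
        catalytic_residues=[
            CatalyticResidue("A", 10, ("OD1", "OD2")),
            CatalyticResidue("A", 762, ("OE1", "OE2")),
            CatalyticResidue("A", 983, ("ND1",)),
            CatalyticResidue("A", 986, ("OD1", "OD2")),
        ],
    )


# ---------------------------------------------------------------------------
# Idealized duplex
# ---------------------------------------------------------------------------

RISE = 3.38          # A per base step
TWIST = np.radians(36.0)
P_RADIUS = 8.9       # A, backbone phosphorus radius
STRAND2_PHASE = np.radians(154.0)


def _strand(chain_id: str, length: int, phase: float, reverse: bool,
            res_name: str) -> Chain:
    chain = Chain(chain_id)
    order = range(length)
    for k in order:
        i = (length - 1 - k) if reverse else k
        theta = i * TWIST + phase
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        sgn = -1.0 if reverse else 1.0
        z = i * RISE
        p = P_RADIUS * u + np.array([0, 0, z])
        o5 = p + (-0.853 * u + 0.96 * sgn * t + 0.96 * sgn * np.array([0, 0, 1]))
        c1 = 5.9 * u + np.array([0, 0, z + 0.5])
        atoms = []
        if k > 0:
            # phosphate of the linkage to the previous residue in chain order
            prev_i = i + 1 if reverse else i - 1
            ptheta = i * TWIST + phase
            atoms.append(("P", "P", p))
            a = _unit(o5 - p)
            sugar_prev = 7.0 * np.array([np.cos(prev_i * TWIST + phase),
                                         np.sin(prev_i * TWIST + phase), 0.0]) \
                + np.array([0, 0, prev_i * RISE + 1.2])
            b = _unit(sugar_prev - p)
            bis = -_unit(a + b)
            n = _unit(np.cross(a, b))
            atoms.append(("OP1", "O", p + 1.48 * _unit(bis + 0.85 * n)))
            atoms.append(("OP2", "O", p + 1.48 * _unit(bis - 0.85 * n)))
        atoms.append(("O5'", "O", o5))
        atoms.append(("C1'", "C", c1))
        # O3' points toward the next residue's phosphate position
        next_i = i - 1 if reverse else i + 1
        if 0 <= next_i < length and not (reverse and k == length - 1) and not (not reverse and k == length - 1):
            ntheta = next_i * TWIST + phase
            pnext = P_RADIUS * np.array([np.cos(ntheta), np.sin(ntheta), 0.0]) \
                + np.array([0, 0, next_i * RISE])
            sugar = 7.0 * u + np.array([0, 0, z + 1.2])
            atoms.append(("O3'", "O", pnext + 1.6 * _unit(sugar - pnext)))
        else:
            atoms.append(("O3'", "O", 8.0 * u + np.array([0, 0, z + 1.5])))
        chain.residues.append(Residue(k + 1, res_name,
                                      [Atom(nm, el, xyz) for nm, el, xyz in atoms]))
    return chain


def make_duplex(length: int = 10, pam: str = "TGG", seed: int = 0,
                ) -> tuple[Structure, FixtureManifest]:
    """Idealized B-form-like duplex with standard backbone atom names.

    Strand D runs 5'->3' with seq 1..length; the PAM-proximal nucleotide is
    the 3'-terminal residue (seq = length), so the scissile linkage between
    positions -3 and -4 is the phosphate of residue ``length - 2``.  Strand
    E is the antiparallel complement scaffold.  Deterministic for a given
    spec; the seed participates only in the manifest identity.
    """
    if length < 5:
        raise ValueError(f"duplex length must be >= 5, got {length}")
    st = Structure(id=f"duplex-{length}bp-seed{seed}")
    st.chains.append(_strand("D", length, 0.0, reverse=False, res_name="DT"))
    st.chains.append(_strand("E", length, STRAND2_PHASE, reverse=True, res_name="DA"))
    st.renumber_serials()
    manifest = FixtureManifest(
        kind="duplex", seed=seed,
        parameters={"length": length, "pam": pam},
        ground_truth={
            "nts_chain": "D",
            "pam_position": length,
            "scissile_position_3p": length - 2,
            "scissile_position_5p": length - 3,
            "n_atoms": st.n_atoms,
        },
    )
    return st, manifest


# ---------------------------------------------------------------------------
# Toy ternary template triplet with planted transforms
# ---------------------------------------------------------------------------

TOY_DOMAINS = {
    "REC1": 101, "REC2": 201, "REC3": 301, "HNH": 401, "RuvC": 501, "PI": 601,
}
TOY_DOMAIN_LENGTH = 12


def _rotation(axis, angle_deg: float) -> np.ndarray:
    a = _unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _apply(st: Structure, R: np.ndarray, t: np.ndarray,
           only: set[str] | None = None) -> None:
    """Transform all atoms, or only residues of the named toy domains."""
    for c in st.chains:
        for r in c.residues:
            if only is not None:
                dom = next((d for d, s in TOY_DOMAINS.items()
                            if s <= r.seq_num < s + TOY_DOMAIN_LENGTH
                            and c.chain_id == "A"), None)
                if dom not in only:
                    continue
            for a in r.atoms:
                a.coords = R @ a.coords + t


def _reference_complex() -> Structure:
    duplex, _ = make_duplex(10)
    st = Structure(id="toy-reference")
    prot = Chain("A")
    st.chains.append(prot)
    for d, (label, start) in enumerate(sorted(TOY_DOMAINS.items(), key=lambda kv: kv[1])):
        ang = np.radians(60.0 * d)
        centre = np.array([26 * np.cos(ang), 26 * np.sin(ang), 12.0])
        for k in range(TOY_DOMAIN_LENGTH):
            hx = np.radians(100.0 * k)
            ca = centre + np.array([2.3 * np.cos(hx), 2.3 * np.sin(hx), 1.5 * k])
            cb = ca + 1.0 * _unit(ca - centre - np.array([0, 0, ca[2] - centre[2]]))
            prot.residues.append(Residue(start + k, "ALA", [
                Atom("CA", "C", ca), Atom("CB", "C", cb)]))
    st.chains.extend(c.copy() for c in duplex.chains)
    ions = Chain("M")
    st.chains.append(ions)
    ions.residues.append(Residue(1, "MG", [Atom("MG", "MG", np.array([13.0, 0.0, 16.0]))]))
    ions.residues.append(Residue(2, "MG", [Atom("MG", "MG", np.array([13.0, 3.0, 18.0]))]))
    st.renumber_serials()
    return st


def make_toy_ternary_templates(seed: int = 0) -> tuple[dict[str, Structure],
                                                       Structure, FixtureManifest]:
    """Three templates with planted rigid transforms plus the designed chimera.

    Template A carries the reference nucleic and ion coordinates.  Template B
    (globally moved by a planted transform) donates REC2 and RuvC; template C
    (another planted transform) donates REC1, REC3, HNH and PI.  The domains
    each template does *not* donate are hinged away so only the recipe's
    assembly reproduces the reference.  The manifest records the true
    transforms; registering a donor's duplex onto template A must recover
    the inverse of its planted transform.
    """
    reference = _reference_complex()

    tmpl_a = reference.copy()
    tmpl_a.id = "toy-template-A"

    RB = _rotation([0, 0, 1], 25.0)
    tB = np.array([5.0, -3.0, 4.0])
    tmpl_b = reference.copy()
    tmpl_b.id = "toy-template-B"
    hingeR = _rotation([0, 0, 1], 15.0)
    _apply(tmpl_b, hingeR, np.array([12.0, 6.0, 8.0]),
           only={"REC1", "REC3", "HNH", "PI"})
    _apply(tmpl_b, RB, tB)

    RC = _rotation([0, 1, 0], -40.0)
    tC = np.array([-6.0, 2.0, -3.0])
    tmpl_c = reference.copy()
    tmpl_c.id = "toy-template-C"
    _apply(tmpl_c, hingeR, np.array([-10.0, 9.0, 14.0]), only={"REC2", "RuvC"})
    _apply(tmpl_c, RC, tC)

    manifest = FixtureManifest(
        kind="toy_ternary_templates", seed=seed,
        parameters={"domains": TOY_DOMAINS, "domain_length": TOY_DOMAIN_LENGTH},
        ground_truth={
            "transform_B": [*RB.reshape(9).tolist(), *tB.tolist()],
            "transform_C": [*RC.reshape(9).tolist(), *tC.tolist()],
            "donors": {"B": ["REC2", "RuvC"], "C": ["REC1", "REC3", "HNH", "PI"]},
            "reference_atoms": reference.n_atoms,
            "duplex_chains": ["D", "E"],
        },
    )
    return {"A": tmpl_a, "B": tmpl_b, "C": tmpl_c}, reference, manifest


# ---------------------------------------------------------------------------
# Perturbation helper
# ---------------------------------------------------------------------------

def perturb_structure(structure: Structure, sigma: float, seed: int,
                      center: np.ndarray | None = None,
                      radius: float | None = None) -> Structure:
    """Add seeded Gaussian noise (sigma per axis, angstrom) to atom positions.

    With ``center``/``radius`` given, only atoms inside the sphere move —
    the same convention as the refiner's mobile selection.
    """
    rng = np.random.default_rng(seed)
    out = structure.copy()
    for _, _, a in out.iter_atoms():
        shift = rng.normal(0.0, sigma, 3)
        if center is not None and radius is not None:
            if np.linalg.norm(a.coords - center) > radius:
                continue
        a.coords = a.coords + shift
    return out
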