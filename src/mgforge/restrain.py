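"""Coordination restraints and restrained geometry refinement.

The refinement model is a deliberately small surrogate for restrained
molecular dynamics: a sum of harmonic terms that encode the one- and
two-metal coordination principles —

    E = sum k_d (d - d0)^2                    metal-ligand distances
      + sum k_a (theta - theta0)^2            ligand-metal-ligand angles
      + sum_{pairs, d < r_min} k_rep (r_min - d)^2   soft-sphere floor

with distance targets near 2.0 A for every Mg-O and Mg-N pair and angle
targets of 90 deg for the cis ligand pairs of each ion's best octahedral
vertex assignment.  There is deliberately *no* ion-ion term in two-metal
sites: the Mg-Mg spacing must emerge from the shared bridging-ligand
geometry, so the characteristic ~3 A separation is an output of refinement,
never an input.

The soft-sphere floor applies to heavy-atom pairs whose geometry is not
already governed by the restraint network (pairs in the same residue, in
covalently bonded neighbor residues, or where both atoms are restrained
members of the site are exempt).  At the tight inter-ion spacings of shared-
ligand two-metal sites, cross-shell donor contacts shorter than a generic
van der Waals floor are intrinsic to the architecture; the restraints, not
the floor, own that geometry.

Minimization is deterministic (quasi-Newton with line search guaranteeing
monotone non-increasing energy over accepted iterates); only atoms inside a
mobile sphere around the site move, mirroring coordination fixation of the
site within a rigid scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from mgforge.errors import AtomLookupError, PlacementError, RestraintError
from mgforge.metalgeom import (
    AtomRef,
    MetalSiteDefinition,
    _resolve_ions,
)
from mgforge.structio import Atom, Chain, Residue, Structure

DEFAULT_TARGET = 2.0        # A, metal-donor distance ("near 2.0 A")
DEFAULT_K_DISTANCE = 100.0  # energy / A^2
DEFAULT_K_ANGLE = 0.02      # energy / deg^2
DEFAULT_R_MIN = 2.4         # A, soft-sphere contact floor
DEFAULT_K_REP = 50.0        # energy / A^2
DEFAULT_MOBILE_RADIUS = 8.0  # A around the site center
LIGAND_INCLUSION_RADIUS = 3.5  # A; a named donor further than this is not a ligand
WATER_SEARCH_RADIUS = 4.5   # A; how far to look for coordinating waters

#: nucleic backbone oxygens eligible as phosphate/backbone ligands
BACKBONE_O_NAMES = ("OP1", "OP2", "O1P", "O2P", "O5'", "O3'")


@dataclass(frozen=True)
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    target: float = DEFAULT_TARGET
    force_constant: float = DEFAULT_K_DISTANCE

    def __post_init__(self) -> None:
        if self.target <= 0 or self.force_constant <= 0:
            raise ValueError("distance restraint needs positive target and force constant")


@dataclass(frozen=True)
class AngleRestraint:
    """Ligand-metal-ligand angle: atom_b is the vertex (the metal)."""

    atom_a: AtomRef
    atom_b: AtomRef
    atom_c: AtomRef
    target: float
    force_constant: float = DEFAULT_K_ANGLE

    def __post_init__(self) -> None:
        if not 0.0 < self.target <= 180.0:
            raise ValueError("angle target must lie in (0, 180] degrees")
        if self.force_constant <= 0:
            raise ValueError("angle force constant must be positive")


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    r_min: float = DEFAULT_R_MIN
    k_rep: float = DEFAULT_K_REP
    mobile: list[AtomRef] | None = None  # None -> every atom mobile

    def network_atoms(self) -> set[AtomRef]:
        """Atoms whose geometry the restraints govern (ions + ligands)."""
        out: set[AtomRef] = set()
        for r in self.distances:
            out.add(r.atom_a)
            out.add(r.atom_b)
        for a in self.angles:
            out.update((a.atom_a, a.atom_b, a.atom_c))
        return out


@dataclass
class RefinementResult:
    structure: Structure
    energy_trajectory: list[float]
    converged: bool
    n_iterations: int
    residuals: dict[str, float]  # per distance restraint: |observed - target|

    @property
    def final_energy(self) -> float:
        return self.energy_trajectory[-1]


# ---------------------------------------------------------------------------
# Octahedral vertex assignment (shared by restraint building and water placement)
# ---------------------------------------------------------------------------

_OCT = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)


def _fit_octahedron(directions: np.ndarray) -> tuple[tuple[int, ...], np.ndarray]:
    """Assign k <= 6 unit directions to octahedron vertices.

    Tries every injective assignment of directions to vertex slots; for each,
    the optimal rotation comes from an SVD (Wahba's problem with the
    reflection guard).  Returns (vertex index per direction, rotation matrix
    R such that R @ ideal_vertex approximates each direction).
    """
    k = len(directions)
    if not 1 <= k <= 6:
        raise ValueError("need 1..6 directions")
    best = (np.inf, None, None)
    for perm in permutations(range(6), k):
        V = _OCT[list(perm)]
        H = V.T @ directions
        U, _, Wt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Wt.T @ U.T))
        R = Wt.T @ np.diag([1.0, 1.0, d]) @ U.T
        resid = float(np.sum((directions - V @ R.T) ** 2))
        if resid < best[0]:
            best = (resid, perm, R)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Restraint construction
# ---------------------------------------------------------------------------

def _ligands_for_ions(structure: Structure, site: MetalSiteDefinition,
                      ions: list[tuple[str, AtomRef]],
                      ) -> dict[str, list[AtomRef]]:
    """Designate up to six ligand atoms per ion from the site definition.

    Catalytic-residue donor atoms and nucleic backbone oxygens within the
    inclusion radius attach to their nearest ion; a backbone oxygen within
    range of *both* ions of a two-metal site bridges them (it appears in both
    shells).  Remaining slots are filled with the nearest water oxygens.
    """
    ion_pos = {label: ref.resolve(structure).coords for label, ref in ions}
    shells: dict[str, list[AtomRef]] = {label: [] for label, _ in ions}

    def nearest_ion(coords: np.ndarray) -> tuple[str, float]:
        label = min(ion_pos, key=lambda l: np.linalg.norm(coords - ion_pos[l]))
        return label, float(np.linalg.norm(coords - ion_pos[label]))

    for cres in site.catalytic_residues:
        try:
            residue = structure.get_residue(cres.chain_id, cres.seq_num, cres.icode)
        except AtomLookupError as exc:
            raise RestraintError(
                f"site {site.site_name}: residue {cres.chain_id}:{cres.seq_num} "
                "not found") from exc
        present = [n for n in cres.ligand_atoms if residue.has_atom(n)]
        if not present:
            raise RestraintError(
                f"residue {residue.res_name} {cres.chain_id}:{cres.seq_num} has none "
                f"of the ligand atoms {cres.ligand_atoms} (mutated side chain?)")
        in_range = []
        for name in present:
            coords = residue.atom(name).coords
            label, dist = nearest_ion(coords)
            if dist <= LIGAND_INCLUSION_RADIUS:
                in_range.append((name, coords, label))
        if len(in_range) == 2 and len(ion_pos) == 2:
            # bridging carboxylate: one oxygen per ion, paired to minimize
            # total distance (robust to noise near the inter-ion midplane)
            labels = list(ion_pos)
            (n1, c1, _), (n2, c2, _) = in_range
            d = {(n, l): float(np.linalg.norm(c - ion_pos[l]))
                 for n, c in ((n1, c1), (n2, c2)) for l in labels}
            if d[(n1, labels[0])] + d[(n2, labels[1])] <= \
                    d[(n1, labels[1])] + d[(n2, labels[0])]:
                pairing = [(n1, labels[0]), (n2, labels[1])]
            else:
                pairing = [(n1, labels[1]), (n2, labels[0])]
            in_range = [(n, residue.atom(n).coords, l) for n, l in pairing]
        for name, _, label in in_range:
            shells[label].append(AtomRef(cres.chain_id, cres.seq_num, name, cres.icode))
        if len(in_range) == 0:
            raise RestraintError(
                f"residue {residue.res_name} {cres.chain_id}:{cres.seq_num}: no ligand "
                f"atom within {LIGAND_INCLUSION_RADIUS} A of a site ion")

    # nucleic backbone oxygens, closest-first per ion while the shell has
    # room; an oxygen in range of both ions bridges them (both shells)
    backbone: dict[str, list[tuple[float, AtomRef]]] = {l: [] for l in ion_pos}
    for c in structure.chains:
        for r in c.residues:
            if r.mol_class != "nucleic":
                continue
            for a in r.atoms:
                if a.name not in BACKBONE_O_NAMES:
                    continue
                ref = AtomRef(c.chain_id, r.seq_num, a.name, r.icode)
                for label, pos in ion_pos.items():
                    d = float(np.linalg.norm(a.coords - pos))
                    if d <= LIGAND_INCLUSION_RADIUS:
                        backbone[label].append((d, ref))
    for label in ion_pos:
        for _, ref in sorted(backbone[label], key=lambda t: (t[0], str(t[1]))):
            if len(shells[label]) < 6 and ref not in shells[label]:
                shells[label].append(ref)

    # waters fill the shell to six, nearest first
    waters: list[tuple[AtomRef, np.ndarray]] = []
    for c in structure.chains:
        for r in c.residues:
            if r.mol_class != "water":
                continue
            for a in r.atoms:
                if a.element.upper() == "O":
                    waters.append((AtomRef(c.chain_id, r.seq_num, a.name, r.icode),
                                   a.coords))
    claimed: set[AtomRef] = set()
    for label, _ in ions:
        need = 6 - len(shells[label])
        if need <= 0:
            continue
        pool = sorted(
            ((float(np.linalg.norm(w - ion_pos[label])), ref)
             for ref, w in waters
             if ref not in claimed and
             np.linalg.norm(w - ion_pos[label]) <= WATER_SEARCH_RADIUS),
            key=lambda t: (t[0], str(t[1])),
        )
        for _, ref in pool[:need]:
            shells[label].append(ref)
            claimed.add(ref)
    return shells


def build_restraints(structure: Structure, site: MetalSiteDefinition,
                     mechanism: str = "one_metal",
                     target: float = DEFAULT_TARGET,
                     k_distance: float = DEFAULT_K_DISTANCE,
                     k_angle: float = DEFAULT_K_ANGLE,
                     mobile_radius: float = DEFAULT_MOBILE_RADIUS) -> RestraintSet:
    """Build the default coordination restraint set for a metal site.

    One-metal sites get 6 distance restraints on the single ion; two-metal
    sites get 6 per ion (12 total) with bridging backbone oxygens shared
    between shells.  Every shell also gets angle restraints of 90 deg on the
    12 cis ligand pairs of its best octahedral vertex assignment.  There is
    no ion-ion restraint.
    """
    if mechanism not in ("one_metal", "two_metal"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    ions = _resolve_ions(structure, site)
    if mechanism == "one_metal" and len(ions) != 1:
        raise RestraintError(f"one_metal mechanism needs 1 ion, site has {len(ions)}")
    if mechanism == "two_metal" and len(ions) != 2:
        raise RestraintError(f"two_metal mechanism needs 2 ions, site has {len(ions)}")

    shells = _ligands_for_ions(structure, site, ions)
    rset = RestraintSet()
    for label, ion_ref in ions:
        ligands = shells[label]
        if len(ligands) != 6:
            raise RestraintError(
                f"ion {label}: {len(ligands)} ligands designated, need 6 "
                "(add waters or call place_waters first)")
        ion_pos = ion_ref.resolve(structure).coords
        for lig in ligands:
            rset.distances.append(DistanceRestraint(lig, ion_ref, target, k_distance))
        # cis pairs (90 deg) under the best octahedral assignment
        dirs = np.array([lig.resolve(structure).coords - ion_pos for lig in ligands])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        perm, _ = _fit_octahedron(dirs)
        for i in range(6):
            for j in range(i + 1, 6):
                trans = (perm[i] // 2 == perm[j] // 2)  # same octahedron axis
                if not trans:
                    rset.angles.append(AngleRestraint(
                        ligands[i], ion_ref, ligands[j], 90.0, k_angle))

    center = np.mean([ref.resolve(structure).coords for _, ref in ions], axis=0)
    mobile = []
    for c in structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if np.linalg.norm(a.coords - center) <= mobile_radius:
                    mobile.append(AtomRef(c.chain_id, r.seq_num, a.name, r.icode))
    rset.mobile = mobile
    return rset


# ---------------------------------------------------------------------------
# Energy and gradient
# ---------------------------------------------------------------------------

class _System:
    """Flattened view of a structure for energy evaluation."""

    def __init__(self, structure: Structure, rset: RestraintSet) -> None:
        self.structure = structure
        self.refs: list[AtomRef] = []
        self.atoms: list[Atom] = []
        res_key = []
        heavy = []
        for c in structure.chains:
            for r in c.residues:
                for a in r.atoms:
                    self.refs.append(AtomRef(c.chain_id, r.seq_num, a.name, r.icode))
                    self.atoms.append(a)
                    res_key.append((c.chain_id, r.seq_num, r.icode))
                    heavy.append(not a.is_hydrogen)
        self.index = {ref: i for i, ref in enumerate(self.refs)}
        if len(self.index) != len(self.refs):
            raise RestraintError("duplicate atom identifiers; cannot build energy system")
        self.coords = np.array([a.coords for a in self.atoms])
        self.res_key = res_key
        self.heavy = np.array(heavy)

        def need(ref: AtomRef) -> int:
            if ref not in self.index:
                raise RestraintError(f"restraint references missing atom {ref}")
            return self.index[ref]

        self.dist_idx = np.array([[need(r.atom_a), need(r.atom_b)]
                                  for r in rset.distances], dtype=int).reshape(-1, 2)
        self.dist_target = np.array([r.target for r in rset.distances])
        self.dist_k = np.array([r.force_constant for r in rset.distances])
        self.ang_idx = np.array([[need(r.atom_a), need(r.atom_b), need(r.atom_c)]
                                 for r in rset.angles], dtype=int).reshape(-1, 3)
        self.ang_target = np.array([r.target for r in rset.angles])
        self.ang_k = np.array([r.force_constant for r in rset.angles])
        self.r_min = rset.r_min
        self.k_rep = rset.k_rep

        network = {need(ref) for ref in rset.network_atoms()}
        self.network = network
        restrained_pairs = {tuple(sorted(p)) for p in self.dist_idx.tolist()}
        self.restrained_pairs = restrained_pairs

        if rset.mobile is None:
            self.mobile_idx = np.arange(len(self.refs))
        else:
            self.mobile_idx = np.array(sorted(need(ref) for ref in set(rset.mobile)),
                                       dtype=int)
        self.mobile_mask = np.zeros(len(self.refs), dtype=bool)
        self.mobile_mask[self.mobile_idx] = True

    # -- repulsion pair exemptions ------------------------------------------
    def _exempt(self, i: int, j: int) -> bool:
        if self.res_key[i] == self.res_key[j]:
            return True
        ci, si, _ = self.res_key[i]
        cj, sj, _ = self.res_key[j]
        if ci == cj and abs(si - sj) == 1:
            return True  # covalently bonded neighbor residues
        if tuple(sorted((i, j))) in self.restrained_pairs:
            return True
        if i in self.network and j in self.network:
            return True  # geometry owned by the restraint network
        return False

    def energy_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray, dict[str, float]]:
        grad = np.zeros_like(coords)
        breakdown = {"distance": 0.0, "angle": 0.0, "repulsion": 0.0}

        if len(self.dist_idx):
            vi = coords[self.dist_idx[:, 0]] - coords[self.dist_idx[:, 1]]
            d = np.linalg.norm(vi, axis=1)
            dev = d - self.dist_target
            breakdown["distance"] = float(np.sum(self.dist_k * dev ** 2))
            coef = (2.0 * self.dist_k * dev / np.maximum(d, 1e-12))[:, None] * vi
            np.add.at(grad, self.dist_idx[:, 0], coef)
            np.add.at(grad, self.dist_idx[:, 1], -coef)

        deg = 180.0 / np.pi
        for (ia, im, ic), t0, k in zip(self.ang_idx, self.ang_target, self.ang_k):
            u = coords[ia] - coords[im]
            v = coords[ic] - coords[im]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cos_t = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
            theta = np.degrees(np.arccos(cos_t))
            dev = theta - t0
            breakdown["angle"] += float(k * dev ** 2)
            sin_t = np.sqrt(max(1.0 - cos_t ** 2, 1e-12))
            dcos_da = v / (nu * nv) - cos_t * u / nu ** 2
            dcos_dc = u / (nu * nv) - cos_t * v / nv ** 2
            pref = 2.0 * k * dev * deg * (-1.0 / sin_t)
            ga = pref * dcos_da
            gc = pref * dcos_dc
            grad[ia] += ga
            grad[ic] += gc
            grad[im] -= ga + gc

        tree = cKDTree(coords[self.heavy])
        heavy_idx = np.where(self.heavy)[0]
        for ih, jh in tree.query_pairs(self.r_min):
            i, j = int(heavy_idx[ih]), int(heavy_idx[jh])
            if self._exempt(i, j):
                continue
            vij = coords[i] - coords[j]
            d = float(np.linalg.norm(vij))
            if d >= self.r_min or d < 1e-12:
                continue
            breakdown["repulsion"] += self.k_rep * (self.r_min - d) ** 2
            coef = -2.0 * self.k_rep * (self.r_min - d) / d
            grad[i] += coef * vij
            grad[j] -= coef * vij

        grad[~self.mobile_mask] = 0.0
        total = float(sum(breakdown.values()))
        return total, grad, breakdown

    def write_coords(self, coords: np.ndarray) -> None:
        for a, xyz in zip(self.atoms, coords):
            a.coords = xyz.copy()


def restraint_energy(structure: Structure, rset: RestraintSet,
                     ) -> tuple[float, dict[str, float]]:
    """Total restraint energy and its per-class breakdown (sums to the total)."""
    sys = _System(structure, rset)
    total, _, breakdown = sys.energy_grad(sys.coords)
    return total, breakdown


def restraint_gradient(structure: Structure, rset: RestraintSet) -> np.ndarray:
    """Analytic gradient of the restraint energy, (N, 3) over all atoms."""
    sys = _System(structure, rset)
    _, grad, _ = sys.energy_grad(sys.coords)
    return grad


def refine(structure: Structure, rset: RestraintSet,
           max_iterations: int = 5000, tolerance: float = 1e-6,
           seed: int | None = None) -> RefinementResult:
    """Deterministic restrained local minimization.

    Quasi-Newton (L-BFGS) descent on the restraint energy over the mobile
    atoms; the line search guarantees every accepted iterate does not
    increase the energy, which the returned trajectory records.  ``seed`` is
    accepted for interface symmetry with stochastic refiners but unused: the
    minimization is fully deterministic.
    """
    refined = structure.copy()
    sys = _System(refined, rset)
    x_full = sys.coords.copy()
    if not np.all(np.isfinite(x_full)):
        raise RestraintError("non-finite coordinates at refinement start")
    mob = sys.mobile_idx
    if len(mob) == 0:
        raise RestraintError("mobile selection is empty")

    trajectory: list[float] = []

    def fun(x_mob: np.ndarray):
        x_full[mob] = x_mob.reshape(-1, 3)
        e, g, _ = sys.energy_grad(x_full)
        return e, g[mob].ravel()

    e0, _, _ = sys.energy_grad(x_full)
    if not np.isfinite(e0):
        raise RestraintError("non-finite energy at refinement start")
    trajectory.append(e0)

    def callback(xk: np.ndarray) -> None:
        x_full[mob] = xk.reshape(-1, 3)
        e, _, _ = sys.energy_grad(x_full)
        trajectory.append(e)

    result = minimize(
        fun, x_full[mob].ravel(), jac=True, method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iterations, "gtol": tolerance,
                 "ftol": 1e-14, "maxls": 60},
    )
    x_full[mob] = result.x.reshape(-1, 3)
    e_final, _, _ = sys.energy_grad(x_full)
    if e_final <= trajectory[-1]:
        trajectory.append(e_final)
    sys.write_coords(x_full)

    residuals: dict[str, float] = {}
    for r in rset.distances:
        d = float(np.linalg.norm(r.atom_a.resolve(refined).coords -
                                 r.atom_b.resolve(refined).coords))
        residuals[f"{r.atom_a}--{r.atom_b}"] = abs(d - r.target)
    return RefinementResult(
        structure=refined,
        energy_trajectory=trajectory,
        converged=bool(result.success) or e_final < tolerance,
        n_iterations=int(result.nit),
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# Water placement
# ---------------------------------------------------------------------------

def place_waters(structure: Structure, site: MetalSiteDefinition,
                 seed: int | None = None, target: float = DEFAULT_TARGET,
                 water_chain_id: str = "W") -> Structure:
    """Add water oxygens at the open octahedral vertices of each site ion.

    The occupied vertices come from the current protein/phosphate ligands'
    best octahedral assignment; waters go at ``target`` angstrom along the
    open ideal-vertex directions.  Deterministic (the seed is accepted for
    interface symmetry).  Raises :class:`PlacementError` if no vertex is
    open.
    """
    out = structure.copy()
    ions = _resolve_ions(out, site)
    shells = _ligands_for_ions(out, site, ions)
    max_seq = max((r.seq_num for c in out.chains for r in c.residues
                   if c.chain_id == water_chain_id), default=0)
    added = 0
    new_residues: list[Residue] = []
    for label, ion_ref in ions:
        ligands = shells[label]
        if len(ligands) >= 6:
            continue
        ion_pos = ion_ref.resolve(out).coords
        dirs = np.array([l.resolve(out).coords - ion_pos for l in ligands])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        perm, R = _fit_octahedron(dirs)
        open_slots = [v for v in range(6) if v not in perm]
        for v in open_slots[: 6 - len(ligands)]:
            direction = R @ _OCT[v]
            pos = ion_pos + target * direction
            max_seq += 1
            added += 1
            new_residues.append(Residue(max_seq, "HOH",
                                        [Atom("O", "O", pos)], ""))
    if added == 0:
        raise PlacementError("every site ion is already six-coordinate; "
                             "no open octahedral vertex")
    if out.has_chain(water_chain_id):
        out.chain(water_chain_id).residues.extend(new_residues)
    else:
        out.chains.append(Chain(water_chain_id, new_residues))
    out.renumber_serials()
    return out
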