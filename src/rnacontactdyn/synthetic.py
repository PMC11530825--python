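"""Seeded generator of structural ensembles with known ground truth.

Builds reduced-atom RNA nucleotides (full base with polar and aromatic
hydrogens, sugar ring, phosphate, 2'-hydroxyl) from idealized internal
coordinates, with the sugar pucker and glycosidic torsion under caller
control; poses Watson-Crick, Hoogsteen and triple base-pair arrangements by
constrained rigid-body optimization; and turns single reference frames into
ensembles with prescribed per-residue fluctuation amplitudes and scheduled
contact occupancies.

Base geometry comes from the chemical component dictionary's ideal
coordinates (via biotite); the furanose ring is generated analytically from
an out-of-plane displacement model and refined so that the realized
Altona-Sundaralingam pseudorotation phase matches the requested conformer
to well under a degree.  The generator is deterministic: equal inputs and
seeds give bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import geometry
from .topology import (
    BACKBONE_ATOMS,
    AtomRecord,
    Ensemble,
    PAPER_SCHEME,
    RegionScheme,
    ResidueRecord,
    StructureTopology,
    classify_atom_role,
)


class SyntheticError(ValueError):
    """Raised for invalid generator requests."""


class StericClashError(SyntheticError):
    """Raised when a pairing plan forces residues closer than 1.5 A."""


# ---------------------------------------------------------------------------
# Internal-coordinate machinery
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as requested."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@lru_cache(maxsize=None)
def _ccd_residue(nucleotide: str):
    import biotite.structure.info as struc_info

    res = struc_info.residue(nucleotide)
    names = [str(n) for n in res.atom_name]
    coords = np.asarray(res.coord, dtype=float)
    return names, coords


def _ccd_internal(nucleotide: str, quad: tuple[str, str, str, str]):
    """(bond, angle, dihedral) of atom quad[3] against quad[0:3] in the
    ideal component-dictionary geometry."""
    names, coords = _ccd_residue(nucleotide)
    p = [coords[names.index(n)] for n in quad]
    bond = float(np.linalg.norm(p[3] - p[2]))
    v1 = p[1] - p[2]
    v2 = p[3] - p[2]
    angle = float(
        np.degrees(
            np.arccos(
                np.clip(
                    np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2),
                    -1, 1,
                )
            )
        )
    )
    dih = geometry.dihedral(*p)
    return bond, angle, dih


#: A-form backbone torsions used for the free backbone atoms, degrees.
A_FORM_TORSIONS = {"gamma": 54.0, "beta": 178.0}

#: Atoms placed after the sugar ring: (atom, (ref_a, ref_b, ref_c)).
#: Bond/angle always come from the ideal component geometry; the dihedral
#: too unless overridden (glycosidic chi, A-form backbone torsions).
_BACKBONE_RECIPE: tuple[tuple[str, tuple[str, str, str], str | None], ...] = (
    ("C5'", ("C2'", "C3'", "C4'"), None),
    ("O3'", ("C5'", "C4'", "C3'"), None),
    ("O2'", ("C1'", "C3'", "C2'"), None),
    ("HO2'", ("C3'", "C2'", "O2'"), None),
    ("O5'", ("C3'", "C4'", "C5'"), "gamma"),
    ("P", ("C4'", "C5'", "O5'"), "beta"),
    ("OP1", ("C5'", "O5'", "P"), None),
    ("OP2", ("C5'", "O5'", "P"), None),
)

#: Pseudorotation amplitude of generated sugars, degrees (typical ~38).
DEFAULT_AMPLITUDE_DEG = 38.0

#: Conformers the builder accepts (any sector name is allowed).
_RING_RADIUS = 1.48 / (2.0 * np.sin(np.pi / 5.0))


def _ring_coords(cp_phase_deg: float, q: float) -> np.ndarray:
    """Five ring atoms (O4', C1', C2', C3', C4') on a pentagon with
    out-of-plane displacements z_j = sqrt(2/5) q cos(phi + 4 pi j / 5)."""
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    z = np.sqrt(2.0 / 5.0) * q * np.cos(
        np.radians(cp_phase_deg) + 4.0 * np.pi * j / 5.0
    )
    return np.stack(
        [_RING_RADIUS * np.cos(theta), _RING_RADIUS * np.sin(theta), z], axis=1
    )


@lru_cache(maxsize=None)
def _solve_ring(target_phase_deg: float, amplitude_deg: float) -> np.ndarray:
    """Find displacement-model parameters so the realized AS phase hits the
    target (fine grid inversion; residual error << 1 degree)."""

    def realized(phi, q):
        st = geometry.pucker_from_torsions(
            geometry.ring_torsions(_ring_coords(phi, q))
        )
        return st.phase, st.amplitude

    # amplitude scale: AS amplitude is proportional to q for small q
    q = 0.38
    _, amp = realized(0.0, q)
    q *= amplitude_deg / amp

    grid = np.arange(0.0, 360.0, 0.2)
    phases = np.array([realized(phi, q)[0] for phi in grid])
    diff = (phases - target_phase_deg + 180.0) % 360.0 - 180.0
    best = grid[int(np.argmin(np.abs(diff)))]
    # local refinement
    fine = np.arange(best - 0.3, best + 0.3, 0.01)
    phases = np.array([realized(phi, q)[0] for phi in fine])
    diff = (phases - target_phase_deg + 180.0) % 360.0 - 180.0
    best = fine[int(np.argmin(np.abs(diff)))]
    coords = _ring_coords(best, q)
    coords.setflags(write=False)
    return coords


def build_nucleotide(
    nucleotide: str,
    pucker_conformer: str = "C3'-endo",
    chi_deg: float = -160.0,
    amplitude_deg: float = DEFAULT_AMPLITUDE_DEG,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Idealized single nucleotide with the requested sugar pucker and chi.

    Returns (atom_names, coordinates, elements).  The atom set is the full
    base (with hydrogens), the sugar ring with the 2'-hydroxyl, and the
    5'-phosphate.  The endocyclic torsions realize the pseudorotation phase
    of the requested conformer's sector centre to within a fraction of a
    degree; chi is exact.
    """
    if nucleotide not in ("A", "C", "G", "U"):
        raise SyntheticError(f"unsupported nucleotide {nucleotide!r}")
    target_phase = geometry.conformer_center(pucker_conformer)  # may raise

    pos: dict[str, np.ndarray] = dict(
        zip(geometry.RING_ATOMS, _solve_ring(target_phase, amplitude_deg))
    )

    # glycosidic nitrogen and the two base anchors defining the base plane
    n_glyc = "N9" if nucleotide in geometry.PURINES else "N1"
    anchor2 = "C4" if nucleotide in geometry.PURINES else "C2"
    anchor3 = "C8" if nucleotide in geometry.PURINES else "C6"

    bond, angle, dih = _ccd_internal(nucleotide, ("C3'", "C2'", "C1'", n_glyc))
    pos[n_glyc] = _place_atom(pos["C3'"], pos["C2'"], pos["C1'"], bond, angle, dih)

    bond, angle, _ = _ccd_internal(nucleotide, ("O4'", "C1'", n_glyc, anchor2))
    pos[anchor2] = _place_atom(
        pos["O4'"], pos["C1'"], pos[n_glyc], bond, angle, chi_deg
    )
    bond, angle, dih3 = _ccd_internal(nucleotide, ("O4'", "C1'", n_glyc, anchor3))
    _, _, dih2 = _ccd_internal(nucleotide, ("O4'", "C1'", n_glyc, anchor2))
    pos[anchor3] = _place_atom(
        pos["O4'"], pos["C1'"], pos[n_glyc], bond, angle,
        chi_deg + (dih3 - dih2),
    )

    # rigid fit of the full base onto the three anchors
    names, coords = _ccd_residue(nucleotide)
    base_names = [
        n for n in names
        if n not in BACKBONE_ATOMS and not n.startswith(("HOP",))
    ]
    tmpl = np.array([coords[names.index(n)] for n in base_names])
    anchors = [n_glyc, anchor2, anchor3]
    tmpl_anchor = np.array([coords[names.index(n)] for n in anchors])
    placed_anchor = np.array([pos[n] for n in anchors])
    rot, _ = Rotation.align_vectors(
        placed_anchor - placed_anchor.mean(axis=0),
        tmpl_anchor - tmpl_anchor.mean(axis=0),
    )
    shift = placed_anchor.mean(axis=0) - rot.apply(tmpl_anchor.mean(axis=0))
    for n, c in zip(base_names, rot.apply(tmpl) + shift):
        pos[n] = c

    for atom, refs, override in _BACKBONE_RECIPE:
        bond, angle, dih = _ccd_internal(nucleotide, refs + (atom,))
        if override is not None:
            dih = A_FORM_TORSIONS[override]
        pos[atom] = _place_atom(
            pos[refs[0]], pos[refs[1]], pos[refs[2]], bond, angle, dih
        )

    out_names = list(pos.keys())
    out_coords = np.array([pos[n] for n in out_names])
    elements = [("H" if n.startswith("H") else n[0]) for n in out_names]
    return out_names, out_coords, elements


# ---------------------------------------------------------------------------
# Topology assembly
# ---------------------------------------------------------------------------

def assemble_topology(
    residues: Sequence[tuple[int, str, str]],
    atom_lists: Sequence[tuple[list[str], list[str]]],
    region_scheme: RegionScheme | None = PAPER_SCHEME,
) -> StructureTopology:
    """Topology from (index, nucleotide, chain) residue specs and matching
    per-residue (atom_names, elements) lists."""
    res_records = []
    atom_records = []
    for (idx, nt, chain), (names, elements) in zip(residues, atom_lists):
        region = region_scheme.region_of(idx) if region_scheme else None
        res_records.append(ResidueRecord(idx, nt, chain, region))
        for n, e in zip(names, elements):
            atom_records.append(
                AtomRecord(
                    atom_name=n,
                    element=e,
                    role=classify_atom_role(n),
                    residue_index=idx,
                    is_heavy=e != "H",
                )
            )
    return StructureTopology(res_records, atom_records)


# ---------------------------------------------------------------------------
# Base pairing plans
# ---------------------------------------------------------------------------

#: Donor/acceptor atom pairs realized for each (anchored, partner, kind).
#: "WC" pairs join both Watson-Crick edges; "Hoogsteen" pairs join the
#: purine Hoogsteen edge (N7 side) with the pyrimidine WC edge.
PAIR_TARGETS: dict[tuple[str, str, str], tuple[tuple[str, str], ...]] = {
    ("A", "U", "WC"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C", "WC"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("G", "U", "WC"): (("O6", "N3"), ("N1", "O4")),  # wobble
    ("A", "U", "Hoogsteen"): (("N7", "N3"), ("N6", "O4")),
    ("G", "C", "Hoogsteen"): (("O6", "N4"), ("N7", "N3")),
}
for (a, b, kind), targets in list(PAIR_TARGETS.items()):
    PAIR_TARGETS.setdefault(
        (b, a, kind), tuple((y, x) for x, y in targets)
    )

HBOND_BUILD_DISTANCE = 2.85  # Angstrom, donor-heavy to acceptor


@dataclass(frozen=True)
class PairSpec:
    """One requested base pair: anchored residue, partner residue, kind."""

    residue_i: int
    residue_j: int
    kind: str = "WC"  # WC | Hoogsteen


@dataclass(frozen=True)
class PairingPlan:
    """Residues (index, nucleotide) and the pairs/triples to realize.

    A triple is expressed as two pairs sharing the central residue with
    different kinds, e.g. U.A-U = WC(A,U1) + Hoogsteen(A,U2).
    """

    residues: tuple[tuple[int, str], ...]
    pairs: tuple[PairSpec, ...] = ()
    chains: dict[int, str] | None = None


def _pose_partner(
    fixed: np.ndarray,
    fixed_ring_idx,
    moving: np.ndarray,
    moving_heavy: np.ndarray,
    moving_ring_idx,
    target_pairs: list[tuple[int, int]],
    fixed_heavy: np.ndarray,
) -> np.ndarray:
    """Rigid-body placement of ``moving`` so target atom pairs sit at
    H-bond distance and face each other along their base-edge outward
    directions, with coplanar base planes and no heavy-atom clashes.
    Deterministic multi-start least squares."""

    centroid = moving.mean(axis=0)
    n_targets = len(target_pairs)
    fixed_base_normal = _plane_normal(fixed[fixed_ring_idx])
    fixed_ring_centroid = fixed[fixed_ring_idx].mean(axis=0)
    tgt_mid = fixed[[i for i, _ in target_pairs]].mean(axis=0)
    u = tgt_mid - fixed_ring_centroid
    u /= np.linalg.norm(u)

    def transform(x, pts):
        return Rotation.from_rotvec(x[:3]).apply(pts - centroid) + centroid + x[3:]

    def residuals(x):
        pts = transform(x, moving)
        mov_ring_centroid = pts[moving_ring_idx].mean(axis=0)
        r = []
        for (i, j) in target_pairs:
            v = pts[j] - fixed[i]
            d = np.linalg.norm(v)
            r.append((d - HBOND_BUILD_DISTANCE) / 0.02)
            # contact atoms face each other along their outward edge
            out_i = fixed[i] - fixed_ring_centroid
            out_j = pts[j] - mov_ring_centroid
            r.append((1.0 - np.dot(out_i / np.linalg.norm(out_i), v / d)) / 0.12)
            r.append((1.0 + np.dot(out_j / np.linalg.norm(out_j), v / d)) / 0.12)
        n2 = _plane_normal(pts[moving_ring_idx])
        r.append((1.0 - abs(np.dot(fixed_base_normal, n2))) / 0.02)
        d_all = cdist(fixed[fixed_heavy], pts[moving_heavy])
        for (i, j) in target_pairs:
            fi = np.nonzero(fixed_heavy == i)[0]
            mj = np.nonzero(moving_heavy == j)[0]
            if fi.size and mj.size:
                d_all[fi[0], mj[0]] = 10.0
        r.extend((np.clip(2.95 - d_all, 0.0, None) / 0.02).ravel())
        return np.array(r)

    def pose_ok(sol) -> bool:
        if sol is None:
            return False
        r = residuals(sol.x)
        head = r[: 3 * n_targets + 1]
        return bool(np.all(np.abs(head) < 4.0) and np.all(r[len(head):] < 1.0))

    best = None
    for delta in (7.5, 8.5, 9.5):
        t0 = fixed_ring_centroid + u * delta - centroid
        for axis, angle in [
            (fixed_base_normal, 0.0),
            (fixed_base_normal, np.pi / 2),
            (fixed_base_normal, np.pi),
            (fixed_base_normal, -np.pi / 2),
            (u, np.pi),
            (np.cross(fixed_base_normal, u), np.pi),
        ]:
            x0 = np.concatenate([np.asarray(axis) * angle, t0])
            sol = least_squares(residuals, x0, method="lm", max_nfev=400)
            if best is None or sol.cost < best.cost:
                best = sol
            if pose_ok(best):
                break
        if pose_ok(best):
            break
    pts = transform(best.x, moving)
    for (i, j) in target_pairs:
        d = np.linalg.norm(fixed[i] - pts[j])
        if abs(d - HBOND_BUILD_DISTANCE) > 0.08:
            raise SyntheticError(
                f"pair posing failed to converge (H-bond distance {d:.2f} A)"
            )
    return pts


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    return vt[2]


def build_paired_arrangement(
    plan: PairingPlan,
    region_scheme: RegionScheme | None = PAPER_SCHEME,
    pucker_conformer: str = "C3'-endo",
    chi_deg: float = -160.0,
) -> Ensemble:
    """One-frame ensemble realizing the requested pairs/triples.

    For each requested pair at least two donor-acceptor distances sit at
    H-bond geometry on the requested edge (one distance constraint may be
    the single Hoogsteen contact for non-canonical combinations).  Residues
    not referenced by any pair are parked on a wide grid.  Plans that force
    residues within 1.5 A raise :class:`StericClashError`.
    """
    index_to_nt = dict(plan.residues)
    built = {}
    for idx, nt in plan.residues:
        names, coords, elements = build_nucleotide(nt, pucker_conformer, chi_deg)
        built[idx] = (names, coords.copy(), elements)

    placed: dict[int, np.ndarray] = {}
    order = [r[0] for r in plan.residues]

    for k, pair in enumerate(plan.pairs):
        key = (index_to_nt[pair.residue_i], index_to_nt[pair.residue_j], pair.kind)
        if key not in PAIR_TARGETS:
            raise SyntheticError(f"no pairing template for {key}")
        targets = PAIR_TARGETS[key]
        if pair.residue_i not in placed and pair.residue_j not in placed:
            # fresh anchor: park each independent pairing cluster apart
            placed[pair.residue_i] = built[pair.residue_i][1] + np.array(
                [0.0, -30.0 * len(placed), 0.0]
            )
        if pair.residue_i in placed and pair.residue_j in placed:
            continue
        if pair.residue_i in placed:
            anchor, mover = pair.residue_i, pair.residue_j
            tpairs = targets
        else:
            anchor, mover = pair.residue_j, pair.residue_i
            tpairs = tuple((y, x) for x, y in targets)
        an_names, _, an_el = built[anchor]
        mv_names, mv_coords, mv_el = built[mover]
        anchor_coords = placed[anchor]
        tp_idx = [
            (an_names.index(a), mv_names.index(b)) for a, b in tpairs
        ]
        ring_a = [an_names.index(n)
                  for n in geometry.base_ring_atoms(index_to_nt[anchor])]
        ring_m = [mv_names.index(n)
                  for n in geometry.base_ring_atoms(index_to_nt[mover])]
        heavy_a = np.array([i for i, e in enumerate(an_el) if e != "H"])
        heavy_m = np.array([i for i, e in enumerate(mv_el) if e != "H"])
        placed[mover] = _pose_partner(
            anchor_coords,
            ring_a,
            mv_coords,
            heavy_m,
            ring_m,
            tp_idx,
            heavy_a,
        )

    # park unpaired residues on a wide grid
    grid = 0
    for idx in order:
        if idx not in placed:
            names, coords, elements = built[idx]
            placed[idx] = coords + np.array([40.0 + 30.0 * grid, 40.0, 0.0])
            grid += 1

    chains = plan.chains or {}
    residues = [(idx, nt, chains.get(idx, "A")) for idx, nt in plan.residues]
    atom_lists = [(built[idx][0], built[idx][2]) for idx, _ in plan.residues]
    topology = assemble_topology(residues, atom_lists, region_scheme)
    frame = np.concatenate([placed[idx] for idx, _ in plan.residues], axis=0)

    # steric sanity over distinct residues
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            d = cdist(placed[order[a]], placed[order[b]])
            if d.min() < 1.5:
                raise StericClashError(
                    f"residues {order[a]} and {order[b]} overlap "
                    f"(min distance {d.min():.2f} A)"
                )

    return Ensemble(topology, frame[None, :, :], np.array([0.0]))


# ---------------------------------------------------------------------------
# Fluctuations and contact schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationSpec:
    """Isotropic Gaussian per-residue displacement amplitudes.

    ``per_residue_sigma`` maps residue index to sigma (Angstrom, applied
    independently to each Cartesian component of each atom); residues not
    listed use ``default_sigma``.
    """

    n_frames: int
    seed: int
    per_residue_sigma: dict[int, float] = field(default_factory=dict)
    default_sigma: float = 0.0
    time_step_ns: float = 1.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SyntheticError("n_frames must be >= 1")
        if self.default_sigma < 0 or any(
            s < 0 for s in self.per_residue_sigma.values()
        ):
            raise SyntheticError("sigma must be >= 0")


def perturb(reference: Ensemble | np.ndarray, spec: FluctuationSpec,
            topology: StructureTopology | None = None) -> Ensemble:
    """Ensemble of ``spec.n_frames`` frames, each the reference plus
    independent isotropic Gaussian noise with the residue's sigma."""
    if isinstance(reference, Ensemble):
        topology = reference.topology
        ref = reference.frames[0]
    else:
        if topology is None:
            raise SyntheticError("topology required with a bare frame")
        ref = np.asarray(reference, dtype=float)
    sigma_atom = np.array(
        [
            spec.per_residue_sigma.get(resi, spec.default_sigma)
            for resi in topology.residue_indices
        ]
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_frames,) + ref.shape)
    frames = ref[None] + noise * sigma_atom[None, :, None]
    times = np.arange(spec.n_frames, dtype=float) * spec.time_step_ns
    return Ensemble(topology, frames, times)


@dataclass(frozen=True)
class ContactSchedule:
    """Target occupancy for one residue pair's contact."""

    residue_pair: tuple[int, int]
    target_occupancy: float
    contact_type: str = "hbond"

    def __post_init__(self):
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise SyntheticError("occupancy must be in [0, 1]")


def scheduled_frame_count(occupancy: float, n_frames: int) -> int:
    """Frames in contact: occupancy * n rounded half away from zero, so the
    realized fraction is within 1/n of the target."""
    return int(np.floor(occupancy * n_frames + 0.5))


def schedule_contacts(
    ensemble: Ensemble, schedules: Sequence[ContactSchedule], seed: int
) -> tuple[Ensemble, dict[tuple[int, int], np.ndarray]]:
    """Impose contact occupancies by rigidly separating the second residue
    of each scheduled pair in the complementary frames.

    The input ensemble must hold the pair in contact geometry in every
    frame; contact frames are chosen deterministically from the seed.
    Returns the modified ensemble and the boolean on-mask per pair.
    """
    pairs = [s.residue_pair for s in schedules]
    if len(set(pairs)) != len(pairs):
        raise SyntheticError("conflicting schedules on the same residue pair")
    top = ensemble.topology
    resids = {r.residue_index for r in top.residues}
    for s in schedules:
        if s.residue_pair[0] not in resids or s.residue_pair[1] not in resids:
            raise SyntheticError(f"schedule references missing residues "
                                 f"{s.residue_pair}")
    frames = ensemble.frames.copy()
    n = ensemble.n_frames
    masks: dict[tuple[int, int], np.ndarray] = {}
    for k, s in enumerate(schedules):
        rng = np.random.default_rng([seed, k])
        n_on = scheduled_frame_count(s.target_occupancy, n)
        on = np.zeros(n, dtype=bool)
        on[rng.choice(n, size=n_on, replace=False)] = True
        masks[s.residue_pair] = on
        i, j = s.residue_pair
        idx_i = top.residue_atom_indices(i)
        idx_j = top.residue_atom_indices(j)
        direction = frames[0, idx_j].mean(axis=0) - frames[0, idx_i].mean(axis=0)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        off = ~on
        frames[np.ix_(off, idx_j)] += 25.0 * direction
    return Ensemble(top, frames, ensemble.times.copy()), masks


# ---------------------------------------------------------------------------
# Nonbonded parameter table
# ---------------------------------------------------------------------------

#: Element-level Lennard-Jones parameters (sigma A, epsilon kcal/mol),
#: AMBER-flavoured magnitudes.
_LJ_BY_ELEMENT = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "P": (3.74, 0.200),
    "H": (1.07, 0.016),
}

#: Coarse partial charges (e) by atom name; base atoms default by element.
_CHARGE_BY_NAME = {
    "P": 1.17, "OP1": -0.78, "OP2": -0.78,
    "O5'": -0.50, "O3'": -0.52, "O4'": -0.36, "O2'": -0.61, "HO2'": 0.43,
    "C1'": 0.06, "C2'": 0.07, "C3'": 0.20, "C4'": 0.11, "C5'": 0.06,
}
#: Chosen so hydrogen-bonded base pairs come out net attractive (donor
#: hydrogens carry enough positive charge to beat the N/O repulsion).
_CHARGE_BY_ELEMENT = {"C": 0.25, "N": -0.60, "O": -0.50, "H": 0.40, "P": 1.17}


def synthetic_param_table(topology: StructureTopology) -> pd.DataFrame:
    """Plausible charge/sigma/epsilon table covering every topology atom."""
    rows = []
    seen = set()
    for atom in topology.atoms:
        nt = topology.residue(atom.residue_index).nucleotide
        key = (nt, atom.atom_name)
        if key in seen:
            continue
        seen.add(key)
        sigma, eps = _LJ_BY_ELEMENT[atom.element]
        charge = _CHARGE_BY_NAME.get(
            atom.atom_name, _CHARGE_BY_ELEMENT[atom.element]
        )
        rows.append((nt, atom.atom_name, charge, sigma, eps))
    return pd.DataFrame(
        rows, columns=["residue", "atom", "charge_e", "sigma_A", "epsilon_kcal"]
    )


# ---------------------------------------------------------------------------
# Composite scenes
# ---------------------------------------------------------------------------

def scheduled_scene(
    occupancies: Sequence[float],
    n_frames: int,
    seed: int,
    contact_type: str = "hbond",
) -> tuple[Ensemble, dict[tuple[int, int], np.ndarray]]:
    """Well-separated A-U pairs, one per requested occupancy.

    Pair k occupies residues (2k+1, 2k+2) on different chains (so the
    covalent-neighbour exclusion does not apply) at 50 A grid spacing;
    contact frames follow the seeded schedule exactly.
    """
    n_pairs = len(occupancies)
    residues = []
    atom_lists = []
    coords = []
    pair_plan = PairingPlan(
        residues=((1, "A"), (2, "U")), pairs=(PairSpec(1, 2, "WC"),)
    )
    ens = build_paired_arrangement(pair_plan, region_scheme=None)
    for k in range(n_pairs):
        offset = np.array([50.0 * k, 0.0, 0.0])
        for local_idx, chain in ((1, "A"), (2, "B")):
            res = ens.topology.residue(local_idx)
            idx = ens.topology.residue_atom_indices(local_idx)
            residues.append((2 * k + local_idx, res.nucleotide, chain))
            atom_lists.append(
                (
                    list(ens.topology.atom_names[idx]),
                    list(ens.topology.elements[idx]),
                )
            )
            coords.append(ens.frames[0, idx] + offset)
    topology = assemble_topology(residues, atom_lists, region_scheme=None)
    frame = np.concatenate(coords, axis=0)
    base = Ensemble(
        topology,
        np.repeat(frame[None], n_frames, axis=0),
        np.arange(n_frames, dtype=float),
    )
    schedules = [
        ContactSchedule((2 * k + 1, 2 * k + 2), occ, contact_type)
        for k, occ in enumerate(occupancies)
    ]
    return schedule_contacts(base, schedules, seed)


def random_scene(
    n_residues: int,
    seed: int,
    box: float = 18.0,
    region_scheme: RegionScheme | None = None,
) -> Ensemble:
    """Randomly rotated/translated nucleotides in a box: an arbitrary-
    geometry single frame for detector stress tests."""
    rng = np.random.default_rng(seed)
    nts = rng.choice(["A", "C", "G", "U"], size=n_residues)
    residues, atom_lists, coords = [], [], []
    chains = "ABCD"
    for k, nt in enumerate(nts):
        names, c, elements = build_nucleotide(str(nt))
        rot = Rotation.random(
            random_state=np.random.RandomState((seed * 977 + k) % (2**32 - 1))
        )
        c = rot.apply(c - c.mean(axis=0)) + rng.uniform(0, box, size=3)
        residues.append((k + 1, str(nt), chains[k % len(chains)]))
        atom_lists.append((names, elements))
        coords.append(c)
    topology = assemble_topology(residues, atom_lists, region_scheme)
    return Ensemble(
        topology, np.concatenate(coords)[None], np.array([0.0])
    )


def demo_scene(
    seed: int, n_frames: int = 120
) -> tuple[Ensemble, dict]:
    """Small ASO-hairpin-like complex exercising every analysis stage.

    Two Watson-Crick ASO-hairpin pairs, one Hoogsteen interaction closing
    a base triple on the first hairpin adenine, per-residue fluctuations
    with a mobile ASO tail, and one scheduled intermittent contact.
    Returns the ensemble plus a ground-truth dictionary.
    """
    plan = PairingPlan(
        residues=((1, "U"), (2, "G"), (11, "A"), (12, "C"), (27, "U")),
        pairs=(
            PairSpec(11, 1, "WC"),
            PairSpec(12, 2, "WC"),
            PairSpec(11, 27, "Hoogsteen"),
        ),
    )
    scene = build_paired_arrangement(plan)
    # thermal-like amplitudes: large enough to spread distributions, small
    # enough that independent per-atom noise cannot collapse contact pairs
    # into the steep repulsive wall
    sigma = {1: 0.12, 2: 0.25, 11: 0.1, 12: 0.1, 27: 0.15}
    spec = FluctuationSpec(
        n_frames=n_frames, seed=seed, per_residue_sigma=sigma,
        default_sigma=0.1
    )
    ens = perturb(scene, spec)
    schedules = [ContactSchedule((2, 12), 0.6, "hbond")]
    ens, masks = schedule_contacts(ens, schedules, seed)
    truth = {
        "sigma": sigma,
        "pairs": [(11, 1, "WC"), (12, 2, "WC"), (11, 27, "Hoogsteen")],
        "triple_central": 11,
        "schedules": {"(2, 12)": 0.6},
        "seed": seed,
        "n_frames": n_frames,
    }
    return ens, truth
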