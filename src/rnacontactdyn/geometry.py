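"""Nucleic-acid geometry: backbone torsions, sugar pucker, base-pair params.

Torsions follow the standard nucleic-acid nomenclature (alpha through zeta
along the backbone, chi about the glycosidic bond).  Sugar pucker uses the
Altona-Sundaralingam pseudorotation construction from the five endocyclic
torsions nu0-nu4; the phase wheel is divided into twenty 18-degree sectors
alternating envelope and twist conformers, with C3'-endo centred at 18 deg
and C2'-endo at 162 deg.

Base-pair and step parameters use reference frames least-squares fitted to
idealized base templates and the mid-frame algebra: the relative rotation
and translation of two frames are expressed in their average frame, giving
(shear, stretch, stagger, buckle, propeller, opening) for a pair and
(shift, slide, rise, tilt, roll, twist) for a step.  This is the standard
reference-frame convention, not the curvilinear-axis analysis of CURVES+,
so values agree in convention but not bit-for-bit with that program.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .topology import Ensemble, StructureTopology


class GeometryError(ValueError):
    """Raised for degenerate or incomplete geometric input."""


# ---------------------------------------------------------------------------
# Dihedral primitive
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180].

    Standard atan2 construction on the two bond-plane normals.  Raises
    :class:`GeometryError` if consecutive points coincide or three points
    are collinear (undefined torsion).
    """
    return float(dihedrals(np.asarray([[p1, p2, p3, p4]], dtype=float))[0])


def dihedrals(quads: np.ndarray) -> np.ndarray:
    """Vectorized signed dihedrals for an (n, 4, 3) array, degrees."""
    quads = np.asarray(quads, dtype=float)
    b1 = quads[:, 1] - quads[:, 0]
    b2 = quads[:, 2] - quads[:, 1]
    b3 = quads[:, 3] - quads[:, 2]
    if np.any(np.linalg.norm(b2, axis=1) < 1e-9):
        raise GeometryError("coincident central atoms in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-9) or np.any(
        np.linalg.norm(n2, axis=1) < 1e-9
    ):
        raise GeometryError("collinear atoms make the dihedral undefined")
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = -np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def circular_mean_deg(values: np.ndarray) -> float:
    """Mean of angles in degrees, robust to wrap-around at +-180."""
    rad = np.radians(np.asarray(values, dtype=float))
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return float(mean)


# ---------------------------------------------------------------------------
# Sugar pucker
# ---------------------------------------------------------------------------

#: Endocyclic ring atoms in cyclic order; nu_j is the torsion about the bond
#: ring[j]-ring[(j+1) % 5] using the four atoms centred on that bond.
RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

#: Twenty 18-degree pseudorotation sectors (centres 0, 18, ..., 342 deg),
#: alternating twist and envelope conformers.
CONFORMER_WHEEL = (
    "C3'-endo-C2'-exo",   # 0
    "C3'-endo",           # 18
    "C3'-endo-C4'-exo",   # 36
    "C4'-exo",            # 54
    "C4'-exo-O4'-endo",   # 72
    "O4'-endo",           # 90
    "O4'-endo-C1'-exo",   # 108
    "C1'-exo",            # 126
    "C1'-exo-C2'-endo",   # 144
    "C2'-endo",           # 162
    "C2'-endo-C3'-exo",   # 180
    "C3'-exo",            # 198
    "C3'-exo-C4'-endo",   # 216
    "C4'-endo",           # 234
    "C4'-endo-O4'-exo",   # 252
    "O4'-exo",            # 270
    "O4'-exo-C1'-endo",   # 288
    "C1'-endo",           # 306
    "C1'-endo-C2'-exo",   # 324
    "C2'-exo",            # 342
)


def conformer_center(name: str) -> float:
    """Phase-sector centre (degrees) of a named pucker conformer."""
    try:
        return 18.0 * CONFORMER_WHEEL.index(name)
    except ValueError:
        raise GeometryError(f"unknown pucker conformer {name!r}") from None


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase (deg, [0, 360)), amplitude (deg), conformer."""

    phase: float
    amplitude: float
    conformer: str


def ring_torsions(ring_coords: np.ndarray) -> np.ndarray:
    """nu0..nu4 (degrees) from the five ring atoms ordered as
    ``RING_ATOMS`` (O4', C1', C2', C3', C4')."""
    ring_coords = np.asarray(ring_coords, dtype=float)
    if ring_coords.shape != (5, 3):
        raise GeometryError("ring_torsions expects 5 ring atoms")
    quads = np.array(
        [
            [ring_coords[(j - 1) % 5], ring_coords[j], ring_coords[(j + 1) % 5],
             ring_coords[(j + 2) % 5]]
            for j in range(5)
        ]
    )
    return dihedrals(quads)


def pucker_from_torsions(nu: np.ndarray, flat_tol: float = 1e-6) -> PuckerState:
    """Altona-Sundaralingam phase/amplitude from endocyclic torsions.

    tan(P) = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
    amplitude nu_max = nu2 / cos(P).  A flat ring (all torsions ~ 0) has
    amplitude 0 and the sentinel conformer ``"flat"``.
    """
    nu = np.asarray(nu, dtype=float)
    if np.all(np.abs(nu) < flat_tol):
        return PuckerState(phase=0.0, amplitude=0.0, conformer="flat")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    phase = np.degrees(np.arctan2(num, den))
    amplitude = nu[2] / np.cos(np.radians(phase)) if abs(
        np.cos(np.radians(phase))
    ) > 1e-12 else num / (
        2.0 * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    ) / np.sin(np.radians(phase))
    if amplitude < 0:
        amplitude = -amplitude
        phase += 180.0
    phase %= 360.0
    sector = int(np.floor(phase / 18.0 + 0.5)) % 20
    return PuckerState(
        phase=float(phase),
        amplitude=float(amplitude),
        conformer=CONFORMER_WHEEL[sector],
    )


def pucker(coords_by_name: dict[str, np.ndarray]) -> PuckerState:
    """Pucker state from a residue's atom name -> coordinate mapping."""
    missing = [n for n in RING_ATOMS if n not in coords_by_name]
    if missing:
        raise GeometryError(f"missing sugar ring atoms: {missing}")
    ring = np.array([coords_by_name[n] for n in RING_ATOMS], dtype=float)
    return pucker_from_torsions(ring_torsions(ring))


# ---------------------------------------------------------------------------
# Backbone / glycosidic torsions
# ---------------------------------------------------------------------------

#: Torsion definitions as (residue offset, atom name) quadruples.
TORSION_DEFS: dict[str, tuple[tuple[int, str], ...]] = {
    "alpha": ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta": ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma": ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}

#: The subset of torsions analysed in the ASO-hairpin study
#: (beta and delta are computed alongside for completeness).
STUDY_TORSIONS = ("chi", "alpha", "gamma", "epsilon", "zeta")

CHI_DEFS = {
    "purine": (("O4'", "C1'", "N9", "C4")),
    "pyrimidine": (("O4'", "C1'", "N1", "C2")),
}
PURINES = ("A", "G")


def chi_atoms(nucleotide: str) -> tuple[str, str, str, str]:
    return CHI_DEFS["purine" if nucleotide in PURINES else "pyrimidine"]


def residue_torsions(
    topology: StructureTopology, coords: np.ndarray, residue_index: int
) -> dict[str, float]:
    """All defined torsions (deg) of one residue in one frame.

    A torsion is reported only when all four defining atoms exist (terminal
    residues lack alpha or epsilon/zeta, for instance).
    """
    out: dict[str, float] = {}
    chain = topology.residue(residue_index).chain_label
    residue_ids = {r.residue_index for r in topology.residues}
    for name, spec in TORSION_DEFS.items():
        pts = []
        for offset, atom in spec:
            resi = residue_index + offset
            # covalent continuation only within the same chain
            if (
                resi not in residue_ids
                or topology.residue(resi).chain_label != chain
                or not topology.has_atom(resi, atom)
            ):
                pts = None
                break
            pts.append(coords[topology.atom_index(resi, atom)])
        if pts is not None:
            out[name] = dihedral(*pts)
    nt = topology.residue(residue_index).nucleotide
    chi_quad = chi_atoms(nt)
    if all(topology.has_atom(residue_index, a) for a in chi_quad):
        pts = [coords[topology.atom_index(residue_index, a)] for a in chi_quad]
        out["chi"] = dihedral(*pts)
    return out


def residue_pucker(
    topology: StructureTopology, coords: np.ndarray, residue_index: int
) -> PuckerState:
    mapping = {}
    for name in RING_ATOMS:
        if topology.has_atom(residue_index, name):
            mapping[name] = coords[topology.atom_index(residue_index, name)]
    return pucker(mapping)


# ---------------------------------------------------------------------------
# Base reference frames
# ---------------------------------------------------------------------------

#: Ring atoms used for the frame fit.
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: Watson-Crick edge anchors whose midpoint seeds the frame origin.
_WC_ANCHORS = {"A": ("N1", "N6"), "G": ("N1", "O6"),
               "C": ("N3", "N4"), "U": ("N3", "O4")}

#: Per-nucleotide pose calibration (rotation, origin shift) applied to the
#: raw edge-anchor frame so that the two frames of an idealized
#: Watson-Crick pair coincide after the strand-II y/z flip -- the defining
#: property of a standard base reference frame.  Calibrated once on
#: idealized A-U and G-C pair geometry; the pyrimidine rotation is the
#: near-180-degree in-plane flip that reconciles the ring-walk normals of
#: the two paired bases.
_FRAME_CALIBRATION: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "A": (np.eye(3), np.array([0.930465, 1.078774, 0.000084])),
    "G": (np.eye(3), np.array([1.001737, 1.011829, 0.009516])),
    "U": (
        np.array(
            [
                [-0.163505, 0.986542, -0.000803],
                [0.986541, 0.163506, 0.001346],
                [0.001459, -0.000572, -0.999999],
            ]
        ),
        np.array([1.216392, -0.741556, -0.002059]),
    ),
    "C": (
        np.array(
            [
                [-0.148245, 0.988944, 0.003616],
                [0.988936, 0.148262, -0.004839],
                [-0.005321, 0.002858, -0.999982],
            ]
        ),
        np.array([1.149179, -0.840684, -0.001294]),
    ),
}


def base_ring_atoms(nucleotide: str) -> tuple[str, ...]:
    return _PURINE_RING if nucleotide in PURINES else _PYRIMIDINE_RING


@lru_cache(maxsize=None)
def _canonical_base_template(nucleotide: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Idealized base heavy atoms in the canonical pose.

    Canonical pose: frame origin at the midpoint of the WC-edge anchors,
    x pointing from the six-ring centroid through the origin (the WC edge
    side), z along the base-plane normal (right-handed with the ring
    traversal), y completing the frame.  Derived from the chemical
    component dictionary's ideal coordinates.
    """
    import biotite.structure.info as struc_info

    res = struc_info.residue(nucleotide)
    names = [str(n) for n in res.atom_name]
    ring_names = base_ring_atoms(nucleotide)
    base_names = tuple(
        n for n in names
        if n in ring_names or n in _WC_ANCHORS[nucleotide]
        or n in ("N2", "O2", "O4", "N4", "N6", "O6")
    )
    idx = {n: names.index(n) for n in base_names}
    coords = np.array([res.coord[idx[n]] for n in base_names], dtype=float)

    ring = np.array([res.coord[names.index(n)] for n in ring_names])
    six_ring = ring[-6:] if nucleotide in PURINES else ring
    centroid = six_ring.mean(axis=0)
    # plane normal by SVD; orient right-handed with ring traversal
    _, _, vt = np.linalg.svd(ring - ring.mean(axis=0))
    z = vt[2]
    walk = np.cross(ring[1] - ring[0], ring[2] - ring[1])
    if np.dot(z, walk) < 0:
        z = -z
    a1, a2 = _WC_ANCHORS[nucleotide]
    origin = 0.5 * (res.coord[names.index(a1)] + res.coord[names.index(a2)])
    x = origin - centroid
    x -= np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    rot = np.stack([x, y, z], axis=1)  # columns = axes
    canonical = (coords - origin) @ rot
    corr, delta = _FRAME_CALIBRATION[nucleotide]
    corr = Rotation.from_matrix(corr).as_matrix()  # re-orthonormalize
    canonical = (canonical - delta) @ corr
    return base_names, canonical


@dataclass(frozen=True)
class BaseFrame:
    """Right-handed orthonormal frame (columns of ``rotation``) + origin."""

    rotation: np.ndarray
    origin: np.ndarray

    def flipped(self) -> "BaseFrame":
        """Strand-II convention: y and z axes negated."""
        return BaseFrame(self.rotation @ np.diag([1.0, -1.0, -1.0]), self.origin)


def base_frame(
    nucleotide: str, coords_by_name: dict[str, np.ndarray]
) -> BaseFrame:
    """Fit the canonical base template to observed base atoms.

    Returns the rigid transform (proper rotation + origin) that carries the
    canonical template onto the observed base in the least-squares sense.
    A template in canonical pose therefore yields the identity frame.
    """
    names, template = _canonical_base_template(nucleotide)
    pairs = [(n, coords_by_name[n]) for n in names if n in coords_by_name]
    ring_names = base_ring_atoms(nucleotide)
    present_ring = [n for n, _ in pairs if n in ring_names]
    if len(present_ring) < len(ring_names):
        raise GeometryError(
            f"missing base ring atoms for {nucleotide}: "
            f"{sorted(set(ring_names) - set(present_ring))}"
        )
    obs = np.array([c for _, c in pairs], dtype=float)
    tmpl = np.array(
        [template[names.index(n)] for n, _ in pairs], dtype=float
    )
    obs_c = obs.mean(axis=0)
    tmpl_c = tmpl.mean(axis=0)
    rot, _ = Rotation.align_vectors(obs - obs_c, tmpl - tmpl_c)
    r = rot.as_matrix()
    origin = obs_c - r @ tmpl_c
    return BaseFrame(r, origin)


def residue_base_frame(
    topology: StructureTopology, coords: np.ndarray, residue_index: int
) -> BaseFrame:
    res = topology.residue(residue_index)
    mapping = {
        topology.atoms[i].atom_name: coords[i]
        for i in topology.residue_atom_indices(residue_index)
    }
    return base_frame(res.nucleotide, mapping)


# ---------------------------------------------------------------------------
# Base-pair and step parameters (mid-frame algebra)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BpStepParams:
    """Translational (Angstrom) and rotational (degree) helicoidal params.

    For an intra-base-pair computation the fields read (shear, stretch,
    stagger, buckle, propeller, opening); for a step they read (shift,
    slide, rise, tilt, roll, twist).
    """

    translation: tuple[float, float, float]
    rotation: tuple[float, float, float]

    @property
    def shear(self): return self.translation[0]
    @property
    def stretch(self): return self.translation[1]
    @property
    def stagger(self): return self.translation[2]
    @property
    def buckle(self): return self.rotation[0]
    @property
    def propeller(self): return self.rotation[1]
    @property
    def opening(self): return self.rotation[2]
    shift = shear
    slide = stretch
    rise = stagger
    tilt = buckle
    roll = propeller
    twist = opening


def _check_orthonormal(r: np.ndarray) -> None:
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
        raise GeometryError("frame rotation must be proper orthonormal")


def mid_frame(f1: BaseFrame, f2: BaseFrame) -> BaseFrame:
    """Average of two frames: half-way rotation and mean origin."""
    r1 = Rotation.from_matrix(f1.rotation)
    r2 = Rotation.from_matrix(f2.rotation)
    rel = r1.inv() * r2
    rm = r1 * Rotation.from_rotvec(0.5 * rel.as_rotvec())
    return BaseFrame(rm.as_matrix(), 0.5 * (f1.origin + f2.origin))


def frame_step_params(f1: BaseFrame, f2: BaseFrame) -> BpStepParams:
    """Relative rotation/translation of two frames in their mid-frame.

    The translation components are the mid-frame coordinates of the origin
    displacement; the rotation components are the mid-frame components of
    the rotation vector carrying frame 1 onto frame 2 (degrees).
    """
    _check_orthonormal(f1.rotation)
    _check_orthonormal(f2.rotation)
    fm = mid_frame(f1, f2)
    trans = fm.rotation.T @ (f2.origin - f1.origin)
    q = Rotation.from_matrix(f2.rotation @ f1.rotation.T)  # world rotation
    rotvec = fm.rotation.T @ q.as_rotvec(degrees=True)
    return BpStepParams(tuple(float(v) for v in trans),
                        tuple(float(v) for v in rotvec))


def bp_params(frame_strand1: BaseFrame, frame_strand2: BaseFrame) -> BpStepParams:
    """Intra-base-pair parameters: the strand-II frame is y/z-flipped so
    both z axes point along the helix before the mid-frame algebra."""
    return frame_step_params(frame_strand2.flipped(), frame_strand1)


def bp_mid_frame(frame_strand1: BaseFrame, frame_strand2: BaseFrame) -> BaseFrame:
    return mid_frame(frame_strand2.flipped(), frame_strand1)


def step_params(bp_frame_1: BaseFrame, bp_frame_2: BaseFrame) -> BpStepParams:
    """Base-pair step parameters between consecutive pair mid-frames."""
    return frame_step_params(bp_frame_1, bp_frame_2)


# ---------------------------------------------------------------------------
# Ensemble-level profiles
# ---------------------------------------------------------------------------

def geometry_profiles(
    ensemble: Ensemble,
    pairing: list[tuple[int, int]] | None = None,
    window: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-frame torsion, pucker, base-pair and step parameter tables.

    ``pairing`` lists (strand-I residue, strand-II residue) base pairs in
    helical order; step parameters are computed between consecutive listed
    pairs.  Long-format data frames are returned under the keys
    ``torsions``, ``puckers``, ``bp_params`` and ``step_params``.
    """
    top = ensemble.topology
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if hi <= lo:
        raise GeometryError("empty analysis window")
    if pairing:
        for i, j in pairing:
            for resi in (i, j):
                if resi not in {r.residue_index for r in top.residues}:
                    raise GeometryError(
                        f"pairing references missing residue {resi}"
                    )

    torsion_rows, pucker_rows, bp_rows, step_rows = [], [], [], []
    for f in range(lo, hi):
        coords = ensemble.frames[f]
        for res in top.residues:
            for name, value in residue_torsions(
                top, coords, res.residue_index
            ).items():
                torsion_rows.append(
                    (f, res.residue_index, name, value, name in STUDY_TORSIONS)
                )
            ps = residue_pucker(top, coords, res.residue_index)
            pucker_rows.append(
                (f, res.residue_index, ps.phase, ps.amplitude, ps.conformer)
            )
        if pairing:
            mids = []
            for i, j in pairing:
                f1 = residue_base_frame(top, coords, i)
                f2 = residue_base_frame(top, coords, j)
                p = bp_params(f1, f2)
                mids.append(bp_mid_frame(f1, f2))
                bp_rows.append((f, i, j) + p.translation + p.rotation)
            for k in range(len(mids) - 1):
                sp = step_params(mids[k], mids[k + 1])
                step_rows.append(
                    (f, f"{pairing[k]}-{pairing[k + 1]}")
                    + sp.translation + sp.rotation
                )

    out = {
        "torsions": pd.DataFrame(
            torsion_rows,
            columns=["frame", "residue", "torsion", "value_deg", "in_study_set"],
        ),
        "puckers": pd.DataFrame(
            pucker_rows,
            columns=["frame", "residue", "phase_deg", "amplitude_deg",
                     "conformer"],
        ),
    }
    out["bp_params"] = pd.DataFrame(
        bp_rows,
        columns=["frame", "residue_i", "residue_j", "shear", "stretch",
                 "stagger", "buckle", "propeller", "opening"],
    )
    out["step_params"] = pd.DataFrame(
        step_rows,
        columns=["frame", "step", "shift", "slide", "rise", "tilt", "roll",
                 "twist"],
    )
    return out
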