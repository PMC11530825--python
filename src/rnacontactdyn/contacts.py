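"""Dynamic residue-pair contact analysis.

Per-frame typed atom contacts (hydrogen bond, salt bridge, apolar) are
aggregated to residue pairs with unit weight per contact regardless of type
(the energetic cost of the different contact classes varies too much for a
meaningful common scale, so each qualifying atom pair contributes exactly
1 to the pair's strength).  A contact is *specific* when both atoms are
base-role, *nonspecific* when at least one backbone atom is involved.
Residue-pair series carry occupancies (fraction of frames with at least
one contact) and are filtered at a strict >10% occupancy threshold by
default.

Default geometric criteria follow the common trajectory-analysis
conventions: donor-acceptor heavy-atom distance <= 3.0 A with a
donor-H...acceptor angle >= 135 deg for hydrogen bonds (distance-only when
the topology carries no hydrogens), 4.0 A between opposite formally
charged groups for salt bridges, and 4.0 A carbon-carbon for apolar
contacts.  All criteria are configurable.  When the same atom pair
qualifies as several types it is reported once with precedence
hbond > salt_bridge > apolar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .topology import Ensemble, StructureTopology


class ContactError(ValueError):
    """Raised for invalid contact-analysis input."""


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for the three contact types."""

    hbond_heavy_dist_max: float = 3.0   # A, donor heavy ... acceptor
    hbond_angle_min: float = 135.0      # deg, donor-H...acceptor
    salt_bridge_dist_max: float = 4.0   # A, charged-group heavy atoms
    apolar_dist_max: float = 4.0        # A, carbon-carbon

    def __post_init__(self):
        for name in ("hbond_heavy_dist_max", "salt_bridge_dist_max",
                     "apolar_dist_max"):
            if getattr(self, name) <= 0:
                raise ContactError(f"{name} must be > 0")
        if not 0.0 < self.hbond_angle_min <= 180.0:
            raise ContactError("hbond_angle_min must be in (0, 180]")


@dataclass(frozen=True)
class ContactRecord:
    """One atom-level contact in one frame."""

    frame_index: int
    residue_pair: tuple[int, int]       # i < j
    contact_type: str                   # hbond | salt_bridge | apolar
    atom_pair: tuple[int, int]          # topology atom indices
    specificity: str                    # specific | nonspecific


@dataclass
class ContactSeries:
    """Time series of one residue pair's contacts over a frame window."""

    residue_pair: tuple[int, int]
    presence: np.ndarray                # bool per window frame
    strength: np.ndarray                # int contact count per frame
    specific_strength: np.ndarray
    nonspecific_strength: np.ndarray
    window: tuple[int, int]

    @property
    def occupancy(self) -> float:
        return float(self.presence.mean())

    @property
    def mean_strength(self) -> float:
        """Average contact count over the frames where the pair is in
        contact (0 when it never is)."""
        n = int(self.presence.sum())
        return float(self.strength.sum() / n) if n else 0.0

    def mean_strength_mode(self, mode: str) -> float:
        n = int(self.presence.sum())
        if n == 0:
            return 0.0
        arr = {
            "all": self.strength,
            "specific": self.specific_strength,
            "nonspecific": self.nonspecific_strength,
        }[mode]
        return float(arr.sum() / n)


def _neighbour_excluded(top: StructureTopology, ri: int, rj: int) -> bool:
    """Covalent neighbours (|i-j| <= 1 within one molecule) are not
    contacts; a residue never contacts itself."""
    if ri == rj:
        return True
    return top.molecule_of(ri) == top.molecule_of(rj) and abs(ri - rj) <= 1


def detect_contacts(
    frame: np.ndarray,
    topology: StructureTopology,
    criteria: ContactCriteria = ContactCriteria(),
    frame_index: int = 0,
) -> list[ContactRecord]:
    """All typed atom contacts in one frame.

    Hydrogen bonds require a donor-heavy/acceptor distance within cutoff
    and, when the donor's hydrogens are present in the topology, a
    donor-H...acceptor angle above the threshold; salt bridges pair
    anionic with cationic group atoms; apolar contacts pair carbon atoms.
    Each qualifying atom pair is reported once, with type precedence
    hbond > salt_bridge > apolar.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ContactError(
            f"frame has shape {frame.shape}, topology expects "
            f"({topology.n_atoms}, 3)"
        )
    resi = topology.residue_indices
    typed: dict[tuple[int, int], str] = {}

    # -- hydrogen bonds ---------------------------------------------------
    donor_map = topology.donor_map()
    acceptor_map = topology.acceptor_map()
    donors = [
        (d, hs) for per_res in donor_map.values() for d, hs in per_res.items()
    ]
    acceptors = [a for per_res in acceptor_map.values() for a in per_res]
    if donors and acceptors:
        d_idx = np.array([d for d, _ in donors])
        a_idx = np.array(acceptors)
        dist = cdist(frame[d_idx], frame[a_idx])
        for di, ai in zip(*np.nonzero(dist <= criteria.hbond_heavy_dist_max)):
            d_atom, a_atom = int(d_idx[di]), int(a_idx[ai])
            if _neighbour_excluded(topology, resi[d_atom], resi[a_atom]):
                continue
            hydrogens = donors[di][1]
            if hydrogens:
                ok = False
                for h in hydrogens:
                    v1 = frame[d_atom] - frame[h]
                    v2 = frame[a_atom] - frame[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if angle >= criteria.hbond_angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            key = (min(d_atom, a_atom), max(d_atom, a_atom))
            typed.setdefault(key, "hbond")

    # -- salt bridges -----------------------------------------------------
    an = topology.anionic_indices()
    cat = topology.cationic_indices()
    if an.size and cat.size:
        dist = cdist(frame[an], frame[cat])
        for ii, jj in zip(*np.nonzero(dist <= criteria.salt_bridge_dist_max)):
            i, j = int(an[ii]), int(cat[jj])
            if _neighbour_excluded(topology, resi[i], resi[j]):
                continue
            key = (min(i, j), max(i, j))
            typed.setdefault(key, "salt_bridge")

    # -- apolar -----------------------------------------------------------
    ap = topology.apolar_indices()
    if ap.size:
        dist = cdist(frame[ap], frame[ap])
        iu, ju = np.nonzero(np.triu(dist <= criteria.apolar_dist_max, k=1))
        for ii, jj in zip(iu, ju):
            i, j = int(ap[ii]), int(ap[jj])
            if _neighbour_excluded(topology, resi[i], resi[j]):
                continue
            key = (min(i, j), max(i, j))
            typed.setdefault(key, "apolar")

    records = []
    roles = topology.roles
    for (i, j), ctype in sorted(typed.items()):
        ri, rj = int(resi[i]), int(resi[j])
        pair = (min(ri, rj), max(ri, rj))
        spec = "specific" if roles[i] == "base" and roles[j] == "base" \
            else "nonspecific"
        records.append(
            ContactRecord(frame_index, pair, ctype, (i, j), spec)
        )
    return records


def contact_strength(
    records: Iterable[ContactRecord], residue_pair: tuple[int, int]
) -> int:
    """Unit-weight strength: the number of contact records for the pair
    (every contact counts 1 regardless of type)."""
    pair = (min(residue_pair), max(residue_pair))
    return sum(1 for r in records if r.residue_pair == pair)


def hbond_mode(topology: StructureTopology) -> str:
    """``"distance_and_angle"`` when donor hydrogens exist, else the
    degraded ``"distance_only"`` criterion (flagged in outputs)."""
    for per_res in topology.donor_map().values():
        for hydrogens in per_res.values():
            if hydrogens:
                return "distance_and_angle"
    return "distance_only"


def build_series(
    ensemble: Ensemble,
    criteria: ContactCriteria = ContactCriteria(),
    window: tuple[int, int] | None = None,
) -> list[ContactSeries]:
    """One :class:`ContactSeries` per residue pair ever in contact within
    the frame window (default: all frames)."""
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if not 0 <= lo < hi <= ensemble.n_frames:
        raise ContactError(f"empty or out-of-range window ({lo}, {hi})")
    n = hi - lo
    per_pair: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for f in range(lo, hi):
        records = detect_contacts(ensemble.frames[f], ensemble.topology,
                                  criteria, frame_index=f)
        for r in records:
            slot = per_pair.setdefault(
                r.residue_pair,
                {
                    "strength": np.zeros(n, dtype=int),
                    "specific": np.zeros(n, dtype=int),
                    "nonspecific": np.zeros(n, dtype=int),
                },
            )
            slot["strength"][f - lo] += 1
            key = "specific" if r.specificity == "specific" else "nonspecific"
            slot[key][f - lo] += 1
    out = []
    for pair in sorted(per_pair):
        slot = per_pair[pair]
        out.append(
            ContactSeries(
                residue_pair=pair,
                presence=slot["strength"] > 0,
                strength=slot["strength"],
                specific_strength=slot["specific"],
                nonspecific_strength=slot["nonspecific"],
                window=(lo, hi),
            )
        )
    return out


def occupancy_filter(
    series_list: Sequence[ContactSeries], threshold: float = 0.10
) -> list[ContactSeries]:
    """Keep series whose occupancy strictly exceeds the threshold
    (a pair present exactly 10% of the time is dropped)."""
    if not 0.0 < threshold < 1.0:
        raise ContactError("threshold must be in (0, 1)")
    return [s for s in series_list if s.occupancy > threshold]


def contact_map(
    series_list: Sequence[ContactSeries], mode: str = "all"
) -> pd.DataFrame:
    """Symmetric residue x residue matrix of mean contact strengths.

    ``mode`` selects specific, nonspecific or all contributions; the
    specific and nonspecific matrices add up to the full one entry-wise.
    """
    if mode not in ("specific", "nonspecific", "all"):
        raise ContactError(f"unknown contact-map mode {mode!r}")
    residues = sorted({r for s in series_list for r in s.residue_pair})
    mat = pd.DataFrame(0.0, index=residues, columns=residues)
    for s in series_list:
        v = s.mean_strength_mode(mode)
        if v:
            i, j = s.residue_pair
            mat.loc[i, j] = v
            mat.loc[j, i] = v
    return mat


def contact_evolution(
    series_list: Sequence[ContactSeries], n_blocks: int
) -> pd.DataFrame:
    """Per-block occupancy and mean strength for each pair.

    The window is split into ``n_blocks`` near-equal consecutive frame
    blocks, resolving how contacts appear, vanish or rearrange over time.
    """
    if n_blocks < 1:
        raise ContactError("n_blocks must be >= 1")
    rows = []
    for s in series_list:
        n = len(s.presence)
        if n_blocks > n:
            raise ContactError("more blocks than frames in window")
        bounds = np.array_split(np.arange(n), n_blocks)
        for b, idx in enumerate(bounds):
            pres = s.presence[idx]
            stren = s.strength[idx]
            npres = int(pres.sum())
            rows.append(
                {
                    "residue_i": s.residue_pair[0],
                    "residue_j": s.residue_pair[1],
                    "block": b,
                    "occupancy": float(pres.mean()),
                    "mean_strength": float(stren.sum() / npres) if npres else 0.0,
                }
            )
    return pd.DataFrame(rows)
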