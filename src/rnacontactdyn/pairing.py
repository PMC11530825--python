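"""Base-pair and base-triple motif detection.

Pairs are detected from base-base hydrogen bonds and classified by the
nucleobase edges involved: Watson-Crick, Hoogsteen (the purine N7 face) or
sugar.  A base simultaneously hydrogen-bonded to two partners -- the
central element of motifs like the U.A-U triple -- is reported as a base
triple with the edge usage of each interaction.  Pair persistence over the
trajectory exposes terminal fraying as a declining presence fraction.

Every hydrogen-bond-capable base atom of A, C, G and U is assigned to
exactly one edge class (a design simplification: atoms like the adenine
amine chemically serve both the WC and Hoogsteen faces; here each atom
gets its primary edge and the pair-level classification weights ring
atoms double, which recovers the conventional pair categories).

Pair detection uses a more permissive, heavy-atom-only hydrogen-bond
criterion (3.7 A, no angle term) than the general contact analysis -- the
usual convention for base-pair annotation; minimum H-bond counts default
to 2 for Watson-Crick and 1 for Hoogsteen pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactCriteria, detect_contacts
from .topology import Ensemble, StructureTopology


class PairingError(ValueError):
    """Raised for invalid pairing-analysis input."""


#: Edge class of every H-bond-capable base atom (partition per nucleotide).
EDGE_ASSIGNMENT: dict[str, dict[str, str]] = {
    "A": {"N1": "WC", "N6": "WC", "N7": "hoogsteen", "N3": "sugar"},
    "G": {"N1": "WC", "N2": "WC", "O6": "WC", "N7": "hoogsteen", "N3": "sugar"},
    "C": {"N3": "WC", "N4": "WC", "O2": "sugar"},
    "U": {"N3": "WC", "O4": "WC", "O2": "sugar"},
}

#: Ring heteroatoms dominate the edge vote over exocyclic substituents.
_RING_VOTE_ATOMS = frozenset({"N1", "N3", "N7"})


@dataclass(frozen=True)
class PairingCriteria:
    """Geometric and count thresholds for base-pair detection.

    The default is a heavy-atom, distance-only hydrogen-bond criterion
    (``hbond_angle_min=0``), the usual convention of base-pair annotation
    tools, which also makes detection robust to thermal scatter of the
    hydrogens; set an angle to enforce donor-H...acceptor linearity.
    """

    hbond_dist_max: float = 3.7       # A, donor-heavy to acceptor
    hbond_angle_min: float = 0.0      # deg; 0 = distance-only
    min_hbonds_wc: int = 2
    min_hbonds_hoogsteen: int = 1
    min_hbonds_other: int = 2


@dataclass(frozen=True)
class BasePair:
    """A detected base-base interaction with its edge classification."""

    residue_pair: tuple[int, int]     # i < j
    n_hbonds: int
    edges: tuple[str, str]            # edge of residue i, edge of residue j
    category: str                     # watson_crick | hoogsteen | other
    hbond_atoms: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TripleBp:
    """One base hydrogen-bonded to two partners on non-identical edges."""

    central: int
    partners: tuple[int, int]
    edges: dict[int, tuple[str, str]]  # partner -> (central edge, partner edge)
    closed: bool                       # partners also pair with each other


def _edge_vote(nucleotide: str, atom_names: Iterable[str]) -> str:
    """Edge presented by a base given its participating atoms: weighted
    vote with ring heteroatoms counting double; ties resolve to WC."""
    table = EDGE_ASSIGNMENT[nucleotide]
    votes: dict[str, int] = {}
    for name in atom_names:
        if name not in table:
            raise PairingError(
                f"atom {name!r} of {nucleotide} lacks an edge assignment"
            )
        w = 2 if name in _RING_VOTE_ATOMS else 1
        votes[table[name]] = votes.get(table[name], 0) + w
    best = max(votes.values())
    winners = [e for e, v in votes.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    for preferred in ("WC", "hoogsteen", "sugar"):
        if preferred in winners:
            return preferred
    return winners[0]


def detect_base_pairs(
    frame: np.ndarray,
    topology: StructureTopology,
    criteria: PairingCriteria = PairingCriteria(),
    edge_assignment: dict[str, dict[str, str]] | None = None,
) -> list[BasePair]:
    """Base pairs in one frame from base-base hydrogen bonds.

    A pair is reported when its base-base H-bond count reaches the
    category threshold; the category comes from the edge classes of the
    participating atoms on each side.
    """
    table = EDGE_ASSIGNMENT if edge_assignment is None else edge_assignment
    for res in topology.residues:
        if res.nucleotide not in table:
            raise PairingError(
                f"nucleotide {res.nucleotide!r} lacks an edge assignment"
            )
    contact_criteria = ContactCriteria(
        hbond_heavy_dist_max=criteria.hbond_dist_max,
        hbond_angle_min=max(criteria.hbond_angle_min, 1e-9),
    )
    records = detect_contacts(frame, topology, contact_criteria)
    per_pair: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r in records:
        if r.contact_type != "hbond" or r.specificity != "specific":
            continue
        per_pair.setdefault(r.residue_pair, []).append(r.atom_pair)

    pairs = []
    names = topology.atom_names
    resi = topology.residue_indices
    for (ri, rj), atom_pairs in sorted(per_pair.items()):
        atoms_i = [
            names[a] if resi[a] == ri else names[b]
            for a, b in atom_pairs
        ]
        atoms_j = [
            names[a] if resi[a] == rj else names[b]
            for a, b in atom_pairs
        ]
        nt_i = topology.residue(ri).nucleotide
        nt_j = topology.residue(rj).nucleotide
        edge_i = _edge_vote(nt_i, atoms_i)
        edge_j = _edge_vote(nt_j, atoms_j)
        n = len(atom_pairs)
        if edge_i == "WC" and edge_j == "WC":
            category, minimum = "watson_crick", criteria.min_hbonds_wc
        elif "hoogsteen" in (edge_i, edge_j):
            category, minimum = "hoogsteen", criteria.min_hbonds_hoogsteen
        else:
            category, minimum = "other", criteria.min_hbonds_other
        if n < minimum:
            continue
        pairs.append(
            BasePair(
                residue_pair=(ri, rj),
                n_hbonds=n,
                edges=(edge_i, edge_j),
                category=category,
                hbond_atoms=tuple(atom_pairs),
            )
        )
    return pairs


def detect_triples(base_pairs: Sequence[BasePair]) -> list[TripleBp]:
    """Base triples: any residue in two or more pairs.

    Output is independent of input ordering; every reported triple's pairs
    exist in the input.  ``closed`` marks triples whose two partners also
    pair with each other (both open and closed triples are reported).
    """
    by_residue: dict[int, list[BasePair]] = {}
    for bp in base_pairs:
        for r in bp.residue_pair:
            by_residue.setdefault(r, []).append(bp)
    pair_keys = {bp.residue_pair for bp in base_pairs}
    triples = []
    seen = set()
    for central in sorted(by_residue):
        bps = by_residue[central]
        if len(bps) < 2:
            continue
        from itertools import combinations

        for bp1, bp2 in combinations(
            sorted(bps, key=lambda b: b.residue_pair), 2
        ):
            p1 = [r for r in bp1.residue_pair if r != central][0]
            p2 = [r for r in bp2.residue_pair if r != central][0]
            partners = tuple(sorted((p1, p2)))
            key = (central, partners)
            if key in seen:
                continue
            seen.add(key)
            edges = {}
            for bp, partner in ((bp1, p1), (bp2, p2)):
                if bp.residue_pair[0] == central:
                    edges[partner] = (bp.edges[0], bp.edges[1])
                else:
                    edges[partner] = (bp.edges[1], bp.edges[0])
            closed = tuple(sorted((p1, p2))) in pair_keys
            triples.append(
                TripleBp(central=central, partners=partners, edges=edges,
                         closed=closed)
            )
    return triples


def pair_persistence(
    ensemble: Ensemble,
    criteria: PairingCriteria = PairingCriteria(),
    n_blocks: int = 2,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Presence fraction and per-block series for every detected pair.

    Declining presence of terminal pairs is the signature of base fraying;
    pairs whose first-to-last block fraction drops by more than 0.5 are
    flagged as fraying candidates.
    """
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if not 0 <= lo < hi <= ensemble.n_frames:
        raise PairingError(f"empty or out-of-range window ({lo}, {hi})")
    n = hi - lo
    if n_blocks < 1 or n_blocks > n:
        raise PairingError("invalid block count")
    presence: dict[tuple[int, int], np.ndarray] = {}
    for f in range(lo, hi):
        for bp in detect_base_pairs(ensemble.frames[f], ensemble.topology,
                                    criteria):
            arr = presence.setdefault(bp.residue_pair, np.zeros(n, dtype=bool))
            arr[f - lo] = True
    rows = []
    for pair in sorted(presence):
        arr = presence[pair]
        blocks = [float(chunk.mean()) for chunk in np.array_split(arr, n_blocks)]
        rows.append(
            {
                "residue_i": pair[0],
                "residue_j": pair[1],
                "persistence": float(arr.mean()),
                **{f"block_{b}": v for b, v in enumerate(blocks)},
                "fraying_candidate": blocks[0] - blocks[-1] > 0.5,
            }
        )
    return pd.DataFrame(rows)
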