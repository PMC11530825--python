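"""Structure model: atom/residue records, role partition, ensembles, PDB I/O.

Every atom of an RNA residue is assigned exactly one *role*, ``base`` or
``backbone``.  The phosphate and the full sugar (including O2'/HO2', treated
as a sugar substituent) are backbone; all ring and exocyclic base atoms and
their hydrogens are base.  This dichotomy drives the specific/nonspecific
contact classification and the four-group energy decomposition downstream.

Residue indices follow a configurable numbering profile; the default is the
ASO-hairpin scheme in which the oligonucleotide occupies residues 1-10 and
the hairpin residues 11-42, split into strand 1 (11-26) and strand 2 (27-42).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "U")

#: Sugar + phosphate atoms (PDB v3 names).  O2'/HO2' are counted as backbone.
BACKBONE_ATOMS = frozenset(
    {
        "P", "OP1", "OP2", "OP3",
        "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
        "HO2'", "HO3'", "HO5'", "HOP2", "HOP3",
        "H5'", "H5''", "H4'", "H3'", "H2'", "H1'",
    }
)

#: Base ring + exocyclic atoms and base hydrogens across A, C, G, U.
BASE_ATOMS = frozenset(
    {
        "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
        "N6", "O6", "N2", "N4", "O2", "O4",
        "H1", "H2", "H3", "H5", "H6", "H8",
        "H21", "H22", "H41", "H42", "H61", "H62",
    }
)

#: Hydrogen-bond donor heavy atoms of the bases, with their hydrogen names.
BASE_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "U": {"N3": ("H3",)},
}

#: Hydrogen-bond acceptor heavy atoms of the bases.
BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N7", "N3"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}

BACKBONE_DONORS: dict[str, tuple[str, ...]] = {"O2'": ("HO2'",)}
BACKBONE_ACCEPTORS: tuple[str, ...] = ("OP1", "OP2", "O5'", "O3'", "O4'", "O2'")

#: Formally charged atom-name groups.  RNA has anionic phosphate oxygens;
#: there is no cationic group in an unmodified RNA-RNA complex, so the
#: cation set defaults to empty (salt-bridge detection then never fires
#: unless the user supplies cationic atoms, e.g. for modified backbones).
ANIONIC_ATOMS = frozenset({"OP1", "OP2", "OP3"})
CATIONIC_ATOMS: frozenset[str] = frozenset()

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


class TopologyError(ValueError):
    """Raised for inconsistent or unsupported topology input."""


class PDBParseError(TopologyError):
    """Raised when a multi-model PDB stream violates the ensemble contract."""


class UnsupportedResidueError(TopologyError):
    """Raised for residues outside the supported A/C/G/U alphabet."""


class ClassificationError(TopologyError):
    """Raised when an atom name cannot be assigned a base/backbone role."""


class ParameterError(TopologyError):
    """Raised when nonbonded parameters are missing for some atoms."""


def classify_atom_role(atom_name: str, *, o2prime_as_base: bool = False) -> str:
    """Return ``"base"`` or ``"backbone"`` for a PDB-convention atom name.

    The partition is total and exclusive over standard RNA residues.  The
    O2'/HO2' hydroxyl is backbone by default (sugar substituent); set
    ``o2prime_as_base=True`` to move it to the base class.
    """
    if o2prime_as_base and atom_name in ("O2'", "HO2'"):
        return "base"
    if atom_name in BACKBONE_ATOMS:
        return "backbone"
    if atom_name in BASE_ATOMS:
        return "base"
    raise ClassificationError(
        f"cannot classify atom name {atom_name!r} as base or backbone"
    )


def classify_atom_roles(
    topology: "StructureTopology", *, o2prime_as_base: bool = False
) -> dict[int, str]:
    """Role of every atom in ``topology`` (atom index -> role)."""
    return {
        i: classify_atom_role(a.atom_name, o2prime_as_base=o2prime_as_base)
        for i, a in enumerate(topology.atoms)
    }


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, role, and (optional) nonbonded parameters."""

    atom_name: str
    element: str
    role: str                      # "base" | "backbone"
    residue_index: int             # 1-based, contiguous per complex
    is_heavy: bool
    charge: float = np.nan         # partial charge, e
    lj_sigma: float = np.nan       # Lennard-Jones sigma, Angstrom
    lj_epsilon: float = np.nan     # Lennard-Jones epsilon, kcal/mol


@dataclass(frozen=True)
class ResidueRecord:
    """One nucleotide with its chain and region labels."""

    residue_index: int
    nucleotide: str                # A | C | G | U
    chain_label: str = "A"
    region: str | None = None      # aso | hairpin_strand1 | hairpin_strand2


@dataclass(frozen=True)
class RegionScheme:
    """Residue-index to region mapping.

    The default is the ASO-hairpin profile: residues 1-10 are the
    oligonucleotide, 11-26 hairpin strand 1 and 27-42 hairpin strand 2.
    """

    aso: tuple[int, int] = (1, 10)
    hairpin_strand1: tuple[int, int] = (11, 26)
    hairpin_strand2: tuple[int, int] = (27, 42)

    def region_of(self, residue_index: int) -> str | None:
        for name in ("aso", "hairpin_strand1", "hairpin_strand2"):
            lo, hi = getattr(self, name)
            if lo <= residue_index <= hi:
                return name
        return None

    def validate(self) -> list[str]:
        errors = []
        ranges = {
            name: getattr(self, name)
            for name in ("aso", "hairpin_strand1", "hairpin_strand2")
        }
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                errors.append(f"region {name}: empty range {lo}-{hi}")
        items = list(ranges.items())
        for i, (na, (la, ha)) in enumerate(items):
            for nb, (lb, hb) in items[i + 1:]:
                if la <= hb and lb <= ha:
                    errors.append(f"regions {na} and {nb} overlap")
        return errors


PAPER_SCHEME = RegionScheme()


class StructureTopology:
    """Atoms + residues + H-bond/apolar/charged atom sets.

    Donor/acceptor/apolar/charged sets are stored as per-residue atom-name
    collections derived from the nucleotide identity; they can be overridden
    wholesale for non-standard chemistry.
    """

    def __init__(
        self,
        residues: Sequence[ResidueRecord],
        atoms: Sequence[AtomRecord],
        cationic_atoms: Iterable[str] = CATIONIC_ATOMS,
    ):
        self.residues = list(residues)
        self.atoms = list(atoms)
        self.cationic_atoms = frozenset(cationic_atoms)
        self._residue_by_index = {r.residue_index: r for r in self.residues}
        if len(self._residue_by_index) != len(self.residues):
            raise TopologyError("duplicate residue indices")
        for a in self.atoms:
            if a.residue_index not in self._residue_by_index:
                raise TopologyError(
                    f"atom {a.atom_name} references unknown residue "
                    f"{a.residue_index}"
                )
        self._build_arrays()

    def _build_arrays(self) -> None:
        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_indices = np.array(
            [a.residue_index for a in self.atoms], dtype=int
        )
        self.roles = np.array([a.role for a in self.atoms])
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.base_mask = self.roles == "base"
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.masses = np.array(
            [ELEMENT_MASSES[a.element] for a in self.atoms], dtype=float
        )
        self._atom_lookup = {
            (a.residue_index, a.atom_name): i for i, a in enumerate(self.atoms)
        }

    # -- basic queries ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue(self, residue_index: int) -> ResidueRecord:
        return self._residue_by_index[residue_index]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        return self._atom_lookup[(residue_index, atom_name)]

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._atom_lookup

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return np.nonzero(self.residue_indices == residue_index)[0]

    def molecule_of(self, residue_index: int) -> str:
        """``"aso"`` or ``"hairpin"`` (regions strand1/strand2 are one
        molecule); residues without a region label form their own chain-
        labelled molecule."""
        region = self._residue_by_index[residue_index].region
        if region == "aso":
            return "aso"
        if region in ("hairpin_strand1", "hairpin_strand2"):
            return "hairpin"
        return f"chain:{self._residue_by_index[residue_index].chain_label}"

    # -- H-bond / apolar / charged atom sets ------------------------------
    def donor_map(self) -> dict[int, dict[int, list[int]]]:
        """residue -> {donor heavy atom index -> attached H atom indices}.

        Hydrogens absent from the topology are simply omitted, which lets
        the contact module fall back to a distance-only H-bond criterion.
        """
        out: dict[int, dict[int, list[int]]] = {}
        for res in self.residues:
            donors: dict[int, list[int]] = {}
            name_map = dict(BASE_DONORS[res.nucleotide])
            name_map.update(BACKBONE_DONORS)
            for heavy, hydrogens in name_map.items():
                if not self.has_atom(res.residue_index, heavy):
                    continue
                hi = self.atom_index(res.residue_index, heavy)
                donors[hi] = [
                    self.atom_index(res.residue_index, h)
                    for h in hydrogens
                    if self.has_atom(res.residue_index, h)
                ]
            out[res.residue_index] = donors
        return out

    def acceptor_map(self) -> dict[int, list[int]]:
        """residue -> acceptor heavy atom indices."""
        out: dict[int, list[int]] = {}
        for res in self.residues:
            names = BASE_ACCEPTORS[res.nucleotide] + BACKBONE_ACCEPTORS
            out[res.residue_index] = [
                self.atom_index(res.residue_index, n)
                for n in names
                if self.has_atom(res.residue_index, n)
            ]
        return out

    def apolar_indices(self) -> np.ndarray:
        """Apolar heavy atoms: all carbons."""
        return np.nonzero((self.elements == "C") & self.heavy_mask)[0]

    def anionic_indices(self) -> np.ndarray:
        return np.nonzero(np.isin(self.atom_names, list(ANIONIC_ATOMS)))[0]

    def cationic_indices(self) -> np.ndarray:
        if not self.cationic_atoms:
            return np.array([], dtype=int)
        return np.nonzero(np.isin(self.atom_names, list(self.cationic_atoms)))[0]

    def region_residues(self, *regions: str) -> list[int]:
        return [
            r.residue_index for r in self.residues if r.region in regions
        ]

    def with_atoms(self, atoms: Sequence[AtomRecord]) -> "StructureTopology":
        return StructureTopology(self.residues, atoms, self.cationic_atoms)


@dataclass
class Ensemble:
    """Ordered frames of coordinates over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times`` is in
    nanoseconds and strictly increasing.
    """

    topology: StructureTopology
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but the topology "
                f"has {self.topology.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise TopologyError("times length must equal the frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise TopologyError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def build_topology_from_atoms(
    residue_specs: Sequence[tuple[str, str]],
    atom_table: Sequence[tuple[int, str, str]],
    region_scheme: RegionScheme | None = PAPER_SCHEME,
    *,
    o2prime_as_base: bool = False,
) -> StructureTopology:
    """Assemble a topology from (nucleotide, chain) residue specs and
    (residue_index, atom_name, element) atom rows.  Residue indices are
    1-based positions into ``residue_specs``."""
    residues = []
    for i, (nt, chain) in enumerate(residue_specs, start=1):
        if nt not in NUCLEOTIDES:
            raise UnsupportedResidueError(f"unsupported residue {nt!r}")
        region = region_scheme.region_of(i) if region_scheme else None
        residues.append(ResidueRecord(i, nt, chain, region))
    atoms = []
    for resi, name, element in atom_table:
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=element,
                role=classify_atom_role(name, o2prime_as_base=o2prime_as_base),
                residue_index=resi,
                is_heavy=element != "H",
            )
        )
    return StructureTopology(residues, atoms)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_RES_NAME_ALIASES = {"A": "A", "C": "C", "G": "G", "U": "U",
                     "RA": "A", "RC": "C", "RG": "G", "RU": "U",
                     "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U"}


def read_multimodel_pdb(
    source,
    region_scheme: RegionScheme | None = PAPER_SCHEME,
    *,
    time_step_ns: float = 1.0,
    o2prime_as_base: bool = False,
    renumber: str = "contiguous",
) -> Ensemble:
    """Read a (multi-model) PDB into an :class:`Ensemble`.

    One frame per MODEL record (a single frame for a plain coordinate file).
    With ``renumber="contiguous"`` residues are renumbered from 1 in file
    order (a recorded bijection); ``renumber="preserve"`` keeps the file's
    own residue numbers when they are unique.  The default region scheme
    then labels 1-10 as the ASO and 11-42 as the hairpin.  Non-nucleotide
    residues and inter-model atom-count mismatches are rejected with
    structured errors.
    """
    if renumber not in ("contiguous", "preserve"):
        raise TopologyError(f"unknown renumber mode {renumber!r}")
    import biotite.structure.io.pdb as pdbio

    if hasattr(source, "read"):
        pdb_file = pdbio.PDBFile.read(source)
    else:
        pdb_file = pdbio.PDBFile.read(str(source))

    counts = _model_atom_counts(pdb_file.lines)
    if len(set(counts)) > 1:
        expected = counts[0]
        for model_no, c in enumerate(counts, start=1):
            if c != expected:
                raise PDBParseError(
                    f"model {model_no} has {c} atoms, expected {expected} "
                    f"(model 1)"
                )
    stack = pdb_file.get_structure(model=None)

    arr0 = stack[0]
    index_map: dict[tuple[str, int], int] = {}
    res_records: list[ResidueRecord] = []
    atom_records: list[AtomRecord] = []
    for i in range(arr0.array_length()):
        key = (str(arr0.chain_id[i]), int(arr0.res_id[i]))
        if key not in index_map:
            res_name = str(arr0.res_name[i]).strip()
            if res_name not in _RES_NAME_ALIASES:
                raise UnsupportedResidueError(
                    f"unsupported residue {res_name!r} at chain {key[0]} "
                    f"resid {key[1]} (only A/C/G/U nucleotides are handled)"
                )
            if renumber == "contiguous":
                new_index = len(index_map) + 1
            else:
                new_index = key[1]
                if any(r.residue_index == new_index for r in res_records):
                    raise PDBParseError(
                        f"duplicate residue number {new_index} across chains; "
                        f"use renumber='contiguous'"
                    )
            index_map[key] = new_index
            region = region_scheme.region_of(new_index) if region_scheme else None
            res_records.append(
                ResidueRecord(new_index, _RES_NAME_ALIASES[res_name],
                              key[0], region)
            )
        element = str(arr0.element[i]).capitalize()
        name = str(arr0.atom_name[i])
        atom_records.append(
            AtomRecord(
                atom_name=name,
                element=element,
                role=classify_atom_role(name, o2prime_as_base=o2prime_as_base),
                residue_index=index_map[key],
                is_heavy=element != "H",
            )
        )
    topology = StructureTopology(res_records, atom_records)
    frames = np.asarray(stack.coord, dtype=float)
    times = np.arange(frames.shape[0], dtype=float) * time_step_ns
    return Ensemble(topology, frames, times)


def _model_atom_counts(lines: Sequence[str]) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if saw_model and not in_model:
                continue
            current += 1
    if not saw_model:
        counts.append(current)
    elif in_model:
        counts.append(current)
    return counts or [0]


def write_multimodel_pdb(ensemble: Ensemble, target) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    top = ensemble.topology
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.zeros((n, 3))
    arr.chain_id = np.array(
        [top.residue(a.residue_index).chain_label for a in top.atoms]
    )
    arr.res_id = top.residue_indices.copy()
    arr.res_name = np.array(
        [top.residue(a.residue_index).nucleotide for a in top.atoms]
    )
    arr.atom_name = top.atom_names.copy()
    arr.element = np.char.upper(top.elements)
    arr.hetero = np.zeros(n, dtype=bool)

    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.frames.copy()
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    if hasattr(target, "write"):
        pdb_file.write(target)
    else:
        pdb_file.write(str(target))


# ---------------------------------------------------------------------------
# Nonbonded parameter attachment
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ("residue", "atom", "charge_e", "sigma_A", "epsilon_kcal")


def attach_nonbonded_params(
    topology: StructureTopology, table: pd.DataFrame | str | Path
) -> StructureTopology:
    """Attach per-atom partial charges and LJ parameters from a table.

    The table is keyed by (residue name, atom name) with columns
    ``residue, atom, charge_e, sigma_A, epsilon_kcal``.  Every atom must be
    covered; missing entries are reported as a complete list (no silent
    zero-fill).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    missing_cols = set(PARAM_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ParameterError(f"parameter table lacks columns {sorted(missing_cols)}")
    lookup = {
        (str(r.residue), str(r.atom)): (
            float(r.charge_e), float(r.sigma_A), float(r.epsilon_kcal)
        )
        for r in table.itertuples()
    }
    missing: list[tuple[str, str]] = []
    new_atoms: list[AtomRecord] = []
    for a in topology.atoms:
        nt = topology.residue(a.residue_index).nucleotide
        entry = lookup.get((nt, a.atom_name))
        if entry is None:
            missing.append((nt, a.atom_name))
            continue
        q, sigma, eps = entry
        if sigma < 0 or eps < 0:
            raise ParameterError(
                f"negative LJ parameter for ({nt}, {a.atom_name})"
            )
        new_atoms.append(replace(a, charge=q, lj_sigma=sigma, lj_epsilon=eps))
    if missing:
        uniq = sorted(set(missing))
        raise ParameterError(f"unparameterized atoms: {uniq}")
    return topology.with_atoms(new_atoms)
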