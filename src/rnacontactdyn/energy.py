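"""Short-range nonbonded interaction energies and their four-group
base/backbone decomposition.

The pair potential is the force-field nonbonded form: Coulomb
k q_i q_j / r with k = 332.0636 kcal A mol^-1 e^-2 plus Lennard-Jones
4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6] under Lorentz-Berthelot
combination (arithmetic sigma, geometric epsilon), truncated sharply at a
10 A cutoff by default (no switching function and no long-range
correction, matching the short-range convention of trajectory energy
tools).  Intermolecular group energies need no 1-2/1-3/1-4 exclusions;
intramolecular requests are refused rather than silently mis-summed.

The decomposition splits the ASO-hairpin interaction into the four role
cross terms (base-base, backbone-backbone, base-backbone, backbone-base);
base-base is the *specific* component and the other three are
*nonspecific*.  The per-residue-pair matrix is the force-field analogue of
an implicit-solvent residue interaction map (no solvation term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .descriptors import moving_average
from .topology import Ensemble, StructureTopology

#: Coulomb constant, kcal A mol^-1 e^-2.
COULOMB_K = 332.0636

DEFAULT_CUTOFF = 10.0  # Angstrom

COMPONENTS = ("base_base", "backbone_backbone", "base_backbone",
              "backbone_base")


class EnergyError(ValueError):
    """Raised for invalid energy-computation input."""


@dataclass(frozen=True)
class EnergyDecomposition:
    """Window means and SDs of the four group energies, kcal/mol.

    Components are named with the ASO role first: ``base_backbone`` is
    ASO bases against hairpin backbone.  ``total`` is the sum of the four
    component means.
    """

    means: dict[str, float]
    sds: dict[str, float]
    cutoff: float
    traces: pd.DataFrame  # per-frame component energies

    @property
    def total(self) -> float:
        return decomposition_total(self.means)

    @property
    def total_sd(self) -> float:
        return float(self.traces[list(COMPONENTS)].sum(axis=1).std(ddof=1))


def decomposition_total(component_means) -> float:
    """Total interaction energy as the sum of the four group means.

    Accepts a mapping or a sequence of the four component values."""
    if isinstance(component_means, dict):
        values = [component_means[c] for c in COMPONENTS]
    else:
        values = list(component_means)
        if len(values) != 4:
            raise EnergyError("expected exactly four group means")
    return float(np.sum(values))


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Gibbs bookkeeping: gibbs = enthalpy - entropy term (both kcal/mol,
    the entropy term being T*dS)."""

    enthalpy: float
    entropy_term_TdS: float

    @property
    def gibbs(self) -> float:
        return self.enthalpy - self.entropy_term_TdS


def combine_free_energy(enthalpy: float, entropy_term_TdS: float) -> FreeEnergyRecord:
    """dG = dH - T dS with both terms in kcal/mol."""
    return FreeEnergyRecord(float(enthalpy), float(entropy_term_TdS))


# ---------------------------------------------------------------------------
# Pair and group energies
# ---------------------------------------------------------------------------

def pair_energy(
    charge_i: float, charge_j: float,
    sigma_i: float, sigma_j: float,
    eps_i: float, eps_j: float,
    distance: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Coulomb + Lennard-Jones energy of one atom pair, kcal/mol.

    Zero beyond the cutoff; Lorentz-Berthelot combination rules."""
    if distance <= 0:
        raise EnergyError("zero or negative interatomic distance")
    if distance > cutoff:
        return 0.0
    sigma_ij = 0.5 * (sigma_i + sigma_j)
    eps_ij = np.sqrt(eps_i * eps_j)
    sr6 = (sigma_ij / distance) ** 6
    return float(
        COULOMB_K * charge_i * charge_j / distance
        + 4.0 * eps_ij * (sr6 * sr6 - sr6)
    )


def _require_params(topology: StructureTopology) -> None:
    if np.any(~np.isfinite(topology.charges)):
        raise EnergyError(
            "topology carries unparameterized atoms; call "
            "attach_nonbonded_params first"
        )


def group_energy(
    frame: np.ndarray,
    topology: StructureTopology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Summed pair energies over the cross product of two disjoint atom
    groups (indices into the topology), kcal/mol.  Symmetric in (a, b)."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise EnergyError("groups overlap; intra-group energies are refused")
    _require_params(topology)
    if group_a.size == 0 or group_b.size == 0:
        return 0.0
    frame = np.asarray(frame, dtype=float)
    d = cdist(frame[group_a], frame[group_b])
    if np.any(d <= 0):
        raise EnergyError("coincident atoms across the two groups")
    mask = d <= cutoff
    if not mask.any():
        return 0.0
    q = topology.charges
    s = topology.lj_sigma
    e = topology.lj_epsilon
    qq = np.outer(q[group_a], q[group_b])[mask]
    sig = 0.5 * (s[group_a][:, None] + s[group_b][None, :])[mask]
    eps = np.sqrt(np.outer(e[group_a], e[group_b]))[mask]
    r = d[mask]
    sr6 = (sig / r) ** 6
    return float(np.sum(COULOMB_K * qq / r + 4.0 * eps * (sr6 * sr6 - sr6)))


def _role_groups(topology: StructureTopology) -> dict[str, np.ndarray]:
    """ASO/hairpin x base/backbone atom index groups from region labels."""
    regions = np.array(
        [topology.residue(r).region or "" for r in topology.residue_indices]
    )
    aso = regions == "aso"
    hairpin = np.isin(regions, ["hairpin_strand1", "hairpin_strand2"])
    if not aso.any() or not hairpin.any():
        raise EnergyError(
            "four-group decomposition needs both an ASO and a hairpin region"
        )
    base = topology.base_mask
    return {
        "aso_base": np.nonzero(aso & base)[0],
        "aso_backbone": np.nonzero(aso & ~base)[0],
        "hairpin_base": np.nonzero(hairpin & base)[0],
        "hairpin_backbone": np.nonzero(hairpin & ~base)[0],
    }


_COMPONENT_GROUPS = {
    "base_base": ("aso_base", "hairpin_base"),
    "backbone_backbone": ("aso_backbone", "hairpin_backbone"),
    "base_backbone": ("aso_base", "hairpin_backbone"),
    "backbone_base": ("aso_backbone", "hairpin_base"),
}


def four_group_decomposition(
    ensemble: Ensemble,
    window: tuple[int, int] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> EnergyDecomposition:
    """Mean +- SD of the four ASO/hairpin role-cross energies over the
    window, with the total as their sum."""
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if not 0 <= lo < hi <= ensemble.n_frames:
        raise EnergyError(f"empty or out-of-range window ({lo}, {hi})")
    groups = _role_groups(ensemble.topology)
    rows = []
    for f in range(lo, hi):
        frame = ensemble.frames[f]
        row = {"frame": f}
        for comp, (ga, gb) in _COMPONENT_GROUPS.items():
            row[comp] = group_energy(
                frame, ensemble.topology, groups[ga], groups[gb], cutoff
            )
        rows.append(row)
    traces = pd.DataFrame(rows)
    means = {c: float(traces[c].mean()) for c in COMPONENTS}
    sds = {
        c: float(traces[c].std(ddof=1)) if len(traces) > 1 else 0.0
        for c in COMPONENTS
    }
    return EnergyDecomposition(means=means, sds=sds, cutoff=cutoff,
                               traces=traces)


def per_residue_pair_matrix(
    ensemble: Ensemble,
    window: tuple[int, int] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Mean ASO-residue x hairpin-residue interaction energies, kcal/mol.

    Entry (i, j) averages the summed atom-pair energies between the two
    residues over the window; the matrix total equals the four-group total
    to round-off.
    """
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if not 0 <= lo < hi <= ensemble.n_frames:
        raise EnergyError(f"empty or out-of-range window ({lo}, {hi})")
    top = ensemble.topology
    _require_params(top)
    aso_res = top.region_residues("aso")
    hp_res = top.region_residues("hairpin_strand1", "hairpin_strand2")
    if not aso_res or not hp_res:
        raise EnergyError("matrix needs both ASO and hairpin residues")
    a_idx = np.concatenate([top.residue_atom_indices(r) for r in aso_res])
    h_idx = np.concatenate([top.residue_atom_indices(r) for r in hp_res])
    a_res_pos = np.searchsorted(aso_res, top.residue_indices[a_idx])
    h_res_pos = np.searchsorted(hp_res, top.residue_indices[h_idx])

    q, s, e = top.charges, top.lj_sigma, top.lj_epsilon
    acc = np.zeros((len(aso_res), len(hp_res)))
    for f in range(lo, hi):
        frame = ensemble.frames[f]
        d = cdist(frame[a_idx], frame[h_idx])
        mask = d <= cutoff
        energies = np.zeros_like(d)
        if mask.any():
            qq = np.outer(q[a_idx], q[h_idx])[mask]
            sig = 0.5 * (s[a_idx][:, None] + s[h_idx][None, :])[mask]
            eps = np.sqrt(np.outer(e[a_idx], e[h_idx]))[mask]
            r = d[mask]
            sr6 = (sig / r) ** 6
            energies[mask] = COULOMB_K * qq / r + 4.0 * eps * (sr6 ** 2 - sr6)
        block = np.zeros((len(aso_res), len(hp_res)))
        np.add.at(block, (a_res_pos[:, None], h_res_pos[None, :]), energies)
        acc += block
    acc /= (hi - lo)
    return pd.DataFrame(acc, index=aso_res, columns=hp_res)


def energy_timeseries(
    ensemble: Ensemble,
    smoothing_window: int = 1,
    window: tuple[int, int] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-frame component and total traces with centred moving averages.

    ``smoothing_window`` is in frames; smoothed columns carry the
    ``_smooth`` suffix.
    """
    dec = four_group_decomposition(ensemble, window, cutoff)
    traces = dec.traces.copy()
    traces["total"] = traces[list(COMPONENTS)].sum(axis=1)
    if smoothing_window > len(traces):
        raise EnergyError("smoothing window larger than the trace")
    for col in list(COMPONENTS) + ["total"]:
        traces[f"{col}_smooth"] = moving_average(
            traces[col].to_numpy(), smoothing_window
        )
    return traces
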