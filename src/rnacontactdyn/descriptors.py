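"""Ensemble descriptors: RMSD, per-residue RMSF, radius of gyration,
moving averages and principal component analysis.

All descriptors operate on heavy atoms by default and are invariant under
rigid motion of whole frames: RMSD is computed after optimal least-squares
superposition (Kabsch), RMSF about the window-mean structure after
superposition, and PCA on the superposed, mean-centred 3N coordinate
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .topology import Ensemble, StructureTopology


class DescriptorError(ValueError):
    """Raised for invalid descriptor input."""


@dataclass
class DescriptorTrace:
    """Per-frame scalar descriptor with its time axis (ns)."""

    times: np.ndarray
    values: np.ndarray
    reference_label: str = ""
    selection: str = "heavy"


@dataclass
class PcaResult:
    """Eigen-decomposition of the 3N coordinate covariance.

    ``eigenvalues`` (A^2) descend; ``variance_fractions`` sum to 1;
    ``mode_vectors`` holds one 3N eigenvector per row; ``mean_structure``
    is the superposed selection mean, shape (n_selected, 3).
    """

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    mode_vectors: np.ndarray
    mean_structure: np.ndarray
    selection_indices: np.ndarray


def _selection_mask(
    topology: StructureTopology, selection
) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "heavy":
            mask = topology.heavy_mask
        elif selection == "all":
            mask = np.ones(topology.n_atoms, dtype=bool)
        else:
            raise DescriptorError(f"unknown selection {selection!r}")
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise DescriptorError("empty atom selection")
    return mask


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto
    ``reference``; returns the fitted coordinates and the RMSD."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DescriptorError("superposition needs equal atom counts")
    w = None if weights is None else np.asarray(weights, dtype=float)
    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    fitted = rot.apply(mobile - mc) + rc
    diff = fitted - reference
    if w is None:
        rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    else:
        rmsd = float(np.sqrt(np.average(np.sum(diff**2, axis=1), weights=w)))
    return fitted, rmsd


def rmsd_trace(
    ensemble: Ensemble,
    reference: np.ndarray | None = None,
    selection="heavy",
    fit: bool = True,
) -> DescriptorTrace:
    """Per-frame RMSD (A) to a reference structure over the selection.

    The default reference is the first frame.  With ``fit=True`` each frame
    is optimally superposed before the deviation is measured (rigid-body
    motion contributes nothing); ``fit=False`` gives the raw deviation.
    """
    mask = _selection_mask(ensemble.topology, selection)
    ref = ensemble.frames[0] if reference is None else np.asarray(reference)
    if ref.shape[0] == ensemble.n_atoms:
        ref = ref[mask]
    elif ref.shape[0] != int(mask.sum()):
        raise DescriptorError("reference atom count does not match selection")
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        mob = ensemble.frames[f][mask]
        if fit:
            _, values[f] = superpose(mob, ref)
        else:
            values[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return DescriptorTrace(
        times=ensemble.times.copy(),
        values=values,
        reference_label="frame0" if reference is None else "user",
        selection=selection if isinstance(selection, str) else "mask",
    )


def rmsf_per_residue(
    ensemble: Ensemble,
    window: tuple[int, int] | None = None,
    selection="heavy",
    fit: bool = True,
) -> pd.Series:
    """Per-residue RMSF (A) about the window-mean structure.

    With ``fit=True`` (the usual trajectory convention) frames in the
    window are first superposed to their mean structure (two-pass: fit to
    the first window frame, average, refit to the average).  ``fit=False``
    measures fluctuation about the mean in the ensemble's own coordinates,
    appropriate when frames are already aligned -- e.g. the synthetic
    generator adds no rigid-body motion, so the no-fit mode recovers the
    injected amplitudes exactly.  The per-atom RMSF sqrt(<|r - <r>|^2>) is
    averaged, unweighted, over each residue's selected atoms.
    """
    lo, hi = (0, ensemble.n_frames) if window is None else window
    if not 0 <= lo < hi <= ensemble.n_frames:
        raise DescriptorError(f"empty or out-of-range window ({lo}, {hi})")
    mask = _selection_mask(ensemble.topology, selection)
    frames = ensemble.frames[lo:hi, mask]
    fitted = _align(frames) if fit else frames
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    resi = ensemble.topology.residue_indices[mask]
    series = pd.Series(per_atom).groupby(resi).mean()
    series.index.name = "residue"
    series.name = "rmsf_A"
    return series


def radius_of_gyration(
    frame: np.ndarray,
    topology: StructureTopology,
    selection="heavy",
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration (A): sqrt(sum m |r - r_com|^2 / sum m)."""
    mask = _selection_mask(topology, selection)
    pts = np.asarray(frame, dtype=float)[mask]
    w = topology.masses[mask] if mass_weighted else np.ones(int(mask.sum()))
    com = np.average(pts, axis=0, weights=w)
    return float(
        np.sqrt(np.average(np.sum((pts - com) ** 2, axis=1), weights=w))
    )


def rg_trace(
    ensemble: Ensemble, selection="heavy", mass_weighted: bool = True
) -> DescriptorTrace:
    values = np.array(
        [
            radius_of_gyration(ensemble.frames[f], ensemble.topology,
                               selection, mass_weighted)
            for f in range(ensemble.n_frames)
        ]
    )
    return DescriptorTrace(ensemble.times.copy(), values, "com", "heavy")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; endpoints use truncated windows."""
    if window <= 0:
        raise DescriptorError("moving-average window must be positive")
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise DescriptorError("moving-average window exceeds the trace")
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _align(frames: np.ndarray) -> np.ndarray:
    """Two-pass superposition of all frames onto their mean structure."""
    fitted = np.empty_like(frames)
    ref = frames[0]
    for f in range(frames.shape[0]):
        fitted[f], _ = superpose(frames[f], ref)
    mean = fitted.mean(axis=0)
    for f in range(frames.shape[0]):
        fitted[f], _ = superpose(fitted[f], mean)
    return fitted


def pca(ensemble: Ensemble, selection="heavy", fit: bool = True) -> PcaResult:
    """Principal component analysis of the superposed heavy-atom
    coordinate covariance.

    Frames are superposed to the mean structure (``fit=False`` skips the
    superposition for pre-aligned ensembles); the eigenvalues (A^2) of
    the 3N covariance descend, their sum equals the total positional
    variance, and variance fractions are lambda_k / sum lambda.
    """
    if ensemble.n_frames < 2:
        raise DescriptorError("PCA needs at least 2 frames")
    mask = _selection_mask(ensemble.topology, selection)
    frames = ensemble.frames[:, mask]
    fitted = _align(frames) if fit else frames
    mean = fitted.mean(axis=0)
    x = (fitted - mean).reshape(frames.shape[0], -1)
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = svals**2 / (frames.shape[0] - 1)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else eigenvalues
    return PcaResult(
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        mode_vectors=vt,
        mean_structure=mean,
        selection_indices=np.nonzero(mask)[0],
    )


def pc_interpolation(
    result: PcaResult, mode: int = 0, n_frames: int = 21, n_sigma: float = 2.0
) -> np.ndarray:
    """Coordinates interpolating +-n_sigma along one PC about the mean
    (for multi-model mode-animation output), shape (n_frames, n_sel, 3)."""
    amp = n_sigma * np.sqrt(result.eigenvalues[mode])
    scales = np.linspace(-amp, amp, n_frames)
    vec = result.mode_vectors[mode].reshape(-1, 3)
    return result.mean_structure[None] + scales[:, None, None] * vec[None]
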