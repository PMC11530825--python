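"""RMSD/RMSF/Rg/moving average/PCA contracts and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnacontactdyn import descriptors as desc, synthetic as syn
from rnacontactdyn import topology as topo


def _rigid(frame, seed=0, angle=40.0):
    r = Rotation.from_euler("xyz", [angle, -15.0, 70.0], degrees=True)
    return r.apply(frame) + np.array([5.0, -3.0, 2.0])


def test_rmsd_zero_for_identity_and_rigid_motion(two_residue_topology):
    top, ref = two_residue_topology
    frames = np.stack([ref, _rigid(ref)])
    ens = topo.Ensemble(top, frames, np.array([0.0, 1.0]))
    trace = desc.rmsd_trace(ens)
    assert trace.values[0] == pytest.approx(0.0, abs=1e-9)
    assert trace.values[1] == pytest.approx(0.0, abs=1e-9)
    # without superposition the rigid motion is visible
    raw = desc.rmsd_trace(ens, fit=False)
    assert raw.values[1] > 1.0


def test_rmsd_matches_independent_superposition_oracle():
    """Optimal-superposition RMSD against MDAnalysis' independent
    quaternion-based implementation on random coordinate pairs."""
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    rng = np.random.default_rng(7)
    for _ in range(5):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, ours = desc.superpose(a, b)
        theirs = mda_rmsd(a, b, center=True, superposition=True)
        assert ours == pytest.approx(theirs, rel=1e-8)


def test_rmsf_static_ensemble_zero(two_residue_topology):
    top, ref = two_residue_topology
    ens = topo.Ensemble(top, np.repeat(ref[None], 5, axis=0),
                        np.arange(5.0))
    rmsf = desc.rmsf_per_residue(ens)
    assert np.all(rmsf.values < 1e-12)


def test_rmsf_recovers_generator_sigma(two_residue_topology):
    """sigma = 0.5 A residue among static residues: RMSF/sqrt(3) recovers
    sigma; static residues stay at numerical zero (no-fit mode, since the
    generator injects no rigid-body motion)."""
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=3000, seed=5,
                               per_residue_sigma={1: 0.5, 2: 0.0})
    ens = syn.perturb(ref, spec, top)
    rmsf = desc.rmsf_per_residue(ens, fit=False)
    assert rmsf[1] == pytest.approx(0.5 * np.sqrt(3), rel=0.03)
    assert rmsf[2] < 1e-10


def test_rmsf_windowing(two_residue_topology):
    """A window excluding the mobile block shows no fluctuation."""
    top, ref = two_residue_topology
    frames = np.repeat(ref[None], 40, axis=0)
    rng = np.random.default_rng(3)
    frames[20:] += rng.normal(0, 0.5, size=frames[20:].shape)
    ens = topo.Ensemble(top, frames, np.arange(40.0))
    quiet = desc.rmsf_per_residue(ens, window=(0, 20), fit=False)
    noisy = desc.rmsf_per_residue(ens, window=(20, 40), fit=False)
    assert np.all(quiet.values < 1e-12)
    assert np.all(noisy.values > 0.5)


def test_radius_of_gyration_cases(two_residue_topology):
    top, ref = two_residue_topology
    single = topo.StructureTopology(
        [topo.ResidueRecord(1, "A", "A", None)],
        [topo.AtomRecord("N1", "N", "base", 1, True)],
    )
    assert desc.radius_of_gyration(np.zeros((1, 3)), single) == 0.0
    # two equal masses at distance d -> d/2
    two = topo.StructureTopology(
        [topo.ResidueRecord(1, "A", "A", None)],
        [topo.AtomRecord("N1", "N", "base", 1, True),
         topo.AtomRecord("N3", "N", "base", 1, True)],
    )
    coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    assert desc.radius_of_gyration(coords, two) == pytest.approx(2.0)
    # direct-sum oracle on a real residue frame
    rg = desc.radius_of_gyration(ref, top)
    mask = top.heavy_mask
    m = top.masses[mask]
    pts = ref[mask]
    com = (pts * m[:, None]).sum(axis=0) / m.sum()
    expected = np.sqrt((m * ((pts - com) ** 2).sum(axis=1)).sum() / m.sum())
    assert rg == pytest.approx(expected, rel=1e-12)
    # invariance under rigid motion
    assert desc.radius_of_gyration(_rigid(ref), top) == pytest.approx(
        rg, rel=1e-9
    )


def test_moving_average_contracts():
    const = np.full(20, 3.0)
    assert np.allclose(desc.moving_average(const, 5), const)
    alternating = np.array([1.0, -1.0] * 10)
    sm = desc.moving_average(alternating, 2)
    assert np.allclose(sm[1:], 0.0)  # interior pairs cancel
    with pytest.raises(desc.DescriptorError):
        desc.moving_average(const, 0)
    with pytest.raises(desc.DescriptorError):
        desc.moving_average(const, 21)


def test_pca_single_line_motion(two_residue_topology):
    """Motion along one direction loads entirely on PC1."""
    top, ref = two_residue_topology
    frames = np.repeat(ref[None], 15, axis=0)
    frames[:, 0, 0] += np.linspace(-2, 2, 15)
    ens = topo.Ensemble(top, frames, np.arange(15.0))
    res = desc.pca(ens, fit=False)
    assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_trace_identity_and_rank(two_residue_topology):
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=12, seed=2, default_sigma=0.3)
    ens = syn.perturb(ref, spec, top)
    res = desc.pca(ens, fit=False)
    frames = ens.frames[:, top.heavy_mask]
    centred = frames - frames.mean(axis=0)
    total_var = (centred**2).sum() / (ens.n_frames - 1)
    assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    nonzero = (res.eigenvalues > 1e-10 * res.eigenvalues[0]).sum()
    assert nonzero <= ens.n_frames - 1
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)


def test_pca_isotropic_noise_has_no_dominant_mode(two_residue_topology):
    """Isotropic independent noise at large n: leading fractions approach
    equality (max < 3x min over the top 10)."""
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=1500, seed=8, default_sigma=0.4)
    ens = syn.perturb(ref, spec, top)
    res = desc.pca(ens, fit=False)
    top10 = res.variance_fractions[:10]
    assert top10[0] < 3 * top10[9]


def test_pca_needs_two_frames(two_residue_topology):
    top, ref = two_residue_topology
    ens = topo.Ensemble(top, ref[None], np.array([0.0]))
    with pytest.raises(desc.DescriptorError):
        desc.pca(ens)


def test_pca_eigenvalues_invariant_under_rigid_motion(two_residue_topology):
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=40, seed=4, default_sigma=0.3)
    ens = syn.perturb(ref, spec, top)
    moved = np.stack([_rigid(f) for f in ens.frames])
    ens2 = topo.Ensemble(top, moved, ens.times)
    a = desc.pca(ens)
    b = desc.pca(ens2)
    assert np.allclose(a.eigenvalues[:5], b.eigenvalues[:5], rtol=1e-6)


def test_empty_selection_rejected(two_residue_topology):
    top, ref = two_residue_topology
    ens = topo.Ensemble(top, ref[None], np.array([0.0]))
    with pytest.raises(desc.DescriptorError):
        desc.rmsd_trace(ens, selection=np.zeros(top.n_atoms, dtype=bool))


def test_pc_interpolation_shape(two_residue_topology):
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=10, seed=1, default_sigma=0.2)
    ens = syn.perturb(ref, spec, top)
    res = desc.pca(ens)
    frames = desc.pc_interpolation(res, 0, n_frames=7)
    assert frames.shape == (7, int(top.heavy_mask.sum()), 3)
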