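"""Torsion, pucker, base-frame and helicoidal-parameter geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnacontactdyn import geometry as geom, synthetic as syn
from rnacontactdyn import topology as topo


# ---------------------------------------------------------------------------
# Dihedral primitive
# ---------------------------------------------------------------------------

def test_dihedral_cis_trans():
    p1, p2, p3 = [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]
    assert geom.dihedral(p1, p2, p3, [1.0, 1.0, 0.0]) == pytest.approx(0.0)
    assert geom.dihedral(p1, p2, p3, [1.0, -1.0, 0.0]) == pytest.approx(180.0)


def test_dihedral_matches_rotation_oracle():
    """Rotating the fourth point about the central bond by a known angle
    from the cis arrangement must read back exactly that angle."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        axis_start = rng.normal(size=3)
        axis_end = axis_start + rng.normal(size=3)
        p1 = axis_start + rng.normal(size=3)
        b = axis_end - axis_start
        b /= np.linalg.norm(b)
        # build p4 cis to p1, then rotate by theta about the bond axis
        theta = float(rng.uniform(-179.0, 179.0))
        perp = p1 - axis_start
        perp -= np.dot(perp, b) * b
        p4_cis = axis_end + perp
        rot = Rotation.from_rotvec(np.radians(theta) * b)
        p4 = rot.apply(p4_cis - axis_end) + axis_end
        measured = geom.dihedral(p1, axis_start, axis_end, p4)
        assert measured == pytest.approx(theta, abs=1e-8)


def test_dihedral_degenerate_rejected():
    with pytest.raises(geom.GeometryError):
        geom.dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
    with pytest.raises(geom.GeometryError):
        geom.dihedral([2, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


def test_circular_mean_wraps():
    vals = np.array([179.0, -179.0, 178.0, -178.0])
    mean = geom.circular_mean_deg(vals)
    assert abs(abs(mean) - 180.0) < 1.0


# ---------------------------------------------------------------------------
# Pucker
# ---------------------------------------------------------------------------

def test_flat_ring_flagged():
    ring = np.array(
        [[np.cos(2 * np.pi * j / 5), np.sin(2 * np.pi * j / 5), 0.0]
         for j in range(5)]
    )
    state = geom.pucker_from_torsions(geom.ring_torsions(ring))
    assert state.amplitude == 0.0
    assert state.conformer == "flat"


def test_pucker_missing_atom_rejected():
    with pytest.raises(geom.GeometryError, match="C2'"):
        geom.pucker({"O4'": np.zeros(3), "C1'": np.zeros(3),
                     "C3'": np.zeros(3), "C4'": np.zeros(3)})


def test_conformer_wheel_sectors():
    assert geom.conformer_center("C3'-endo") == 18.0
    assert geom.conformer_center("C4'-exo") == 54.0
    assert geom.conformer_center("C2'-endo") == 162.0
    assert geom.conformer_center("C2'-exo") == 342.0
    with pytest.raises(geom.GeometryError):
        geom.conformer_center("boat")


def test_pucker_rigid_motion_invariant():
    names, coords, _ = syn.build_nucleotide("G", "C3'-endo")
    m1 = dict(zip(names, coords))
    rot = Rotation.from_euler("zyx", [11, 62, -40], degrees=True)
    m2 = {n: rot.apply(c) + np.array([1.0, 2.0, 3.0])
          for n, c in zip(names, coords)}
    s1, s2 = geom.pucker(m1), geom.pucker(m2)
    assert s1.phase == pytest.approx(s2.phase, abs=1e-8)
    assert s1.amplitude == pytest.approx(s2.amplitude, abs=1e-8)


# ---------------------------------------------------------------------------
# Base frames and helicoidal parameters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("nucleotide", ["A", "C", "G", "U"])
def test_base_frame_identity_on_canonical_pose(nucleotide):
    names, template = geom._canonical_base_template(nucleotide)
    frame = geom.base_frame(nucleotide, dict(zip(names, template)))
    assert np.allclose(frame.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(frame.origin, 0.0, atol=1e-6)


def test_base_frame_recovers_rotation():
    names, template = geom._canonical_base_template("G")
    rot = Rotation.from_euler("xyz", [25, -70, 140], degrees=True)
    t = np.array([1.0, -4.0, 2.5])
    moved = {n: rot.apply(c) + t for n, c in zip(names, template)}
    frame = geom.base_frame("G", moved)
    assert np.abs(frame.rotation - rot.as_matrix()).max() < 1e-6
    assert np.abs(frame.origin - t).max() < 1e-6


def test_base_frame_origins_on_wc_edge():
    """Purine and pyrimidine origins are distinct but both sit past the
    six-ring centroid toward the WC edge."""
    for nt, ring_names in (("A", geom._PURINE_RING), ("C", geom._PYRIMIDINE_RING)):
        names, template = geom._canonical_base_template(nt)
        m = dict(zip(names, template))
        ring = np.array([m[n] for n in ring_names])
        centroid = ring[-6:].mean(axis=0) if nt == "A" else ring.mean(axis=0)
        anchors = geom._WC_ANCHORS[nt]
        edge_mid = 0.5 * (m[anchors[0]] + m[anchors[1]])
        # origin (frame origin is the template origin = 0)
        assert np.linalg.norm(edge_mid - centroid) > 1.0


def test_base_frame_missing_ring_atom():
    names, template = geom._canonical_base_template("A")
    m = dict(zip(names, template))
    del m["N7"]
    with pytest.raises(geom.GeometryError, match="N7"):
        geom.base_frame("A", m)


def test_step_params_constructed():
    identity = geom.BaseFrame(np.eye(3), np.zeros(3))
    assert geom.step_params(identity, identity).translation == (0, 0, 0)
    assert geom.step_params(identity, identity).rotation == (0, 0, 0)
    risen = geom.BaseFrame(np.eye(3), np.array([0.0, 0.0, 3.4]))
    p = geom.step_params(identity, risen)
    assert p.rise == pytest.approx(3.4, abs=1e-12)
    assert p.shift == p.slide == 0.0
    assert p.rotation == (0.0, 0.0, 0.0)
    twisted = geom.BaseFrame(
        Rotation.from_euler("z", 36, degrees=True).as_matrix(), np.zeros(3)
    )
    p = geom.step_params(identity, twisted)
    assert p.twist == pytest.approx(36.0, abs=1e-9)
    assert p.tilt == pytest.approx(0.0, abs=1e-9)
    assert p.roll == pytest.approx(0.0, abs=1e-9)


def test_bp_params_strand_swap_symmetry():
    """Under strand-order swap: shear and buckle change sign; stretch,
    stagger, propeller and opening are invariant."""
    rng = np.random.default_rng(12)
    for k in range(5):
        f1 = geom.BaseFrame(
            Rotation.random(random_state=np.random.RandomState(k)).as_matrix(),
            rng.normal(size=3),
        )
        f2 = geom.BaseFrame(
            Rotation.random(
                random_state=np.random.RandomState(100 + k)
            ).as_matrix(),
            rng.normal(size=3),
        )
        a = geom.bp_params(f1, f2)
        b = geom.bp_params(f2, f1)
        assert b.shear == pytest.approx(-a.shear, abs=1e-9)
        assert b.buckle == pytest.approx(-a.buckle, abs=1e-9)
        assert b.stretch == pytest.approx(a.stretch, abs=1e-9)
        assert b.stagger == pytest.approx(a.stagger, abs=1e-9)
        assert b.propeller == pytest.approx(a.propeller, abs=1e-9)
        assert b.opening == pytest.approx(a.opening, abs=1e-9)


def test_non_orthonormal_frame_rejected():
    bad = geom.BaseFrame(np.eye(3) * 2.0, np.zeros(3))
    good = geom.BaseFrame(np.eye(3), np.zeros(3))
    with pytest.raises(geom.GeometryError):
        geom.frame_step_params(bad, good)


def test_ideal_wc_pair_params_near_zero(au_wc_scene, gc_wc_scene):
    """The calibrated frame convention gives near-zero intra-pair
    parameters for idealized Watson-Crick pairs."""
    for scene in (au_wc_scene, gc_wc_scene):
        top, f = scene.topology, scene.frames[0]
        fr1 = geom.residue_base_frame(top, f, 1)
        fr2 = geom.residue_base_frame(top, f, 2)
        p = geom.bp_params(fr1, fr2)
        assert np.abs(p.translation).max() < 0.2
        assert np.abs(p.rotation).max() < 2.0


# ---------------------------------------------------------------------------
# Ensemble profiles
# ---------------------------------------------------------------------------

def _build_duplex(scene, n_steps=4, twist=32.7, rise=2.8):
    """Stack copies of an ideal pair with a helical operator about the
    pair mid-frame z axis."""
    top, f0 = scene.topology, scene.frames[0]
    fr1 = geom.residue_base_frame(top, f0, 1)
    fr2 = geom.residue_base_frame(top, f0, 2)
    mid = geom.bp_mid_frame(fr1, fr2)
    ax = mid.rotation[:, 2]
    residues, atom_lists, coords, pairing_list = [], [], [], []
    for k in range(n_steps):
        rot = Rotation.from_rotvec(np.radians(twist * k) * ax)
        tvec = rise * k * ax
        for local, chain in ((1, "A"), (2, "B")):
            idx = top.residue_atom_indices(local)
            res = top.residue(local)
            residues.append((2 * k + local, res.nucleotide, chain))
            atom_lists.append(
                (list(top.atom_names[idx]), list(top.elements[idx]))
            )
            coords.append(rot.apply(f0[idx] - mid.origin) + mid.origin + tvec)
        pairing_list.append((2 * k + 1, 2 * k + 2))
    dup_top = syn.assemble_topology(residues, atom_lists, region_scheme=None)
    ens = topo.Ensemble(
        dup_top, np.concatenate(coords)[None], np.array([0.0])
    )
    return ens, pairing_list


def test_duplex_step_twist_recovered(au_wc_scene):
    """Every step of a constructed helix reads back the constructed twist
    and rise."""
    ens, pairing_list = _build_duplex(au_wc_scene)
    prof = geom.geometry_profiles(ens, pairing_list)
    steps = prof["step_params"]
    assert np.allclose(steps["twist"], 32.7, atol=1e-6)
    assert np.allclose(steps["rise"], 2.8, atol=1e-6)


def test_profiles_single_frame_point_masses(au_wc_scene):
    ens, pairing_list = _build_duplex(au_wc_scene, n_steps=2)
    prof = geom.geometry_profiles(ens, pairing_list)
    assert set(prof["torsions"]["frame"]) == {0}
    assert set(prof["puckers"]["frame"]) == {0}
    # single frame: every distribution is a point mass
    assert prof["puckers"].groupby("residue").phase_deg.nunique().max() == 1


def test_profiles_frame_order_invariance(two_residue_topology):
    top, ref = two_residue_topology
    spec = syn.FluctuationSpec(n_frames=6, seed=3, default_sigma=0.1)
    ens = syn.perturb(ref, spec, top)
    shuffled = topo.Ensemble(
        top, ens.frames[::-1].copy(), ens.times.copy()
    )
    a = geom.geometry_profiles(ens)["puckers"]
    b = geom.geometry_profiles(shuffled)["puckers"]
    assert sorted(a["phase_deg"].round(9)) == sorted(b["phase_deg"].round(9))


def test_profiles_missing_pairing_residue(au_wc_scene):
    with pytest.raises(geom.GeometryError, match="missing residue"):
        geom.geometry_profiles(au_wc_scene, pairing=[(1, 99)])


def test_torsions_defined_only_with_all_atoms(two_residue_topology):
    """Single nucleotides lack alpha/epsilon/zeta (no neighbours) but have
    chi, gamma, beta, delta."""
    top, ref = two_residue_topology
    tors = geom.residue_torsions(top, ref, 1)
    assert "chi" in tors and "gamma" in tors
    assert "alpha" not in tors and "zeta" not in tors
    assert set(tors) <= {"alpha", "beta", "gamma", "delta", "epsilon",
                         "zeta", "chi"}
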