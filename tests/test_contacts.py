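"""Contact detection, classification, occupancy and evolution."""

import numpy as np
import pytest

from rnacontactdyn import contacts, synthetic as syn
from rnacontactdyn import topology as topo
from rnacontactdyn.contacts import ContactCriteria, ContactSeries


# ---------------------------------------------------------------------------
# Independent O(n^2) brute-force re-implementation (the oracle)
# ---------------------------------------------------------------------------

def brute_force_contacts(frame, top, crit):
    """Plain-loop contact detection over every atom pair, independent of
    the vectorized implementation: returns {(i, j): type}."""
    donor_h = {}
    for per_res in top.donor_map().values():
        donor_h.update(per_res)
    acceptors = {a for accs in top.acceptor_map().values() for a in accs}
    apolar = set(top.apolar_indices().tolist())
    anions = set(top.anionic_indices().tolist())
    cations = set(top.cationic_indices().tolist())
    resi = top.residue_indices
    found = {}
    n = top.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = int(resi[i]), int(resi[j])
            if ri == rj:
                continue
            if top.molecule_of(ri) == top.molecule_of(rj) and abs(ri - rj) <= 1:
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            ctype = None
            for da, ac in ((i, j), (j, i)):
                if da in donor_h and ac in acceptors \
                        and d <= crit.hbond_heavy_dist_max:
                    hydrogens = donor_h[da]
                    if not hydrogens:
                        ctype = "hbond"
                        break
                    for h in hydrogens:
                        v1 = frame[da] - frame[h]
                        v2 = frame[ac] - frame[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= crit.hbond_angle_min:
                            ctype = "hbond"
                            break
                    if ctype:
                        break
            if ctype is None and d <= crit.salt_bridge_dist_max:
                if (i in anions and j in cations) or (
                    j in anions and i in cations
                ):
                    ctype = "salt_bridge"
            if ctype is None and d <= crit.apolar_dist_max:
                if i in apolar and j in apolar:
                    ctype = "apolar"
            if ctype:
                found[(i, j)] = ctype
    return found


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_detection_matches_brute_force(seed):
    """Vectorized detection equals the plain-loop oracle on random frames."""
    ens = syn.random_scene(n_residues=4 + seed, seed=seed, box=16.0)
    crit = ContactCriteria()
    records = contacts.detect_contacts(ens.frames[0], ens.topology, crit)
    got = {r.atom_pair: r.contact_type for r in records}
    expected = brute_force_contacts(ens.frames[0], ens.topology, crit)
    assert got == expected


def test_empty_beyond_cutoffs(two_residue_topology):
    """Residues 30 A apart produce no contacts at all."""
    top, ref = two_residue_topology
    records = contacts.detect_contacts(ref, top)
    assert records == []


def test_specificity_rule(demo_ensemble):
    """A contact is specific iff both atoms have the base role."""
    ens, _ = demo_ensemble
    records = contacts.detect_contacts(ens.frames[0], ens.topology)
    assert records, "demo scene should produce contacts"
    roles = ens.topology.roles
    for r in records:
        i, j = r.atom_pair
        both_base = roles[i] == "base" and roles[j] == "base"
        assert (r.specificity == "specific") == both_base


def test_unit_weight_strength_counts():
    """Strength counts every record once, whatever its type."""
    recs = [
        contacts.ContactRecord(0, (1, 5), "hbond", (0, 10), "specific"),
        contacts.ContactRecord(0, (1, 5), "hbond", (1, 11), "specific"),
        contacts.ContactRecord(0, (1, 5), "apolar", (2, 12), "nonspecific"),
        contacts.ContactRecord(0, (2, 5), "salt_bridge", (3, 13), "nonspecific"),
    ]
    assert contacts.contact_strength(recs, (1, 5)) == 3
    assert contacts.contact_strength(recs, (2, 5)) == 1
    assert contacts.contact_strength(recs, (3, 4)) == 0


def test_strength_tally_random_records():
    """Per-pair counts equal a multiset tally oracle."""
    rng = np.random.default_rng(5)
    pairs = [(1, 2), (1, 3), (2, 4), (3, 4)]
    recs = []
    for k in range(25):
        p = pairs[rng.integers(len(pairs))]
        recs.append(contacts.ContactRecord(0, p, "hbond", (k, 100 + k),
                                           "specific"))
    from collections import Counter

    tally = Counter(r.residue_pair for r in recs)
    for p in pairs:
        assert contacts.contact_strength(recs, p) == tally.get(p, 0)


def _series(pair, presence, specific=None):
    presence = np.asarray(presence, dtype=bool)
    strength = presence.astype(int)
    spec = np.zeros_like(strength) if specific is None else np.asarray(specific)
    return ContactSeries(
        residue_pair=pair,
        presence=presence,
        strength=strength,
        specific_strength=spec,
        nonspecific_strength=strength - spec,
        window=(0, len(presence)),
    )


def test_occupancy_filter_strict_boundary():
    """Keep occupancy > threshold, strictly: exactly 10% is dropped."""
    occupancies = [0.05, 0.10, 0.101, 0.95]
    series = []
    n = 1000
    for k, occ in enumerate(occupancies):
        pres = np.zeros(n, dtype=bool)
        pres[: int(round(occ * n))] = True
        series.append(_series((k, k + 10), pres))
    kept = contacts.occupancy_filter(series, threshold=0.10)
    assert [s.residue_pair for s in kept] == [(2, 12), (3, 13)]


def test_occupancy_filter_matches_brute_force():
    rng = np.random.default_rng(11)
    series = [
        _series((k, k + 50), rng.random(40) < rng.random()) for k in range(100)
    ]
    kept = contacts.occupancy_filter(series, 0.10)
    expected = [s for s in series if s.presence.mean() > 0.10]
    assert [s.residue_pair for s in kept] == [s.residue_pair for s in expected]


def test_filter_threshold_range():
    with pytest.raises(contacts.ContactError):
        contacts.occupancy_filter([], threshold=0.0)
    with pytest.raises(contacts.ContactError):
        contacts.occupancy_filter([], threshold=1.0)


def test_build_series_static_repeat(au_wc_scene):
    """A static in-contact frame repeated gives occupancy 1 and constant
    strength."""
    ens = au_wc_scene
    rep = topo.Ensemble(
        ens.topology, np.repeat(ens.frames, 10, axis=0),
        np.arange(10, dtype=float),
    )
    series = contacts.build_series(rep)
    assert series
    s = {x.residue_pair: x for x in series}[(1, 2)]
    assert s.occupancy == 1.0
    assert s.mean_strength == s.strength[0]
    assert np.all(s.strength == s.strength[0])


def test_build_series_scheduled_occupancy():
    """Scheduled 0.4 occupancy over 200 frames is recovered exactly."""
    ens, masks = syn.scheduled_scene([0.4], n_frames=200, seed=2)
    series = contacts.build_series(ens)
    s = {x.residue_pair: x for x in series}[(1, 2)]
    assert s.occupancy == pytest.approx(0.4, abs=1 / 200)
    assert np.array_equal(s.presence, masks[(1, 2)])


def test_build_series_empty_window(au_wc_scene):
    with pytest.raises(contacts.ContactError):
        contacts.build_series(au_wc_scene, window=(1, 1))


def test_occupancy_invariant_under_frame_reordering():
    rng = np.random.default_rng(0)
    pres = rng.random(60) < 0.3
    s1 = _series((1, 2), pres)
    s2 = _series((1, 2), rng.permutation(pres))
    assert s1.occupancy == s2.occupancy


def test_strength_additivity(demo_ensemble):
    """Specific + nonspecific strengths equal the total, per frame and
    pair, and the contact-map modes add up entry-wise."""
    ens, _ = demo_ensemble
    series = contacts.build_series(ens, window=(0, 15))
    assert series
    for s in series:
        assert np.array_equal(
            s.strength, s.specific_strength + s.nonspecific_strength
        )
    m_all = contacts.contact_map(series, "all")
    m_spec = contacts.contact_map(series, "specific")
    m_non = contacts.contact_map(series, "nonspecific")
    assert np.allclose(m_all.values, m_spec.values + m_non.values, atol=1e-12)


def test_contact_map_specificity_separation(au_wc_scene, demo_ensemble):
    """A pure base-base H-bond pair appears only in the specific map."""
    ens = au_wc_scene
    rep = topo.Ensemble(
        ens.topology, np.repeat(ens.frames, 3, axis=0),
        np.arange(3, dtype=float),
    )
    series = contacts.build_series(rep)
    hb_only = [s for s in series if s.nonspecific_strength.sum() == 0]
    assert hb_only, "WC pose should give at least base-base-only pairs"
    m_spec = contacts.contact_map(series, "specific")
    m_non = contacts.contact_map(series, "nonspecific")
    for s in hb_only:
        i, j = s.residue_pair
        assert m_spec.loc[i, j] > 0
        assert m_non.loc[i, j] == 0


def test_evolution_blocks():
    """Step-change occupancies resolve in the block table."""
    pres = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
    evo = contacts.contact_evolution([_series((1, 2), pres)], 2)
    assert list(evo.occupancy) == [0.0, 1.0]
    const = contacts.contact_evolution([_series((1, 2), np.ones(60, bool))], 5)
    assert list(const.occupancy) == [1.0] * 5
    # 0.2 -> 0.8 step at midpoint, 4 blocks
    rng = np.random.default_rng(8)
    half = 200
    pres = np.concatenate(
        [rng.random(half) < 0.2, rng.random(half) < 0.8]
    )
    evo = contacts.contact_evolution([_series((1, 2), pres)], 4)
    expected = [0.2, 0.2, 0.8, 0.8]
    for got, want in zip(evo.occupancy, expected):
        assert got == pytest.approx(want, abs=3 / (half / 2) ** 0.5 / 10 + 0.1)


def test_evolution_too_many_blocks():
    with pytest.raises(contacts.ContactError):
        contacts.contact_evolution([_series((1, 2), np.ones(3, bool))], 5)


def test_frame_shape_mismatch(two_residue_topology):
    top, ref = two_residue_topology
    with pytest.raises(contacts.ContactError):
        contacts.detect_contacts(ref[:-1], top)


def test_criteria_validation():
    with pytest.raises(contacts.ContactError):
        ContactCriteria(hbond_heavy_dist_max=-1.0)
    with pytest.raises(contacts.ContactError):
        ContactCriteria(hbond_angle_min=200.0)
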