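"""Shared fixtures: expensive constructed scenes are built once per session."""

import numpy as np
import pytest

from rnacontactdyn import synthetic as syn
from rnacontactdyn import topology as topo


@pytest.fixture(scope="session")
def au_wc_scene():
    """Idealized Watson-Crick A-U pair on separate chains."""
    plan = syn.PairingPlan(
        residues=((1, "A"), (2, "U")),
        pairs=(syn.PairSpec(1, 2, "WC"),),
        chains={1: "A", 2: "B"},
    )
    return syn.build_paired_arrangement(plan, region_scheme=None)


@pytest.fixture(scope="session")
def gc_wc_scene():
    plan = syn.PairingPlan(
        residues=((1, "G"), (2, "C")),
        pairs=(syn.PairSpec(1, 2, "WC"),),
        chains={1: "A", 2: "B"},
    )
    return syn.build_paired_arrangement(plan, region_scheme=None)


@pytest.fixture(scope="session")
def au_hoogsteen_scene():
    plan = syn.PairingPlan(
        residues=((1, "A"), (2, "U")),
        pairs=(syn.PairSpec(1, 2, "Hoogsteen"),),
        chains={1: "A", 2: "B"},
    )
    return syn.build_paired_arrangement(plan, region_scheme=None)


@pytest.fixture(scope="session")
def uau_triple_scene():
    """U.A-U triple: central adenine pairs one uracil on its WC edge and
    the other on its Hoogsteen edge."""
    plan = syn.PairingPlan(
        residues=((1, "U"), (2, "A"), (3, "U")),
        pairs=(syn.PairSpec(2, 1, "WC"), syn.PairSpec(2, 3, "Hoogsteen")),
        chains={1: "A", 2: "B", 3: "C"},
    )
    return syn.build_paired_arrangement(plan, region_scheme=None)


@pytest.fixture(scope="session")
def demo_ensemble():
    """Small parameterized ASO-hairpin-like demo ensemble (40 frames)."""
    ens, truth = syn.demo_scene(seed=17, n_frames=40)
    table = syn.synthetic_param_table(ens.topology)
    ens.topology = topo.attach_nonbonded_params(ens.topology, table)
    return ens, truth


@pytest.fixture(scope="session")
def two_residue_topology():
    """An adenosine and a uridine on separate chains, 30 A apart."""
    na, ca, ea = syn.build_nucleotide("A")
    nu, cu, eu = syn.build_nucleotide("U")
    top = syn.assemble_topology(
        [(1, "A", "A"), (2, "U", "B")], [(na, ea), (nu, eu)],
        region_scheme=None,
    )
    ref = np.concatenate([ca, cu + np.array([30.0, 0.0, 0.0])])
    return top, ref
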