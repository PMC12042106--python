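"""Adjacency inference and exhaustive tree enumeration tests.

The enumeration oracle is written independently of the implementation: it
scans every increasing parent vector (every rooted tree shape admits one)
crossed with every assignment of the label multiset to positions, and
canonicalizes by its own recursive sorted-string form.
"""

from itertools import permutations, product

import numpy as np
import pytest

from glycaninfer.fragment_annotator import FragmentAnnotation, Peak, annotate_spectrum
from glycaninfer.glycan_mass import GlycanComposition, default_registry
from glycaninfer.synthetic_data import (
    SpectrumSimConfig,
    random_topology,
    simulate_spectrum,
)
from glycaninfer.topology_inference import (
    AdjacencyHypothesis,
    GlycanTopology,
    TopologySizeError,
    consistent_topologies,
    enumerate_topologies,
    infer_adjacencies,
)


def _fa(series, text, mz=500.0):
    return FragmentAnnotation(Peak(mz, 1.0), series, GlycanComposition.parse(text),
                              mz, 0.0)


# --- independent tree-enumeration oracle -----------------------------------

def _oracle_canon(labels, parents, i=0):
    kids = sorted(
        _oracle_canon(labels, parents, j)
        for j, p in enumerate(parents)
        if p == i
    )
    return (labels[i], tuple(kids))


def oracle_enumerate(label_multiset, max_children=4):
    """All rooted labeled trees up to isomorphism, by exhaustive scan."""
    n = len(label_multiset)
    out = set()
    for parents_tail in product(*[range(i) for i in range(1, n)]):
        parents = (None,) + parents_tail
        if any(sum(1 for p in parents if p == j) > max_children for j in range(n)):
            continue
        for labels in set(permutations(label_multiset)):
            out.add(_oracle_canon(labels, parents))
    return out


@pytest.mark.parametrize(
    "labels",
    [
        ("Hex", "Hex"),
        ("Hex", "Hex", "Hex"),
        ("Hex", "HexNAc", "QuiS"),
        ("Hex", "Hex", "HexNAc", "QuiS"),
        ("Hex", "Hex", "Hex", "HexNAc", "HexNAc"),
    ],
)
def test_enumeration_matches_brute_force_oracle(labels):
    comp = GlycanComposition(
        {c: labels.count(c) for c in set(labels)}
    )
    got = {t._as_tuple_tree() for t in enumerate_topologies(comp)}
    assert got == oracle_enumerate(labels)


def test_two_hexoses_single_topology():
    trees = enumerate_topologies(GlycanComposition.parse("Hex2"))
    assert len(trees) == 1
    assert trees[0].n_nodes == 2


def test_enumeration_respects_size_limit():
    with pytest.raises(TopologySizeError, match="max_nodes"):
        enumerate_topologies(GlycanComposition.parse("Hex9"))
    with pytest.raises(TopologySizeError):
        consistent_topologies(GlycanComposition.parse("Hex9"))


def test_branching_cap():
    # a 5-node star needs 4 children; with max_children=2 it must disappear
    comp = GlycanComposition.parse("Hex5")
    wide = {t._as_tuple_tree() for t in enumerate_topologies(comp, max_children=4)}
    narrow = {t._as_tuple_tree() for t in enumerate_topologies(comp, max_children=2)}
    assert narrow < wide
    assert narrow == oracle_enumerate(("Hex",) * 5, max_children=2)


# --- adjacency inference ----------------------------------------------------

def test_published_fragment_pair_yields_quis_on_hexnac(registry):
    annotations = [_fa("Y", "HexNAc2", 755.32), _fa("Y", "HexNAc2QuiS1", 981.34)]
    hyps = infer_adjacencies(annotations, registry)
    assert len(hyps) == 1
    assert hyps[0].attached == "sulfoquinovose"
    assert hyps[0].anchor == "N-acetylhexosamine"
    assert hyps[0].support_count >= 1


def test_two_residue_gap_does_not_fire(registry):
    annotations = [_fa("Y", "HexNAc2"), _fa("Y", "HexNAc2Hex1QuiS1")]
    assert infer_adjacencies(annotations, registry) == []


def test_mixed_class_anchor_does_not_fire(registry):
    annotations = [_fa("Y", "Hex1HexNAc1"), _fa("Y", "Hex1HexNAc1QuiS1")]
    assert infer_adjacencies(annotations, registry) == []


def test_series_are_not_mixed(registry):
    annotations = [_fa("Y", "HexNAc2"), _fa("B", "HexNAc2QuiS1")]
    assert infer_adjacencies(annotations, registry) == []


def test_empty_annotations_empty_hypotheses(registry):
    assert infer_adjacencies([], registry) == []


def test_hypotheses_are_sound_on_random_trees(registry):
    """Noise-free single-cleavage fragment sets never imply an adjacency the
    generating tree does not have."""
    rng = np.random.default_rng(7)
    for k in range(100):
        topo = random_topology(int(rng.integers(5, 9)), rng)
        spec, _ = simulate_spectrum(
            SpectrumSimConfig(topology=topo, mz_jitter_sd=0.0, seed=k), registry
        )
        result = annotate_spectrum(spec, topo.composition(), 0.02, registry)
        true_edges = {
            frozenset(
                (registry.class_of(topo.nodes[p]), registry.class_of(topo.nodes[c]))
            )
            for p, c in topo.edges()
        }
        for h in infer_adjacencies(result.annotations, registry):
            assert frozenset((h.attached, h.anchor)) in true_edges


# --- consistency filtering --------------------------------------------------

def test_generating_tree_survives_its_own_evidence(registry):
    rng = np.random.default_rng(13)
    for k in range(30):
        topo = random_topology(int(rng.integers(5, 9)), rng)
        spec, _ = simulate_spectrum(
            SpectrumSimConfig(topology=topo, mz_jitter_sd=0.0, seed=k), registry
        )
        result = annotate_spectrum(spec, topo.composition(), 0.02, registry)
        hyps = infer_adjacencies(result.annotations, registry)
        kept = consistent_topologies(
            topo.composition(), hyps, result.annotations, registry
        )
        assert any(t.isomorphic_to(topo) for t in kept)


def test_retained_heptasaccharide_trees_all_bond_quis_to_hexnac(
    host_glycan_spectrum, heptasaccharide, registry
):
    result = annotate_spectrum(host_glycan_spectrum, heptasaccharide, 0.02, registry)
    hyps = infer_adjacencies(result.annotations, registry)
    kept = consistent_topologies(heptasaccharide, hyps, result.annotations, registry)
    assert kept
    for t in kept:
        assert any(
            {t.nodes[p], t.nodes[c]} == {"QuiS", "HexNAc"} for p, c in t.edges()
        )


def test_cut_condition_matches_brute_force_on_hex3(registry):
    """Evidence Y:Hex1 keeps exactly the trees with a cut whose root side is
    a single hexose: the 3-chain qualifies, the 2-branch star does not."""
    comp = GlycanComposition.parse("Hex3")
    evidence = [_fa("Y", "Hex1")]
    kept = consistent_topologies(comp, [], evidence, registry)
    all_trees = enumerate_topologies(comp)
    expected = [
        t for t in all_trees
        if any(t.composition().subtract(t.subtree_composition(c)).total == 1
               for _, c in t.edges())
    ]
    assert {t.canonical() for t in kept} == {t.canonical() for t in expected}
    assert len(all_trees) == 2 and len(kept) == 1


def test_filtering_is_anti_monotone(host_glycan_spectrum, heptasaccharide, registry):
    result = annotate_spectrum(host_glycan_spectrum, heptasaccharide, 0.02, registry)
    hyps = infer_adjacencies(result.annotations, registry)
    no_constraints = consistent_topologies(heptasaccharide, [], [], registry)
    with_evidence = consistent_topologies(
        heptasaccharide, [], result.annotations, registry
    )
    with_both = consistent_topologies(
        heptasaccharide, hyps, result.annotations, registry
    )
    k = lambda ts: {t.canonical() for t in ts}
    assert k(with_both) <= k(with_evidence) <= k(no_constraints)


# --- topology plumbing ------------------------------------------------------

def test_tree_text_round_trip(ssv19_tree):
    text = ssv19_tree.to_text()
    assert GlycanTopology.from_text(text).isomorphic_to(ssv19_tree)
    branched = GlycanTopology.from_text("HexNAc(QuiS,Hex(Hex,Hex))")
    assert branched.n_nodes == 5
    assert branched.composition() == GlycanComposition.parse("Hex3HexNAc1QuiS1")


def test_invalid_trees_rejected():
    with pytest.raises(ValueError):
        GlycanTopology(("Hex", "Hex"), (None, None))  # two roots
    with pytest.raises(ValueError):
        GlycanTopology(("Hex", "Hex"), (1, 0))  # cycle, no root
    with pytest.raises(ValueError):
        GlycanTopology.from_text("Hex(Hex")
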