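"""RBH extraction, clique ortholog sets and the Venn partition."""

import numpy as np
import pytest

from estkit import homology as hom
from estkit import orthology as orth

from _oracles import enumerate_assignments


def mk_hit(q, s, e, bit):
    return hom.Hit(q, s, 0.9, 100, 5, 0, 0, 100, 0, 100, e, bit)


def edge(sa, ga, sb, gb, bit=100.0):
    return orth.RBHEdge(sa, ga, sb, gb, bit / 2, bit / 2)


def test_mutual_best_hits_form_an_edge():
    ab = [mk_hit("x", "y", 1e-30, 200), mk_hit("x", "y2", 1e-10, 100)]
    ba = [mk_hit("y", "x", 1e-30, 200)]
    edges = orth.rbh_pairs(ab, ba, "A", "B")
    assert [(e.gene_a, e.gene_b) for e in edges] == [("x", "y")]


def test_non_mutual_best_is_no_edge():
    ab = [mk_hit("x", "y", 1e-30, 200)]
    ba = [mk_hit("y", "xprime", 1e-40, 300), mk_hit("y", "x", 1e-30, 200)]
    assert orth.rbh_pairs(ab, ba, "A", "B") == []


def test_cutoff_and_self_hits_are_excluded():
    ab = [mk_hit("x", "y", 1e-5, 200)]  # above the 1e-6 cutoff
    ba = [mk_hit("y", "x", 1e-30, 200)]
    assert orth.rbh_pairs(ab, ba, "A", "B") == []
    ab = [mk_hit("g", "g", 0.0, 500), mk_hit("g", "y", 1e-30, 200)]
    ba = [mk_hit("y", "g", 1e-30, 200)]
    assert [(e.gene_a, e.gene_b)
            for e in orth.rbh_pairs(ab, ba, "A", "B")] == [("g", "y")]


def _random_hit_tables(rng, n_a, n_b):
    hits_ab, hits_ba = [], []
    for i in range(n_a):
        for j in range(n_b):
            if rng.random() < 0.5:
                continue
            e = 10.0 ** -rng.integers(7, 40)
            bit = float(rng.integers(50, 400))
            hits_ab.append(mk_hit(f"a{i}", f"b{j}", e, bit))
            if rng.random() < 0.8:
                hits_ba.append(mk_hit(f"b{j}", f"a{i}", e, bit))
    return hits_ab, hits_ba


def test_rbh_matches_bruteforce_on_random_tables(rng):
    """Independent recomputation: best hit per gene found by explicit
    scan with the same tie rules, then mutuality checked by hand."""
    for _ in range(20):
        ab, ba = _random_hit_tables(rng, 6, 6)
        edges = orth.rbh_pairs(ab, ba, "A", "B")
        def best(hits, q):
            pool = [h for h in hits
                    if h.query == q and h.evalue < 1e-6 and h.query != h.subject]
            pool.sort(key=lambda h: (h.evalue, -h.bitscore, -h.identity,
                                     h.subject))
            return pool[0].subject if pool else None
        expect = []
        for i in range(6):
            y = best(ab, f"a{i}")
            if y is not None and best(ba, y) == f"a{i}":
                expect.append((f"a{i}", y))
        assert sorted((e.gene_a, e.gene_b) for e in edges) == sorted(expect)


def test_three_clique_is_one_set():
    edges = [edge("A", "a1", "B", "b1"), edge("A", "a1", "C", "c1"),
             edge("B", "b1", "C", "c1")]
    osets, assignment = orth.ortholog_sets(edges)
    assert len(osets) == 1
    assert osets[0].genes == {"A": "a1", "B": "b1", "C": "c1"}
    assert all(v.genes == osets[0].genes for v in assignment.values())


def test_pair_only_and_unconnected_genes():
    edges = [edge("A", "a2", "B", "b2")]
    osets, assignment = orth.ortholog_sets(edges)
    assert osets[0].genes == {"A": "a2", "B": "b2"}
    venn = orth.venn_partition(assignment, {"A": 3, "B": 2, "C": 4})
    df = venn.counts
    # c-genes have no edges: all land in the species-only region
    assert df[(df.region == "C") & (df.species == "C")]["count"].item() == 4


def test_broken_triangle_resolved_by_bit_score():
    """a3 pairs with b3 and d3 but b3-d3 is missing: the higher-scoring
    pair wins, deterministically."""
    edges = [edge("A", "a3", "B", "b3", bit=150.0),
             edge("A", "a3", "D", "d3", bit=300.0)]
    for _ in range(3):
        osets, assignment = orth.ortholog_sets(edges)
        chosen = assignment[("A", "a3")]
        assert chosen.genes == {"A": "a3", "D": "d3"}


def _random_edge_instance(rng, n_species=4, max_genes=5):
    species = [f"s{i}" for i in range(n_species)]
    genes = {sp: [f"{sp}g{j}" for j in range(rng.integers(1, max_genes + 1))]
             for sp in species}
    edges = []
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            # random partial matching preserves best-hit uniqueness
            ga = list(genes[sa])
            gb = list(genes[sb])
            rng.shuffle(ga)
            rng.shuffle(gb)
            for x, y in zip(ga, gb):
                if rng.random() < 0.6:
                    bit = float(rng.integers(100, 1000))
                    edges.append(orth.RBHEdge(sa, x, sb, y, bit / 2, bit / 2))
    return genes, edges


def test_assignment_matches_exhaustive_enumeration(rng):
    for _ in range(30):
        _genes, edges = _random_edge_instance(rng)
        if not edges:
            continue
        _osets, assignment = orth.ortholog_sets(edges)
        oracle = enumerate_assignments(edges)
        mine = {g: frozenset(sorted(s.genes.items()))
                for g, s in assignment.items()}
        want = {g: frozenset(sorted(dict(m).items()))
                for g, m in oracle.items()}
        assert mine == want


def test_every_emitted_set_is_a_clique(rng):
    for _ in range(10):
        _genes, edges = _random_edge_instance(rng)
        keys = {e.key() for e in edges}
        osets, _ = orth.ortholog_sets(edges)
        for oset in osets:
            members = sorted(oset.genes.items())
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert frozenset((a, b)) in keys


def test_venn_additivity_enforced(rng):
    genes, edges = _random_edge_instance(rng)
    _osets, assignment = orth.ortholog_sets(edges)
    totals = {sp: len(gs) for sp, gs in genes.items()}
    venn = orth.venn_partition(assignment, totals)
    sums = venn.counts.groupby("species")["count"].sum().to_dict()
    assert sums == {sp: n for sp, n in totals.items() if n}


def test_uniqueness_violation_is_an_internal_error():
    edges = [edge("A", "a1", "B", "b1"), edge("A", "a1", "B", "b2")]
    with pytest.raises(RuntimeError):
        orth.ortholog_sets(edges)


def test_single_species_no_edges():
    venn = orth.venn_partition({}, {"A": 7})
    df = venn.counts
    assert len(df) == 1
    assert df.iloc[0]["region"] == "A" and df.iloc[0]["count"] == 7
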