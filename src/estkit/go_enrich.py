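"""GO transfer, level-3 rollup and Fisher's exact enrichment.

Annotations are inherited from the single top database hit of each unigene
(E < 1e-6).  Terms are rolled up to ontology level 3, where the namespace
root is level 1 and a term's level is one plus its minimum is_a distance to
the root; a term at level >= 3 contributes to every level-3 ancestor, at
most once per unigene.  Per level-3 term, the unigene proportion is
compared against a reference annotation set with a two-sided Fisher exact
test (hypergeometric enumeration; tables with probability at most that of
the observed one are summed).  Stars mark p < 0.01 (*) and p < 0.001 (**);
a Bonferroni column is emitted alongside but the stars use raw p.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .homology import Hit, hits_by_query, top_hit

NAMESPACES = {"biological_process": "BP", "molecular_function": "MF",
              "cellular_component": "CC"}


@dataclasses.dataclass
class OntologyDAG:
    """is_a-only GO graph with per-namespace roots and term levels."""

    graph: nx.DiGraph            # edges child -> parent (is_a only)
    names: dict[str, str]
    namespaces: dict[str, str]   # term -> BP/MF/CC
    roots: dict[str, str]        # BP/MF/CC -> root term id
    levels: dict[str, int]       # root = 1
    alt_map: dict[str, str]

    def resolve(self, term: str) -> str | None:
        if term in self.graph:
            return term
        return self.alt_map.get(term)

    def level3_ancestors(self, term: str) -> set[str]:
        """Level-3 ancestors of a term (including itself when at level 3)."""
        t = self.resolve(term)
        if t is None:
            return set()
        reach = {t} | nx.descendants(self.graph, t)  # upward closure
        return {a for a in reach if self.levels.get(a) == 3}


def load_ontology(obo_path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 file: is_a edges only, obsoletes dropped,
    alt_ids mapped to their primary term.  A cyclic is_a graph is a hard
    failure naming one offending cycle."""
    full = obonet.read_obo(str(obo_path))  # skips obsolete terms
    g = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_map: dict[str, str] = {}
    for node, data in full.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
        ns = data.get("namespace", "biological_process")
        namespaces[node] = NAMESPACES.get(ns, ns)
        for alt in data.get("alt_id", []):
            alt_map[alt] = node
    for child, parent, key in full.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cyclic is_a structure: {cycle}")
    roots: dict[str, str] = {}
    levels: dict[str, int] = {}
    for node in g.nodes:
        if g.out_degree(node) == 0:
            ns = namespaces[node]
            if ns in roots:
                raise ValueError(f"multiple roots for namespace {ns}")
            roots[ns] = node
    rev = g.reverse()
    for ns, root in roots.items():
        for node, dist in nx.single_source_shortest_path_length(
                rev, root).items():
            lvl = dist + 1
            if node not in levels or lvl < levels[node]:
                levels[node] = lvl
    return OntologyDAG(g, names, namespaces, roots, levels, alt_map)


def transfer_annotations(unigene_hits: Sequence[Hit],
                         reference_go: Mapping[str, Sequence[str]],
                         evalue_cutoff: float = 1e-6) -> dict[str, set]:
    """Each unigene inherits the full GO set of its single top hit."""
    out: dict[str, set] = {}
    for uid, hits in hits_by_query(
            [h for h in unigene_hits if h.evalue < evalue_cutoff]).items():
        best = top_hit(hits)
        terms = reference_go.get(best.subject)
        if terms:
            out[uid] = set(terms)
    return out


def rollup_level3(annotations: Mapping[str, Sequence[str]],
                  dag: OntologyDAG) -> pd.DataFrame:
    """Per-namespace level-3 term -> number of annotated units.

    Each unigene (or gene) contributes at most once per level-3 ancestor.
    Terms above level 3 contribute nothing; terms missing from the DAG are
    skipped.
    """
    counts: dict[str, int] = {}
    for _uid, terms in annotations.items():
        bins: set[str] = set()
        for t in terms:
            bins |= dag.level3_ancestors(t)
        for b in bins:
            counts[b] = counts.get(b, 0) + 1
    rows = [(dag.namespaces[t], t, dag.names[t], c)
            for t, c in counts.items()]
    rows.sort()
    return pd.DataFrame(rows, columns=["namespace", "term", "name", "count"])


def fisher_two_sided(a: int, n1: int, b: int, n2: int) -> float:
    """Exact two-sided Fisher p for the 2x2 table [[a, n1-a], [b, n2-b]].

    Margins (n1, n2, a+b) are fixed; all tables whose hypergeometric
    probability is at most that of the observed table (within a relative
    guard of 1e-7 for floating-point ties) are summed.  All-zero margins
    give p = 1 by convention.
    """
    for v in (a, n1, b, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a > n1 or b > n2:
        raise ValueError("cell counts exceed their totals")
    k = a + b
    if k == 0 or n1 + n2 == 0 or k == n1 + n2:
        return 1.0
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = range(lo, hi + 1)
    pmf = hypergeom.pmf(list(support), n1 + n2, k, n1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, max(p, float(p_obs)))


def compare_proportions(species_counts: Mapping[str, int], n1: int,
                        reference_counts: Mapping[str, int], n2: int,
                        dag: OntologyDAG) -> pd.DataFrame:
    """Per level-3 term: proportions, direction, two-sided p and stars.

    The vocabularies are unioned (missing counts are 0); rows are sorted
    by namespace then term name.  Stars: * for p < 0.01, ** for p < 0.001;
    the Bonferroni-adjusted p is reported but not used for the stars.
    """
    vocab = sorted(set(species_counts) | set(reference_counts))
    rows = []
    n_tests = len(vocab)
    for term in vocab:
        a = int(species_counts.get(term, 0))
        b = int(reference_counts.get(term, 0))
        p1 = a / n1 if n1 else 0.0
        p2 = b / n2 if n2 else 0.0
        p = fisher_two_sided(a, n1, b, n2)
        stars = "**" if p < 0.001 else ("*" if p < 0.01 else "")
        direction = "over" if p1 > p2 else ("under" if p1 < p2 else "equal")
        rows.append((dag.namespaces.get(term, "?"), term,
                     dag.names.get(term, term), a, n1, b, n2,
                     p1, p2, direction, p, min(1.0, p * n_tests), stars))
    df = pd.DataFrame(rows, columns=["namespace", "term", "name",
                                     "count_species", "total_species",
                                     "count_reference", "total_reference",
                                     "prop_species", "prop_reference",
                                     "direction", "p_two_sided",
                                     "p_bonferroni", "stars"])
    return df.sort_values(["namespace", "name"]).reset_index(drop=True)
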