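"""Reciprocal-best-hit orthology across two to four species.

An RBH edge joins genes x (species A) and y (species B) when y is x's top
hit in B and x is y's top hit in A.  Multi-species ortholog sets are
pairwise-RBH-complete cliques: a candidate set (one gene per species) is
valid only if every pair in it is an RBH edge.  Each gene is assigned to
its maximum-size valid set (ties by largest summed bit score, then by
lexicographic species subset), which induces the Venn-region partition:
per species, region counts sum exactly to the species' gene total.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import Hit, hits_by_query, top_hit


@dataclasses.dataclass(frozen=True)
class RBHEdge:
    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    bit_ab: float
    bit_ba: float

    @property
    def bit_sum(self) -> float:
        return self.bit_ab + self.bit_ba

    def key(self) -> frozenset:
        return frozenset(((self.species_a, self.gene_a),
                          (self.species_b, self.gene_b)))


@dataclasses.dataclass
class OrthologSet:
    genes: dict[str, str]  # species -> gene, 2-4 entries
    bit_sum: float

    @property
    def species(self) -> frozenset:
        return frozenset(self.genes)

    def key(self) -> frozenset:
        return frozenset(self.genes.items())


def rbh_pairs(hits_a_to_b: Sequence[Hit], hits_b_to_a: Sequence[Hit],
              species_a: str, species_b: str,
              evalue_cutoff: float = 1e-6) -> list[RBHEdge]:
    """RBH edges between two species from the two directional hit lists.

    Hits at or above the cutoff and self-hits are discarded before top-hit
    extraction (top_hit tie rules decide bests uniquely).
    """
    def bests(hits: Sequence[Hit]) -> dict[str, Hit]:
        eligible = [h for h in hits
                    if h.evalue < evalue_cutoff and h.query != h.subject]
        return {q: top_hit(hs)
                for q, hs in hits_by_query(eligible).items()}

    best_ab = bests(hits_a_to_b)
    best_ba = bests(hits_b_to_a)
    edges = []
    for x in sorted(best_ab):
        h_ab = best_ab[x]
        y = h_ab.subject
        h_ba = best_ba.get(y)
        if h_ba is not None and h_ba.subject == x:
            edges.append(RBHEdge(species_a, x, species_b, y,
                                 h_ab.bitscore, h_ba.bitscore))
    return edges


def _partner_map(edges: Iterable[RBHEdge]) -> dict:
    """gene (species, id) -> {other species: (partner id, bit_sum)}."""
    partners: dict = {}
    for e in edges:
        a = (e.species_a, e.gene_a)
        b = (e.species_b, e.gene_b)
        for x, y in ((a, b), (b, a)):
            slot = partners.setdefault(x, {})
            if y[0] in slot and slot[y[0]][0] != y[1]:
                raise RuntimeError(
                    f"RBH uniqueness violated for {x} in species {y[0]}")
            slot[y[0]] = (y[1], e.bit_sum)
    return partners


def ortholog_sets(edges: Sequence[RBHEdge]
                  ) -> tuple[list[OrthologSet], dict]:
    """Assign every gene touched by an edge to its maximal valid clique.

    Returns (deduplicated OrthologSet list, per-gene assignment mapping
    (species, gene) -> OrthologSet).  Candidate sets for gene g are the
    subsets of {g} union g's unique RBH partners that contain g; a set is
    valid iff every pair in it is an edge.  Maximum size wins; ties break
    by largest summed bit score over the set's pairwise edges, then by
    lexicographically smallest species subset.
    """
    edge_index = {e.key(): e for e in edges}
    partners = _partner_map(edges)
    assignment: dict = {}
    emitted: dict = {}
    for g in sorted(partners):
        others = sorted(partners[g])
        best_choice = None
        for r in range(len(others), 0, -1):
            for combo in itertools.combinations(others, r):
                members = [g] + [(sp, partners[g][sp][0]) for sp in combo]
                pairs = list(itertools.combinations(members, 2))
                es = [edge_index.get(frozenset(p)) for p in pairs]
                if any(e is None for e in es):
                    continue
                bit = sum(e.bit_sum for e in es)
                subset = tuple(sorted(sp for sp, _ in members))
                # larger size, then larger bit sum, then smaller subset
                choice = (members, bit, subset)
                if best_choice is None:
                    best_choice = choice
                else:
                    b_members, b_bit, b_subset = best_choice
                    if (len(members), bit) > (len(b_members), b_bit) or (
                            (len(members), bit) == (len(b_members), b_bit)
                            and subset < b_subset):
                        best_choice = choice
            if best_choice is not None:
                break
        members, bit, _ = best_choice
        oset = OrthologSet(dict(sorted(members)), bit)
        emitted.setdefault(oset.key(), oset)
        assignment[g] = emitted[oset.key()]
    return list(emitted.values()), assignment


@dataclasses.dataclass
class VennPartition:
    """Counts of genes per species per species-subset region."""

    counts: pd.DataFrame       # columns: region, species, count
    species_totals: dict


def venn_partition(assignment: Mapping, species_totals: Mapping[str, int]
                   ) -> VennPartition:
    """Tabulate the Venn regions induced by per-gene set assignment.

    ``assignment`` maps (species, gene) -> OrthologSet for genes in a
    clique; genes counted in ``species_totals`` but not assigned fall to
    their species-only region.  The per-species additivity invariant
    (region counts sum to the species total) is enforced, not just
    reported: a violation raises.
    """
    counter: dict = {}
    for (sp, _gene), oset in assignment.items():
        region = tuple(sorted(oset.species))
        counter[(region, sp)] = counter.get((region, sp), 0) + 1
    for sp, total in species_totals.items():
        assigned = sum(c for (region, s), c in counter.items() if s == sp)
        if assigned > total:
            raise RuntimeError(f"species {sp}: {assigned} genes assigned to "
                               f"regions but only {total} exist")
        solo = total - assigned
        if solo:
            counter[((sp,), sp)] = counter.get(((sp,), sp), 0) + solo
    rows = [("+".join(region), sp, c)
            for (region, sp), c in sorted(counter.items())]
    df = pd.DataFrame(rows, columns=["region", "species", "count"])
    for sp, total in species_totals.items():
        if df[df["species"] == sp]["count"].sum() != total:
            raise RuntimeError(f"Venn additivity violated for {sp}")
    return VennPartition(df, dict(species_totals))


def sets_table(osets: Sequence[OrthologSet]) -> pd.DataFrame:
    """One row per ortholog set: species:gene columns, size, bit sum."""
    rows = []
    for oset in sorted(osets, key=lambda o: (-len(o.genes),
                                             sorted(o.genes.items()))):
        rows.append({"size": len(oset.genes),
                     "bit_sum": round(oset.bit_sum, 1),
                     **{sp: g for sp, g in sorted(oset.genes.items())}})
    return pd.DataFrame(rows)


def pairwise_region_counts(partition: VennPartition) -> pd.DataFrame:
    """Convenience: counts of genes per exact region per species."""
    return partition.counts.pivot_table(index="region", columns="species",
                                        values="count", fill_value=0,
                                        aggfunc="sum")
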