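"""Taxonomic binning, novel-gene classification and gene-panel screening.

Each unigene's lineage category comes from the lineage path of its top hit
against the reference protein database (threshold E < 1e-4); unigenes with
no passing hit are NoHit.  Category precedence is most-specific-first
(Viruses -> Archaea -> Bacteria -> Fungi -> Chlorophyta -> Streptophyta ->
OtherEukaryotes) because lineage strings can contain several matching
tokens.  A unigene is "novel" when it has a predicted coding region but no
passing hit; NoHit without a coding region is binned as
noncoding-or-contaminant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .homology import AlignerParams, Hit, hits_by_query, search, top_hit

LINEAGE_CATEGORIES = ("Archaea", "Viruses", "Bacteria", "Fungi",
                      "Chlorophyta", "Streptophyta", "OtherEukaryotes",
                      "NoHit")

# precedence order for token matching (most specific first)
_PRECEDENCE = ("Viruses", "Archaea", "Bacteria", "Fungi", "Chlorophyta",
               "Streptophyta")


def assign_lineage(unigene: str, hits: Sequence[Hit],
                   lineage_map: Mapping[str, str],
                   evalue_cutoff: float = 1e-4) -> str:
    """Lineage category of one unigene from its top passing hit."""
    passing = [h for h in hits if h.evalue < evalue_cutoff]
    if not passing:
        return "NoHit"
    best = top_hit(passing)
    lineage = lineage_map.get(best.subject)
    if lineage is None:
        return "OtherEukaryotes"  # unresolvable subject; logged by caller
    tokens = {t.strip() for t in lineage.split(";")}
    for cat in _PRECEDENCE:
        if cat in tokens:
            return cat
    return "OtherEukaryotes"


def assign_lineages(hits: Sequence[Hit], unigene_ids: Sequence[str],
                    lineage_map: Mapping[str, str],
                    evalue_cutoff: float = 1e-4) -> dict[str, str]:
    by_query = hits_by_query(hits)
    return {uid: assign_lineage(uid, by_query.get(uid, []), lineage_map,
                                evalue_cutoff)
            for uid in unigene_ids}


def summarize_lineages(assignments: Mapping[str, str]) -> pd.DataFrame:
    """Counts and proportions per category; proportions sum to 1."""
    total = len(assignments)
    rows = []
    for cat in LINEAGE_CATEGORIES:
        n = sum(1 for c in assignments.values() if c == cat)
        rows.append((cat, n, n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["category", "count", "proportion"])


def classify_novel(coding_verdicts: Mapping[str, str],
                   lineage_assignments: Mapping[str, str]) -> dict[str, str]:
    """Partition unigenes into {novel, known, noncoding-or-contaminant}.

    novel = predicted coding region AND no passing database hit;
    NoHit without a coding region = noncoding-or-contaminant;
    everything with a hit = known.
    """
    out = {}
    for uid, verdict in coding_verdicts.items():
        nohit = lineage_assignments.get(uid, "NoHit") == "NoHit"
        if nohit and verdict == "coding":
            out[uid] = "novel"
        elif nohit:
            out[uid] = "noncoding-or-contaminant"
        else:
            out[uid] = "known"
    return out


def cross_library_novel_overlap(novel_a: Mapping[str, str],
                                novel_b: Mapping[str, str],
                                params: AlignerParams = AlignerParams(),
                                evalue_cutoff: float = 1e-4) -> dict:
    """Directional hit counts and RBH count between two novel peptide sets.

    Mirrors the cross-library check of how many of one library's novel
    genes have any counterpart in the other library.
    """
    if set(novel_a) & set(novel_b):
        raise ValueError("novel sets must be disjoint")
    if not novel_a or not novel_b:
        return {"a_with_hit": 0, "b_with_hit": 0, "rbh_pairs": 0}
    ab = [h for h in search(novel_a, novel_b, "prot_prot", params)
          if h.evalue < evalue_cutoff]
    ba = [h for h in search(novel_b, novel_a, "prot_prot", params)
          if h.evalue < evalue_cutoff]
    best_ab = {q: top_hit(hs) for q, hs in hits_by_query(ab).items()}
    best_ba = {q: top_hit(hs) for q, hs in hits_by_query(ba).items()}
    rbh = sum(1 for x, h in best_ab.items()
              if best_ba.get(h.subject) is not None
              and best_ba[h.subject].subject == x)
    return {"a_with_hit": len(best_ab), "b_with_hit": len(best_ba),
            "rbh_pairs": rbh}


def screen_gene_panel(panel_proteins: Mapping[str, str],
                      unigenes_nt: Mapping[str, str],
                      params: AlignerParams = AlignerParams(),
                      evalue_cutoff: float = 1e-20) -> pd.DataFrame:
    """Translated search of unigenes against a panel of reference proteins.

    Per panel gene: the number of unigenes with a passing hit (E below the
    stringent panel cutoff) and the best/worst passing E-values, mirroring
    the hit-count and E-value-range reporting of a candidate-gene screen.
    """
    rows = []
    hits: list[Hit] = []
    if unigenes_nt and panel_proteins:
        hits = [h for h in search(unigenes_nt, dict(panel_proteins),
                                  "transl_prot", params)
                if h.evalue < evalue_cutoff]
    by_subject: dict[str, list[Hit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject, []).append(h)
    for gene in sorted(panel_proteins):
        gh = by_subject.get(gene, [])
        n = len({h.query for h in gh})
        best = min((h.evalue for h in gh), default=float("nan"))
        worst = max((h.evalue for h in gh), default=float("nan"))
        rows.append((gene, n, best, worst))
    return pd.DataFrame(rows, columns=["panel_gene", "n_hits",
                                       "best_evalue", "worst_evalue"])
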