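"""Greedy overlap clustering of reads into unigenes.

A simplified, deterministic stand-in for the classic OLC assemblers used in
EST projects, with the study design's two-step structure: the 454 reads are
clustered first, then the step-1 contigs and singletons are combined with
the Sanger reads in a second pass.  The acceptance rule for a merge is the
classic "100 bp overlap at 95% identity" criterion, with identity computed
over the overlap region only.

Reads are processed longest-first and joined to the first existing cluster
whose consensus yields an accepted overlap (first-accept, not best-accept),
which makes the procedure deterministic and near-linear at desk scale.
Consensus columns are majority-called; ties keep the incumbent base.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import edlib
import pandas as pd

from ._seq import gc_content, revcomp
from .io import Read

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclasses.dataclass(frozen=True)
class OverlapParams:
    min_overlap: int = 100      # aligned columns
    min_identity: float = 0.95  # matches / aligned columns of the overlap
    seed_k: int = 16            # exact k-mer seed length
    band: int = 20              # slack when bucketing seed diagonals

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap < self.seed_k:
            raise ValueError("min_overlap must be >= seed_k")


@dataclasses.dataclass
class Overlap:
    length: int          # aligned columns
    identity: float
    a_start: int
    a_end: int
    b_start: int         # coordinates on the oriented copy of b
    b_end: int
    orientation: str     # "+" if b used as given, "-" if reverse-complemented
    cigar: str           # extended CIGAR of b-sub vs a-sub

    @property
    def score(self) -> float:
        return self.length * self.identity

    @property
    def offset(self) -> int:
        """Position of oriented-b base 0 in a's coordinates (may be < 0)."""
        return self.a_start - self.b_start


def _seed_kmers(seq: str, k: int, step: int = 1) -> dict[str, list[int]]:
    """Positions of unmasked, unambiguous k-mers (lowercase = masked)."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(seq) - k + 1, step):
        kmer = seq[i:i + k]
        if kmer.isupper() and set(kmer) <= set("ACGT"):
            index.setdefault(kmer, []).append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned columns) from an extended CIGAR."""
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _try_diagonal(a: str, b: str, d: int,
                  params: OverlapParams) -> Overlap | None:
    """Evaluate the overlap implied by diagonal offset d (b0 at a-coord d)."""
    a_start, a_end = max(0, d), min(len(a), d + len(b))
    b_start, b_end = max(0, -d), min(len(b), len(a) - d)
    if a_end - a_start < params.min_overlap - params.band:
        return None
    a_sub = a[a_start:a_end].upper()
    b_sub = b[b_start:b_end].upper()
    res = edlib.align(b_sub, a_sub, mode="NW", task="path")
    if res["cigar"] is None:
        return None
    matches, columns = _cigar_stats(res["cigar"])
    if columns < params.min_overlap:
        return None
    identity = matches / columns
    if identity < params.min_identity:
        return None
    return Overlap(columns, identity, a_start, a_end, b_start, b_end, "+",
                   res["cigar"])


def find_overlap(a: str, b: str, params: OverlapParams = OverlapParams(),
                 a_index: dict | None = None) -> Overlap | None:
    """Best dovetail/containment overlap between a and b, or None.

    Candidate placements come from shared exact k-mers (diagonal seeding,
    nearby diagonals bucketed within the band); each candidate region is
    verified by edit-distance alignment.  Both orientations of b are tried;
    the reported coordinates of b refer to the oriented copy.
    """
    if min(len(a), len(b)) < params.seed_k:
        return None
    if a_index is None:
        a_index = _seed_kmers(a, params.seed_k)
    best: Overlap | None = None
    for orientation in "+-":
        bseq = b if orientation == "+" else revcomp(b)
        votes: dict[int, int] = {}
        for j, kmer in ((j, bseq[j:j + params.seed_k].upper())
                        for j in range(0, len(bseq) - params.seed_k + 1, 4)):
            for i in a_index.get(kmer, ()):
                d = i - j
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            continue
        # bucket diagonals within the band, keep the top few buckets
        buckets: list[list[int]] = []
        for d in sorted(votes, key=lambda x: -votes[x]):
            for bucket in buckets:
                if abs(bucket[0] - d) <= params.band:
                    bucket.append(d)
                    break
            else:
                buckets.append([d])
        for bucket in buckets[:3]:
            d = max(bucket, key=lambda x: (votes[x], -abs(x)))
            ov = _try_diagonal(a, bseq, d, params)
            if ov is not None:
                ov = dataclasses.replace(ov, orientation=orientation)
                if best is None or ov.score > best.score:
                    best = ov
    return best


@dataclasses.dataclass
class Unigene:
    id: str
    consensus: str
    members: list[tuple[str, str]]       # (read id, technology)
    kind: str                            # "contig" | "singleton"
    provenance: str  # "contig"|"454-only-contig"|"454-single-read"|"sanger-only"
    n_reads: int
    accepted_overlaps: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class _Item:
    """One clusterable sequence: a read or a previous-step contig."""

    id: str
    seq: str
    members: list[tuple[str, str]]
    tag: str  # "454read" | "454contig" | "sanger" | "read"


class _Cluster:
    def __init__(self, item: _Item, params: OverlapParams) -> None:
        self.params = params
        self.items = [item]
        self.members = list(item.members)
        self.columns: list[dict[str, int]] = [
            {c.upper(): 1} for c in item.seq]
        self.consensus = item.seq.upper()
        self.overlaps: list[Overlap] = []
        self._index: dict | None = None

    def index(self) -> dict:
        # step 1: the overlap verifier must see every diagonal offset
        if self._index is None:
            self._index = _seed_kmers(self.consensus, self.params.seed_k)
        return self._index

    def _recall(self) -> None:
        cons = []
        for col, old in zip(self.columns, self.consensus):
            best = max(col.items(), key=lambda kv: (kv[1], kv[0] == old))
            # tie keeps the incumbent consensus base
            top = best[1]
            winners = [b for b, c in col.items() if c == top]
            cons.append(old if old in winners else sorted(winners)[0])
        self.consensus = "".join(cons)
        self._index = None

    def merge(self, item: _Item, ov: Overlap) -> None:
        seq = item.seq.upper()
        if ov.orientation == "-":
            seq = revcomp(seq)
        d = ov.offset
        old_len = len(self.consensus)
        # walk the overlap alignment column by column, adding read evidence
        ai, bi = ov.a_start, ov.b_start
        for num, op in _CIGAR_RE.findall(ov.cigar):
            for _ in range(int(num)):
                if op in "=XM":
                    col = self.columns[ai]
                    col[seq[bi]] = col.get(seq[bi], 0) + 1
                    ai += 1
                    bi += 1
                elif op == "I":   # insertion in b relative to consensus
                    bi += 1
                elif op == "D":   # consensus column with no read evidence
                    ai += 1
        if d < 0:  # b sticks out on the left: prepend new columns
            self.columns = [{c: 1} for c in seq[:-d]] + self.columns
            self.consensus = seq[:-d] + self.consensus
        right_ext = d + len(seq) - old_len  # b sticks out on the right
        if right_ext > 0:
            self.columns.extend({c: 1} for c in seq[-right_ext:])
            self.consensus = self.consensus + seq[-right_ext:]
        self.items.append(item)
        self.members.extend(item.members)
        self.overlaps.append(ov)
        self._recall()


def _cluster_items(items: Sequence[_Item],
                   params: OverlapParams) -> list[_Cluster]:
    """Greedy longest-first, first-accept clustering of generic items."""
    order = sorted(items, key=lambda it: (-len(it.seq), it.id))
    clusters: list[_Cluster] = []
    kmer_to_clusters: dict[str, set[int]] = {}

    def register(ci: int) -> None:
        for kmer in _seed_kmers(clusters[ci].consensus, params.seed_k,
                                step=2):
            kmer_to_clusters.setdefault(kmer, set()).add(ci)

    for item in order:
        candidates: set[int] = set()
        # odd stride so sampled read/consensus k-mers cover both parities
        for kmer in _seed_kmers(item.seq, params.seed_k, step=3):
            candidates |= kmer_to_clusters.get(kmer, set())
            candidates |= kmer_to_clusters.get(revcomp(kmer), set())
        joined = False
        for ci in sorted(candidates):  # creation order = first-accept rule
            cl = clusters[ci]
            ov = find_overlap(cl.consensus, item.seq, params,
                              a_index=cl.index())
            if ov is not None:
                cl.merge(item, ov)
                register(ci)
                joined = True
                break
        if not joined:
            clusters.append(_Cluster(item, params))
            register(len(clusters) - 1)
    return clusters


def cluster_reads(reads: Sequence[Read],
                  params: OverlapParams = OverlapParams()) -> list[Unigene]:
    """Single-pass clustering of a read set into contigs and singletons."""
    items = [_Item(r.id, r.seq, [(r.id, r.technology)], "read")
             for r in reads]
    clusters = _cluster_items(items, params)
    out = []
    for i, cl in enumerate(clusters):
        kind = "contig" if len(cl.items) >= 2 else "singleton"
        out.append(Unigene(f"unigene_{i:05d}", cl.consensus,
                           list(cl.members), kind, kind, len(cl.members),
                           list(cl.overlaps)))
    return out


def two_step_assemble(reads_454: Sequence[Read], reads_sanger: Sequence[Read],
                      params: OverlapParams = OverlapParams()
                      ) -> list[Unigene]:
    """The study design's two-step assembly with provenance tracking.

    Step 1 clusters the 454 reads alone; step 2 clusters the step-1 contigs
    and singletons together with the Sanger reads.  Final clusters with a
    single step-2 item are singletons whose provenance records what that
    item was (a step-1 contig that stayed alone, a lone 454 read, or a lone
    Sanger read); the three classes partition the singleton set.
    """
    step1 = _cluster_items(
        [_Item(r.id, r.seq, [(r.id, r.technology)], "454read")
         for r in reads_454], params)
    items: list[_Item] = []
    for i, cl in enumerate(step1):
        if len(cl.items) >= 2:
            items.append(_Item(f"c454_{i:05d}", cl.consensus,
                               list(cl.members), "454contig"))
        else:
            items.append(cl.items[0])
    items.extend(_Item(r.id, r.seq, [(r.id, r.technology)], "sanger")
                 for r in reads_sanger)
    step2 = _cluster_items(items, params)
    out = []
    for i, cl in enumerate(step2):
        if len(cl.items) >= 2:
            kind, prov = "contig", "contig"
        else:
            kind = "singleton"
            prov = {"454contig": "454-only-contig",
                    "454read": "454-single-read",
                    "sanger": "sanger-only",
                    "read": "454-single-read"}[cl.items[0].tag]
        out.append(Unigene(f"unigene_{i:05d}", cl.consensus,
                           list(cl.members), kind, prov, len(cl.members),
                           list(cl.overlaps)))
    return out


def assembly_stats(groups: dict[str, Iterable[str]]) -> pd.DataFrame:
    """Count / mean length / pooled GC per named class of sequences.

    Pooled GC counts G+C over A+C+G+T across all sequences of the class;
    ambiguity codes are excluded from both numerator and denominator.
    An empty input yields an empty table, not an error.
    """
    rows = []
    for name, seqs in groups.items():
        seqs = list(seqs)
        if not seqs:
            continue
        lengths = [len(s) for s in seqs]
        rows.append((name, len(seqs), sum(lengths) / len(lengths),
                     gc_content("".join(seqs))))
    return pd.DataFrame(rows, columns=["class", "count", "mean_length",
                                       "gc_fraction"])


def unigene_stats(unigenes: Sequence[Unigene]) -> pd.DataFrame:
    groups: dict[str, list[str]] = {}
    for u in unigenes:
        groups.setdefault(u.provenance, []).append(u.consensus)
    if unigenes:
        groups["all"] = [u.consensus for u in unigenes]
    return assembly_stats(groups)


def read_stats(reads: Sequence[Read]) -> pd.DataFrame:
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.technology, []).append(r.seq)
    return assembly_stats(groups)
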