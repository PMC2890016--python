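"""Seeded local-alignment search with Karlin-Altschul E-values.

A desk-scale stand-in for a protein database search tool: exact-word
seeding on diagonals, a two-hit trigger, banded affine-gap local extension,
and E-values from the Karlin-Altschul formula E = K*m*n*exp(-lambda*S)
with fixed default gapped-BLOSUM62-style constants (no effective-length
correction; the thresholds used downstream are coarse).  Supports
protein-protein and six-frame translated nucleotide-protein search, an
exact Smith-Waterman oracle for verification, and an import/export adapter
for the standard 12-column tabular hit format so external search tools can
replace the built-in aligner bit-exactly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import revcomp, translate

_NEG = -1e30


@dataclasses.dataclass(frozen=True)
class AlignerParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0        # gap of length k costs gap_open + k*gap_extend
    gap_extend: float = 1.0
    seed_k: int = 4               # exact word length (aa)
    two_hit_window: int = 40      # max diagonal distance between seed words
    band: int = 24                # half-width of the extension band
    exact_limit: int = 250        # pairs at most this long get a full-width
                                  # (exact) gapped extension
    lam: float = 0.267            # Karlin-Altschul lambda
    kappa: float = 0.041          # Karlin-Altschul K
    evalue_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and K must be > 0")
        if self.seed_k < 2:
            raise ValueError("seed_k must be >= 2")

    def load_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        try:
            mat = substitution_matrices.load(self.matrix)
        except FileNotFoundError as exc:
            raise ValueError(f"unknown substitution matrix "
                             f"{self.matrix!r}") from exc
        alphabet = str(mat.alphabet)
        index = {c: i for i, c in enumerate(alphabet)}
        return np.asarray(mat, dtype=float), index


def evalue(score: float, m: int, n: int, params: AlignerParams) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return params.kappa * m * n * math.exp(-params.lam * score)


def bitscore(score: float, params: AlignerParams) -> float:
    """(lambda*S - ln K) / ln 2."""
    return (params.lam * score - math.log(params.kappa)) / math.log(2.0)


@dataclasses.dataclass
class Hit:
    """One query-subject local alignment, 0-based half-open coordinates."""

    query: str
    subject: str
    identity: float        # fraction in [0, 1]
    length: int            # aligned columns
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: float | None = None
    frame: int | None = None   # +-1..3 in translated mode

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


# --------------------------------------------------------------------------
# exact Smith-Waterman oracle

def smith_waterman(a: str, b: str,
                   params: AlignerParams = AlignerParams()
                   ) -> tuple[float, Align.Alignment | None]:
    """Exact affine-gap local alignment optimum (test oracle, guarded).

    A gap of length k costs gap_open + k*gap_extend, matching the banded
    search.  Refuses sequences longer than 2,000 residues: the oracle is
    for verification, not production search.
    """
    if max(len(a), len(b)) > 2000:
        raise ValueError("smith_waterman oracle guard: sequences > 2000")
    mat = substitution_matrices.load(params.matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    score = float(aligner.score(a, b))
    if score <= 0:
        return 0.0, None
    return score, next(iter(aligner.align(a, b)))


# --------------------------------------------------------------------------
# banded extension

def _fill_band(qi, si, mat, center, band, open_cost, ext_cost, neg):
    """Banded affine local-alignment matrix fill (jitted when possible)."""
    m = qi.shape[0]
    n = si.shape[0]
    W = 2 * band + 1
    H = np.full((m + 1, W), neg)
    E = np.full((m + 1, W), neg)
    F = np.full((m + 1, W), neg)
    ptr = np.zeros((m + 1, W), dtype=np.uint8)  # 0 stop,1 diag,2 horiz,3 vert
    goe = np.zeros((m + 1, W), dtype=np.uint8)
    gof = np.zeros((m + 1, W), dtype=np.uint8)
    for i in range(m + 1):
        base = i + center - band
        for k in range(W):
            j = base + k
            if j < 0 or j > n:
                continue
            if i == 0 or j == 0:
                H[i, k] = 0.0
                continue
            diag = neg
            if H[i - 1, k] > neg / 2:
                diag = H[i - 1, k] + mat[qi[i - 1], si[j - 1]]
            # horizontal: gap in query (consume s), same row, k-1
            if k - 1 >= 0:
                h_open = H[i, k - 1] - open_cost
                h_ext = E[i, k - 1] - ext_cost
                E[i, k] = max(h_open, h_ext)
                goe[i, k] = 1 if h_open >= h_ext else 0
            # vertical: gap in subject (consume q), row i-1, k+1
            if k + 1 < W:
                v_open = H[i - 1, k + 1] - open_cost
                v_ext = F[i - 1, k + 1] - ext_cost
                F[i, k] = max(v_open, v_ext)
                gof[i, k] = 1 if v_open >= v_ext else 0
            best = 0.0
            code = 0
            if diag > best:
                best, code = diag, 1
            if E[i, k] > best:
                best, code = E[i, k], 2
            if F[i, k] > best:
                best, code = F[i, k], 3
            H[i, k] = best
            ptr[i, k] = code
    return H, E, F, ptr, goe, gof


try:  # pragma: no cover - plain-Python fallback keeps behaviour identical
    from numba import njit
    _fill_band = njit(cache=False)(_fill_band)
except ImportError:
    pass


def _banded_align(q: str, s: str, center: int, params: AlignerParams,
                  mat: np.ndarray, index: dict[str, int]
                  ) -> tuple[float, tuple] | None:
    """Best local alignment with j - i restricted to center +- band.

    Returns (score, (qstart, qend, sstart, send, matches, columns,
    gapopens)) or None if no positive-scoring cell exists.
    """
    n = len(s)
    band = params.band
    open_cost = params.gap_open + params.gap_extend
    ext_cost = params.gap_extend
    qi = np.array([index.get(c, index.get("X", 0)) for c in q.upper()],
                  dtype=np.int64)
    si = np.array([index.get(c, index.get("X", 0)) for c in s.upper()],
                  dtype=np.int64)
    H, E, F, ptr, gap_open_flag_e, gap_open_flag_f = _fill_band(
        qi, si, mat, center, band, float(open_cost), float(ext_cost), _NEG)

    flat = np.argmax(H)
    bi, bk = np.unravel_index(flat, H.shape)
    score = float(H[bi, bk])
    if score <= 0:
        return None
    # traceback
    i, k = int(bi), int(bk)
    qend, send = i, i + center - band + k
    matches = columns = gapopens = 0
    state = "H"
    while True:
        j = i + center - band + k
        if state == "H":
            code = ptr[i, k]
            if code == 0 or H[i, k] <= 0:
                break
            if code == 1:
                columns += 1
                if q[i - 1].upper() == s[j - 1].upper():
                    matches += 1
                i, k = i - 1, k
            elif code == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consume subject
            columns += 1
            opened = gap_open_flag_e[i, k]
            k -= 1
            if opened:
                gapopens += 1
                state = "H"
        else:               # gap in subject, consume query
            columns += 1
            opened = gap_open_flag_f[i, k]
            i, k = i - 1, k + 1
            if opened:
                gapopens += 1
                state = "H"
    qstart, sstart = i, i + center - band + k
    return score, (qstart, qend, sstart, send, matches, columns, gapopens)


# --------------------------------------------------------------------------
# seeded search

def _words(seq: str, k: int) -> Iterable[tuple[str, int]]:
    s = seq.upper()
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        if "X" not in w and "*" not in w:
            yield w, i


def _seed_diagonals(q: str, word_index: dict, params: AlignerParams
                    ) -> dict[str, list[int]]:
    """Two-hit seeded diagonals per subject id."""
    hits: dict[tuple[str, int], list[int]] = {}
    for w, qpos in _words(q, params.seed_k):
        for sid, spos in word_index.get(w, ()):
            hits.setdefault((sid, qpos - spos), []).append(qpos)
    out: dict[str, list[int]] = {}
    for (sid, diag), positions in hits.items():
        positions.sort()
        ok = False
        for idx, a in enumerate(positions):
            for b in positions[idx + 1:]:
                if b - a > params.two_hit_window:
                    break
                if b - a >= params.seed_k:  # non-overlapping second word
                    ok = True
                    break
            if ok:
                break
        if ok:
            out.setdefault(sid, []).append(diag)
    return out


def _cluster_diagonals(diags: list[int], band: int,
                       cap: int = 8) -> list[int]:
    diags = sorted(set(diags))
    centers: list[int] = []
    for d in diags:
        if not centers or d - centers[-1] > band:
            centers.append(d)
    return centers[:cap]


def _build_word_index(subjects: dict[str, str],
                      params: AlignerParams) -> dict:
    index: dict[str, list[tuple[str, int]]] = {}
    for sid in sorted(subjects):
        for w, pos in _words(subjects[sid], params.seed_k):
            index.setdefault(w, []).append((sid, pos))
    return index


def _search_protein(queries: dict[str, str], subjects: dict[str, str],
                    params: AlignerParams, n_db: int,
                    frame_of: dict[str, int] | None = None,
                    query_name: dict[str, str] | None = None) -> list[Hit]:
    mat, index = params.load_matrix()
    word_index = _build_word_index(subjects, params)
    hits: list[Hit] = []
    for qid in sorted(queries):
        q = queries[qid]
        if len(q) < params.seed_k:
            continue
        for sid, diags in sorted(
                _seed_diagonals(q, word_index, params).items()):
            s = subjects[sid]
            best = None
            if max(len(q), len(s)) <= params.exact_limit:
                # short pair: one band spanning the whole matrix (exact)
                wide = dataclasses.replace(
                    params, band=(len(q) + len(s)) // 2 + 1)
                centers = [(len(s) - len(q)) // 2]
                res = _banded_align(q, s, centers[0], wide, mat, index)
                if res:
                    best = res
            else:
                for center in _cluster_diagonals(
                        [-d for d in diags], params.band):
                    # diag d = qpos - spos; _banded_align uses j-i = spos-qpos
                    res = _banded_align(q, s, center, params, mat, index)
                    if res and (best is None or res[0] > best[0]):
                        best = res
            if best is None:
                continue
            score, (qs, qe, ss, se, matches, columns, gapopens) = best
            m = len(q)
            E = evalue(score, m, n_db, params)
            if E > params.evalue_cutoff:
                continue
            name = (query_name or {}).get(qid, qid)
            # diagonal columns consume one residue of each sequence
            diag_cols = (qe - qs) + (se - ss) - columns
            hits.append(Hit(name, sid, matches / columns if columns else 0.0,
                            columns, diag_cols - matches,
                            gapopens, qs, qe, ss, se, E,
                            bitscore(score, params), score,
                            (frame_of or {}).get(qid)))
    return hits


def search(queries: dict[str, str], subjects: dict[str, str],
           mode: str = "prot_prot",
           params: AlignerParams = AlignerParams()) -> list[Hit]:
    """Seeded banded local-alignment search of queries against subjects.

    ``mode`` is "prot_prot" (both peptide) or "transl_prot" (nucleotide
    queries searched in all six reading frames against peptide subjects;
    the winning frame is reported on each hit and hit query coordinates
    refer to the translated frame).  One best hit per query-subject pair is
    reported when its E-value is at most the cutoff.  Self-hits (query id
    == subject id) are retained; downstream stages exclude them.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    if mode not in ("prot_prot", "transl_prot"):
        raise ValueError(f"unknown mode {mode!r}")
    n_db = sum(len(s) for s in subjects.values())
    if mode == "prot_prot":
        return _search_protein(queries, subjects, params, n_db)
    frame_queries: dict[str, str] = {}
    frame_of: dict[str, int] = {}
    name_of: dict[str, str] = {}
    for qid in sorted(queries):
        nt = queries[qid]
        for fr in (1, 2, 3, -1, -2, -3):
            src = nt if fr > 0 else revcomp(nt)
            pep = translate(src[abs(fr) - 1:])
            key = f"{qid}##frame{fr}"
            frame_queries[key] = pep
            frame_of[key] = fr
            name_of[key] = qid
    raw = _search_protein(frame_queries, subjects, params, n_db,
                          frame_of, name_of)
    best: dict[tuple[str, str], Hit] = {}
    for h in raw:
        key = (h.query, h.subject)
        if key not in best or (h.evalue, -h.bitscore) < (
                best[key].evalue, -best[key].bitscore):
            best[key] = h
    return [best[k] for k in sorted(best)]


def top_hit(hits_for_query: Sequence[Hit]) -> Hit | None:
    """Best hit of one query: min E, then max bit score, max identity,
    lexicographically smallest subject id.  None for an empty list."""
    if not hits_for_query:
        return None
    qids = {h.query for h in hits_for_query}
    if len(qids) > 1:
        raise ValueError(f"mixed query ids: {sorted(qids)}")
    return min(hits_for_query,
               key=lambda h: (h.evalue, -h.bitscore, -h.identity, h.subject))


def hits_by_query(hits: Iterable[Hit]) -> dict[str, list[Hit]]:
    out: dict[str, list[Hit]] = {}
    for h in hits:
        out.setdefault(h.query, []).append(h)
    return out


# --------------------------------------------------------------------------
# 12-column tabular interchange

_COLUMNS = ["query", "subject", "pident", "length", "mismatches", "gapopens",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def export_tabular_hits(hits: Sequence[Hit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (1-based inclusive)."""
    rows = []
    for h in hits:
        rows.append((h.query, h.subject, round(h.identity * 100, 2),
                     h.length, h.mismatches, h.gapopens,
                     h.qstart + 1, h.qend, h.sstart + 1, h.send,
                     h.evalue, round(h.bitscore, 1)))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False,
                                                header=False)


def import_tabular_hits(path: str | Path) -> list[Hit]:
    """Parse 12-column tabular search results into Hit records.

    Input coordinates are 1-based inclusive and identities are
    percentages; both are converted to the package conventions (0-based
    half-open, fractions).  Malformed lines raise with their line number.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(fields)}")
            try:
                hits.append(Hit(
                    fields[0], fields[1], float(fields[2]) / 100.0,
                    int(fields[3]), int(fields[4]), int(fields[5]),
                    int(fields[6]) - 1, int(fields[7]),
                    int(fields[8]) - 1, int(fields[9]),
                    float(fields[10]), float(fields[11])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits
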