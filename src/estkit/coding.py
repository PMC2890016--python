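"""Hexamer-based coding-region prediction with frameshift tolerance.

A phase-aware hexamer log-odds model (coding vs background, one table per
codon phase) is trained from a supplied CDS set, then a dynamic program
over the three reading-frame states per strand locates the best-scoring
local coding segment.  Switching frames mid-segment is allowed at a fixed
penalty, which absorbs the single-base indel errors typical of
pyrosequencing consensus sequences without a full HMM with explicit
insert/delete states.  Internal stop codons on the chosen path are allowed
but each pays a fixed penalty.  A unigene whose best segment scores below
``min_score`` or is shorter than ``min_len`` gets the verdict "none"
(no coding region detected).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import CODON_TABLE, STOP_CODONS, encode, revcomp

_N_HEX = 4096


@dataclasses.dataclass
class CodingModel:
    """Phase-aware hexamer log-odds table (3 x 4096)."""

    log_odds: np.ndarray          # shape (3, 4096)
    pseudocount: float
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.shape != (3, _N_HEX):
            raise ValueError("log_odds must have shape (3, 4096)")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        hexamers = ["".join("ACGT"[(h >> (2 * (5 - i))) & 3]
                            for i in range(6)) for h in range(_N_HEX)]
        return pd.DataFrame({"hexamer": hexamers,
                             "phase0": self.log_odds[0],
                             "phase1": self.log_odds[1],
                             "phase2": self.log_odds[2]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   pseudocount: float = 1.0) -> "CodingModel":
        df = df.sort_values("hexamer").reset_index(drop=True)
        return cls(np.vstack([df["phase0"], df["phase1"], df["phase2"]]),
                   pseudocount)


def _hexamer_codes(seq: str) -> np.ndarray:
    """Code of the hexamer starting at each position (-1 if ambiguous)."""
    enc = encode(seq)
    n = len(enc) - 5
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for off in range(6):
        window = enc[off:off + n]
        codes = codes * 4 + np.where(window < 0, 0, window)
        bad |= window < 0
    codes[bad] = -1
    return codes


def _count_hexamers(seqs: Iterable[str], phased: bool) -> np.ndarray:
    counts = np.zeros((3 if phased else 1, _N_HEX), dtype=float)
    for seq in seqs:
        codes = _hexamer_codes(seq)
        valid = codes >= 0
        if phased:
            phases = np.arange(len(codes)) % 3
            for ph in range(3):
                sel = codes[valid & (phases == ph)]
                np.add.at(counts[ph], sel, 1.0)
        else:
            np.add.at(counts[0], codes[valid], 1.0)
    return counts


def train_hexamer_model(cds_sequences: Sequence[str],
                        background_sequences: Sequence[str],
                        pseudocount: float = 1.0,
                        trained_on: str = "") -> CodingModel:
    """log(freq_coding,phase / freq_background,phase) with pseudocounts.

    CDS inputs must be in frame (position 0 = codon start).  Background
    sequences are counted with the same positional phase convention, so a
    coding set identical to the background yields an all-zero table.
    """
    if not cds_sequences or not background_sequences:
        raise ValueError("both training classes must be non-empty")
    for name, seqs in (("coding", cds_sequences),
                       ("background", background_sequences)):
        if sum(len(s) for s in seqs) < 10_000:
            raise ValueError(f"{name} training set shorter than 10 kb")
    cod = _count_hexamers(cds_sequences, phased=True) + pseudocount
    bg = _count_hexamers(background_sequences, phased=True) + pseudocount
    cod_freq = cod / cod.sum(axis=1, keepdims=True)
    bg_freq = bg / bg.sum(axis=1, keepdims=True)
    return CodingModel(np.log(cod_freq / bg_freq), pseudocount, trained_on)


@dataclasses.dataclass
class CodingPrediction:
    verdict: str                      # "coding" | "none"
    strand: str | None = None         # "+" | "-"
    segment: tuple[int, int] | None = None  # on the input, 0-based half-open
    score: float = 0.0
    frame_path: list = dataclasses.field(default_factory=list)
    n_frameshifts: int = 0
    peptide: str = ""


def position_scores(seq: str, model: CodingModel,
                    stop_penalty: float = 100.0) -> np.ndarray:
    """M[p, f]: log-odds of the hexamer at p read in frame f.

    Frame f means codon boundaries sit at positions congruent to f mod 3;
    the hexamer at p is scored with the phase table (p - f) mod 3.
    Positions whose hexamer contains a non-nucleotide score 0.  A stop
    codon starting at an in-frame position costs ``stop_penalty``.
    """
    codes = _hexamer_codes(seq)
    n = len(codes)
    M = np.zeros((n, 3))
    if n == 0:
        return M
    pos = np.arange(n)
    valid = codes >= 0
    for f in range(3):
        ph = (pos - f) % 3
        M[valid, f] = model.log_odds[ph[valid], codes[valid]]
    s = seq.upper()
    for p in range(len(s) - 2):
        if s[p:p + 3] in STOP_CODONS:
            f = p % 3
            if p < n:
                M[p, f] -= stop_penalty
    return M


def _best_segment(M: np.ndarray, frameshift_penalty: float
                  ) -> tuple[float, int, int, list[tuple[int, int]]]:
    """Max-scoring local path through (position, frame) states.

    Returns (score, start, end_exclusive, path) where path lists
    (position, frame) for every scored position.  Within-frame moves are
    free; switching frames costs ``frameshift_penalty``.
    """
    n = M.shape[0]
    if n == 0:
        return 0.0, 0, 0, []
    best = np.full((n, 3), -np.inf)
    back = np.full((n, 3), -2, dtype=np.int64)  # -1 = segment start
    best[0] = M[0]
    back[0] = -1
    for p in range(1, n):
        prev = best[p - 1]
        for f in range(3):
            cand_score = prev[f]
            cand_from = f
            for g in range(3):
                if g == f:
                    continue
                s = prev[g] - frameshift_penalty
                if s > cand_score:
                    cand_score, cand_from = s, g
            if cand_score < 0.0:
                cand_score, cand_from = 0.0, -1
            best[p, f] = cand_score + M[p, f]
            back[p, f] = cand_from
    p, f = np.unravel_index(np.argmax(best), best.shape)
    score = float(best[p, f])
    path = []
    while True:
        path.append((int(p), int(f)))
        prev_f = back[p, f]
        if prev_f == -1 or p == 0:
            break
        p, f = p - 1, prev_f
    path.reverse()
    start = path[0][0]
    end = path[-1][0] + 6  # last scored hexamer covers 6 nt
    return score, start, end, path


def predict_coding(seq: str, model: CodingModel, min_score: float = 70.0,
                   min_len: int = 150, frameshift_penalty: float = 20.0,
                   stop_penalty: float = 100.0) -> CodingPrediction:
    """Best local coding segment over both strands of `seq`.

    The '-' strand is scored on the reverse complement; reported segment
    coordinates are always on the input sequence.  Ties between strands
    keep '+'.
    """
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    results = {}
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        M = position_scores(s, model, stop_penalty)
        results[strand] = _best_segment(M, frameshift_penalty)
    strand = "+" if results["+"][0] >= results["-"][0] else "-"
    score, start, end, path = results[strand]
    if strand == "-":
        start, end = len(seq) - end, len(seq) - start
    if score < min_score or (end - start) < min_len:
        return CodingPrediction("none", score=score)
    shifts = sum(1 for a, b in zip(path, path[1:]) if a[1] != b[1])
    oriented = seq if strand == "+" else revcomp(seq)
    peptide = _path_peptide(oriented, path)
    return CodingPrediction("coding", strand, (start, end), score, path,
                            shifts, peptide)


def _path_peptide(seq: str, path: list[tuple[int, int]]) -> str:
    """Translate the codons visited by the frame path; frameshifts emit X."""
    if not path:
        return ""
    pep = []
    s = seq.upper()
    prev_f = path[0][1]
    for p, f in path:
        if f != prev_f:
            pep.append("X")
            prev_f = f
        if (p - f) % 3 == 0:
            codon = s[p:p + 3]
            pep.append(CODON_TABLE.get(codon, "X"))
    return "".join(pep)


def classify_unigenes(unigenes: dict[str, str], model: CodingModel,
                      min_score: float = 70.0, min_len: int = 150,
                      frameshift_penalty: float = 20.0,
                      stop_penalty: float = 100.0
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Predict coding segments for a set of unigenes.

    Returns (per-unigene table, peptides for coding unigenes).  The table
    reports verdict, strand, segment, score and frameshift count per
    unigene, and the summary columns let the caller report the count and
    fraction with no coding region detected.
    """
    rows = []
    peptides: dict[str, str] = {}
    for uid in sorted(unigenes):
        seq = unigenes[uid]
        if len(seq) < 6:
            pred = CodingPrediction("none")
        else:
            pred = predict_coding(seq, model, min_score, min_len,
                                  frameshift_penalty, stop_penalty)
        if pred.verdict == "coding":
            peptides[uid] = pred.peptide
            seg = pred.segment
            rows.append((uid, "coding", pred.strand, seg[0], seg[1],
                         pred.score, pred.n_frameshifts))
        else:
            rows.append((uid, "none", "", -1, -1, pred.score, 0))
    table = pd.DataFrame(rows, columns=["unigene", "verdict", "strand",
                                        "start", "end", "score",
                                        "n_frameshifts"])
    return table, peptides


def coding_summary(table: pd.DataFrame) -> dict:
    total = len(table)
    none = int((table["verdict"] == "none").sum()) if total else 0
    return {"total": total, "no_coding_region": none,
            "fraction_none": none / total if total else float("nan")}
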