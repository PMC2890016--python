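"""Read cleaning before clustering.

Collapses the classic pre-assembly toolchain (adapter trimming,
quality-based end trimming, low-complexity masking, minimum-length filter)
into one configurable stage.  Adapters are searched only at the read ends
(they are ligated there) by approximate Hamming match; quality trimming is
a sliding-window mean rule applied inward from both ends; low complexity is
scored DUST-style on triplet composition.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Read


@dataclasses.dataclass(frozen=True)
class TrimParams:
    adapters: tuple[str, ...] = ()
    max_adapter_mismatch: int = 1
    quality_window: int = 20
    quality_floor: float = 15.0
    min_len: int = 60
    dust_threshold: float = 2.0
    dust_window: int = 64

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        for v in (self.max_adapter_mismatch, self.quality_window,
                  self.quality_floor, self.dust_threshold, self.dust_window):
            if v < 0:
                raise ValueError("thresholds must be >= 0")


@dataclasses.dataclass
class TrimResult:
    read: Read | None          # None when discarded
    trimmed_left: int
    trimmed_right: int
    verdict: str               # "kept" | "discarded"


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _strip_adapters(seq: str, params: TrimParams) -> tuple[int, int]:
    """Return (left, right) cut sizes after removing end-anchored adapters."""
    left = right = 0
    changed = True
    while changed:
        changed = False
        for ad in params.adapters:
            n = len(ad)
            if n == 0 or n > len(seq) - left - right:
                continue
            if _hamming_le(seq[left:left + n], ad,
                           params.max_adapter_mismatch):
                left += n
                changed = True
            end = len(seq) - right
            if n <= end - left and _hamming_le(seq[end - n:end], ad,
                                               params.max_adapter_mismatch):
                right += n
                changed = True
    return left, right


def trim_read(read: Read, params: TrimParams) -> TrimResult:
    """Adapter + quality trim one read; discard if it ends up too short.

    The output sequence is always a contiguous substring of the input;
    the decision depends only on this read.
    """
    if not read.seq:
        raise ValueError("read must be non-empty")
    if read.qual is not None and len(read.qual) != len(read.seq):
        raise ValueError("quality/sequence length mismatch")
    left, right = _strip_adapters(read.seq, params)
    lo, hi = left, len(read.seq) - right
    if read.qual is not None and params.quality_window > 0:
        q = np.asarray(read.qual, dtype=float)
        w = params.quality_window
        while hi - lo > 0:
            window = q[lo:min(lo + w, hi)]
            if window.mean() >= params.quality_floor:
                break
            lo += 1
        while hi - lo > 0:
            window = q[max(lo, hi - w):hi]
            if window.mean() >= params.quality_floor:
                break
            hi -= 1
    if hi - lo < params.min_len:
        return TrimResult(None, lo, len(read.seq) - hi, "discarded")
    out = Read(read.id, read.seq[lo:hi], read.technology,
               None if read.qual is None else list(read.qual[lo:hi]))
    return TrimResult(out, lo, len(read.seq) - hi, "kept")


def dust_score(window: str) -> float:
    """DUST-style triplet score: sum c*(c-1)/2 over triplet counts, per span."""
    s = window.upper()
    k = len(s) - 2
    if k < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(k):
        t = s[i:i + 3]
        counts[t] = counts.get(t, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (k - 1)


def mask_low_complexity(seq: str, params: TrimParams) -> str:
    """Lowercase-mask windows whose DUST score exceeds the threshold.

    Scoring is case-insensitive, so masking is idempotent.  Masked bases
    are retained (length preserved); downstream clustering skips lowercase
    bases when seeding.
    """
    if not seq:
        return seq
    w = max(8, params.dust_window)
    half = max(1, w // 2)
    masked = np.zeros(len(seq), dtype=bool)
    for start in range(0, max(1, len(seq) - half), half):
        window = seq[start:start + w]
        if dust_score(window) > params.dust_threshold:
            masked[start:start + len(window)] = True
    return "".join(c.lower() if m else c.upper()
                   for c, m in zip(seq, masked))


def prep_reads(reads: Sequence[Read], params: TrimParams,
               mask: bool = True) -> tuple[list[Read], pd.DataFrame]:
    """Trim + mask a read set; returns kept reads and a per-read audit log."""
    kept: list[Read] = []
    rows = []
    for read in reads:
        res = trim_read(read, params)
        rows.append((read.id, res.trimmed_left, res.trimmed_right,
                     res.verdict))
        if res.read is not None:
            if mask:
                res.read.seq = mask_low_complexity(res.read.seq, params)
            kept.append(res.read)
    log = pd.DataFrame(rows, columns=["read", "trimmed_left",
                                      "trimmed_right", "verdict"])
    return kept, log
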