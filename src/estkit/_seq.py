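"""Small nucleotide/peptide helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard nuclear genetic code.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

NT = np.array(list("ACGT"))
_NT_INDEX = {c: i for i, c in enumerate("ACGT")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Pooled GC over unambiguous bases; ambiguity codes excluded entirely."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    return gc / total if total else float("nan")


def translate(seq: str) -> str:
    """Translate in frame 0; incomplete tail codon dropped, unknowns 'X'."""
    s = seq.upper()
    return "".join(CODON_TABLE.get(s[i:i + 3], "X")
                   for i in range(0, len(s) - 2, 3))


def random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    """IID nucleotide string with P(G or C) = gc (G/C and A/T equiprobable)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(NT[rng.choice(4, size=n, p=p)])


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1."""
    return np.array([_NT_INDEX.get(c, -1) for c in seq.upper()],
                    dtype=np.int64)


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out to n per-stage generators by stable enumeration."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]
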