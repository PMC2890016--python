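"""Hexamer model training and the frameshift-aware coding DP."""

import numpy as np
import pytest

from estkit import coding as cod
from estkit import simulate as sim
from estkit._seq import random_nt, revcomp

from _oracles import best_framepath_score


def _shuffle(seqs, rng):
    out = []
    for s in seqs:
        a = np.array(list(s))
        rng.shuffle(a)
        out.append("".join(a))
    return out


def test_symmetric_training_gives_zero_table(rng):
    seqs = [random_nt(rng, 3000, 0.5) for _ in range(5)]
    model = cod.train_hexamer_model(seqs, seqs)
    assert np.abs(model.log_odds).max() == 0.0


def test_pseudocounts_keep_absent_hexamers_finite(rng):
    # alphabet restricted to A/C: most hexamers absent from both classes
    coding = ["".join(rng.choice(["A", "C"], 6000)) for _ in range(3)]
    bg = ["".join(rng.choice(["A", "C"], 6000)) for _ in range(3)]
    model = cod.train_hexamer_model(coding, bg)
    assert np.all(np.isfinite(model.log_odds))
    ggg = cod._hexamer_codes("GGGGGG")[0]
    assert abs(model.log_odds[0, ggg]) < 0.05  # smoothing, never +-inf


def test_training_counts_match_independent_counter(rng):
    cds = [sim._draw_cds(rng, 160, 0.5) for _ in range(25)]
    bg = _shuffle(cds, rng)
    pc = 1.0
    model = cod.train_hexamer_model(cds, bg, pseudocount=pc)
    # recompute one phase/hexamer cell with a literal string counter
    counts_cod = {}
    counts_bg = {}
    tot_cod = [0, 0, 0]
    tot_bg = [0, 0, 0]
    for store, tot, seqs in ((counts_cod, tot_cod, cds),
                             (counts_bg, tot_bg, bg)):
        for s in seqs:
            for i in range(len(s) - 5):
                store[(i % 3, s[i:i + 6])] = store.get((i % 3, s[i:i + 6]),
                                                       0) + 1
                tot[i % 3] += 1
    for hexamer in ("ATGGCT", "GCTGCT", "TTTTTT"):
        code = cod._hexamer_codes(hexamer)[0]
        for ph in range(3):
            f_cod = (counts_cod.get((ph, hexamer), 0) + pc) / \
                (tot_cod[ph] + 4096 * pc)
            f_bg = (counts_bg.get((ph, hexamer), 0) + pc) / \
                (tot_bg[ph] + 4096 * pc)
            assert model.log_odds[ph, code] == pytest.approx(
                np.log(f_cod / f_bg))


def test_training_errors():
    with pytest.raises(ValueError):
        cod.train_hexamer_model([], ["A" * 20000])
    with pytest.raises(ValueError):
        cod.train_hexamer_model(["ATG" * 10], ["A" * 20000])


def test_planted_cds_recovered_in_frame(coding_model, rng):
    """A planted CDS with UTRs is called coding, '+' strand, in the true
    frame, with the segment covering most of the CDS."""
    cds = sim._draw_cds(rng, 200, 0.48)
    utr5 = random_nt(rng, 70, 0.48)
    tx = utr5 + cds + random_nt(rng, 150, 0.48)
    pred = cod.predict_coding(tx, coding_model)
    assert pred.verdict == "coding" and pred.strand == "+"
    start, end = pred.segment
    true_start, true_end = len(utr5), len(utr5) + len(cds)
    overlap = min(end, true_end) - max(start, true_start)
    # local scoring may shave segment boundaries; the bulk must be covered
    assert overlap >= 0.8 * len(cds)
    frames = [f for _, f in pred.frame_path]
    assert max(set(frames), key=frames.count) == true_start % 3


def test_strand_antisymmetry(coding_model, rng):
    cds = sim._draw_cds(rng, 150, 0.48)
    tx = random_nt(rng, 50, 0.48) + cds + random_nt(rng, 80, 0.48)
    fwd = cod.predict_coding(tx, coding_model)
    rev = cod.predict_coding(revcomp(tx), coding_model)
    assert fwd.score == pytest.approx(rev.score)
    assert {fwd.strand, rev.strand} == {"+", "-"}
    assert rev.segment == (len(tx) - fwd.segment[1],
                           len(tx) - fwd.segment[0])


def test_single_insertion_creates_one_frameshift(coding_model, rng):
    cds = sim._draw_cds(rng, 200, 0.48)
    mid = len(cds) // 2
    broken = cds[:mid] + "A" + cds[mid:]
    pred = cod.predict_coding(broken, coding_model)
    assert pred.verdict == "coding"
    assert pred.n_frameshifts == 1
    assert "X" in pred.peptide  # frameshift position emits X


def test_dp_matches_exhaustive_enumeration(coding_model, rng):
    """On short sequences the DP optimum equals brute-force enumeration of
    all frame paths (the optimum provably uses few switches at the default
    penalty, which is asserted too)."""
    for trial in range(30):
        n = int(rng.integers(20, 61))
        if trial % 3 == 0:
            seq = random_nt(rng, n, 0.5)
        else:  # planted coding fragment, possibly with one insertion
            seq = sim._draw_cds(rng, n // 3 + 2, 0.48)[:n]
            if trial % 3 == 2:
                k = n // 2
                seq = seq[:k] + "G" + seq[k:]
        M = cod.position_scores(seq, coding_model)
        score, _s, _e, path = cod._best_segment(M, 20.0)
        shifts = sum(1 for a, b in zip(path, path[1:]) if a[1] != b[1])
        assert shifts <= 2
        assert score == pytest.approx(best_framepath_score(M, 20.0))


def test_removing_frameshift_option_never_helps(coding_model, rng):
    """With penalty -> infinity the constrained optimum can only drop."""
    seq = sim._draw_cds(rng, 40, 0.48)
    M = cod.position_scores(seq, coding_model)
    free, *_ = cod._best_segment(M, 0.0)
    constrained, *_ = cod._best_segment(M, 1e9)
    default, *_ = cod._best_segment(M, 20.0)
    assert free >= default >= constrained


def test_classify_unigenes_outputs(coding_model, rng):
    txs = {}
    for i in range(4):
        txs[f"c{i}"] = random_nt(rng, 60, 0.48) + \
            sim._draw_cds(rng, 150, 0.48) + random_nt(rng, 60, 0.48)
    for i in range(3):
        txs[f"n{i}"] = random_nt(rng, 450, 0.48)
    table, peps = cod.classify_unigenes(txs, coding_model)
    verdicts = dict(zip(table["unigene"], table["verdict"]))
    assert all(verdicts[f"c{i}"] == "coding" for i in range(4))
    assert set(peps) == {u for u, v in verdicts.items() if v == "coding"}
    summary = cod.coding_summary(table)
    assert summary["total"] == 7
    assert summary["no_coding_region"] == sum(
        1 for v in verdicts.values() if v == "none")
    empty_table, empty_peps = cod.classify_unigenes({}, coding_model)
    assert empty_table.empty and not empty_peps
    assert np.isnan(cod.coding_summary(empty_table)["fraction_none"])


def test_reported_segment_score_meets_threshold(coding_model, rng):
    for _ in range(10):
        tx = random_nt(rng, 40, 0.48) + sim._draw_cds(rng, 120, 0.48)
        pred = cod.predict_coding(tx, coding_model)
        if pred.verdict == "coding":
            assert pred.score >= 70.0
            assert pred.segment[1] - pred.segment[0] >= 150


def test_model_roundtrip_via_frame(coding_model):
    df = coding_model.to_frame()
    back = cod.CodingModel.from_frame(df)
    assert np.allclose(back.log_odds, coding_model.log_odds)
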