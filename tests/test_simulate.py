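"""Generator contracts: determinism, planted truth, error models."""

import numpy as np
import pytest

from estkit import simulate as sim
from estkit._seq import gc_content, revcomp


def test_generator_is_deterministic(small_params):
    a = sim.generate_families(small_params)
    b = sim.generate_families(small_params)
    assert a.genes == b.genes
    assert a.truth.family_of == b.truth.family_of
    assert [(t.id, t.seq, t.coding) for sp in a.transcripts
            for t in a.transcripts[sp]] == \
           [(t.id, t.seq, t.coding) for sp in b.transcripts
            for t in b.transcripts[sp]]


def test_zero_divergence_gives_identical_copies():
    params = sim.GeneratorParams(
        n_families=6, divergence=0.0, paralog_rate=0.0,
        presence_profile={frozenset(("ref_plant", "charoA", "charoB",
                                     "ref_chlorophyte")): 1.0},
        seed=3)
    fam = sim.generate_families(params)
    for members in fam.family_members.values():
        copies = {fam.genes[sp][gids[0]] for sp, gids in members.items()}
        assert len(copies) == 1


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        sim.GeneratorParams(n_families=0)
    with pytest.raises(ValueError):
        sim.GeneratorParams(divergence=-0.1)
    with pytest.raises(ValueError):
        sim.GeneratorParams(cds_len=0)
    with pytest.raises(ValueError):
        sim.GeneratorParams(species_list=("a", "a", "b", "c"))


def test_realized_gc_tracks_target_on_megabase():
    """Direct-count check: >=1 Mb of generated sequence lands within
    +-0.02 of a uniform 0.49 GC target."""
    gc = {sp: 0.49 for sp in ("ref_plant", "charoA", "charoB",
                              "ref_chlorophyte")}
    params = sim.GeneratorParams(n_families=300, gc_target=gc, seed=5)
    fam = sim.generate_families(params)
    pooled = "".join(t.seq for sp in fam.transcripts
                     for t in fam.transcripts[sp])
    assert len(pooled) >= 1_000_000
    assert abs(gc_content(pooled) - 0.49) <= 0.02


def test_coding_intervals_are_consistent(family_data):
    truth = family_data.truth
    for sp, txs in family_data.transcripts.items():
        for t in txs:
            iv = truth.coding_interval_of[t.id]
            assert iv == t.coding
            if iv is not None:
                strand, start, end = iv
                assert 0 <= start < end <= len(t.seq)
                assert (end - start) % 3 == 0


def _zero_noise(tech="flx454", **kw):
    base = sim.flx454_model if tech == "flx454" else sim.sanger_model
    return base(substitution_rate=0.0, homopolymer_indel_rate=0.0,
                adapter_seq="", **kw)


def test_zero_noise_reads_are_exact_substrings(family_data):
    txs = family_data.transcripts["charoA"]
    by_id = {t.id: t.seq for t in txs}
    reads, truth = sim.simulate_reads(txs, _zero_noise(), 2.0, seed=9)
    assert reads
    assert len(truth.read_origin) == len(reads)
    for r in reads:
        tid, start, end, strand = truth.read_origin[r.id]
        expect = by_id[tid][start:end]
        if strand == "-":
            expect = revcomp(expect)
        assert r.seq == expect


def test_sanger_reads_are_five_prime_anchored(family_data):
    txs = family_data.transcripts["charoB"]
    reads, truth = sim.simulate_reads(
        txs, _zero_noise("sanger"), 1.5, seed=4)
    for r in reads:
        _tid, start, _end, strand = truth.read_origin[r.id]
        assert start == 0 and strand == "+"


def test_long_read_request_truncates_to_transcript_end(family_data):
    txs = family_data.transcripts["charoA"][:3]
    model = _zero_noise("sanger", mean_len=100_000, len_sd=0.0)
    reads, truth = sim.simulate_reads(txs, model, 2.0, seed=2)
    for r in reads:
        tid, start, end, _ = truth.read_origin[r.id]
        assert end == len({t.id: t for t in txs}[tid].seq)


def test_substitution_rate_matches_observed_mismatches(family_data):
    """Binomial check: 1% substitution rate -> observed mismatch fraction
    within [0.008, 0.012] over >=1e5 simulated bases."""
    txs = family_data.transcripts["charoA"]
    by_id = {t.id: t.seq for t in txs}
    model = sim.flx454_model(substitution_rate=0.01,
                             homopolymer_indel_rate=0.0, adapter_seq="")
    reads, truth = sim.simulate_reads(txs, model, 10.0, seed=12)
    mism = total = 0
    for r in reads:
        tid, start, end, strand = truth.read_origin[r.id]
        ref = by_id[tid][start:end]
        if strand == "-":
            ref = revcomp(ref)
        mism += sum(1 for x, y in zip(r.seq, ref) if x != y)
        total += len(ref)
    assert total >= 100_000
    assert 0.008 <= mism / total <= 0.012


def test_adapter_is_prepended(family_data):
    txs = family_data.transcripts["charoA"][:2]
    model = _zero_noise()
    model = sim.flx454_model(substitution_rate=0, homopolymer_indel_rate=0,
                             adapter_seq="ACGTACGTAA")
    reads, _ = sim.simulate_reads(txs, model, 3.0, seed=1)
    assert all(r.seq.startswith("ACGTACGTAA") for r in reads)


def test_contaminant_injection_rate_and_labels(family_data):
    txs = family_data.transcripts["charoA"]
    reads, _ = sim.simulate_reads(txs, _zero_noise(), 2.0, seed=3)
    reads = (reads * (9000 // len(reads) + 1))[:9000]
    pool = sim.make_contaminant_pool(seed=5)
    params = sim.GeneratorParams(contam_fraction=0.10, seed=0)
    out, truth = sim.inject_contaminants(reads, params, pool, seed=8)
    n_contam = len(out) - len(reads)
    assert 900 <= n_contam <= 1100  # 3-sigma band around 1000
    assert set(truth.lineage_of.values()) <= set(sim.CONTAMINANT_CATEGORIES)
    assert len(truth.lineage_of) == n_contam


def test_zero_contamination_is_identity(family_data):
    txs = family_data.transcripts["charoA"]
    reads, _ = sim.simulate_reads(txs, _zero_noise(), 1.0, seed=3)
    params = sim.GeneratorParams(contam_fraction=0.0, seed=0)
    out, truth = sim.inject_contaminants(reads, params, [], seed=1)
    assert out == reads and not truth.lineage_of


def test_empty_pool_with_positive_fraction_is_an_error(family_data):
    txs = family_data.transcripts["charoA"]
    reads, _ = sim.simulate_reads(txs, _zero_noise(), 1.0, seed=3)
    params = sim.GeneratorParams(contam_fraction=0.1, seed=0)
    with pytest.raises(ValueError):
        sim.inject_contaminants(reads, params, [], seed=1)


def test_homopolymer_indels_change_run_lengths(rng):
    seq = "AAAACGTGGGGTTTC"
    out = sim._apply_homopolymer_indels(rng, seq, rate=1.0)
    assert out != seq
    # only run lengths change, base order is preserved
    def runs(s):
        collapsed = [s[0]]
        for c in s[1:]:
            if c != collapsed[-1]:
                collapsed.append(c)
        return "".join(collapsed)
    assert runs(out) == runs(seq)


def test_dataset_truth_covers_all_reads(small_dataset):
    truth = small_dataset.truth
    for sp, techs in small_dataset.reads.items():
        for tech, reads in techs.items():
            for r in reads:
                assert r.id in truth.read_origin


def test_dataset_roundtrip_to_disk(tmp_path, small_dataset):
    sim.write_dataset(small_dataset, tmp_path)
    assert (tmp_path / "generator_config.yaml").exists()
    assert (tmp_path / "ontology.obo").exists()
    from estkit import io as eio
    reads = eio.read_reads(tmp_path / "reads_charoA_flx454.fasta",
                           tmp_path / "reads_charoA_flx454.qual")
    orig = small_dataset.reads["charoA"]["flx454"]
    assert [(r.id, r.seq, r.technology) for r in reads] == \
           [(r.id, r.seq, r.technology) for r in orig]
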