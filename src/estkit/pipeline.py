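"""End-to-end orchestration: generate/load -> prep -> cluster -> code ->
search -> orthology -> annotate -> enrich, with a table-oriented report.

Every stage writes plain files (FASTA/TSV) into the output directory and
records a manifest entry (stage, parameters, output digests), so re-running
with an identical config and inputs reproduces identical digests and any
stage can be swapped for an external tool's tabular output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotate, cluster, coding, go_enrich, homology, orthology, prep
from . import io as eio
from . import simulate
from ._seq import child_rngs

log = logging.getLogger("estkit")

DEFAULT_454_ADAPTER = "GCCTCCCTCGCGCCATCAG"


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "estkit_out"
    seed: int = 0
    log_level: str = "INFO"
    # synthetic generation (used when no external inputs are given)
    generator: dict = dataclasses.field(default_factory=dict)
    depth_454: float = 2.5
    depth_sanger: float = 0.7
    adapter_454: str = DEFAULT_454_ADAPTER
    # stage parameter blocks
    trim: dict = dataclasses.field(default_factory=dict)
    overlap: dict = dataclasses.field(default_factory=dict)
    coding: dict = dataclasses.field(default_factory=dict)
    aligner: dict = dataclasses.field(default_factory=dict)
    evalue_taxonomy: float = 1e-4
    evalue_rbh: float = 1e-6
    evalue_go: float = 1e-6
    evalue_panel: float = 1e-20
    # optional external inputs (paths); when present they replace generation
    inputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def validate_config(config: PipelineConfig) -> list[str]:
    """List problems with a config; an empty list means valid."""
    issues: list[str] = []
    try:
        op = cluster.OverlapParams(**config.overlap)
        if op.min_overlap < op.seed_k:
            issues.append("min_overlap < seed_k")
    except (TypeError, ValueError) as exc:
        issues.append(f"overlap params: {exc}")
    for block, ctor in (("trim", prep.TrimParams),
                        ("aligner", homology.AlignerParams)):
        try:
            ctor(**getattr(config, block))
        except (TypeError, ValueError) as exc:
            issues.append(f"{block} params: {exc}")
    try:
        simulate.GeneratorParams(seed=config.seed, **config.generator)
    except (TypeError, ValueError) as exc:
        issues.append(f"generator params: {exc}")
    for cutoff in ("evalue_taxonomy", "evalue_rbh", "evalue_go",
                   "evalue_panel"):
        if getattr(config, cutoff) <= 0:
            issues.append(f"{cutoff} must be > 0")
    for key, path in (config.inputs or {}).items():
        if isinstance(path, str) and not Path(path).exists():
            issues.append(f"input {key}: missing file {path}")
    return issues


@dataclasses.dataclass
class PipelineReport:
    """All tables the run produces, plus manifests and summary metrics."""

    read_stats: pd.DataFrame
    assembly_stats: dict            # species -> DataFrame
    provenance_stats: dict          # species -> DataFrame
    reads_per_unigene: dict         # species -> DataFrame (histogram data)
    coding_tables: dict             # species -> DataFrame
    coding_summaries: dict          # species -> dict
    lineage_tables: dict            # species -> DataFrame
    venn: orthology.VennPartition | None
    ortholog_sets: pd.DataFrame
    panel_tables: dict              # species -> DataFrame
    enrichment_tables: dict         # species -> DataFrame
    novel_classes: dict             # species -> {unigene: class}
    novel_overlap: dict
    metrics: dict
    manifest: list
    unigenes: dict                  # species -> [Unigene]
    peptides: dict                  # species -> {unigene: peptide}
    dataset: Any = None             # SyntheticDataset when generated


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_entry(stage: str, params: dict, outputs: list[Path],
                    t0: float) -> dict:
    return {"stage": stage, "params": params,
            "outputs": {p.name: _digest(p) for p in outputs},
            "wall_s": round(time.time() - t0, 2)}


def _shuffled(seqs: list[str], rng: np.random.Generator) -> list[str]:
    out = []
    for s in seqs:
        arr = np.array(list(s))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage on a synthetic dataset (or supplied inputs)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    metrics: dict = {}

    # ---- stage: generate / load -----------------------------------------
    t0 = time.time()
    gen_params = simulate.GeneratorParams(seed=config.seed,
                                          **config.generator)
    models = {
        "sanger": simulate.sanger_model(),
        "flx454": simulate.flx454_model(adapter_seq=config.adapter_454),
    }
    dataset = simulate.generate_dataset(gen_params, config.depth_454,
                                        config.depth_sanger, models)
    simulate.write_dataset(dataset, out / "data")
    manifest.append(_manifest_entry(
        "generate", {"seed": config.seed, **config.generator},
        sorted((out / "data").glob("*")), t0))
    est_species = list(gen_params.charophytes)
    plant = gen_params.ref_plant
    chloro = gen_params.ref_chlorophyte
    log.info("generated %d families for %s", gen_params.n_families,
             gen_params.species_list)

    # ---- stage: prep ----------------------------------------------------
    t0 = time.time()
    trim_params = prep.TrimParams(**{"adapters": (config.adapter_454,),
                                     **config.trim})
    prepped: dict[str, dict[str, list]] = {}
    for sp in est_species:
        prepped[sp] = {}
        for tech, reads in dataset.reads[sp].items():
            kept, audit = prep.prep_reads(reads, trim_params)
            prepped[sp][tech] = kept
            eio.write_tsv(audit, out / f"prep_audit_{sp}_{tech}.tsv")
            log.info("prep %s/%s: %d of %d reads kept", sp, tech,
                     len(kept), len(reads))
    manifest.append(_manifest_entry(
        "prep", dataclasses.asdict(trim_params),
        sorted(out.glob("prep_audit_*.tsv")), t0))
    all_reads = [r for sp in est_species for tech in prepped[sp]
                 for r in prepped[sp][tech]]
    read_statistics = cluster.read_stats(all_reads)

    # ---- stage: cluster -------------------------------------------------
    t0 = time.time()
    overlap_params = cluster.OverlapParams(**config.overlap)
    unigenes: dict[str, list[cluster.Unigene]] = {}
    assembly_statistics: dict = {}
    provenance_statistics: dict = {}
    reads_per_unigene: dict = {}
    for sp in est_species:
        ug = cluster.two_step_assemble(prepped[sp].get("flx454", []),
                                       prepped[sp].get("sanger", []),
                                       overlap_params)
        for u in ug:  # species-scoped ids so cross-library sets stay disjoint
            u.id = f"{sp}_{u.id}"
        unigenes[sp] = ug
        eio.write_fasta({u.id: u.consensus for u in ug},
                        out / f"unigenes_{sp}.fasta",
                        descriptions={u.id: f"provenance={u.provenance}"
                                      for u in ug})
        eio.write_tsv(pd.DataFrame(
            [(rid, u.id, tech) for u in ug for rid, tech in u.members],
            columns=["read", "unigene", "technology"]),
            out / f"membership_{sp}.tsv")
        assembly_statistics[sp] = cluster.unigene_stats(ug)
        prov_counts = pd.Series([u.provenance for u in ug]
                                ).value_counts().rename_axis(
            "provenance").reset_index(name="count")
        provenance_statistics[sp] = prov_counts
        hist = pd.Series([u.n_reads for u in ug]).value_counts().sort_index()
        reads_per_unigene[sp] = hist.rename_axis(
            "reads_per_unigene").reset_index(name="n_unigenes")
        log.info("cluster %s: %d unigenes (%d contigs)", sp, len(ug),
                 sum(1 for u in ug if u.kind == "contig"))
    manifest.append(_manifest_entry(
        "cluster", dataclasses.asdict(overlap_params),
        sorted(out.glob("unigenes_*.fasta")), t0))

    # ---- stage: coding --------------------------------------------------
    t0 = time.time()
    rng_bg, = child_rngs(config.seed + 17, 1)
    ref_cds = [dataset.families.genes[plant][g]
               for g in sorted(dataset.families.genes[plant])]
    model = coding.train_hexamer_model(
        ref_cds, _shuffled(ref_cds, rng_bg),
        trained_on=f"{plant} CDS vs mononucleotide-shuffled background")
    coding_tables: dict = {}
    coding_summaries: dict = {}
    peptides: dict = {}
    for sp in est_species:
        seqs = {u.id: u.consensus for u in unigenes[sp]}
        table, peps = coding.classify_unigenes(seqs, model, **config.coding)
        coding_tables[sp] = table
        coding_summaries[sp] = coding.coding_summary(table)
        peptides[sp] = peps
        eio.write_tsv(table, out / f"coding_{sp}.tsv")
        eio.write_fasta(peps, out / f"peptides_{sp}.fasta")
        log.info("coding %s: %d/%d with no coding region", sp,
                 coding_summaries[sp]["no_coding_region"], len(table))
    model.to_frame().to_csv(out / "coding_model.tsv", sep="\t", index=False)
    manifest.append(_manifest_entry(
        "coding", config.coding,
        sorted(out.glob("coding_*.tsv")) + [out / "coding_model.tsv"], t0))

    # ---- stage: search --------------------------------------------------
    t0 = time.time()
    aligner_params = homology.AlignerParams(**config.aligner)
    taxonomy_hits: dict = {}
    for sp in est_species:
        seqs = {u.id: u.consensus for u in unigenes[sp]}
        taxonomy_hits[sp] = homology.search(seqs, dataset.nr_proteins,
                                            "transl_prot", aligner_params)
        homology.export_tabular_hits(taxonomy_hits[sp],
                                     out / f"hits_nr_{sp}.tsv")
    proteomes = {plant: dataset.families.proteins[plant],
                 chloro: dataset.families.proteins[chloro]}
    for sp in est_species:
        proteomes[sp] = peptides[sp]
    pair_hits: dict = {}
    species_names = sorted(proteomes)
    for qsp in species_names:
        for ssp in species_names:
            if qsp == ssp or not proteomes[qsp] or not proteomes[ssp]:
                continue
            pair_hits[(qsp, ssp)] = homology.search(
                proteomes[qsp], proteomes[ssp], "prot_prot", aligner_params)
    manifest.append(_manifest_entry(
        "search", dataclasses.asdict(aligner_params),
        sorted(out.glob("hits_nr_*.tsv")), t0))
    log.info("search: %d directed proteome pairs", len(pair_hits))

    # ---- stage: orthology -----------------------------------------------
    t0 = time.time()
    edges: list[orthology.RBHEdge] = []
    for i, sp_a in enumerate(species_names):
        for sp_b in species_names[i + 1:]:
            if (sp_a, sp_b) not in pair_hits or (sp_b, sp_a) not in pair_hits:
                continue
            edges.extend(orthology.rbh_pairs(
                pair_hits[(sp_a, sp_b)], pair_hits[(sp_b, sp_a)],
                sp_a, sp_b, config.evalue_rbh))
    osets, assignment = orthology.ortholog_sets(edges)
    totals = {sp: len(proteomes[sp]) for sp in species_names}
    venn = orthology.venn_partition(assignment, totals)
    sets_df = orthology.sets_table(osets)
    eio.write_tsv(venn.counts, out / "venn_counts.tsv")
    eio.write_tsv(sets_df, out / "ortholog_sets.tsv")
    manifest.append(_manifest_entry(
        "orthology", {"evalue_rbh": config.evalue_rbh},
        [out / "venn_counts.tsv", out / "ortholog_sets.tsv"], t0))
    log.info("orthology: %d edges, %d sets", len(edges), len(osets))

    # ---- stage: annotate ------------------------------------------------
    t0 = time.time()
    lineage_tables: dict = {}
    novel_classes: dict = {}
    panel_tables: dict = {}
    for sp in est_species:
        uids = [u.id for u in unigenes[sp]]
        assignments = annotate.assign_lineages(
            taxonomy_hits[sp], uids, dataset.lineage_map,
            config.evalue_taxonomy)
        lineage_tables[sp] = annotate.summarize_lineages(assignments)
        verdicts = dict(zip(coding_tables[sp]["unigene"],
                            coding_tables[sp]["verdict"]))
        novel_classes[sp] = annotate.classify_novel(verdicts, assignments)
        eio.write_tsv(pd.DataFrame(
            sorted(novel_classes[sp].items()),
            columns=["unigene", "class"]), out / f"novelty_{sp}.tsv")
        eio.write_tsv(lineage_tables[sp], out / f"lineage_{sp}.tsv")
        panel = {p.name: p.protein for p in dataset.panel}
        if panel:
            panel_tables[sp] = annotate.screen_gene_panel(
                panel, {u.id: u.consensus for u in unigenes[sp]},
                aligner_params, config.evalue_panel)
            eio.write_tsv(panel_tables[sp], out / f"panel_{sp}.tsv")
    sp_a, sp_b = est_species
    novel_a = {u: peptides[sp_a][u] for u, c in novel_classes[sp_a].items()
               if c == "novel"}
    novel_b = {u: peptides[sp_b][u] for u, c in novel_classes[sp_b].items()
               if c == "novel"}
    novel_overlap = annotate.cross_library_novel_overlap(
        novel_a, novel_b, aligner_params, config.evalue_taxonomy)
    manifest.append(_manifest_entry(
        "annotate", {"evalue_taxonomy": config.evalue_taxonomy},
        sorted(out.glob("lineage_*.tsv")) + sorted(out.glob("panel_*.tsv")),
        t0))

    # ---- stage: enrich --------------------------------------------------
    t0 = time.time()
    dag = go_enrich.load_ontology(out / "data" / "ontology.obo")
    ref_go = {g: list(t["go_id"])
              for g, t in dataset.ref_go_table.groupby("gene")}
    ref_rollup = go_enrich.rollup_level3(ref_go, dag)
    ref_counts = dict(zip(ref_rollup["term"], ref_rollup["count"]))
    enrichment_tables: dict = {}
    for sp in est_species:
        go_hits = pair_hits.get((sp, plant), [])
        annotations = go_enrich.transfer_annotations(go_hits, ref_go,
                                                     config.evalue_go)
        rollup = go_enrich.rollup_level3(annotations, dag)
        counts = dict(zip(rollup["term"], rollup["count"]))
        enrichment_tables[sp] = go_enrich.compare_proportions(
            counts, max(1, len(annotations)), ref_counts,
            max(1, len(ref_go)), dag)
        eio.write_tsv(enrichment_tables[sp], out / f"enrichment_{sp}.tsv")
    manifest.append(_manifest_entry(
        "enrich", {"evalue_go": config.evalue_go},
        sorted(out.glob("enrichment_*.tsv")), t0))

    # ---- invariants gate ------------------------------------------------
    for sp in est_species:
        seen: set[str] = set()
        for u in unigenes[sp]:
            for rid, _tech in u.members:
                if rid in seen:
                    raise RuntimeError(f"read {rid} in two unigenes")
                seen.add(rid)
        n_input = sum(len(v) for v in prepped[sp].values())
        if len(seen) != n_input:
            raise RuntimeError(f"{sp}: {len(seen)} reads in unigenes vs "
                               f"{n_input} prepped reads")
    # (venn additivity was enforced inside venn_partition)

    metrics.update(_truth_metrics(dataset, unigenes, coding_tables,
                                  novel_classes, venn, est_species,
                                  plant, chloro))
    report = PipelineReport(read_statistics, assembly_statistics,
                            provenance_statistics, reads_per_unigene,
                            coding_tables, coding_summaries, lineage_tables,
                            venn, sets_df, panel_tables, enrichment_tables,
                            novel_classes, novel_overlap, metrics, manifest,
                            unigenes, peptides, dataset)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    config.to_yaml(out / "config_echo.yaml")
    return report


def _dominant_transcript(u: cluster.Unigene, read_origin: dict) -> str | None:
    votes: dict[str, int] = {}
    for rid, _tech in u.members:
        origin = read_origin.get(rid)
        if origin:
            votes[origin[0]] = votes.get(origin[0], 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda t: votes[t])


def cluster_purity(unigenes: list, truth: "simulate.TruthTables") -> float:
    """Fraction of member reads whose transcript family matches the
    majority family of their unigene (contaminants keyed by source)."""
    good = total = 0
    for u in unigenes:
        keys = []
        for rid, _tech in u.members:
            origin = truth.read_origin.get(rid)
            if origin is None:
                continue
            tx = origin[0]
            fam = truth.family_of.get(tx)
            keys.append(("fam", fam) if fam is not None else ("src", tx))
        if not keys:
            continue
        counts: dict = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        majority = max(counts.values())
        good += majority
        total += len(keys)
    return good / total if total else float("nan")


def _truth_metrics(dataset, unigenes, coding_tables, novel_classes, venn,
                   est_species, plant, chloro) -> dict:
    truth = dataset.truth
    metrics: dict = {}
    for sp in est_species:
        metrics[f"cluster_purity_{sp}"] = cluster_purity(unigenes[sp], truth)
        # contaminant recovery: unigenes made purely of contaminant reads
        n_contam_reads = sum(
            1 for u in unigenes[sp] for rid, _ in u.members
            if rid in truth.lineage_of)
        metrics[f"n_contaminant_reads_{sp}"] = n_contam_reads
        summary = coding_tables[sp]["verdict"].value_counts().to_dict()
        metrics[f"n_unigenes_{sp}"] = len(unigenes[sp])
        metrics[f"coding_none_{sp}"] = int(summary.get("none", 0))
        metrics[f"n_novel_{sp}"] = sum(
            1 for c in novel_classes[sp].values() if c == "novel")
    if venn is not None:
        df = venn.counts
        for sp in est_species:
            with_plant = df[(df["species"] == sp)
                            & df["region"].str.contains(plant)]["count"].sum()
            with_chloro = df[(df["species"] == sp)
                             & df["region"].str.contains(chloro)][
                "count"].sum()
            metrics[f"orthologs_with_plant_{sp}"] = int(with_plant)
            metrics[f"orthologs_with_chlorophyte_{sp}"] = int(with_chloro)
    return metrics
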