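# Methods

This note documents the models, parameter choices and known limitations of
`estkit`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic study design

The generator emulates a four-taxon comparative EST survey: two EST-only
species (`charoA`, `charoB`) flanked by two annotated references on the
fixed topology `((ref_plant,(charoA,charoB)),ref_chlorophyte)`.  Branch
lengths are fixed multiples of the `divergence` parameter (substitutions
per site): 0.25 for the streptophyte stem, 0.75 for the plant leaf, 0.25
for the charophyte stem, 0.5 for each charophyte leaf and 1.75 for the
chlorophyte leaf.  With the default `divergence = 0.15` the
charophyte-to-plant path length is 1.5× the base rate and the
charophyte-to-chlorophyte path 2.75×, planting "the EST species resemble
the plant more than the chlorophyte" as a checkable property rather than an
interpretation.

**Gene families.** Each family starts as an ancestral CDS (`ATG` + body +
`TAA`; mean 300 codons, Poisson-distributed, minimum 60).  Codons are drawn
from a biased distribution: one preferred codon per amino acid carries 4×
weight — this is the hexamer signal the coding predictor learns — and an
exponential tilt on codon GC is solved numerically so the expected per-base
GC hits each taxon's target exactly.  Along each branch, sites substitute
independently with probability equal to the branch length; replacement
bases are weighted 3:1 synonymous:non-synonymous, zero for stop-creating
changes, and tilted toward the taxon GC target.  Start and terminal stop
codons are held fixed.  Which species carry a family is drawn from a
presence profile; the default profile includes 10% of families present in
both charophytes but in neither reference (the planted "novel genes"), and
makes plant∩charophyte-without-chlorophyte families (16%) about 2.7× more
common than chlorophyte∩charophyte-without-plant families (6%).  Paralogs
are extra copies with 0.5× additional divergence (rate 0.05).

**Transcripts and reads.** Coding transcripts are 5′UTR + CDS + 3′UTR
(UTR lengths Poisson with means 75/150 nt, i.i.d. sequence at the taxon GC
target).  Non-coding transcripts (default 20% of each species' transcript
set, inside the 16–25% range such surveys report) are unstructured i.i.d.
sequence at the taxon GC target, so they carry no hexamer phase signal by
construction.  Reads follow two technology models: "sanger" (mean 900 bp,
σ 150, 0.1% substitutions, anchored at the transcript 5′ end, forward
strand) and "flx454" (mean 380 bp, σ 80, 0.2% substitutions, ±1-base
errors in homopolymer runs ≥ 3 at 2% per run, uniform start, either
strand, optional ligated adapter).  Per-transcript depth is weighted by a
lognormal(0, 0.75) expression factor.  Contaminant reads from a labelled
pool (Bacteria/Fungi/Viruses/Archaea/other Eukaryotes, each with its own
GC) are mixed in with expected fraction 10% of the final read set.  GC
targets default to 49.4% and 41.1% for the two EST species with 44%/60%
for the references.  One global seed fans out to per-stage child
generators via `numpy.random.SeedSequence.spawn`, so identical parameters
give byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatogram/flowgram-level error structure,
quality-value correlation with true error positions, vector contamination,
chimeric cDNAs, alternative splicing, expression-condition design, and
real codon-usage or GC heterogeneity along sequences.  The coding signal
is stronger and cleaner than in real ESTs; thresholds calibrated here
would need re-calibration on real data.

## Read preparation

Adapters are searched only at read ends by Hamming match (≤ 1 mismatch by
default) and stripped repeatedly; quality trimming slides a 20-base window
inward from each end until its mean Phred ≥ 15; reads shorter than 60 nt
are discarded.  Low complexity is scored DUST-style per 64-base window
(Σ c·(c−1)/2 over triplet counts, divided by the number of triplet
positions minus one) and masked to lowercase above 2.0; masked bases are
excluded from clustering seeds but retained in the sequence.  The
original toolchain this stage replaces published no parameter values;
these are declared defaults, not reconstructions.

## Clustering

Candidate overlaps are found by shared exact 16-mers (voting over
diagonals, nearby diagonals bucketed within a 20-column band) and verified
by edit-distance alignment of the implied overlap region (edlib); identity
is matches over aligned columns *of the overlap region only* — the
adopted reading of the "100 bp plus 95% identity" criterion, since the
source design does not say whether identity applies to the overlap or the
whole read.  Clustering is greedy: reads longest-first, each joining the
first (oldest) cluster whose consensus accepts it — a deliberate,
documented deviation from global overlap-layout-consensus assemblers in
exchange for determinism and near-linear behaviour at desk scale.
Consensus columns are majority-called with ties keeping the incumbent
base; reverse-complement merges are allowed.  The two-step design
clusters 454 reads first, then their contigs/singletons plus Sanger reads;
final single-item clusters are labelled `454-only-contig`,
`454-single-read` or `sanger-only`, which partitions the singletons.  A
step-1 contig that stays alone in step 2 is reported as a singleton (with
its multi-read membership retained), matching the provenance bookkeeping
of the emulated study's Table-2-style output.

## Coding prediction

The model is a phase-aware hexamer log-odds table: for phase p ∈ {0,1,2}
and hexamer h, log(f_coding(p,h) / f_background(p,h)) with +1
pseudocounts, trained on a supplied in-frame CDS set against
mononucleotide-shuffled copies (shuffling preserves GC, destroying only
composition structure).  Prediction is a local dynamic program over
(position, frame) states on each strand: every position contributes its
hexamer score in the current frame, switching frames costs 20 score units
(absorbing single-base indels without a full HMM), in-frame stop codons
cost 100, and the best-scoring segment wins, strands tied toward '+'.
A prediction is reported only if its score ≥ `min_score` and its segment
≥ 150 nt; otherwise the verdict is "no coding region detected".
`min_score` was calibrated on generator output (the signal separation
measured there: non-coding maximum segment score 53 over n = 327
transcripts vs a planted-coding minimum of 120 at divergence 0.15) and
defaults to 70, between the two tails.  Frameshift positions translate to
'X' in the emitted peptide.

## Homology search and statistics

Protein–protein and six-frame translated searches use exact 4-mer words,
a two-hit trigger (two non-overlapping words on one diagonal within 40
positions), and affine-gap local extension (BLOSUM62, gap of length k
costs 11 + k).  Pairs up to 250 residues get a full-width (exact) gapped
extension; longer pairs are extended in a ±24 band around seeded
diagonals — the score can then be below the unbanded optimum, which is the
documented sensitivity trade-off.  E-values use fixed Karlin–Altschul
constants λ = 0.267, K = 0.041 (gapped BLOSUM62-style) with
E = K·m·n·e^(−λS) and bit score (λS − ln K)/ln 2; the effective-length
correction is omitted, a small conservative bias at the coarse thresholds
used downstream (10⁻⁴ taxonomy, 10⁻⁶ orthology and GO transfer, 10⁻²⁰
panel screening; all strict `<`).  Exact-word seeding (no neighbourhood
words) loses sensitivity at high divergence; at the synthetic divergences
used here the loss is negligible for true homologs.  The
`smith_waterman` operation (Biopython's exact affine local aligner behind
the module surface) is a guarded test oracle, not the production path,
and the 12-column tabular adapter converts between 1-based-inclusive
percent-identity records and the package's 0-based half-open fractional
conventions bit-exactly.

## Orthology and the Venn partition

RBH edges require mutual top hits (ties broken by E-value, then bit score,
then identity, then subject id — making bests unique); self-hits are
excluded here, in one place.  A gene's candidate ortholog sets are the
subsets of {itself} ∪ {its unique RBH partners}; a set is valid iff every
pair is an edge, and each gene is assigned to its maximum-size valid set,
ties resolved by summed bit score then lexicographic species subset.  The
source design never states how genes belonging to several possible sets
were resolved; maximal-clique-with-bit-score-tie-break is this package's
codification, chosen because it makes the partition well-defined and
deterministic.  Genes without edges fall to their species-only region.
Per-species additivity of the region counts (the property the emulated
study states for its Venn figure) is enforced at run time, not just
reported.  Orthology for EST species runs on predicted unigene peptides
(fragmented transcripts therefore depress clique recovery); references
contribute annotated proteins.

## Annotation and enrichment

Lineage categories come from the top passing hit's lineage path, matched
in the precedence order Viruses → Archaea → Bacteria → Fungi → Chlorophyta
→ Streptophyta → other Eukaryotes (most specific first, since paths
contain multiple matchable tokens); no passing hit ⇒ NoHit; subjects
missing from the lineage table fall to other Eukaryotes with a warning.
A unigene is *novel* iff it has a predicted coding region and no passing
hit; NoHit without coding is "noncoding-or-contaminant".  GO annotations
transfer from the single top reference hit (E < 10⁻⁶); term levels count
the namespace root as level 1, so "level 3" means grandchildren of the
root, and a term at level ≥ 3 contributes once per unigene to each of its
level-3 `is_a` ancestors (`part_of` edges are excluded — the conservative
reading of the graph-rollup convention the emulated analysis used).
Fisher's exact two-sided p sums all tables at fixed margins whose
hypergeometric probability is at most the observed one (relative
tie-guard 10⁻⁷); stars mark p < 0.01 and p < 0.001 on raw p-values, with
a Bonferroni column emitted alongside but unused for stars, matching the
raw-p reporting convention.

## Problem sizes

The default test suite and acceptance script run the full study at 120
gene families (≈ 600–800 reads per EST species), with module tests at
12–60 families; the ortholog-direction replicate study uses 20 seeds at
60 families, the Fisher exactness check enumerates every 2×2 table with
group totals ≤ 30, and the powered GO-bias check uses 2,600 annotated
reference genes.  These sizes were chosen to give the planted effects
comfortable statistical power while keeping any single check in the
minutes range on one CPU.

## Known limitations

Greedy first-accept clustering can split a transcript tiled with < 100 bp
stagger; consensus columns ignore read insertions except at cluster ends;
the coding DP collapses insert/delete states into one frame-switch
penalty and does not anchor on start/stop codons; E-values are not
BLAST-comparable in absolute terms (fixed λ/K, no length adjustment); GO
transfer uses a single top hit rather than a mapped annotation pool; and
the Venn partition counts genes (per-gene assignment), which is the only
reading under which per-species additivity can hold exactly.
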