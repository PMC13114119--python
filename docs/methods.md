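# Methods

This note documents the statistical procedures, parameter defaults,
and simulator assumptions behind `tnseqfit`, and the design choices
made where the analysis was genuinely open.

## Coordinates and the TA-site universe

All coordinates are 0-based, half-open; GFF3 and BLAST tabular inputs
(1-based, inclusive) are converted at the reader.  A TA dinucleotide
site is identified by the coordinate of its T on the forward strand.
Real pipelines differ on whether an insertion is recorded at the T or
the A; standardizing on the T may shift coordinates by one relative to
other tools, which matters only when mixing site tables from different
sources.

## Terminus exclusion

Insertions near gene termini are frequently tolerated even in
essential genes, so all insertion-density rules operate on each gene's
*internal* span: a site with 5′ offset *o* (strand-aware) in a gene of
length *L* is internal when `o/L ≥ 0.05` and `o/L < 0.90`.  Both edges
are half-open by convention; the boundary site at exactly 5% is kept
and the site at exactly 90% is excluded.  `head_frac`/`tail_frac` are
configurable everywhere they appear.  Genes at contig ends or shorter
than 20 bp go through the same formula with no special-casing.

## Essential-gene candidate calling

The call is operational, not mechanistic: a gene with zero validated
barcodes at its internal TA sites is a *zero-insertion candidate*.
Genes without any internal TA site carry no evidence and are reported
separately as "no-data", never called.

Zero-insertion calls inside repeated genomic elements are mapping
artifacts (a read from any copy maps ambiguously).  Repeat masking
therefore proceeds from a genome self-alignment hit table: hits longer
than 1,000 bp at more than 90% identity are retained (both strict, the
literal reading of the thresholds), the trivial self-diagonal is
dropped, and reciprocal duplicates are collapsed.  Retained spans are
clustered greedily, longest first: a span joins the first cluster
whose representative it matches at identity ≥ 0.90 over ≥ 0.90 of the
shorter sequence, else founds a new cluster.  The length-descending
sort makes membership independent of input row order.  Identity is
estimated by k-mer containment (k = 11, mapped through `J^(1/k)` as
for independent substitutions) and refined by an exact infix
edit-distance alignment (edlib) whenever the estimate falls within
±0.05 of the threshold; because the infix alignment spans the shorter
sequence end to end, the coverage requirement is satisfied by
construction.  This reproduces the stated thresholds, not any
particular clustering tool's word heuristics, so cluster counts on
real data may differ marginally from other implementations.

Only genes *fully contained* in a cluster member span are masked;
genes partially overlapped by a repeat keep their unique flank and
remain mappable.  A curated manual-removal list is an input (there is
no algorithmic rule for it).  The final core set is the zero-insertion
set minus the union of both removal lists — union-aware, so a gene on
both lists is removed once.

The *expanded* candidate list adds genes whose internal TA sites are
hit at a fraction ≤ 0.05 (inclusive), recovering essential genes that
tolerate insertions in a small sub-domain.  Cross-strain concordance
maps focal genes through reciprocal-best-hit ortholog pairs (top
bitscore both ways; ties broken by e-value, then lexicographic subject
id) and intersects with each comparison strain's essential list.

## Fitness scoring

One comparison unit is a replicate mouse: an input sample (the
pre-passage library) and an output sample (e.g. feces after 7 days).

1. **Positional-bias normalization** (`window_bp = 10,000`).  Counts
   at each TA site are scaled by (median window mean)/(own window
   mean), computed per sample over fixed genomic windows; windows with
   zero counts scale by 1, and the sample is rescaled to its original
   total.  Window *means per site* are used rather than raw sums so
   that spatially uniform data are an exact fixed point even when the
   final window of a contig is short.  This removes smooth
   replication-associated (origin-proximal) coverage gradients; it is
   an explicit stand-in for whatever bias correction a given upstream
   pipeline applies, and is the place to swap in an alternative.
2. **Depth-matched resampling** (`n_resamples = 100`).  The input
   sample is resampled multinomially at the output sample's depth; the
   per-site mean of the resamples is the expected input count.  This
   simulates random loss of barcodes at matched sequencing depth; at
   R = 100 the Monte-Carlo error of the mean is negligible relative to
   count noise.
3. **Per-gene score.**  `FC = (Σ out + ψ)/(Σ expected-in + ψ)` over
   the gene's internal sites with pseudocount ψ = 0.5, reported on the
   signed symmetric scale `s = FC if FC ≥ 1 else −1/FC` so that
   "|s| > 2" means more than two-fold in either direction.  The
   p-value is a two-sided Mann–Whitney U comparing the observed
   per-site output counts with the expected per-site input counts:
   exact enumeration over all C(n1+n2, n1) midrank assignments when
   both vectors are shorter than 8, otherwise the tie-corrected normal
   approximation with continuity correction.  Degenerate comparisons
   (all pooled values identical) return p = 1.  Whether the rank test
   should compare per-site counts, per-barcode counts, or per-mouse
   ratios is genuinely open; per-site counts with the resampled input
   as reference is this package's fixed interpretation, recorded in
   output metadata.
4. **Replicate combination.**  `mean_s` and `mean_p` are arithmetic
   means over the mice in which the gene was scored.  The composite
   rank averages the rank by `mean_p` (ascending) and the rank by
   `|mean_s|` (descending), each with average-rank ties, producing
   half-integer ranks for tied genes.

Significance uses strict cutoffs, `|mean_s| > 2` and `mean_p < 0.05`
by default; a gene exactly at either boundary is not selected.  No
multiple-testing correction enters the selection rule; a
Benjamini–Hochberg column (`q_bh`) is emitted alongside for users who
want it.

### Calibration of the rank test

The per-site Mann–Whitney ignores the pairing of sites between input
and output.  When site abundances are heterogeneous (they always are —
barcode placement and clone abundance vary), cross-site rank
comparisons are dominated by the shared abundance profile and are
nearly deterministic, so the null distribution of U is much narrower
than the test assumes.  The consequence, which we measure on the
simulator's neutral runs, is *conservative* p-values concentrated near
1 (Kolmogorov–Smirnov distance from uniform ≈ 0.38 under the default
conditions) rather than a uniform null.  This is characteristic of
per-site rank tests in transposon-screen analysis generally and is why
the selection rule pairs the p-value with a fold-change threshold: the
significant-gene false-positive rate under the neutral null is ≈ 0 at
the default conditions, at the cost of reduced power for subtle
effects.  Users needing calibrated p-values should treat `mean_p` as a
ranking score, not a probability.

## The simulator

`simulate_library` builds, deterministically per seed: a random genome
with TA sites planted at ~8 per kb (background TA dinucleotides are
removed first so site density is controlled); ~1000 genes of mean
length 3 kb tiled with exponential intergenic gaps; an 8% essential
fraction; and repeat families as sequence-identical blocks pasted over
designated member genes (2 families × 3 copies of 2 kb by default).
Barcodes (50,000 by default) are placed uniformly over all TA sites
*except* the internal sites of essential genes — terminal insertions
in essential genes are viable and allowed.  Barcodes landing inside a
repeat block are emitted with multiplicity equal to the family copy
number, exactly as an aligner would report them, and are removed by
the validation filter.  Initial clone abundances are i.i.d.
exponential, a minimal model of the wide abundance spread that
conjugation and plate scraping produce; the real library's
insertion-density heterogeneity (per-gene insertion counts ranging
over three orders of magnitude) is not mechanistically modeled.

`simulate_passage` applies, per replicate mouse: a multinomial
bottleneck of B = 10^5 cells over clone abundances (gut transit);
deterministic exponential growth `2^(w_g·G)` with G = 10 generations,
where only barcodes at *internal* sites of a gene inherit its w_g
(terminal and intergenic insertions are neutral); and a multinomial
sequencing draw of D = 2×10^6 reads summed per TA site.  Demographic
noise during growth is deliberately subsumed into the bottleneck —
the minimal model reproducing over-dispersion across mice.  Column
sums of every emitted tally equal D exactly.

What passing tests on this simulator do **not** show about real data:
no PCR chimeras, barcode sequencing errors, or mapping noise beyond
repeat multiplicity; no strain-level abundance drift unrelated to the
planted effects; fitness effects are constant per gene and condition
(no epistasis, no time-varying selection); and the planted effect size
(w = −1 over 10 generations, a ~1000-fold depletion) is strong, as in
real colonization bottleneck screens, so the measured sensitivity of
~1.0 speaks to that regime, not to marginal effects.

Problem sizes used by the test suite and the acceptance script — 1000
genes / 50,000 barcodes / 5 mice for the recovery and calibration
runs, 300 genes with ~30× barcode-per-site saturation for the
essential-call run — are desk-scale choices that keep the whole
pipeline comfortably reproducible on a laptop while leaving every
statistical feature of the full-scale screen intact.

## Condition-set refinement and enrichment accounting

A condition screen (e.g. colitis day 14 vs day 7) is refined by
subtracting genes significant in a time-matched healthy control and in
a broth exposure control.  Removal is direction-blind — a control hit
in either direction removes the gene from both directions of the
condition set — which is the conservative reading when a control calls
the same gene in the opposite direction; the audit table records every
removal with its reason, and per direction |refined| + |removed| =
|condition| exactly.  Controls are applied after direction assignment;
the audit trail makes the order visible.

COG category fractions use, for category k, the denominator of *all*
annotated genes carrying k in the genome (not just the significant
universe); genes with multiple category letters count in each.  No
enrichment test is attached to the fractions — they are descriptive.
COG assignment itself retains a domain hit when its bitscore is ≥ the
model's published threshold (inclusive), and a protein inherits the
letters of every retained model.  The assignment is monotone: raising
any threshold can only remove letters.  Coverage can be reported
against all genes or protein-coding genes only; both denominators are
available since published coverage figures differ on this point.

TPM expression ranking is `10^6 · (c_i/L_i)/Σ_j (c_j/L_j)` with
average-rank ties, rank 1 highest; each sample's TPM column sums to
10^6 to within floating-point rounding.

## Invertible-promoter assays

The assay module is pure arithmetic on coordinates and band
intensities: amplicon length is the half-open span from the forward
primer start to the reverse primer's 3′ end; digest fragments are the
consecutive differences of {0, cut offsets, length} and always sum to
the amplicon length; orientation fractions match observed bands to the
expected ON and OFF fragment patterns within a ± tolerance (patterns
sharing a size within twice the tolerance are rejected as
indistinguishable) and report `f_ON = I_ON/(I_ON+I_OFF)`.  An optional
helper scans a sequence for a recognition site by exact string match
(CCGG for HpaII); methylation sensitivity and PCR thermodynamics are
out of scope.

## Reproducibility

Every stochastic step takes a seed; the CLI fans a single global seed
deterministically into sub-stage seeds, writes a `manifest.json` with
the parameter hash, and prefixes numeric TSVs with that hash, so
re-running with an identical configuration reproduces byte-identical
numeric columns.

## Known limitations

* The upstream pipeline whose behavior the fitness stage reproduces is
  only sketched publicly; the normalization window, resample count,
  pseudocount, p-combination, and composite rank implemented here are
  explicit, configurable choices, not a bit-level port.
* Rank-test p-values are conservative (see calibration above).
* No barcode-level fitness estimates or time-series models beyond
  paired timepoints.
* Repeat clustering guarantees the identity/coverage thresholds, not
  agreement with any specific clustering tool's output on borderline
  families.
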