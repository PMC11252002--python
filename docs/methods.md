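# Methods

## Scope and model

`valtrans` re-implements, over synthetic data, the downstream statistics of
a codon-biased translation-reprogramming analysis: the question is whether
a condition (for example, therapy resistance or depletion of an
aminoacyl-tRNA synthetase) reshapes the proteome through codon- and
amino-acid-specific translation rather than through transcription.  The
pipeline has five analytic layers:

1. **Codon/amino-acid content enrichment.**  Each gene is represented by
   its longest CDS; content is the fraction of sense codons (start
   included, stops excluded) contributed by each codon or amino acid.
   A gene is a *member* for a feature when its content lies in the top
   quartile of the transcriptome distribution — membership is rank-based,
   exactly ceil(0.25·N) genes per feature with ties broken by gene id, so
   the rule is deterministic under ties.  A gene set's enrichment for a
   feature is a Pearson chi-squared test (1 df, no continuity correction)
   on the 2×2 table of set membership × quartile membership, the query set
   excluded from the outside margin.  Raw p-values drive direction calls;
   BH-adjusted values are reported alongside.
2. **tRNA quantification.**  Isodecoder (tRNA gene) counts are summed to
   isoacceptors (same anticodon) and alloisoacceptors (same amino acid);
   condition differences use a two-tailed unpaired Student t-test (pooled
   variance — appropriate at n = 3 per group; Welch is available) with
   log2 fold changes computed on means with a 0.5 pseudo-count.
   Concordance overlays pair codons with anticodons by exact
   Watson–Crick reverse complement; wobble decoding is deliberately out of
   scope.  An optional filter restricts isoacceptor sums to isodecoders
   that are individually significant (off by default, since the
   corresponding alloisoacceptor rule has no such clause).
3. **Ribosome-footprint statistics.**  The metagene profile divides each
   transcript's per-nucleotide 5′-end footprint density by its own mean
   CDS density (depth invariance), rescales the CDS to a fixed number of
   bins, and averages transcripts with equal weight.  Differential codon
   occupancy assigns each read the codon containing the nucleotide at a
   fixed offset from the 5′ end (9/12/15 nt ≈ E/P/A sites of a ~30-nt
   footprint), forms count-weighted codon fractions per condition
   (over the 61 sense codons; footprints whose site codon is a stop are
   dropped), and standardizes per-codon log2 fraction ratios
   (ε = 10⁻⁶ pseudo-fraction) into z-scores per offset.  The
   content-stratified comparison restricts a differential table to its
   significant genes, ranks them by one amino acid's content, and
   t-tests log2FC between the top and bottom quartiles *within that set*
   (quartiles are recomputed per analysis, not reused from the
   transcriptome-wide membership; both options exist).
4. **Signature derivation and scoring.**  Genes are classified from their
   (protein, mRNA) log2FC pair: *translation down* when |mRNA| < 1 and
   protein < −0.32, *translation up* as the mirror rule, *concordant* when
   both layers move beyond their cuts in the same direction.  The
   signature is the intersection of the translation-down group with the
   target amino acid's top-quartile membership.  Expression matrices are
   filtered (a gene is dropped when more than 30% of samples are below 10
   counts in *both* groups), transformed to log2 CPM with the
   voom-style offsets ((c + 0.5)/(lib + 1)·10⁶), and scored per sample by
   single-sample GSEA: genes ranked by expression (average ranks on
   ties), score = Σ over the ranked list of (rank-weighted in-signature
   ECDF − unweighted out-of-signature ECDF) with weight rank^0.25, then
   normalized across samples by the score range.  Extreme groups take the
   round-half-up(0.15·N) top and bottom samples (N = 233 gives 35 + 35).
5. **Screen arithmetic.**  Relative nuclear fragmentation of a cell-death
   assay is 1 + 100·(induced − spontaneous)/(100 − spontaneous); equality
   of induced and spontaneous death gives exactly 1.

## Synthetic data: what it emulates and what it does not

The generator produces every input with known planted effects so each
downstream statistic can be validated by parameter recovery:

- **Transcriptome**: 1,000 genes of 100–600 codons, codons i.i.d. per
  position from a weight vector over the 61 sense codons (uniform by
  default), each CDS a valid single-stop ORF.  Planted sets multiply the
  target codon's sampling weight (default: 50 genes, GTG ×4), which keeps
  sequences valid ORFs and makes the bias magnitude interpretable.  One
  global seed splits into per-gene substreams by gene index, so output is
  independent of iteration order.
- **Differential tables**: genes in the target amino-acid content quartile
  draw log2FC from N(shift, 0.3), others from N(0, 0.3); the 200 largest
  |log2FC| are flagged significant.  The ribosome/polysome scenario uses
  shift −0.5; the proteome scenario used for signature derivation uses
  −1.0, so that essentially every planted gene clears the −0.32 protein
  cut and the recovery measurement exercises the threshold/set logic
  rather than the normal tail (real effect sizes are unknown; these are
  power-motivated choices).
- **Footprints**: 100 reads of 30 nt per transcript, 5′ ends uniform over
  valid positions, reweighted ×4 for reads whose codon at offset 15 is
  GTG in the pause condition.
- **tRNA counts**: one isoacceptor per sense codon (exact reverse
  complement), two isodecoders each, baselines lognormal around 1,000,
  multiplicative lognormal replicate noise with σ = 0.2 in log space
  (≈20% CV, typical of bulk tRNA-seq biological replicates; chosen so the
  planted Val-CAC ×2 at n = 3 is reliably detectable, which is the
  structure the analysis presumes), 3 + 3 samples.
- **Expression**: negative-binomial counts (dispersion 0.1) with
  lognormal gene baselines; signature genes in designated high samples
  get means ×2^shift.

None of this models real sequence structure: no dinucleotide or
GC-content covariation, no sequencing error, no mapping ambiguity, no
compositional coupling between tRNA families, no patient covariates.
Passing recovery tests therefore shows the *statistics* are implemented
correctly and calibrated, not that the biological conclusions would
survive real-data confounders.

A known structural effect of the design: amino-acid content fractions are
compositional, so valine-rich genes are slightly leucine-poor.  When a
valine-stratified shift is planted and significance flags select large
|log2FC|, the leucine-stratified test inherits a small genuine signal
(~2–10% rejection at α = 0.01 depending on the significance-set size).
Null calibration of the leucine/isoleucine strata is therefore
demonstrated on tables with no planted effect; the leakage on planted
tables is reported, not asserted away.

## Numerical and design choices

- Chi-squared via `scipy.stats.chi2_contingency(correction=False)`;
  degenerate margins return (0, 1) flagged; expected cells < 1 flag
  `low_expected` but the statistic is still reported.
- Pooled t-test via `scipy.stats.ttest_ind`; both-groups-zero-variance
  inputs give p = 1 (equal means) or a flagged p = 0 (unequal means).
- Codons containing non-ACGT characters are skipped with a logged count;
  records with > 5% skipped codons are dropped from content matrices.
- All rank-based selections (quartile membership, strata, extreme groups)
  break ties by identifier so every result is permutation-invariant and
  deterministic.
- ssGSEA normalization divides by the score range across samples
  (max − min), bounding scores in [−1, 1]; constant expression vectors
  and signature-equals-universe are degenerate and score 0 with a flag.
  The kernelized density variant of single-sample scoring is not
  implemented; the rank-weighted ECDF form with exponent 0.25 is used.
- Coordinates are 0-based half-open internally; FASTA headers are
  `gene|transcript`, tables are TSV with header rows.

## Problem sizes

Simulation-based checks run at the scale the analyses use: 1,000-gene
transcriptomes, 200 random null sets for enrichment calibration, 50 seeds
for each recovery rate (stratified defect, tRNA detection, signature
recovery), 2 × 100,000 footprints for occupancy.  The test suite and the
acceptance script regenerate everything from seeds at run time; no data
files ship with the package.

## Limitations

- The enrichment background defaults to all genes in the supplied FASTA;
  restricting to expressed genes is the caller's responsibility.
- The occupancy analysis does not learn P-site offsets from read-length
  distributions; offsets are fixed, configurable inputs.
- The signature's mRNA window uses only the |log2FC| < 1 criterion, with
  no additional significance requirement on the mRNA layer.
- Aggregated tRNA differential testing operates on raw per-sample sums;
  no normalization between samples is applied (the generator produces
  depth-matched samples).
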