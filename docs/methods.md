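# Methods

`sltop` quantifies mTOR-dependent translational control in organisms that
trans-splice a spliced leader (SL) onto mRNA 5' ends, and asks whether
trans-spliced transcripts — whose SL supplies a pyrimidine-enriched,
TOP-like 5' terminus — dominate the translational response to growth
signals. It combines per-gene translational-efficiency (TE) estimation from
paired ribosome-profiling (RPF) and RNA-seq counts, rule-based trans-splice
and SL1/SL2 classification from CAGE-style tag evidence, TOP/TOP-like motif
scanning at transcription start sites, and the contingency/gene-set
statistics used to relate these layers. A synthetic study generator with a
full ground-truth table makes every stage testable end to end.

## Translational efficiency

Counts are normalised per library to reads per million (RPM). For each
condition, TE(g) = mean-over-replicates(RPF RPM) / mean-over-replicates
(RNA RPM); the averaging happens before the ratio. The treatment effect is
log2 dTE = log2 TE(treatment) − log2 TE(control). Genes with fewer than
`min_total` (default 100) reads summed over all libraries are excluded
before any statistic is computed. A zero RNA denominator yields an
undefined (NaN) TE that propagates and is reported, never imputed; an
optional pseudocount (default 0) can be added to both mean RPMs.

Because RPM renormalises each library to a fixed total, a strong one-sided
effect (e.g. suppression of 10% of genes) shifts the apparent log2 dTE of
unaffected genes by the compositional factor −log2(remaining fraction);
with the default study conditions this is < 0.1 and we accept it, as RPM
normalisation is the procedure being modelled.

## Differential testing

The differential-TE engine is a replicate-stratified score test on the
RPF:(RPF+RNA) split. Counts are first rescaled to a common depth (the
geometric mean library size). Per replicate pair r the 2×2 stratum has
rows (treatment, control) and columns (RPF, RNA); with E_r and V_r the
hypergeometric mean and variance of the RPF-in-treatment cell given the
stratum margins, the score is T = Σ_r (a_r − E_r), a Cochran–Mantel–
Haenszel-type statistic.

Sequencing counts are overdispersed, and the overdispersion of the
conditional split grows with the stratum total n_r (a Dirichlet-
multinomial effect), so a constant inflation factor cannot be calibrated
across the abundance range. The variance is therefore inflated as
V_r · (1 + ρ (n_r − 1)) with a single genome-wide quasi-dispersion ρ ≥ 0,
estimated by root-finding so that the median over genes of the per-gene
Pearson statistic T² / Σ_r V_r (1 + ρ (n_r − 1)) equals the χ²(1) median
(0.4549) — a robust moment match that tolerates a minority of truly
affected genes. The two-sided p comes from the normal reference
z = T / sqrt(Σ V_r (1 + ρ (n_r − 1))), with Benjamini–Hochberg FDR across
tested genes and the direction taken from log2 dTE. Genes with all-zero
strata are flagged and reported with p = 1.

Differential mRNA abundance uses the same machinery with strata
(gene count) vs (rest of library) per condition and replicate. There the
overdispersion couples through the gene's own count, not the library
total, so the inflation is quasi-NB: V_r · (1 + ρ m_r) with m_r the
per-condition mean count of the gene in that stratum; ρ is estimated the
same way and recovers the simulator's NB dispersion (ρ̂ ≈ 0.055 for
φ = 0.05).

Against an exact label-permutation reference (sign flips of condition
labels within replicate pairs), the analytic p agrees to within the
conditional-vs-unconditional variance gap, which is O(1/√R) in the number
of replicate pairs; the property test exercises this in the many-pair
regime (see the test for the quantitative budget).

Regulation calls (up / down / unaffected) gate the direction of the effect
on BH FDR < 0.05 by default. The generic fold-change rule (fold change
above/below a threshold with adjusted p below a gate, defaults 1 and
0.001) is exposed separately for reanalyses that publish such cutoffs.
Response categories combine the two calls: translation_only (TE changed,
mRNA unaffected), both (same direction), transcription_only, else
unaffected; discordant directions fall into unaffected and are not given
their own class.

## Trans-splice and SL classification

A gene is called SL trans-spliced iff at least one tag site passes all
three rules: (a) the site matches the gene strand and lies within the gene
body or ≤ 500 bp upstream of the gene start in transcript orientation
(boundary inclusive); (b) its tag count is ≥ 2 ("more than one tag");
(c) the two genomic bases immediately 5' of the site, read in transcript
orientation, are AG — the splice-acceptor dinucleotide. Every failed rule
is recorded per site. The 500 bp window is measured from the annotated
gene start, not the dominant TSS, since the acceptor serves the gene model
rather than a particular TSS call; evidence is per-site (counts are not
summed across sites), the stricter reading.

SL1/SL2 classification from per-gene spliced-leader read counts uses the
SL2 fraction f = sl2/(sl1+sl2): f ≤ 25% with one-sided exact binomial
P(X ≤ sl2 | n, p0) < α gives SL1; f ≥ 75% with the upper tail < α gives
SL2; 25% < f < 75% is mixed; a qualifying fraction with p ≥ α is unknown;
zero total reads is nonSL. The binomial null is p0 = 0.5 (equal SL1/SL2
usage), one-sided toward the observed extreme; both p0 and α (default
0.05) are parameters since different nulls are defensible. The site-count
variant of "mixed" (two or more sites using both leaders) is subsumed by
the fraction rule in this count-pair interface. Threshold comparisons are
exactly ≤ 25%, ≥ 75%, strict < α.

## Motif scanners

Offsets are 0-based from the 5' base (offset 0 = the TSS base). Pyrimidine
means C or T; N and any other symbol count as non-pyrimidine. The
canonical TOP motif is a 5' cytosine followed by ≥ 4 consecutive
pyrimidines; the reported run length counts the cytosine plus the run
capped at 14. TOP-like motifs are maximal pyrimidine runs of ≥ 5 starting
within 4 nt (strict) or 15 nt (relaxed) of the TSS. The scanners are exact
string algorithms, verified against an independent regular-expression
enumerator on random sequences.

The bundled 40-nt Oikopleura dioica SL constant reproduces the hand
checks: 12 pyrimidines among its first 15 nt, a longest run of 5 (TTTTT at
offset 10 — a relaxed but not a strict TOP-like hit), and no canonical TOP
since it begins with adenine.

## Enrichment statistics

All tests are implemented in the package. Fisher's exact 2×2 two-sided p
uses the probability-mass rule (sum hypergeometric masses ≤ the observed
table's, margins fixed) in exact integer arithmetic — no floating-point
tie tolerance is needed, and the result matches R's convention. The odds
ratio is the sample (ad)/(bc) with ±inf/0 sentinels for zero cells and a
Haldane (+0.5) corrected value alongside. The χ² test reports the Pearson
residual matrix used for mosaic-plot-style displays. Welch's t uses the
Welch–Satterthwaite df; TE-distribution comparisons between gene classes
are done on log2 TE excluding undefined values. GO over-representation is
a per-term hypergeometric upper tail including the observed count, with no
ontology-graph propagation (annotations are taken as given); a BH column
is attached but raw p-values remain the primary report.

## Synthetic study generator

The generator emulates the structure of the real experiment at desk scale.
One synthetic chromosome carries non-overlapping genes (0.5–1.5 kb,
0.7–1.2 kb gaps, random strands). Planted per-gene ground truth:

* **trans_spliced** (default fraction 0.43, the observed fraction among
  female-expressed genes): an acceptor with genomic AG immediately 5' of
  it, in the body or ≤ 500 bp upstream, plus an acceptor tag with count
  ≥ 2. Decoy genes (default 10% of non-trans-spliced) violate exactly one
  rule: count 1, non-AG acceptor, or placement 501 bp upstream.
* **suppressed** (default 0.05, ≈ the observed fraction of tested genes):
  planted log2 dTE (default −1) in treatment. A configurable share
  (default 0.5) is also transcriptionally down-regulated ("both"); the
  translation-only share carries the trans-splicing enrichment (odds 2.5,
  emulating the observed ~56% vs ~34% split), the "both" share does not.
* **dormant** (default 0.15): size factors redrawn from the top decile,
  baseline TE scaled by 1/8, insensitive to treatment — the oocyte-stocked
  maternal pool. The 8-fold reduction is a free parameter; the source data
  constrain its direction, not its size. Oocyte evidence (tiling intensity
  > 0 or CAGE ≥ 1 tpm) is emitted so the oocyte rule reproduces the flag.
* **has_top_motif** (default 0.076, the observed relaxed TOP-like
  frequency): C + 4–14 pyrimidines planted at the TSS. All other genes get
  a constructed motif-free 5' prefix (no pyrimidine run ≥ 4 in the first
  20 nt), so planted frequencies are recovered exactly rather than riding
  on a random-sequence background.
* **SL1/SL2**: trans-spliced genes are assigned sl2_fraction 0, 1 or 0.5
  (probabilities 0.6/0.25/0.15, SL1-dominant as in C. elegans); read pairs
  are Binomial splits of a Poisson total (depth 50).

Counts are gamma-Poisson: one mean-1 gamma multiplier with variance φ
(default 0.05) per (gene, condition, replicate), shared between the RPF
and RNA libraries of that replicate pair, then independent Poisson draws
around μ·ε. Marginally every count is exactly NB with Var = μ + φμ²; the
shared multiplier encodes that both libraries sequence the same underlying
biology, making TE the within-pair ratio — the structure a paired design
presumes. This matters quantitatively: with fully independent draws the
biological noise would put an irreducible ~0.37 sd on each gene's log2 dTE
at φ = 0.05 and 3 replicates, and a −1 effect would be undetectable at
high sensitivity by any method. Default per-replicate means are 200 (RNA)
and 100 (RPF) per unit size factor with lognormal(0, 0.5) size factors —
desk-scale stand-ins chosen so that a default run exercises every stage in
seconds.

All stages draw from independent substreams derived from the mandatory
seed, so outputs are byte-identical under a fixed config and inserting a
stage never perturbs another stage's draws.

What the generator does **not** emulate: read-level artefacts (mapping
bias, rRNA contamination, positional codon occupancy), realistic sequence
composition beyond the planted motifs, gene-length effects on counts,
correlated replicate batch structure, and partial/graded suppression
effects. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic and calibration under the stated noise model, not
performance on any real library.

## Numerical and reporting choices

* BH ties and all tabular outputs are ordered by gene_id; floats are
  written as `%.6g`, so re-runs are byte-stable.
* The quasi-dispersion root-find brackets ρ in [0, 1] with tolerance
  1e-12; a median already below the χ²(1) median yields ρ = 0 (never
  negative deflation).
* Coordinates are 0-based half-open internally; GFF3 is converted at the
  boundary and gene spans are treated as the "gene body" (whether the
  source annotation includes UTRs is unknowable here and documented as
  such).
* Degenerate inputs fail loudly: empty libraries, zero-margin tables,
  all-zero Fisher tables, degenerate Welch samples, selections outside the
  universe.

## Problem sizes

The test-suite and acceptance computations use 2,000-gene studies with 3
replicates (the calibration and recovery analyses), 10,000 random
sequences for scanner-oracle equivalence, the exhaustive Fisher sweep over
all 2×2 tables with total ≤ 40, brute-force GO enumeration up to N = 20,
and 500-gene end-to-end runs for determinism — sizes chosen so the whole
suite completes in a few minutes while keeping every statistical check at
the scale its approximations require.

## Known limitations

* The single genome-wide quasi-dispersion is a first-order correction; a
  per-gene (tagwise) dispersion model would calibrate heavy-tailed real
  data better.
* The differential engine is a score test, not an errors-in-variables
  posterior model; genes with extreme RPF:RNA imbalance and few counts
  rely on the normal approximation.
* SL classification treats each gene's SL1/SL2 counts as one pooled pair;
  site-resolved mixed calls are not implemented in the count-pair
  interface.
* GO results inherit whatever bias is in the flat annotation; no
  conditioning on the DAG is attempted.
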