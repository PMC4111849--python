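# Methods

This note records the models, conventions and numerical choices behind
`novex`, and what the synthetic-data validation does and does not show.

## Coordinates and junction representation

External files and all reports use 1-based inclusive coordinates (GTF
convention; `length = end − start + 1`).  Sequence slicing uses the
0-based half-open view exposed by `GenomicInterval.start0/end0`;
conversion happens only at those accessors.  A splice junction is stored
genomically as `(chrom, donor, acceptor, strand)` where `donor` is the
last base of the left exon and `acceptor` the first base of the right
exon; a junction BED line describes the intron as a 0-based half-open
span, so `chr1 200 299` reads as `donor=200, acceptor=300`.  Junction
BED dialects often lack reliable strand, so an unstranded junction
matches either strand when compared against an annotation, and duplicate
records merge by summing read support (multiple samples contribute
evidence).  Both quoted and unquoted GTF attribute dialects are accepted,
since reference annotations from different providers differ here.

## Transcript classification and novel transcript calls

Classes are mutually exclusive with precedence
KNOWN > EXONIC_OVERLAP > INTRONIC > INTERGENIC:

* KNOWN — identical intron chain to an annotated transcript (single-exon
  models require an exactly matching annotated single-exon transcript);
* EXONIC_OVERLAP — any exon overlaps any annotated exon, strand-blind,
  mirroring how intergenic status is usually defined in class-code
  comparators;
* INTRONIC — the span lies inside an annotated gene span without exon
  overlap;
* INTERGENIC — everything else (including unknown chromosomes, logged).

This four-class scheme is a deliberate simplification of the full
class-code taxonomy of assembly comparators; it is exactly what the
"intergenic and unknown in all references" rule needs.  A novel
transcript call requires INTERGENIC in *every* supplied reference
(conjunction) and ≥ `min_exons` exons.  The default `min_exons = 5`
matches the reported catalogs, in which every novel transcript has 5–22
exons; it is configurable.

## Novel exon deduction

"Consecutive novel junctions" are interpreted pairwise: for each
annotated intron (A, B), each ordered pair of unannotated junctions
(J₁ anchored at `end(A)`, J₂ anchored at `start(B)`, `J₁.acceptor ≤
J₂.donor`, both with support ≥ `min_support`) emits the cassette exon
`[J₁.acceptor, J₂.donor]`.  Chains of more than two novel junctions in
one intron emit one call per qualifying pair.  Calls are deduplicated by
exact exon coordinates, keeping the best-supported pair; support is the
minimum of the pair.  `min_support` defaults to 2 to suppress singleton
alignment noise — no published threshold exists, so the default is a
documented choice.  Junctions are pooled across tissues before deduction
(whether the original analysis pooled or worked per sample is not
stated); per-tissue support can be tracked by running per-tissue junction
files through the same call.

## Negative-binomial testing

The count model is NB with variance μ + αμ².  The testing machinery is
an original implementation of the classic small-replicate toolkit — it
does not wrap an external differential-expression package, and exact
numerical agreement with any particular package is a non-goal; the
contracts are the closed-form and simulation oracles in the test suite.

**Size factors** are median-of-ratios: `s_j = median_i(k_ij / gm_i)`
over features with no zero count, rescaled to geometric mean 1.  If no
feature is positive everywhere, `pseudo_reference=True` falls back to
features with a positive geometric mean over their observed samples.

**Dispersion** is method-of-moments with group-specific means: within
each replicated group, `E[v_g] = ξ·μ_g + α·μ_g²` (ξ = mean(1/s_j), the
shot-noise scale), and the per-feature estimate pools these moment
equations weighted by degrees of freedom.  Using each group's own mean
keeps the estimator unbiased for strongly differential features — with a
grand-mean formulation a 100-fold enriched feature would have its
dispersion inflated severalfold, which measurably costs power.  Raw
estimates are clipped at 0, a parametric trend `α(μ) = a₀/μ + a₁` is
fitted by nonnegative least squares across features, and each feature
uses `max(own, trend)` — the conservative "maximum sharing" rule of
early NB differential-expression practice.  All-zero features are
excluded from testing and flagged.

**Exact test.**  Conditional on the summed count K of the two groups,
each split (a, K−a) is scored by the product of the group-sum NB
probabilities under the shared normalized mean `q = K / (s_A + s_B)`;
the two-sided p-value sums the probabilities of splits at most as
probable as the observed one (observation included, capped at 1, so
p ∈ (0, 1]).  Group sums are moment-matched: mean `s_g·q`, effective
dispersion `α·Σs_j²/s_g²` — exact when size factors are equal, since a
sum of i.i.d. NB variables with a common success probability is NB.
With α = 0 the NB probabilities degenerate to Poisson and the split test
reduces to the conditional binomial, verified to 10⁻⁶ at α = 10⁻⁸.
Measured null rejection at nominal 0.05 (μ = 50, α = 0.1, 3 vs 3, known
α, 2000 replicates) sits inside the exact binomial 95% band.

**Enrichment aggregation.**  The target tissue is tested against every
other group separately; dispersion is estimated per pair (the design
leaves open whether a shared six-tissue estimate was used; per-pair is
the more self-contained choice and calibrates well).  `enriched` requires
every pairwise p below the threshold (default 0.05, the published
reporting rule) *and* the target's normalized mean higher in every
comparison; no fold-change floor is imposed beyond direction, since the
catalogs state none.  `p_min`/`p_max` across comparisons are reported as
in the published tables.  No multiple-testing correction is applied by
default (raw p < 0.05 is the reporting rule); `adjust=True` adds
Benjamini–Hochberg columns.

**Exon usage.**  The inclusion proportion `exon/(exon + rest-of-gene)`
is compared between two conditions by a quasi-binomial statistic: pooled
proportions per condition, variance scaled by a Pearson overdispersion
factor estimated from replicate variability (floored at the binomial),
referred to a t distribution with `samples − 2` degrees of freedom.
`usage_change` is the pooled non-baseline minus baseline proportion.
This stands in for a GLM-based exon-usage framework at the granularity
the pipeline needs (one exon against its gene, two conditions);
likelihood-ratio machinery over full exon-by-sample models is out of
scope.  The statistic tracks a sample-relabelling permutation reference
within a few hundredths at n = 10 per group; at n = 3 per group a
permutation reference cannot reach p < 0.05 at all (only 20 relabelings
exist), which is why the parametric form is the primary.

## Consequence prediction

The main ORF is the longest ATG-initiated open reading frame with an
in-frame stop, ties broken 5′-most (a deterministic stand-in for manual
ORF curation); ORFs running off the 3′ end are used only when no stopped
ORF reaches `min_codons` (default 30) and are flagged.  A uORF is, by
default, *fully* upstream: an ATG before the main start whose in-frame
stop ends at or before the main start, spanning ≥ 3 codons including
start and stop.  Because published uORF counts rarely state whether
start-overlapping ORFs were included, `include_overlapping=True` exposes
the permissive definition; counts differ between the modes.

Peptide comparison uses maximal common prefix p and suffix s:

* identical peptides → ALT_5UTR / ALT_3UTR by the position of the
  inserted exons relative to the ORF;
* one peptide a suffix of the other → NTERM_CHANGE;
* one a prefix of the other → CTERM_TRUNCATION (novel shorter) or a
  C-terminal extension reported as INTERNAL_INSERTION with a note;
* novel longer with p + s ≥ len(ref) → INTERNAL_INSERTION;
* shared prefix, no shared suffix, novel shorter (premature in-frame
  stop) → CTERM_TRUNCATION;
* otherwise FRAME_DISRUPTION.

`aa_delta` is always `len(novel) − len(ref)`, so swapping the isoforms
negates it.  N translates to X; motif windows containing unknown symbols
are skipped.  The proline-rich scan flags 10-residue windows with ≥ 50%
proline (the composition of the published proline-rich insertion);
the G-quadruplex scan matches the canonical `G≥3 (loop 1–7 nt) × 4`
motif, non-overlapping and leftmost-first.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis
assumes: 6 tissue labels × 2 replicates (the discovery design), NB counts
with log-normal baselines (exp(N(4, 1)), a realistic bulk dynamic range),
dispersions log-uniform in [0.05, 0.5], size factors log-uniform in
[0.5, 2], planted tissue enrichment at fold 100 (within the published
8.3–1,328-fold range; 80% testes / 20% liver for transcripts, alternating
testes/heart for exons, mirroring the observed tissue skew), junction
support uniform in [5, 50] for planted novelties, and a sham/TAC design
with n = 3 per group, depth 2000, inclusion 0.33 → 0.12 (the reported
~33% baseline inclusion and ~65% exon-level decrease).  Reference
divergence drops a configurable fraction of genes from one reference
(default 0.2), exercising the unknown-in-both conjunction.

It deliberately omits read-level artefacts: no alignment errors, no
mismapped junctions, no positional bias, no confounding novel junctions
that are not part of a planted exon.  Perfect recall with zero false
calls on this data therefore validates the *logic* of discovery, not its
robustness to alignment noise; on real data the junction support
threshold is doing the work the simulation does not test.  Genome
composition is uniform random, so planted ORFs and motifs occur at
background rates only.

Default problem sizes (100 genes over 4 × 600 kb contigs, 10 + 10
planted novelties, 2000 null test replicates, 5000-feature estimator
simulations) keep a full validation run, including the acceptance
script, in the tens of seconds on one core while leaving the binomial
tolerances of the recovery checks comfortably narrow.

## Degenerate inputs and tie-breaks

Empty junction files yield empty exon tables, not errors.  A pair with
`J₂.donor < J₁.acceptor` is skipped as pathological; equality yields a
1-bp exon.  Features with all-zero counts are excluded from testing and
flagged; a gene with zero baseline counts gets fold change NaN and
p = 1.  0/0 inclusion fractions are NaN.  Two-sided p-value ties use a
relative tolerance of 10⁻⁷ when comparing split probabilities, avoiding
floating-point sensitivity in "at most as probable".  The seed default
throughout simulation code is 20140713; every generator is a pure
function of (parameters, seed).

## Known limitations

* The exact test's moment-matching of group sums is approximate for
  unequal size factors (exact for equal ones); calibration under the
  simulated size-factor range is verified empirically, not analytically.
* `max(own, trend)` dispersion sharing is conservative with 2 replicates;
  features with one wildly divergent replicate can escape detection even
  at large planted folds — visible occasionally in power runs as a
  genuinely ambiguous data draw, not an estimator artefact.
* The usage test assumes exon and rest-of-gene counts are disjoint
  (no double-counted reads) and conditions exchangeable across samples.
* Consequence classification assumes the novel isoform differs from the
  reference by exon insertion only; interior substitutions fall through
  to FRAME_DISRUPTION.
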