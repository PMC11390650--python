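# Methods

## Event model and PSI

A cassette-exon (SE) or retained-intron (RI) event is represented by four
genomic boundary coordinates — upstream flanking exon end, alternative
region start and end, downstream flanking exon start — all 0-based
half-open on the forward genomic axis, with the invariant
`upstream_end ≤ target_start < target_end ≤ downstream_start` regardless
of gene strand.  The rMATS-dialect reader maps `exonStart_0base`
directly and treats end columns as half-open; SAMPLE_1 is the basal
condition, SAMPLE_2 the stimulated one.

PSI is the length-normalised inclusion ratio
`100·(I/lI)/((I/lI)+(S/lS))`.  Junction-count (JC) quantification gives
the inclusion isoform two junctions and the skipping isoform one, hence
default effective lengths `lI = 2`, `lS = 1`; the table's
`IncFormLen`/`SkipFormLen` columns override them per event.  Replicates
are summarised as the arithmetic mean of per-replicate PSI values, not
from pooled counts; a replicate with no reads on either form is
undefined and excluded, and an event with no defined replicate is
flagged unquantifiable.

Class boundaries: PI for PSI ≥ 80, PS for PSI ≤ 20, AS strictly between.
The published definitions use strict inequalities on all three classes,
which leaves the exact boundary values unassigned; the outer bins are
closed here so that the classes partition [0, 100].

The expression filter exists in two variants because both are needed
downstream: `all_samples` (max(I, S) strictly greater than the threshold
in every sample of every condition) gates differential calls;
`mean_over_samples` (mean over samples of max(I, S) above the threshold)
defines enrichment backgrounds.

## Liftover

UCSC chain files are parsed bit-exactly (header plus block lines,
optional trailing id) and validated: block sizes plus target/query gaps
must sum to the header spans.  Chains are indexed by an interval tree on
target coordinates; among chains covering a position the highest score
wins, ties broken by (t_start, q_name) for determinism.  A position in a
target-side gap reports status `gap`, a position under no chain
`unmapped`.  With a negative-strand query the file's query coordinates
are on the reversed sequence; lifted positions are always reported on
the forward strand.

Events are lifted boundary-wise through one chain.  Half-open end
coordinates are lifted as (end − 1) then re-opened, avoiding off-by-one
errors at block edges.  Success requires all four boundaries mapped by
the same chain to one query chromosome with consistent order; on a
strand flip the upstream/downstream roles are swapped so the lifted
event satisfies the boundary-order invariant again, and the event strand
toggles.  Whole-interval remapping with a minimum-match fraction is
deliberately out of scope: the downstream matching tolerance subsumes
its role for four-point boundary tuples.

## Orthologous event matching

Candidates require the same chromosome, strand (after lifting), event
type, a gene pair consistent with the strictly 1:1 ortholog map when one
is supplied, and all four absolute boundary offsets at most the
tolerance (default 10 bp, inclusive — "within" read as ≤).  The final
1:1 pairing is greedy by ascending total absolute offset with a
deterministic tie-break on source coordinates; on realistic inputs,
where distinct events are separated by more than the tolerance, this
equals the exact minimum-weight assignment (verified against a Hungarian
oracle in the tests).  Output order and content are invariant to input
permutation.

## Differential inclusion

The activity-response test is a replicate-pooled binomial
likelihood-ratio test: shared read-level inclusion fraction across
conditions versus per-condition fractions, statistic referred to
chi-square with 1 df.  The test runs on raw junction counts rather than
length-normalised ones: both conditions of an event share the same
effective lengths, so equal read-level inclusion fractions are
equivalent to equal PSI, every read retains its unit of statistical
information (normalising would misstate the binomial variance and makes
the test conservative — measured null rejection 0.025 instead of 0.05),
and the p-value is automatically invariant under rescaling both
effective lengths.  Effect size is always reported on the PSI scale
(`delta_psi` = mean stimulated PSI − mean basal PSI).  At sequencing
depth 100 with 3 replicates the null rejection rate at p < 0.05 is
0.050 and power at |ΔPSI| = 20 exceeds 0.9 (both verified by fixed-seed
Monte Carlo in the acceptance suite).

A beta-binomial variant (mean/overdispersion parametrisation, Nelder–Mead
maximum likelihood, 2-df LRT since the alternative fits its own
dispersion) is available for overdispersed replicates; the default
binomial test matches how the synthetic counts are generated.

Significance combines three strict inequalities: p < 0.05, expression
filter passed (`all_samples`, threshold 5), |ΔPSI| > 10.  No
multiple-testing correction is applied to differential calls; the filter
set operates on raw p plus effect size, and an FDR column read from
input tables is carried through unused.

Percent of maximum possible change divides ΔPSI by its ceiling: 100 −
basal for increases, basal for decreases.  The statistic is computed for
any event (it is total, bar the basal = 100 increase case, whose
denominator is zero) but compared only under the 20 < basal < 80 gate,
applied at comparison time.

## Comparative statistics

Pearson correlations carry 95% confidence limits from the Fisher
z-transform with standard error 1/√(n−3) and a two-sided p from the z
statistic; |r| = 1 collapses the interval, and n = 3 defines r but no
interval.  Class enrichment builds the 2×2 table a = |ref ∩ query|,
b = |query \ ref|, c = |ref \ query|, d = rest; the reported fold
enrichment is the ratio of proportions P(ref|query)/P(ref|¬query) with a
Katz log-scale interval (a flag switches the denominator to
P(ref|universe)).  The odds ratio and its Woolf standard error
√(1/a+1/b+1/c+1/d) are carried alongside, and two enrichments are
compared by z = (ln OR₁ − ln OR₂)/√(SE₁²+SE₂²).  Zero cells trigger a
flagged Haldane–Anscombe 0.5 correction for the ratio statistics; the
Fisher p always uses the raw table; a query equal to the whole universe
leaves nothing to condition on and reports fold 1.  Expression-matched
subsetting keeps ortholog pairs whose expression ratio lies in the
log-symmetric band [1/(1+band), 1+band] (default band 0.2); a flag
restores the arithmetic reading [1−band, 1+band].

## Conservation sets

Gene labels are defined over matched orthologous events.  A gene is
conserved-regulated when it has a significant event in the target
species and its 1:1 ortholog has a significant event in at least one
source-species dataset (gene-level, the default); a stricter event-level
variant requires the same orthologous event significant in both and is
the appropriate foreground for factor-target enrichment.
Species-specific genes are regulated in one species with the ortholog
testable (present in the expression background) but never significant.
Genes whose ortholog is untestable in every counterpart dataset are
excluded from the species-specific set rather than counted as divergent
— absence of evidence is not evidence of divergence; a permissive flag
restores the inclusive reading.  Conserved and species-specific sets
partition the regulated, testable gene universe.

Term enrichment is a flat per-term Fisher test (terms annotating fewer
than 5 background genes skipped; optional Benjamini–Hochberg).  It does
not reproduce graph-weighted ontology algorithms that decorrelate nested
terms, so its p-values are not comparable to such methods term-by-term.

## Synthetic data

The generator is the package's study-conditions definition, not a
tuning knob.  Defaults: 200 genes × 3 events (the recovery profile uses
1000 genes ≈ 2100 orthologous events), orthologous fraction 0.7,
PI/PS/AS mixture 0.40/0.25/0.35 (neuronal transcriptomes are dominated
by near-constitutive exons, with a substantial alternative minority),
cross-species basal logit-PSI correlation 0.85 (conserved but visibly
imperfect), responsive fraction 0.15 with half the responses conserved,
response magnitudes |ΔPSI| ~ N(25, 8) truncated to [15, 60] (clearly
regulated exons; the calling threshold is 10), 60% exclusion-biased
(activity-induced skipping is the more prevalent direction in neurons),
ΔPSI magnitude correlation 0.8 for conserved responders, depth 200,
3 replicates.

Basal PSI is drawn by pushing a correlated Gaussian pair through the
quantile function of the class mixture on the logit scale (a Gaussian
copula): PSI is bounded, so correlation is imposed on logits, and the
realized PSI-scale correlation — slightly attenuated by the bounded
transform — is recorded in the truth tables so recovery tests compare
like with like.  Response signs respect headroom (an exon near the
inclusion ceiling responds by exclusion), so planted effects survive
clipping to [1, 99].

The coordinate map is emitted as one chain per gene with random indel
gaps between events and a 10% strand-flip fraction; planted ortholog
boundaries never fall inside gaps (guaranteeing liftability), while a
configurable fraction of non-orthologous events straddles a gap to
exercise failure paths.  Target-side annotations are the lifted source
boundaries plus independent per-boundary jitter within the matching
tolerance; non-orthologous liftable events get a 25-bp-shifted
target-only counterpart so both species carry unmatched events.  Counts
are binomial reads at Poisson replicate depth with read-level inclusion
probability ψ·lI/(ψ·lI+(1−ψ)·lS) (optionally beta-binomial).  All
randomness flows from the single config seed; bundles regenerate
byte-identically from their JSON manifest.

What the simulation does not emulate: read-level artefacts (mapping
bias, positional coverage), shared splicing regulation across events of
a gene, expression-level/PSI coupling, annotation errors, and multi-way
orthology.  Passing recovery tests therefore demonstrate correctness of
the pipeline's logic and calibration of its statistics under a faithful
generative model, not robustness to those real-data complications.

## Problem sizes and numerical choices

The acceptance suite runs the recovery bundle at 1000 genes / depth 200
/ 3 replicates, the null calibration at 10,000 events, the
correlation-coverage check at 500 × n = 2000, and the enrichment
comparison at 2000 null table pairs; the exhaustive Fisher-vs-enumeration
check covers every 2×2 table with N ≤ 60 through canonical
representatives of the table symmetries, with the implementation's
symmetry invariance verified on a random sample.  Ties in the
enumeration oracle use a 1e−7 relative tolerance on point masses, the
convention of the reference implementation.  Degenerate inputs
(all-zero counts, empty universes, zero-variance correlations, n < 3)
return flagged undefined results rather than raising, except where an
empty result would silently corrupt downstream sets (empty background).
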