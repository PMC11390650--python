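# orthosplice

Cross-species comparison of basal and activity-dependent cassette-exon
splicing in neurons, built as a reusable pipeline: percent-spliced-in (PSI)
quantification from replicate junction counts, UCSC-chain coordinate
liftover, orthologous exon matching, activity-response calling, and
Fisher-exact enrichment statistics, exercised end to end on synthetic
two-species data with planted ground truth.

## The problem

Neuronal electrical activity (modelled experimentally by KCl-induced
depolarisation) changes which exons are included in mature transcripts.
Whether such activity-dependent splicing of an exon in mouse neurons
predicts the behaviour of its human ortholog is a quantitative,
genome-wide question.  Answering it requires:

1. **PSI per event.**  For a cassette exon with inclusion-junction count
   *I*, skipping-junction count *S* and effective junction lengths *lI*,
   *lS* (2 and 1 for junction-count quantification):

   `PSI = 100 · (I/lI) / (I/lI + S/lS)`

   averaged over biological replicates.  Exons are classed as primarily
   included (PI, PSI > 80), primarily skipped (PS, PSI < 20) or
   alternatively spliced (AS, 20 < PSI < 80).

2. **Orthologous event matching.**  Source-species event boundaries
   (upstream exon end, alternative exon start/end, downstream exon start)
   are lifted through a UCSC chain file; a lifted event and a target
   event are orthologous when all four boundaries agree to within 10 bp
   and the genes are 1:1 orthologs.

3. **Activity-response calls.**  ΔPSI = stimulated − basal, with a
   binomial likelihood-ratio test on the junction counts; an event is
   regulated when p < 0.05, max(I, S) > 5 in every sample, and
   |ΔPSI| > 10.

4. **Percent of maximum possible change.**  An increase is scaled by the
   headroom (100 − basal PSI), a decrease by the basal PSI, and the
   statistic is compared only for exons with 20 < basal PSI < 80 (an exon
   moving 95 → 98 already consumes 60% of its possible change).

5. **Conservation sets and enrichment.**  Genes regulated in both species
   (conserved) versus in exactly one (species-specific), with
   splicing-factor-target and annotation-term enrichment via Fisher's
   exact test, fold enrichments with Katz confidence limits, and
   comparison of two enrichments by the normal approximation to the
   difference in log odds ratios (Woolf standard errors).

## Layout

- `src/orthosplice/` — the library: `events` (PSI, IO), `liftover`,
  `orthologs`, `differential`, `compstats`, `conservation`, `simulate`
  (synthetic two-species bundles with planted truth), `pipeline` + `cli`.
- `analysis/` — numbered drivers reproducing the full analysis on a
  simulated bundle: `01_simulate.py`, `02_basal_comparison.py`,
  `03_activity_response.py`, `04_conservation_sets.py`.  Outputs land in
  `results/`.
- `tests/` — unit, property and acceptance suites with independent
  brute-force oracles.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_basal_comparison.py
```

prints, for the default 1000-gene bundle (3000 source events, 70%
orthologous, sequencing depth 200, 3 replicates):

```
matched 2100 orthologous events (70.0% of source, 76.9% of target)
basal PSI Pearson r = 0.798 [0.782, 0.813], n = 2100
AS-class enrichment across species: 2.6-fold [2.3, 3.0], Fisher p = 1.19e-49
panel: min within-species r = 0.792 > max cross-species r = 0.516 (yes)
```

The match rate recovers the planted orthologous fraction exactly; the
basal-PSI correlation estimate (0.798) agrees with the realized true
correlation of the planted values (0.799); AS-class membership is
strongly conserved across the species pair; and in a six-dataset panel
with planted within-species correlation 0.8 and cross-species correlation
0.5, every within-species matrix cell exceeds every cross-species cell —
the qualitative signature of inter-species divergence.

`03_activity_response.py` then calls activity-regulated events (~330 per
species at the default 15% responsive fraction, exclusion-biased) and
correlates ΔPSI and percent-of-max change across species;
`04_conservation_sets.py` partitions genes into conserved /
species-specific sets, recovering the planted labels with precision and
recall ≥ 0.96, and demonstrates splicing-factor-target enrichment in
conserved-response events.

A `orthosplice` console command exposes the same stages
(`simulate | psi | lift | match | diff | run`); `orthosplice run --config
cfg.yaml` executes the whole comparison from a declarative config whose
defaults are the analysis thresholds above.

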