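# Methods

This note documents the models implemented in `isocoord`, their
assumptions, the defaults that matter, and the design choices made
where the procedure was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions and transcript models

All internal coordinates are 0-based half-open; GTF I/O converts the
1-based inclusive convention at the boundary. A transcript's end site
(TES) is its 3' terminus in transcription direction (last exon end on
`+`, first exon start on `−`). The CDS is carried as a single genomic
span; exon context labels (5UTR / ORF / 3UTR and the two straddling
combinations) are derived strand-aware from overlap with that span. An
exon spanning the entire ORF has no label in this five-way vocabulary
and raises an error rather than being silently binned.

## PolyA-site clustering

Transcript end sites of a gene are clustered by **single linkage with a
24-nt window**: two sites join one cluster whenever a chain of
neighbours ≤ 24 nt apart connects them. Single linkage was chosen
because it is order-independent and matches common end-site collapsing
practice; the underlying rule ("within 24 nucleotides of each other")
does not dictate a linkage. The cluster representative is the modal
member position, ties resolved to the most distal member in
transcription direction. Proximal rank 1 is the cluster nearest the
gene's 5' end in transcription direction. Clustering is per gene, since
every downstream analysis is gene-scoped. Clustering is idempotent on
representatives and the cluster count is monotone non-increasing in the
window (both property-tested).

## Skipped-exon events and counting

An event requires an inclusion isoform with junctions U→E and E→D
around the alternative exon E and a skipping isoform with the direct
junction U→D, with exactly matching anchor coordinates. Transcripts
carrying neither junction pattern (e.g. alternative-first-exon
isoforms) are *irrelevant*: they contribute to neither count, to avoid
conflating TSS choice with splicing.

Per (event, polyA cluster, sample) cell we sum inclusion-transcript and
skipping-transcript counts. Raw counts are stored; the pseudocount of 1
is applied at model/PSI time so the stored table stays auditable.

**Read-support filter.** A site survives when ≥ 5 samples each carry an
inclusion+skipping total ≥ 10 and those qualifying samples sum to ≥ 50
reads; events keep ≥ 2 surviving sites or are dropped. The "cumulative
count ≥ 50 in at least five samples" wording admits a second reading
(five samples each ≥ 50); both are implemented and selectable via
`site_rule`, with the sum reading as default because it is the only one
in which both clauses constrain.

**Transcript flags.** Microexon: skipped exon < 28 nt. PTC: the ORF's
3' boundary mapped to mature-transcript coordinates lies ≥ 50 nt
upstream of the last exon–exon junction; mono-exonic transcripts can
never carry one. Intron retention: an exon of one isoform exactly spans
one or more consecutive introns of another isoform, where "exactly"
means the exon's ends coincide with the outer boundaries of the
flanking exons. This is a deliberate minimal containment rule, not a
re-implementation of annotation-suite IR logic.

## Quasi-binomial nested models

Each event's design has one row per (site, sample) with
(inclusion, skipping) totals (pseudocounted). Three nested
binomial-logit models — `Time`, `Time + Site`, `Time × Site` — are fit
by IRLS with treatment coding (first sorted level as reference).
Numerical choices: deviance-change tolerance 1e-8, at most 100
iterations, and any |coefficient| > 15 on the logit scale treated as
separation; either condition marks the fit non-convergent, and events
with any non-convergent model are removed (logged). Rank-deficient
designs raise an error naming the aliased terms.

Dispersion is the Pearson χ²/df of the **fuller model of each
comparison**, the standard analysis-of-deviance convention for quasi
families (the procedure's description names the F-test but not the
dispersion source). The F-test is

    F = ((D_reduced − D_full)/Δdf) / φ_full,  p = SF_{F(Δdf, df_full)}(F).

Forcing φ = 1 makes F·Δdf the plain binomial LRT statistic, which the
tests verify against statsmodels GLM fits (the implementation itself is
an independent hand-rolled IRLS, so the two routes are distinct).
Degenerate designs are kept useful: with a single timepoint the
interaction adds no parameters, so the interaction p is reported as
undefined (NaN) while the global test still runs.

BH correction runs across events in two separate families (global and
interaction p-values), matching the two distinct model comparisons.

**Observed PSI** pools pseudocounted counts across a timepoint's
samples: PSI = Σ(inc+1)/Σ(inc+skip+2). A per-sample-mean alternative is
available via `psi_method="mean"`. The global ΔPSI is max−min across
sites of time-averaged PSI; the other admissible order (average of
per-time spreads) is exposed via `global_order` but is not the default.

**Effect-size thresholds** (both at 0.1, on top of FDR < 0.05): global
calls need the time-averaged between-site spread; interaction calls
need within-site movement across time at ≥ 1 site *and* between-site
separation at ≥ 1 timepoint.

**Marginal means** are computed per (site, timepoint) cell from the
interaction fit: η = x'β, SE² = x'(φ·(X'WX)⁻¹)x, CI =
expit(η ± 1.96·SE). The 1.96 normal multiplier follows the reference
marginal-means tooling for GLMs.

## Fisher contingency baseline

The baseline pools counts across all samples per event into an
n-sites × 2 matrix, removes sites with < 100 pooled reads, rejects
events whose pooled inclusion or exclusion total is < 100 or that
retain < 2 sites (site filter applied first), and adds a pseudocount of
1 to the surviving cells. Each site is tested against the pooled
remainder with a two-sided Fisher exact test; BH runs once across all
site tests in the run. Significance requires FDR < 0.05 and
|logOR| ≥ 1, with the documented guard constant 1e-13 added to the OR
before the log. The default OR is the sample cross-product estimator
(deterministic, closed-form); the conditional-MLE estimator is
available behind `or_estimator="conditional"`. Method comparison
restricts to events tested by both routes and reports
|significant in both| / |significant in either|.

## Event annotation metrics

Distance: from the 5' position of the exon immediately downstream (in
transcription direction) of the coordinated exon on the gene's most
abundant isoform, to the representative position of the most proximal
retained polyA cluster — proximal among the *event's* retained sites,
not all gene sites (the narrower reading; the wording is ambiguous).
Intervening exons: exons strictly after the coordinated exon up to and
including the exon containing that proximal site. Both are invariant
under coordinate translation and strand mirroring (tested). Gene-set
enrichment is a one-sided (greater) Fisher exact test over an explicit
background.

## APA usage

Per sample, PAU = 100 · site CPM / unit CPM (CPM library size = column
sum of the retained transcript matrix); per-timepoint PAU is the
**median across the timepoint's samples**. Units must exceed 1 CPM at
every timepoint — mean across samples by default, median behind
`expression_stat` — and carry ≥ 2 sites. PPAU is the proximal site's
PAU; ΔPPAU = PPAU(first timepoint) − PPAU(last); > 20 is a lengthening
call, < −20 shortening, boundaries exclusive. The CDS-identical variant
groups transcripts sharing identical exon structure up to the 3'UTR
start (the ORF's 3' boundary, strand-aware), re-clusters end sites
within each group with the same 24-nt rule, and treats groups as
independent units, isolating 3'UTR choice from upstream structural
differences.

## Expression dynamics

Trajectory codes: per interval, 'U' iff log2FC > 1 and FDR < 0.05, 'D'
iff log2FC < −1 and FDR < 0.05, else '−'; both inequalities strict, so
boundary values fall to '−'. The cell "large fold change but
non-significant FDR" is undefined by the three symbol definitions; it
resolves to '−' (no confident change) with a warning, and a missing FDR
is treated the same way. Direction-bias tests are exact two-sided
binomial tests against 0.5 using the minimum-likelihood two-sided
p-value, BH-corrected across the run's categories. Per-category
enrichment uses one-sided Fisher tests with a Bonferroni multiplier
equal to the number of non-empty categories in the comparison.
Translational efficiency: per replicate TE = (RPF+0.5)/(input+0.5),
replicates averaged **then** log2-transformed; a region is kept only
when every matched input library has ≥ 6 reads (the stricter per-
replicate reading of the input filter).

## MAPS

The neutral baseline regresses per-context synonymous singleton
proportions on the context mutation rate μ by weighted least squares
(weights = context variant counts). Linear-on-μ is the default;
`log_mu=True` switches to log-scaled mutability, since published MAPS
calibrations differ and the procedure's description does not fix the
form. Expected singleton proportion of a class is the mean baseline
prediction over its variants; MAPS = observed − expected. Because the
weighted regression includes an intercept, the training set's in-sample
MAPS is 0 to machine precision, and MAPS is invariant to duplicating
every variant (both tested). CIs are percentile intervals from a
seeded nonparametric bootstrap over variants (B = 1000; the CI method
is a package choice — the source analyses display 95% CIs without
naming one). Class-vs-synonymous significance uses a chi-squared test
on the 2×2 singleton-by-class table without continuity correction
(immaterial at the intended sample sizes), BH-corrected across
classes. Contexts unseen in training are predicted by extrapolating
the fitted line, with a warning. The burden comparison is a two-sided
Fisher exact test on carrier counts with the sample OR (NaN on zero
margins).

## Synthetic data: what it emulates and what it does not

The coordination generator draws from exactly the law the GLM assumes:
logit P(inclusion | site j, time t) = μ + α_j + β_t + γ_jt, totals
Poisson around the target depth, and inclusion counts beta-binomial
with overdispersion ρ (ρ = 0 is binomial; Pearson dispersion grows as
≈ 1 + (n−1)ρ, giving the calibration handle the quasi-likelihood
correction exists for). Defaults are desk-scale study conditions: 200
events, 3 timepoints × 3 samples, 2 polyA sites per event, depth 100
reads per (site, sample). Planted effects use baseline PSI 0.35 and
ΔPSI 0.3: "global" shifts one site's inclusion uniformly; "interaction"
moves one site from baseline − Δ/2 to baseline + Δ/2 across the time
course so its time-average cancels and only the interaction test can
see it. Gene geometries (5–8 exons of 150 nt, one skippable middle
exon, end sites 200 nt apart, CDS covering first-to-penultimate exon,
half the genes mirrored to the − strand) are simple but pass every
ingestion validator, round-trip through GTF, and reconstruct the event
table exactly from transcript counts.

What the generator does **not** emulate: sequence content, read-level
error, truncation/degradation biases of long reads, transcripts shared
between events, library-size variation between samples, or correlated
overdispersion across events. Passing tests therefore demonstrate
correctness and calibration of the statistics under the assumed
generative law — not robustness to artefacts real long-read data may
carry.

Variant tables draw contexts proportional to μ and singleton flags
Bernoulli(0.25 + 1.5e6·μ + class shift) over 16 synthetic contexts with
μ ∈ [2e-8, 1.6e-7] — rates and proportions chosen to sit in the range
typical of population-scale SNV data, with the baseline linear so that
the default MAPS regression is correctly specified. Expression tables
draw (log2FC, FDR) strictly inside each of the nine trajectory regions
with margins (|log2FC| ≥ 1.2 or ≤ 0.85; FDR ≤ 0.04 for significant
intervals) so label recovery is exact and float-robust.

All generators are pure functions of (config, seed); every
simulation-facing entry point takes an explicit seed and no global RNG
state is used.

## Problem sizes

The test suite and the acceptance script use the generator defaults
above (500 events for calibration checks, 200 for power, 50,000
variants per class for MAPS, 100 genes per trajectory code) — sizes at
which the measured properties are stable across seeds while keeping a
full run in the tens of seconds on one CPU.

## Known limitations

- Only skipped-exon events are extracted; A5/A3/MX/AF/AL event classes
  are out of scope.
- The IR rule requires exact flank matching; annotation suites with
  fuzzier matching will call more IR transcripts.
- The Fisher baseline deliberately pools replicates — it exists as the
  comparison method whose shortcomings the GLM addresses.
- MAPS assumes the mutability table's contexts cover the variant
  classes well; heavy extrapolation outside the training μ range is
  flagged but not prevented.
- The CLI's `run-all` orchestrates the synthetic end-to-end path; real
  datasets are expected to enter through the library API or the
  per-stage subcommands.
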