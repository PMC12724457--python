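# isocoord

Statistical machinery for detecting **coordination between alternative
splicing (AS) and alternative polyadenylation (APA)** in long-read
isoform count data, together with the surrounding quantitative toolkit a
long-read transcriptomic study of neuronal differentiation needs:
polyA-site usage metrics, expression-trajectory classification,
direction-bias tests, and mutational-constraint (MAPS) / de novo burden
statistics. Everything runs on seeded synthetic data with known truth,
so every stage is testable without any external download.

## Who this is for

Full-length reads observe an alternative exon and the transcript's 3'
end on the same molecule, so they can reveal whether exon inclusion is
statistically coupled to polyA-site choice — a long-range layer of
co-regulation invisible to short reads. `isocoord` is for
transcriptomics researchers who have a transcript-by-sample count
matrix from long-read sequencing (plus a GTF of isoform models) and
want calibrated, replicate-aware statistics for that coupling.

## The core model

For each skipped-exon event, inclusion and skipping read counts are
tallied per (polyA site, sample) cell. Counts get a pseudocount of 1 and
are fit with three nested binomial-logit GLMs under quasi-likelihood
(free dispersion φ estimated from Pearson residuals):

    Inclusion ~ Time                 (reduced)
    Inclusion ~ Time + PolyA_Site    (global)
    Inclusion ~ Time × PolyA_Site    (interaction)

Nested models are compared with F-tests on the analysis of deviance,

    F = ((D_reduced − D_full)/Δdf) / φ,   p = P(F(Δdf, df_full) > F),

BH-corrected across events separately for the global and interaction
families. A significant call additionally requires a percent-spliced-in
effect size: global events need ΔPSI ≥ 0.1 between sites after
averaging over time; interaction events need ≥ 0.1 PSI movement across
time at some site *and* ≥ 0.1 separation between sites at some
timepoint. Unlike pooled contingency-table tests (provided here as the
`fisher` baseline), the GLM keeps samples separate, so sample-to-sample
overdispersion widens the F-test's denominator instead of inflating
false positives.

The other modules implement: single-linkage 24-nt clustering of
transcript end sites; PAU/PPAU/ΔPPAU with lengthening (>20) and
shortening (<−20) calls; nine-way U/D/− trajectory codes over two
timepoint intervals; exact binomial direction-bias tests; translational
efficiency log2((RPF+0.5)/(input+0.5)) averaged over replicates; and
MAPS — the mutability-adjusted proportion of singletons, with a
synonymous-trained linear baseline, bootstrap CIs and chi-squared tests
versus synonymous.

## Worked example

Simulate six events with a stable site effect (inclusion probability
0.35 at the proximal site vs 0.65 at the distal site, depth 200 reads
per site and sample, 3 timepoints × 3 samples), then run the
coordination tests:

```python
from isocoord import (SimulationConfig, make_truths, simulate_event_counts,
                      filter_events, run_coordination)
from isocoord.glm import results_to_frame

cfg = SimulationConfig(n_events=6, seed=11, depth=200)
table = simulate_event_counts(make_truths(cfg, "global"), cfg)
results = run_coordination(filter_events(table))
print(results_to_frame(results))
```

```
 event_id     p_global   fdr_global  p_interaction  delta_psi  passes_global
gG0000:ev 1.172219e-10 1.172219e-10       0.475775   0.302397           True
gG0001:ev 2.462325e-13 7.386975e-13       0.110320   0.325771           True
gG0002:ev 2.374546e-12 3.561819e-12       0.755042   0.313257           True
gG0003:ev 1.232155e-12 2.464309e-12       0.277880   0.315708           True
gG0004:ev 4.058882e-11 4.870659e-11       0.980495   0.287157           True
gG0005:ev 4.545908e-16 2.727545e-15       0.051769   0.310044           True
```

Every event is recovered as a *global* coordination call: the site term
is overwhelmingly significant (`fdr_global` ≪ 0.05) with the recovered
effect size `delta_psi` ≈ 0.3 matching the planted value, while the
interaction p-values stay null — the coupling is stable over time, as
simulated. Estimated marginal means give the fitted inclusion
probability per (site, timepoint) with 95% CIs on the probability
scale:

```
      site timepoint  estimate   ci_low  ci_high
gG0000:pA1       t00  0.352518 0.310163 0.397325
gG0000:pA1       t04  0.356667 0.315702 0.399841
gG0000:pA1       t30  0.311864 0.272296 0.354382
gG0000:pA2       t00  0.654941 0.611883 0.695600
gG0000:pA2       t04  0.632432 0.587313 0.675345
gG0000:pA2       t30  0.640867 0.599247 0.680469
```

The same pipeline is scriptable from the shell (`isocoord simulate`,
`isocoord coordinate`, `isocoord fisher-baseline`, `isocoord compare`,
`isocoord maps`, ... or `isocoord run-all` on a flat key=value config).

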