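# Methods

## Model and procedure

`rifnet` analyses a gene-by-sample matrix of normalized, log-scale
expression split into a treated condition S and a control condition C.
The pipeline has four stages.

**1. DE screen.** Each gene gets its grand mean x_j, condition means x_jS
and x_jC, differential expression d_j = x_jS − x_jC, and a two-sided Welch
two-sample *t* p-value on the log scale. The DE target set is every gene
with raw p strictly below the threshold (default 0.001). No multiplicity
correction is applied at this stage: the threshold is an operational
selection rule for the target set, not an inference, and the test is
deliberately the simplest defensible choice (unequal-variance *t*); the
correlation-based statistics downstream do not depend on its optimality.
A gene with zero variance in both conditions is assigned p = 1 and
flagged degenerate; zero variance in a single condition goes through the
Welch formula unchanged (the standard error remains positive).

**2. RIF scoring.** For each candidate regulator r and DE target j, the
within-condition Pearson correlations r_rjS and r_rjC give the
differential co-expression DC_rj = r_rjS − r_rjC, and

    RIF1_r = (1/n_DE) Σ_j  x_j · d_j · DC_rj²
    RIF2_r = (1/n_DE) Σ_j [(x_jS·r_rjS)² − (x_jC·r_rjC)²]

Both raw scores are z-standardized across the regulator universe
(sample SD, ddof = 1) and combined as |z1| + |z2|. Regulators are ranked
by the combined score, descending, with a stable sort and a lexical
gene-ID tie-break so output is deterministic.

**3. PIF target ranking.** Around a focal regulator, each DE target is
scored PIF_j · |DC_rj| with PIF_j = x_j · d_j. The absolute value on DC
makes the product's sign follow the direction of DE; the table is sorted
ascending, so one extreme collects abundant targets down in S with strong
connectivity change, the other the symmetric up-in-S case.

**4. Ranked-list enrichment.** For a gene set of size B in a ranked
universe of size N, prefix cutoffs n = step, 2·step, …, N/2 are scanned
(step defaults to max(1, N/100)); at each cutoff the upper hypergeometric
tail P(X ≥ b | N, B, n) is computed and the minimum over cutoffs reported
with its cutoff. `direction="tail"` scans the other end by reversing the
list. Benjamini–Hochberg correction is applied across sets, never across
cutoffs.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| `de_pvalue_threshold` | 0.001 | probability | strict raw-p selection rule for the target set |
| `correlation_method` | pearson | — | matches the RIF statistics' derivation on log intensities; spearman available for heavy-tailed data |
| `min_samples_per_condition` | 3 | samples | correlation is undefined below 3; small-n correlations are noisy, not forbidden |
| `combine` | sum_abs | — | combined score = \|z1\|+\|z2\|; `mean_abs` halves it (pure rescaling, ranking unchanged) |
| `fisher_z` | off | — | optional variance-stabilized DC = atanh(r_S) − atanh(r_C) |
| `pif_variant` | overall_mean | — | abundance term in PIF; `half_sum` uses (x_jS+x_jC)/2, which differs only with unequal group sizes |
| enrichment `step` | N/100 | ranks | cutoff grid granularity; finer grids sharpen the optimum but inflate the minimum further |

## Numerical choices

* Correlations are computed by row-standardized matrix products and
  clipped to [−1, 1]; a regulator that is itself a DE target has its
  self-link fixed to r = 1 on both sides (DC = 0), so self-pairs
  contribute nothing to RIF1 and (x_jS² − x_jC²) to RIF2. DE genes are
  retained in the regulator universe.
* A gene with zero variance inside one condition gets r = 0 on that side
  and the link flagged; the regulator is retained so the standardization
  population is stable.
* Standardization uses the sample SD; with fewer than two regulators, or
  a constant raw score vector, scoring raises rather than emitting NaNs.
* Ties anywhere in a ranking break lexically by gene ID after a stable
  sort; outputs are byte-identical across repeated runs of the same
  inputs and seed.

## The synthetic generator

`simulate_study` emulates the structure of a two-condition microarray
study: per-gene baseline means uniform on [6, 12] log units, i.i.d.
Gaussian noise with SD 1.0, 20 + 20 samples, 2000 genes. Planted DE
targets (200 by default) receive a +2-SD shift in every treated sample —
an effect size at which the Welch screen at p < 0.001 has ≈ 0.997 power,
so the planted set is recovered nearly completely. Each planted regulator
(one by default) keeps equal means in both conditions; a 60-target block
inside the DE set is rebuilt per condition as
coupling · z_R + √(1−coupling²) · ε on standardized residuals (coupling
0.8 in S, 0.0 in C by default) and rescaled to the target's mean and SD.
The shared latent variable means two same-block targets correlate at
about coupling² within a condition — block-level tests expect 0.64, not
independence. The regulator universe defaults to the first 500 genes of
the layout (planted regulators, then DE genes, then background), so DE
genes compete as regulators just as expressed genes do in a real study.
A paper-scale preset (7350 genes, 1279 DE, 23 + 23 samples) exists for
slower integration runs; default sizes are desk-scale so the full suite
and the acceptance script run in seconds.

What the generator does **not** emulate: probe effects, batch structure,
amplification bias, correlated background co-expression beyond the
planted blocks, non-Gaussian intensity noise, or realistic DE effect-size
spectra. Passing recovery tests therefore demonstrate that the statistics
detect the phenomenon they define — a non-DE regulator with condition-
dependent coupling — not that they will rank any particular biological
regulator first in real data.

## Enrichment calibration caveat

The min-over-cutoffs p-value is an optimisation over many correlated
tests and is therefore anti-conservative: in permutation experiments a
uniformly random gene set attains p_min < 0.05 well above 5% of the time
(the suite asserts this inflation rather than hiding it). The exact
minimum-hypergeometric (mHG) correction used by GOrilla-style tools is
deliberately out of scope. For calibrated significance use the seeded
permutation option (`n_permutations`), which compares the observed
minimum with minima of random same-size sets; BH-adjusted q-values across
sets are computed on p_min either way and inherit its inflation.

## Design choices where the design was open

* **Combined score = sum of absolutes.** The source table of top
  regulators that motivated this convention prints combined values equal
  to |z1| + |z2|, although its caption says "absolute average"; the sum
  is the default here and the halved version is a flag, since the two
  differ only by a factor of 2 and never reorder.
* **DC is the raw correlation difference**, not a Fisher-z difference
  (flag available). The raw difference is bounded in [−2, 2] and keeps
  DC² commensurable across pairs.
* **Regulator universe includes the DE genes.** Excluding them would
  change every z-score denominator and silently shrink the universe; the
  expressed-gene universe is the documented convention.
* **Role mapping of free condition labels** defaults to lexical order
  (first → control) with a logged warning, so literal "C"/"S" labels map
  to their conventional roles; explicit `treated_label`/`control_label`
  settings override and are recommended, because d_j, RIF2 and all PIF
  products are antisymmetric in the roles.
* **Missing values are rejected** at load unless `drop_genes` is chosen,
  because RIF sums over every DE target and silent NA propagation would
  corrupt every regulator's score.

## Known limitations

* Correlations at n ≈ 20 per condition carry sampling SD ≈ 0.2; DC for a
  single pair is noisy, and the statistics rely on averaging over many
  targets. Very small DE sets make RIF unstable.
* The Welch screen assumes approximate normality on the log scale; count
  data should be transformed (or the screen swapped) before use.
* The enrichment scan tests prefix concentration only; it does not model
  set-set overlap, and q-values are across the supplied sets only.
* Probe-to-gene annotation, preprocessing and figure rendering are out of
  scope; exports are plot-ready tables, not figures.
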