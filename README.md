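# rifnet

Differential co-expression network analysis for two-condition
transcriptome studies: **regulatory impact factor (RIF) scoring** of
candidate regulators, **phenotypic impact factor (PIF) × differential
co-expression target ranking** around a chosen regulator, and
**hypergeometric enrichment** of gene sets in the extremes of the resulting
ranked lists — together with a synthetic-data generator that plants
differentially connected regulators so the whole pipeline is testable
end-to-end without any external data.

## Who this is for

A differential-expression screen only sees genes whose own mRNA level
shifts between conditions. Much regulation is post-transcriptional: a
regulator can change its *position in the co-expression network* — which
genes it correlates with, and how strongly — while its own abundance stays
flat. `rifnet` is for analysts of two-condition bulk expression data
(treated vs control, case vs control) who want to rank candidate
regulators by exactly that network rewiring.

## The statistics

Samples belong to a treated condition **S** or a control condition **C**.
A DE screen (Welch *t*-test on log expression, raw *p* < 0.001 by default)
selects the set of *n*<sub>DE</sub> differentially expressed target genes.
For target *j*: *x<sub>j</sub>* is its mean log expression over all
samples, *x<sub>jS</sub>* and *x<sub>jC</sub>* its condition means, and
*d<sub>j</sub>* = *x<sub>jS</sub>* − *x<sub>jC</sub>* its differential
expression. For a candidate regulator *r*, *r<sub>rjS</sub>* and
*r<sub>rjC</sub>* are its Pearson correlations with target *j* within each
condition, and DC<sub>rj</sub> = *r<sub>rjS</sub>* − *r<sub>rjC</sub>* the
differential co-expression. Then

    RIF1_r = (1/n_DE) Σ_j  x_j · d_j · DC_rj²
    RIF2_r = (1/n_DE) Σ_j [(x_jS · r_rjS)² − (x_jC · r_rjC)²]

RIF1 favours regulators consistently differentially co-expressed with the
abundant, strongly shifted targets; RIF2 favours regulators whose ability
to predict target abundance changes most. Raw scores are z-standardized
across the regulator universe (every expressed gene by default) and
combined as |z₁| + |z₂|; regulators are ranked by this combined score.

Around a focal regulator, each DE target also gets a signed link score
PIF<sub>j</sub> · |DC<sub>rj</sub>| with PIF<sub>j</sub> = *x<sub>j</sub>* ·
*d<sub>j</sub>*; the sign follows the direction of DE (positive = higher
in S). Gene sets can then be tested for concentration in either extreme of
that ranking with a min-over-cutoffs hypergeometric scan (BH-corrected
across sets; see `docs/methods.md` for the calibration caveat).

## Worked example

Simulate a study with one planted regulator (`g00001`): non-DE, but
correlated at 0.8 with a 60-gene block of DE targets in the treated
samples and at 0.0 in controls. Then run the full pipeline with that
regulator as the focal gene:

```sh
rifnet simulate --out sim --seed 11
rifnet all --matrix sim/matrix.tsv --conditions sim/conditions.tsv \
           --out run --focal-regulator g00001 --de-p 0.001 --seed 11
```

`run/de_summary.tsv` reports nDE = 205 genes at *p* < 0.001 (200 planted
plus a handful of false positives at this threshold). The top of
`run/rif_scores.tsv`:

```
regulator_id  rif1_raw  rif2_raw   rif1_z   rif2_z  combined  rank
      g00001  5.369648 24.243211 6.481047 7.329478 13.810525     1
      g00058  5.270887 19.495932 6.285171 5.732479 12.017651     2
      g00018  5.071350 19.905786 5.889424 5.870355 11.759779     3
```

The planted regulator ranks 1st of 500 despite being invisible to the DE
screen (its own *p* = 0.51 here); the runners-up are members of its target
block, which inherit differential connectivity from the shared latent
factor. `run/pif_targets.tsv` holds the signed PIF × |DC| ranking around
`g00001`, and `run/rif_scatter.tsv` / `run/ma_plot.tsv` are plot-ready
projections (RIF1-z vs RIF2-z; abundance vs DE).

The same steps are available as library calls (`simulate_study`,
`summarize_targets`, `select_de_targets`, `score_regulators`,
`pif_rank_targets`, `ranked_enrichment`) — see the module docstrings.

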