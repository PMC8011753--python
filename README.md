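# pacseq

Guide-RNA detection, quality control, differential expression and power
analysis for single-cell CRISPR screens in which the gRNA is read out
directly in droplet scRNA-seq (poly-A-tailed guide transcripts captured by
oligo(dT) priming, e.g. for probing gene cis-regulatory elements).

## Who this is for

CRISPR mutagenesis of a cis-regulatory element rarely silences its target
gene in every cell: even strongly disruptive guides typically produce
partial (monoallelic) loss in ~20–30% of cells and full (biallelic) loss
in under 5%. Detecting such dilute, one-gene effects in scRNA-seq requires
(a) confidently knowing which guide each cell carries and (b) enough cells
per guide for the target's baseline expression. `pacseq` implements the
computational side of that experiment for screen analysts: mapping
guide-enriched reads to a guide panel, a per-guide mixture model for
guide-to-cell assignment, standard droplet QC, rank-sum differential
expression, and a simulation framework that predicts the number of cells
per guide needed before the experiment is run.

## The model

For each guide *g* independently, let *n_i* be cell *i*'s total gRNA UMI
count and *k_i* its count for *g*. Counts follow a two-component binomial
mixture,

    z_i ~ Bernoulli(π),   k_i | z_i ~ Binomial(n_i, p_{z_i}),

with a noise rate *p₀* (mapping artefacts, ambient molecules) and a signal
rate *p₁* ≫ *p₀* (the guide is in the cell). The fit is by EM, initialised
from a two-component Gaussian mixture on the count fractions *k_i / n_i*.
A guide is called **present** when the posterior probability that its
count arose from the noise component,

    P(noise | k, n) = (1−π)·B(k; n, p₀) / [(1−π)·B(k; n, p₀) + π·B(k; n, p₁)],

is below 0.05; cells with exactly one present guide are assigned to it,
and the **detection rate** is the assigned fraction of high-quality cells.

The power framework buckets genes by baseline log-normalised expression,
injects loss into treatment populations resampled from a control profile
(biallelic → expression zeroed, monoallelic → halved, at user-supplied
fractions *f_full*, *f_mono*), tests each against the control by two-sided
Wilcoxon rank-sum, Bonferroni-adjusts either over all genes or after
independent filtering, and reads off the minimum cells per guide reaching
adjusted *p* < 0.05.

## Worked example

Fit the mixture and assign guides on a simulated 800-cell, 10-guide pool
(`python examples/03_guide_assignment.py`):

```
guide_id  p_noise  p_signal  pi_signal  converged
    sg01   0.0057    0.9504     0.0925       True
    sg02   0.0061    0.9524     0.0988       True
    ...
detection rate: 100.0% of cells mapped to exactly one guide
agreement with simulated truth: 100.0%
```

The fitted noise rate ~0.006 and signal rate ~0.95 recover the generating
truth (0.005, 0.95); every cell is assigned to exactly one guide because
the simulated signal/noise separation is large. Real libraries sit lower
(detection rates around 75–91% depending on sorting), because ambient
guide molecules and multi-guide droplets — which the simulation
deliberately omits — move cells into the `none_present` and
`multiple_present` categories.

Predict cells-per-guide for the observed loss regime
(`python examples/06_power_analysis.py`, loss 25% mono / 5% biallelic):

```
bucket  mean-expression range   min cells (all genes)  (filtered)
     0  [  0.0202,   0.0499]                  never      never
     ...
     5  [  0.7720,   1.3173]                    400        400
     6  [  1.3239,   2.0227]                    200        100
     9  [  3.5273,   4.1975]                    100        100
```

Genes in low-expression buckets are undetectable at any tested cell count
("never") — the regime where transcript-targeted sequencing is needed —
while highly expressed targets need only ~100 cells; independent filtering
(adjusting only over genes at or above the bucket's expression) lowers
some minima.

All commands are also available from the shell:
`pacseq simulate|quant|qc|assign|de|power --help`.

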