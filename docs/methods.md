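# Methods

## Gene-state mixture model

Each gene's expression across a cohort is modelled as a two-component gamma
mixture. The suppressed state is frequently near-exponential and the promoted
state near-normal; both are special or limiting cases of the gamma family, so
a gamma pair accommodates the spectrum of shapes seen on RMA-scale data
without switching families. Fitting is EM:

* **Initialization** is deterministic: values are split at the median and
  each half is fitted by the method of moments. No random restarts in the
  normal path; the `seed` only drives one jittered restart when EM collapses.
* **M-step** is the exact weighted gamma MLE — the shape solves
  `log k − ψ(k) = log(weighted mean) − weighted mean of logs` by Newton from
  Minka's closed-form start — so the log-likelihood is non-decreasing across
  iterations (asserted in tests at every iteration).
* **Convergence**: relative log-likelihood change < `tol` (default 1e−6) or
  `max_iter` (default 500).
* **Relabelling**: components are ordered by mean after convergence; "up" is
  the larger-mean component, whatever EM's internal labelling did.
* **Degeneracy policy**: genes with fewer than 20 values, (near-)zero
  variance, a collapsed weight (< 0.01) or an underflowing component variance
  get a degenerate model whose posteriors are all 0.5. Maximal uncertainty
  keeps every pathway score defined instead of silently shrinking pathways.
  Posteriors are clipped to [1e−12, 1 − 1e−12] before products are taken.

Identifiability caveat: when the two components overlap heavily, the mixing
weight is only weakly identified at cohort-scale n; tests that assert tight
weight recovery therefore use well-separated components, and the weight is
compared against the *realised* component draw rather than the asymptotic
parameter (at n = 500 the realised mixing fraction itself has a standard
error of ~0.022).

## Pathway scoring

An interaction is active when its promoter inputs are up and its inhibitor
inputs are down; with independent per-gene posteriors the activity is the
product of `P(up)` over promoters and `1 − P(up)` over inhibitors. The
inhibitor complement is the natural probabilistic reading of "takes the
interaction type into account". Consistency compares activity with the
output genes' observed state: `a·q + (1−a)·(1−q)` with `q` the mean output
up-posterior, flipped for interactions marked as repressing their output
(a programmatic flag; the TSV dialect carries promoter/inhibitor/output roles
only). The verbal three-clause definition of consistency admits more than
one completion; the implemented bilinear form is one faithful reading and is
documented as such, not asserted to be the original tool's formula.

Pathway scores are arithmetic means over the pathway's scoreable
interactions. A mean (rather than sum or product) keeps scores in [0, 1] and
comparable across pathways of different size. Genes missing from the
expression matrix are dropped from their interactions; an interaction with
no surviving input is skipped; a pathway below 50% gene coverage
(`min_coverage`) is excluded and logged. The survival screen uses the
activity metric by default; consistency is computed, reported and screenable
via `metric="consistency"`.

## Survival screening

1-D features are split by **exact 2-means**: sort, evaluate all n−1
contiguous splits, minimize within-cluster sum of squares. This returns the
optimum that Lloyd-style K-means (K = 2) approximates, with no random
initialization; ties in WSS (relative 1e−9) go to the more balanced split.
Group 1 is the lower-mean cluster (better-prognosis convention in the
reported tables). Kaplan–Meier and the two-group log-rank test are
implemented in closed form and verified against lifelines to 1e−8 on random
censored data.

The screen applies **no multiple-testing correction** by design: robustness
is enforced by the cross-cohort intersection of significant sets, not by
within-cohort FWER/FDR control. A Benjamini–Hochberg option exists
(`correction="bh"`, off by default). Survival input must be explicit
`(time, event)` pairs; vital-status-only tables are out of scope.

## Genomic targeting

Alteration calls use strict thresholds: CNV log2 ratio > +0.3 (amplified) or
< −0.3 (deleted); methylation beta > 0.5 (methylated). The per-patient
pathway statistic is a hypergeometric tail; `patient_pathway_p` exposes two
conventions:

* **exclusive**, `P(X > x) = 1 − CDF(x)` — the printed-formula reading; it
  assigns p = 0 whenever x attains its maximum (such zeros are floored at
  1e−300 before the omnibus log, with a logged warning);
* **inclusive**, `P(X ≥ x)` — the statistically conventional tail.

`TargetingScan` defaults to the inclusive tail: the exclusive convention is
anti-conservative per patient (`E[−2 ln p] > 2` under the null because the
observed point's probability mass is excluded), and that excess accumulates
linearly in the patient count, so a Fisher statistic over hundreds of
patients would flag essentially every pathway under the null. With the
inclusive tail the per-patient p-values are sub-uniform and the omnibus test
is conservative-to-calibrated, which the null-calibration tests confirm.
The tested universe M is the intersection of the call matrix's genes with
genes mappable to any pathway; Bonferroni divides the family-wise alpha by
the number of pathways actually tested (those with at least one gene in the
universe).

## Group characterization

Per-gene amplification/deletion/methylation frequencies are reported per
survival group as percentages. Between-layer correlations (expression~CNV,
expression~methylation, methylation~CNV) and gene-pair co-expression are
Pearson by default — all layers are continuous and the phenomenon of
interest is linear co-movement — with Spearman behind a flag. A correlation
is called "present" in the cross-cohort consistency table at r ≥ 0.3 and
p < 0.05 (both configurable; the strength cutoff is a convention, not an
estimate).

## Synthetic cohort generator

The generator is first-class, tested code that emulates exactly the
structure the analysis assumes:

* **Latent driver state** `L ~ Bernoulli(1/2)` per sample; genes of one
  designated driver pathway follow `L` with probability `state_coupling`
  (0.9 by default), other genes mix with a per-gene random weight
  independent of `L` and of survival.
* **Per-cohort instability**: in each dataset an independent random
  `decouple_fraction` (0.3) of driver genes is severed from `L` and behaves
  like background. Under three cohorts the expected fraction of driver genes
  coupled everywhere is (1−0.3)³ ≈ 0.34, and each of those must additionally
  reach significance in all three screens — the designed mechanism that
  makes single genes non-robust while the pathway average, which pools all
  member genes, survives.
* **Expression**: down/up gamma components with means 5.0 / 6.8 and sd 1.5
  (log2-like scale). The modest separation is deliberate: a single gene's
  state call is noisy (the two modes overlap), while averaging ~60 member
  genes in the driver pathway's activity gives a clean per-sample signal —
  the single-gene-vs-network contrast arises from this, not from a tuned
  threshold.
* **Pathways**: 15 pathways over 200 genes; the driver pathway has 60
  member genes wired as a ring of single-promoter interactions (every gene
  enters the activity mean exactly once, with equal weight) plus a quarter
  as many two-input interactions, ~10% of which carry an inhibitor input.
  Background pathways (8–30 genes) draw from the non-driver gene pool.
* **Survival**: exponential with rate `hazard_base · hazard_ratio^L`
  (defaults 0.002/day and 3 — median ~1 year at baseline), censored
  uniformly on (0, `censor_max` = 8000 days), i.e. most deaths observed.
  Exponential-with-uniform-censoring is the simplest model under which the
  log-rank test is exactly calibrated.
* **Alterations**: CNV spikes of ±0.8 on N(0, 0.1) background and
  methylation spikes in (0.7, 0.95) on a Beta(1.5, 10) background, at rates
  0.25 (driver genes) vs 0.05 (background). Spikes always cross the call
  thresholds, separating threshold logic from noise modelling.
* **Determinism**: one `numpy` Generator seeded from the config; identical
  config ⇒ bit-identical cohorts.

What the generator does **not** emulate: platform/batch effects, probe-level
structure, correlated background genes, non-proportional hazards, or
clinical covariates. Passing tests therefore demonstrate that the pipeline
recovers the planted structure under its own model assumptions — not
performance on real microarray data.

### Problem sizes and statistical margins

Robustness runs use 20 cohorts of 3 datasets (n = 200/120/50 samples); null
calibrations use 1000 noise features, 2000 omnibus replicates and 50 null
cohorts. One inherent limit is worth stating: with 50 samples, a hazard
ratio of 3 and α = 0.05, the log-rank test's power is ~0.93 *even when the
two groups are the true latent states* — so requiring the driver pathway to
be recovered in ≥ 18/20 three-cohort runs sits close to the theoretical
ceiling, and the margin of the end-to-end robustness result is governed by
the smallest cohort's event count, not by the scoring machinery.

## Numerical choices

* Gamma log-pdfs and posterior odds computed in log space; `logaddexp` for
  mixture likelihoods.
* Hypergeometric tails via `scipy.stats.hypergeom.sf` (log-space internally;
  verified overflow-free at M = 20 000, K = 2 000).
* 2-means split via prefix sums (O(n log n) in the sort), with the balanced
  tie-break above.
* TSV writers emit `%.17g` / round-trip float parsing, so write-then-read
  reproduces doubles exactly.
* All stage outputs are pure functions of (inputs, config, seed).
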