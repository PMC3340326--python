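# Methods

## Model and procedure

`qtlgsa` tests a **competitive null hypothesis**: the genes of a set are no
more associated with the phenotype contrast than the background of all
measured genes. The chain of computations is:

1. **Gene-level statistic.** For each two-group comparison (high- vs
   low-phenotype strains) the statistic is the log2 fold change. With
   log2-scale inputs (RMA-style) this is the difference of group means,
   i.e. the log-ratio of geometric means; with `input_scale: linear` it is
   log2 of the ratio of linear-scale means. We default to the log2-scale
   reading because normalized array intensities are conventionally already
   on the log2 scale.
2. **Transformation.** Either none (signed statistics, detecting
   single-direction enrichment) or the absolute value (detecting
   bi-directional but coordinated change).
3. **Set statistic.** For a set with measured-member mean `x̄` and size
   `n`, `z = (x̄ − μ)/sqrt(σ²/n)` where `μ`, `σ` are the mean and
   **population** (divide-by-N) standard deviation of all measured genes'
   statistics. The population form is chosen because `μ`, `σ` act as
   background population parameters in the formula; with ≥ 10,000 genes
   the numerical difference from the sample SD is negligible, but fixing
   it makes exactness tests well-defined (the whole background as a set
   gives `z = 0` exactly). Backgrounds are computed per transformation:
   signed background for the signed tests, absolute background for the
   absolute test.
4. **Tails and direction variants.** Signed statistics are tested
   one-sided in each direction (upper tail → label **U**, lower → **D**);
   absolute statistics upper-tail only (**B**) — a *depressed* mean
   magnitude of change is not enrichment. P-values are standard-normal
   tail probabilities.
5. **Intersection significance.** With `Q` the union of genes overlapping
   any of the trait's QTL intervals, each retained pathway `G_i`
   contributes a sub-set `G_i ∩ Q`. Sub-set p-values are sorted ascending
   (ties broken by whole-pathway p, then set name, so ranks are
   deterministic) and rank `i` is flagged iff
   `P(G_i ∩ Q) < min{P(G_i), i·α/m}`. The criterion is applied **per
   rank** as displayed, not as a step-up over the largest passing rank;
   the discovery set is therefore always a subset of the plain
   Benjamini–Hochberg step-up rejections at the same α (a tested
   invariant).
6. **Combination across comparisons.** Per-pathway maximum p-values over
   the comparisons are fed through the same significance step, and a
   pathway is significant overall only if that passes **and** it is
   flagged in every individual comparison — the strictest reading of
   "common to all comparisons". Each variant (U/D/B) is a separate run of
   the procedure with the same `m`; a pathway significant in at least one
   variant is reported once, labelled by the passing variant with the
   smallest combined p (exact ties prefer a signed call over B, and U
   over D). For non-significant pathways the table reports the values of
   the most significant variant; `rank` and `critical_value` always refer
   to that variant's combined ranking.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `alpha` | 0.05 | target FDR of the experiment |
| `min_set_size` / `max_set_size` | 10 / 500 | bounds on *measured* pathway size (membership is intersected with the array universe first) |
| `min_intersection` | 10 | smallest sub-set `G_i ∩ Q` retained |
| `drop_categories` | `Human Diseases` | pathway categories excluded |
| `fallback_halfwidth_bp` | 20,000,000 | half-width of peak ± h intervals when flanking markers are unknown |
| `control_prefix` | `AFFX-` | array control probe sets removed |
| `modes` | U, D, B | direction variants run |

The `min_intersection` default of 10 mirrors the lower set-size bound: a
z statistic on the mean of fewer than ~10 absolute fold changes leans too
heavily on the central limit theorem (the mean of a handful of
half-normal-like values is visibly right-skewed, inflating small upper-tail
p-values), and reported real-data intersections do not go below 10.
Setting the knob to 1 keeps every non-empty sub-set; by default `m` counts
retained pathways after the drop (`count_dropped_in_m` switches to the
alternative reading).

Probe-level preprocessing: control-probe filtering, replicate averaging
(arithmetic mean per array group), then probe→gene collapse keeping, per
gene, the probe set with the **largest mean expression across all
samples** — the retained row is verbatim one measured probe profile, never
a per-sample mixture of probes; ties break to the lexicographically
smallest probe id.

Coordinates are 1-based fully closed throughout; a gene and an interval
overlap iff `gene.start ≤ qtl.end` and `gene.end ≥ qtl.start`, so
single-base touching counts (the inclusive, candidate-capturing choice).
Minus-strand annotation records (start > end) are canonicalized on read;
strand is not modeled because the overlap rule is strand-agnostic.
Intervals are not clamped at chromosome ends (chromosome sizes are not an
input) and are not merged — `Q` is a set union.

## Synthetic data

The generator emulates the *statistical* structure of a strain-comparison
microarray experiment with QTL annotations, at gene level:

- fixed-length 10 kb genes placed uniformly on equal-length chromosomes
  (19 × 100 Mb by default);
- QTL intervals as disjoint uniform segments covering a target fraction
  of each chromosome (default 30%, two segments per chromosome);
- log2 expression = per-gene baseline (normal, SD 2 around 8) + iid
  normal residual noise (SD 1) — **no gene–gene correlation by default**,
  so normal-theory set p-values are calibrated and FDR simulations are
  clean; an `equicorrelation` knob adds a shared per-sample factor to
  emulate the correlation that inflates false positives on real arrays;
- disjoint pathways (default 100 × 20 genes); a spiked pathway places a
  controlled fraction of its members inside QTL regions and shifts exactly
  those members in the high-phenotype group(s) by the effect size
  (upward, downward, or random sign per gene for B). The spike-in
  reference scenario is one 40-gene pathway with 20 in-QTL members
  carrying a 1.0 log2-unit shift against 3 vs 3 samples.

All randomness flows through one PCG64 generator
(`numpy.random.default_rng(seed)`), so a fixed seed reproduces a bundle
bit-for-bit on any platform.

What the generator does **not** emulate: probe-level noise models
(MAS5/RMA artifacts), gene–gene correlation beyond the optional
equicorrelated factor, linkage disequilibrium or realistic gene/QTL length
distributions, and intensity-dependent variance. Passing simulation tests
therefore demonstrate the procedure's behaviour under its own
distributional assumptions, not its performance on any particular real
array dataset.

## Simulation results computed by the test suite

- **Null FDR control** (also recomputed by `scripts/acceptance.py`): over
  200 global-null replicates at the default conditions, the
  single-direction procedure's mean false-discovery proportion stays at
  or below α = 0.05 within two Monte-Carlo standard errors.
- **Spike-in recovery**: over seeds 1–100 of the reference spike scenario
  the spiked pathway is recovered as significant in 98/100 runs, with the
  correct U label in 96/100 (pinned as regression values), and no
  unspiked pathway is discovered more often than the nominal rate.

## Numerical and design notes

- Problem sizes in the simulation harness (10,000 genes, 100 pathways,
  200/100 replicates) were chosen as the smallest sizes at which the
  normal-theory calibration and Monte-Carlo error bars are meaningful.
- The `two_sided` tail doubles the smaller tail and caps at 1.
- `z` recomputed from the stored `(x̄, μ, σ, n)` reproduces the stored
  value exactly; oracle tests require agreement with brute-force
  recomputation to 1e-12.
- Degenerate inputs: a zero-variance background and an empty
  member/universe intersection raise errors naming the set; an empty
  expression matrix after control filtering is allowed.
- A pathway wholly contained in `Q` has `P(G_i ∩ Q) = P(G_i)` and can
  never pass the strict sub-beats-whole comparison; this is inherent to
  the criterion (the method looks specifically for QTL-localized signal).
- Results files are versioned TSVs sorted by (max sub-set p, set name)
  with floats written in shortest round-tripping form, so identical
  config + inputs give byte-identical outputs.

## Known limitations

- **Variant multiplicity.** The three direction variants are three
  α-level procedures without cross-variant correction; under a global
  null the *union* of their discoveries can approach 3α (the U and D
  tails are nearly disjoint events). This mirrors the uncorrected
  multi-variant practice the method descends from; users wanting strict
  experiment-wise control should run a single variant or lower α.
- **Correlation.** The whole-pathway filter empirically removes many
  correlation-induced false positives but tests no explicit null for the
  sub-vs-whole comparison; no dependence structure among sets is
  estimated.
- Absolute-mode p-values for sets near the minimum size remain slightly
  anti-conservative in the extreme upper tail (CLT skewness), which is
  the main reason sub-sets below 10 genes are dropped by default.
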