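# Methods

## The model and its assumptions

The pipeline assumes already-normalised array methylation data: a
sample × probe matrix of β values in [0, 1] (fraction methylated) and
a manifest of probe coordinates. It does not model array chemistry,
probe-type bias, batch effects or raw IDAT processing; those belong to
an upstream normalisation step, and probe blacklists (cross-reactive
or SNP-confounded probes) are supplied by the user as a plain list.

Subgroup discovery treats methylation heterogeneity as approximately
low-rank: after the logit transform M = log2(β′/(1−β′)), the matrix is
assumed to decompose into a small number r of nonnegative "metagene"
programs whose per-sample weights separate the subgroups. NMF needs a
nonnegative input, while M-scores are signed, so a single global
affine shift (subtracting the matrix minimum) is applied; this
preserves all between-sample contrasts. An alternative — stacking the
positive and negative parts as separate features — was considered and
rejected as it doubles the feature space and changes the geometry the
reproducibility literature for this design assumes.

Region calling is deliberately rule-based rather than test-based: a
probe contributes to a region when its group-mean β difference Δβ
exceeds a threshold, and regions are maximal chains of such probes.
No kernel smoothing and no per-CpG p-values are computed, hence no
multiple-testing correction is applicable; specificity comes instead
from the stacked filters (effect size at the probe, the region, the
best sub-window, persistence across every pairwise subgroup
comparison, TSS proximity, and expression concordance). This makes
every call reproducible by exhaustive window enumeration, which the
test suite exploits.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `epsilon` | 0.001 | β clamp before the logit; keeps M finite at β ∈ {0, 1} |
| `top_n` | 10 000 | most-variable probes (sample SD, n−1 denominator) kept for clustering |
| `r_range`, `k_range` | 2..10 | metagene and cluster counts searched |
| `n_boot` | 250 | resamples per grid point for the stability score |
| `subsample_fraction` | 0.8 | resample size (without replacement) |
| `delta_threshold` | 0.2 | per-probe and per-region mean \|Δβ\| for region membership |
| `lambda_bp` | 1000 | maximum gap (bp) between consecutive CpGs of one region |
| `min_probes` | 2 | minimum CpGs per region |
| `max_change_threshold` | 0.3 | required mean \|Δβ\| of the best ≥2-CpG sub-window; also the persistence threshold |
| `tss_max_distance` | 20 000 | maximum bp from region to the nearest TSS (inclusive at the limit) |

Expression concordance uses subgroup **medians** with a strict
inequality (target above every other subgroup); medians are robust to
expression outliers, and means are available as an option. Region-to-
gene distance is measured from the region's endpoints (not midpoint)
to the TSS, strand ignored.

## Stability scoring and determinism

For each r the cohort matrix is factorised once in full and once per
resample; for each k, K-means (k-means++, 10 restarts) labels each
fit's W rows, and each resample's labels are matched to the full-data
reference restricted to the resample by the optimal label permutation
(Hungarian algorithm on the contingency table). The score at (r, k) is
the mean matched-agreement over resamples; the NMF fits are shared
across k because the factorisation does not depend on k. Ties on the
surface resolve to the smallest k, then the smallest r. Every seed is
derived from the master seed via `numpy` SeedSequence spawn keys, so a
run is bit-reproducible and grid cells are mutually independent. A
degenerate resample that covers the full cohort reuses the reference
fit's seeds, so self-agreement is exactly 1. The consensus matrix
reported with the solution is the pairwise co-clustering frequency
over resample re-fits at the chosen (r, k), conditioned on both
samples being drawn.

## The synthetic generator

`ssv_meth.synth.generate_dataset` emulates the features of array data
the analysis depends on, with ground truth:

- probe positions per chromosome from shifted-exponential gaps (mean
  `probe_spacing` = 1500 bp), reproducing CpG clustering and the long
  gaps that exercise the λ rule;
- a bimodal β baseline (unmethylated mode 0.10, methylated mode 0.85,
  equal weights), additive Gaussian noise (default sd 0.05), clamped
  to [0.001, 0.999] so M-scores stay finite;
- k latent subgroups (balanced, shuffled) separated by
  `n_background_dmrs` planted differential regions per subgroup
  (3–6 probes, β offset ≈ 0.5–0.6, alternating direction);
- `n_ssv_loci` planted SSV loci: 3–5 CpG promoter regions at β ≈ 0.10
  in the designated subgroup and ≈ 0.85 in all others, with the gene's
  TSS 0.2–2 kb upstream and log2 expression elevated by
  `expression_effect` (default 2.0, noise sd 0.5) in that subgroup
  only; optional control samples share the low-methylation/high-
  expression profile, mimicking normal tissue;
- within a planted region consecutive probes are 150–850 bp apart and
  the flanking gaps exceed 1.3 kb, so each planted region is exactly
  recoverable — and maximal — under the chaining rule.

Two placement rules are deliberate design choices. SSV loci occupy a
chromosome that carries no background regions, and decoy gene TSSs are
resampled until ≥ 25 kb from every planted region: background
differential regions are thereby modelled as *distal* (enhancer-like)
differences rather than promoter events. Without this, a background
region hypomethylated in the target subgroup next to a decoy promoter
would be statistically indistinguishable from a planted SSV locus —
the generator would be planting unlabeled positives. Relatedly, the
target subgroup's own background regions are hypermethylated-only.
Consequences for interpretation: recovery tests certify the pipeline's
filters against the stated data model, not against real tissue, where
promoter-proximal subgroup hypomethylation unrelated to expression
does occur and is removed only by the expression filter. The generator
also omits probe-type effects, batch structure, cellular-composition
gradients and correlated noise, so real-data performance is expected
to be noisier than the planted-data results.

Defaults (120 samples, 5 subgroups, 4000 probes on 4 chromosomes, 20
background regions per subgroup, 2 SSV loci, 200 decoy genes) give a
cohort at the scale of a typical tumour methylation study while
keeping a full run in seconds.

## Numerical choices and degenerate inputs

- β↔M round-trips to 1e−12 on (ε, 1−ε); values at the clamp are
  mapped to the boundary and not invertible, by construction.
- Probe-SD ties in `select_most_variable` break lexicographically by
  probe ID; surviving probes keep genomic order.
- In the caller, a chain breaks at a gap > λ **or** a sign change of
  Δβ; single qualifying probes are discarded (min 2 CpGs). The
  best-window scan prefers the leftmost, then shortest window on ties
  (1e−15 slack). All boundary comparisons are strict where the rule
  says "greater than" (Δβ > 0.2, window > 0.3) and inclusive where it
  says "up to" (gap ≤ 1000 bp, TSS ≤ 20 kb).
- Probes missing in more than 20% of samples are dropped before delta
  computation; within a group, missing values are excluded from the
  group mean, and probes with an empty group mean are dropped with a
  log record.
- Threshold monotonicity (relaxing `delta_threshold` never loses a
  called footprint) holds on direction-consistent data and is tested
  as such; with mixed signs, a newly qualifying opposite-sign probe
  between two members can legitimately split a chain.
- A gene with several qualifying regions is reported once with its
  closest region; candidate genes sort alphabetically.

## Test and verification scale

The test suite and the acceptance script run the recovery experiments
at 120 samples × 4000 probes with the stability grid restricted to
r, k ∈ 2..6 (covering the planted k ∈ {3, 4, 5}), 500 most-variable
probes and 25 resamples per grid point; these sizes were chosen as the
smallest at which the planted structure is comfortably in the regime
the defaults target, and all of them are ordinary function arguments
at real-data scale. The region caller is verified exactly against an
independent brute-force enumerator on hundreds of randomised ≤50-probe
fixtures.

## Known limitations

- The subgrouping clusters NMF sample weights (rows of W); clustering
  consensus matrices or H-projections are plausible alternatives that
  are not implemented.
- Resampling is without replacement; a with-replacement bootstrap
  would need duplicate-sample handling in the label matching.
- The caller applies the Δβ threshold at both the probe and the
  region level (the region check is implied by the probe check when
  signs are consistent); smoothed-estimate variants are out of scope.
- No survival, pathway or drug-target annotation of candidates.
- Auto-selection of the target subgroup (most persistent
  subgroup-specific regions, either direction) is an interpretation;
  when in doubt, fix the target explicitly.
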