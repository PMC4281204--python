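# Methods

This note states the exact definitions and algorithmic choices implemented in
`focalcna`. Coordinates are 0-based half-open base pairs internally; tabular
outputs can be switched to 1-based inclusive display (`output.one_based`).

## Copy-number segmentation

**Median normalization.** Each sample's probe-level log2ratio profile is
shifted so its median (over non-missing probes) is 0.

**Circular binary segmentation.** Per chromosome, the changepoint statistic
for an arc `[i, j)` of width `k` inside a segment of `n` probes with
mean-centred partial sums `S` is

```
U(i, j) = |S_j − S_i| / sqrt(k (n − k) / n),
```

the circular two-sample t statistic up to a constant noise scale. The
maximizing arc is found by exhaustive search over all pairs when `n ≤ 130`;
for longer segments the search runs over all widths 3–32 plus a geometric
width grid (ratio 1.3) and the winning boundaries are refined by a local
exhaustive search over widths within one grid ratio. Significance comes from a
permutation test on the same width grid: the profile segment is permuted, and
the split is accepted when the estimated p-value `(1 + exceedances) /
(1 + permutations)` is below `alpha` (default 0.01). Permutations are drawn in
growing batches with sequential early stopping — accept after
`ceil(1/alpha) + 1` permutations with zero exceedances, reject as soon as
exceedances reach `floor(alpha · n_perm) + 1` (default `n_perm` 1000).
Accepted boundaries closer than `min_width` (3) probes to a segment edge are
clamped to the edge. Segmentation recurses on the resulting pieces; finally,
adjacent segments whose means differ by less than `merge_tol` (0.05) are
remerged. Missing probes are excluded from the statistic and inherit the
segment of the preceding probe. Segments tile each chromosome exactly.

**Mode normalization.** Segment means are summarized by a probe-count-weighted
Gaussian kernel density (bandwidth 0.05 log2 units); the highest peak, with
parabolic sub-grid refinement, is taken as the diploid level and subtracted.
When two peaks tie in height, the one closer to 0 wins (the least aberrant
level is the safer diploid guess).

**Calling.** Segment means ≤ −0.2 are losses, ≥ +0.2 gains (inclusive),
otherwise neutral.

## Focal aberrations, germline filters, HFRs

Adjacent same-direction non-neutral segments merge into one aberration. An
aberration is **focal** when its size is ≤ 3,000,000 bp (inclusive).

An aberration is **recurrent** when its single-linkage overlap cluster (≥ 1 bp
overlap, same direction) contains focal aberrations from at least 2 distinct
samples. The **filter ledger** counts recurrent focal aberrations before
filtering, then removals among them:

* **Catalog filter:** a focal aberration is removed when the union of
  germline-CNV catalog intervals covers ≥ 50% of its length (a 1 bp rule would
  delete aberrations merely touching a common CNV).
* **Bidirectional filter:** focal aberrations of both directions are pooled
  and clustered by overlap; a cluster is removed in full when it has focal
  gains from ≥ 2 distinct samples *and* focal losses from ≥ 2 distinct
  samples — somatic selection is directional, so mixed recurrent loci behave
  like inherited polymorphisms missing from the catalog.

The identity `retained = observed − removed_catalog − removed_bidirectional`
is enforced structurally; inconsistent counts raise.

**High-frequency regions.** Per direction, surviving focal aberrations are
clustered by single-linkage overlap. Within a cluster, each sample's intervals
are unioned (a sample never counts twice), per-base depth of distinct-sample
coverage is computed, and the HFR is the leftmost maximal contiguous run at
the maximum depth; clusters whose maximum depth is below 2 yield no HFR. The
HFR's `focal_count` is that depth; its `total_count` is the number of distinct
samples having *any* same-direction aberration (focal or broad) that fully
contains the HFR. Genes overlap an HFR at ≥ 1 bp.

## Expression integration

Expression matrices are linear-scale intensities (genes × samples). Default
normalization computes per-tumor `M = log2(tumor) − log2(mean reference)`,
removes the intensity-dependent trend of `M` on the average intensity `A` by
LOESS (span 0.3), quantile-normalizes the per-sample `M` distributions, and
takes `FC = 2^M`; a raw mode (`normalize_first: false`) uses plain intensity
ratios against the mean reference. Multi-probe genes collapse to the probe
with the highest mean intensity. Genes requested but absent from a platform
are reported as `no_information`, never silently dropped.

A tumor is concordant for a loss-HFR gene when `FC ≤ 0.75` and for a gain-HFR
gene when `FC ≥ 1.5` (inclusive; a strict mode exists). A gene is a
**candidate driver** when concordant in ≥ 35% of *all* tumors in the set (not
only copy-number carriers). Validation applies the same rule to an independent
set: `confirmed`, `not_confirmed`, or `no_information` when the validation
platform lacks a probe.

## Statistics

**Census enrichment.** Upper-tail hypergeometric probability of the observed
overlap between the HFR gene set and a curated driver census intersected with
the analysis universe, optionally cross-checked by seeded random same-size
draws with the (+1)/(+1) permutation p-value estimator.

**Cohort comparison.** Two call sets are remapped onto the intersection tiling
of their segment boundaries (restricted to jointly covered ranges); per bin,
per-sample ordinal scores (loss = −1, neutral = 0, gain = +1) are compared by
the two-sided rank-sum test with tie correction (or its seeded permutation
version), and Benjamini–Hochberg q-values control the FDR across bins. Bins
where every sample of both cohorts ties get p = 1.

## Synthetic cohort

The generator plants, per sample: broad q-arm gains/losses (probability 0.3
per arm), one focal driver aberration per planted driver gene with carrier
probability 0.6 (each driver is guaranteed ≥ 2 carriers), germline CNV events
at 10 fixed polymorphic loci (carrier probability 0.6; catalogued loci are
unidirectional per locus, uncatalogued loci draw gain or loss per sample —
exactly the signature the bidirectional filter targets), and Poisson(2)
random focal passengers. Gains add +0.58 and losses −1.0 to the log2ratio
(one-copy changes at typical tumor purity); probe noise is N(0, 0.15).
Expression couples only driver genes to copy number: carriers' linear
intensities are multiplied by 0.5 (losses) or 2.0 (gains) over a log-normal
baseline with N(0, 0.25) log2 noise. Driver genes are placed on p-arms ≥ 4 Mb
apart and ≥ 2 Mb clear of polymorphic loci so planted signals are
unambiguous. All generation flows from one master seed via fixed-derivation
child seeds (31-bit), making every run reproducible byte for byte.
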