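# Methods

## Model and procedure

The pipeline treats two data modalities with a shared question — is X
chromatin structurally distinct from autosomal chromatin in males and in
females?

**Shearing-coverage side.** Sonicated chromatin breaks preferentially in
open regions, so the density of uniquely mapped fragment-end reads is a
structural readout. Reads are modeled as independent draws from a per-base
propensity distribution; no fragment-pair structure is simulated because
only densities are analyzed downstream. Coverage is normalized as average
depth per base, per kb of region, per million sequenced base pairs, so
samples of slightly different sequencing depth are comparable; the formula
divides the region's summed depth before any window averaging and is
applied identically to 1 kb windows and to gene features. Whether an arm's
coverage distribution differs from the genome is decided by permutation KS
testing: 100 permutations, each drawing 1000 values per arm (200 for the
dot chromosome, which has far fewer windows) and equally many from the
genome pool. The genome pool deliberately includes the tested arm (an
`exclude_self` flag is provided), and sampling is without replacement (a
`replace` flag provides the weaker reading). The male X coverage of gene
features can be multiplied by 2 to correct for the single-copy X; the
correction is exposed as a flag and applied at the feature level.

**ChIP-chip side.** The analyzed quantity is the log2 ChIP/input ratio per
gene. The normalization chain runs: median-centering of per-array ratios;
quantile normalization of the input channel across arrays with the ChIP
channel reconstructed as normalized input + centered ratio (preserving
every element's centered ratio exactly — the only reading under which the
normalization is "based on the input channel"); background correction
against the mean intensities of non-genomic control elements, per channel
(elements below background in *both* channels are excluded, the control
mean is subtracted on the linear scale, and non-positive intensities become
missing rather than clamped, to avoid fabricating ratios); duplicate probes
merged by available-case mean; replicates averaged per sample. The order
follows the procedure's natural reading (centering before background
correction); a `background_first` switch exists for sensitivity analysis,
and the element-exclusion rule uses per-channel control means (the pooled
reading is obtainable through the same switch mechanism).

Enrichment statistics: "N-fold higher" is defined as the ratio of
linear-scale geometric means, `2^(Δ mean log2 ratio)` — self-consistent
with log-scale handling and exactly invertible, which is what makes planted
folds recoverable. The dot chromosome counts as an autosome in "all
autosomes" (both with- and without-dot folds are reported). Percentile
ranks use Hazen plotting positions `(rank − 0.5)/n` with mean ranks for
ties; the >90% / <10% cuts are strict, so boundary ties join neither class
and 100 distinct values yield exactly 10 + 10. K-means uses k = 2 on
within-sample percentile ranks, Euclidean distance, 10 k-means++ restarts
under a fixed seed; the cluster with the higher mean rank is labeled
"enriched-like", making output orientation deterministic. Clustering
correctness is defined at the label level on well-separated data, not as
bit-identity with any particular desktop implementation, since k-means
initialization schemes differ between tools.

## Synthetic-data generator

The generator is first-class, tested code and fixes the conditions every
verification runs under:

* **Karyotype**: five major arms near 20% of the genome each and a dot arm
  under 1%; male X copy number 1, everything else 2.
* **Reads**: per-base propensity = copy number × arm openness × exon boost ×
  TSS/TTS boosts within ±3000 bp. Default openness (X 1.2, major 1.0, dot
  0.45) reproduces the observed pattern of an open X and a
  shearing-resistant dot chromosome.
* **Arrays**: per gene and sex, true ratio = X shift (X genes) + gene
  effect; gene effects across sexes are bivariate normal with latent
  Pearson correlation `2 sin(π ρ_S / 6)`, the closed form that makes a
  Spearman target exactly plantable. Observed ratios add a per-array bias
  (N(0, 0.15²) log2) and element noise; input intensities scale with
  arm-class openness around a log2 base of 12; control elements sit at a
  low background (log2 ≈ 6) independent of genes; 10% of genes are spotted
  twice. `reference_effects(mark)` plants the reference effect sizes: X folds
  1.39/1.06 (H4K16ac male/female), 1.09/1.02 (H3S10ph), cross-sex X
  Spearman targets 0.46/0.68/0.92, and enriched-vs-depleted expression
  folds 2.68/3.77 for H4K16ac. The H3K4me2 X folds (1.15/1.10) and the
  non-H4K16ac expression folds (2.0) are this package's own choices where
  no reference magnitude exists. Replicate structure: 4♂/3♀ for
  H4K16ac, 2/2 for the other marks.
* **Expression**: log2 expression = baseline + slope × ratio + noise, with
  the slope calibrated on the decile classes of the *measured* ratio matrix
  so the planted enriched-vs-depleted fold is exact in the noise-free
  limit. Sex-bias labels are assigned by exponential tilting toward
  low-ratio genes (strength 0.8 ≈ a 0.4 log2 depletion at the defaults),
  planting the depletion of the mark at sex-biased genes.

**Noise magnitudes** are not dictated by any external source; they are
package defaults chosen once so that planted effects are recoverable at
n = 10,000 genes, and exposed in `EffectConfig` rather than asserted as
biological truth. Element noise is 0.06 log2 sd and the gene-effect sd is
0.5: with 2 replicates and 10% duplicates this attenuates a planted
cross-sex Spearman of 0.92 by about 0.006–0.012, inside the ±0.02 recovery
band, while the X-fold recovery error is dominated by the gene-effect
sampling term (sd ≈ 0.011 on a 1.39 fold at 2000 X genes).

What the generator does **not** emulate: sequence content (no FASTQ bases,
no mappability or GC structure), dye effects (the assayed platform's
end-labeling shows none), spatial array artifacts, isoform structure (one
transcript per gene, as on a 3'-biased amplicon platform), and
heterochromatin assembly gaps. Passing tests therefore demonstrate that the
analysis recovers planted effects through realistic replicate/bias/noise
structure — not that it is robust to mappability artifacts or probe-level
sequence biases absent from the generator.

## Numerical choices

* Coordinates are 0-based half-open everywhere; GFF3 is converted at the
  parse boundary. The TTS anchor of a + strand gene is the half-open
  `tx_end`, mirrored for − strand, chosen for symmetry with the TSS.
* Depth counts full 35 bp read bodies, unstranded. Trailing partial windows
  are dropped rather than rescaled so window-value distributions are
  comparable across arms. Meta-profile windows (width = region/10) are
  centered at 100 evenly spaced positions from `start + w/2` to
  `end − w/2`; genes with regions shorter than 100 bp are skipped and
  counted.
* The asymptotic two-sample KS P value is used throughout (sample sizes are
  ≥ 200 in every configured use). The two-sample KS statistic at
  n = m = 1000 is lattice-valued, which makes its P value granular at the
  ~0.04 level near the median; uniformity checks of permutation P values
  are therefore performed on independent subsamples (one P per arm per
  seeded run) at sample sizes where that granularity is far inside the
  test's critical band, rather than on thousands of pooled, mutually
  dependent P values, where any correct implementation would be rejected
  for granularity alone.
* Quantile normalization uses the mean of the arrays' quantile functions on
  plotting positions `(k − 0.5)/n` as reference; on complete equal-length
  columns this reduces exactly to the mean of order statistics, ties
  receive the mean of their tied reference quantiles, and missing entries
  neither consume quantiles nor get imputed.
* Genes whose elements are all missing after background correction stay
  missing; the cross-sample gene universe is the intersection of genes
  surviving normalization in all compared samples; k-means drops incomplete
  rank rows (counted) rather than imputing.
* Degenerate inputs are contracts, not crashes: intronless genes yield
  missing intron coverage (never zero), constant ratio vectors yield empty
  enrichment classes, identical rank rows yield a flagged degenerate
  clustering with one populated cluster.

## Pipeline and problem sizes

The CLI orchestrates simulate → coverage → permtest and chipnorm → enrich →
cluster from one YAML config; every stochastic stage derives its seed from
the master seed, outputs carry a config-hash provenance header, and reruns
are byte-identical. Because the linked expression table is generated from
the *normalized* ratio matrix, expression simulation runs inside the enrich
stage.

Default verification scales, chosen as the package's working sizes: a
~5 Mb toy genome for read-level checks (3 × 10⁵ reads gives the male
X/autosome density ratio 0.50 ± 0.01), a 10,000-gene genome for array-level
parameter recovery, and 20 seeded runs × 6 arms × 100 permutations for null
calibration of the permutation KS machinery.

## Known limitations

* One transcript per gene; no isoform collapse rules are modeled.
* No mappability, GC, or heterochromatin masking on the coverage side, so
  absolute coverage levels are idealized.
* The background-correction subtraction slightly perturbs log ratios at
  finite intensity-to-background ratios (≈ +0.01 log2 on a 0.47 log2 shift
  at the default 64:1 separation); this is a property of the procedure
  itself, not of the implementation, and is visible in recovery tests as a
  small upward bias well inside the stated tolerances.
* The permutation test's genome pool contains the tested arm, so the KS
  statistic saturates below 1 for extreme shifts (the P value, not D, is
  the off-scale quantity).
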