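# Methods

## Model and procedure

The pipeline treats a cross-species aging transcriptome study as five
stages, each a deterministic function of its inputs:

1. **Per-array Z normalization.**  Each array's intensities are
   natural-log transformed and standardized over its genes:
   z = (ln x − mean)/SD, with the sample SD (n−1 denominator, used
   consistently throughout the package).  The per-array mean and SD are
   retained as metadata, so the transform is invertible.  Because a
   multiplicative array scale factor becomes an additive ln-scale offset,
   the centering removes it exactly; no cross-array scaling model is
   assumed.  Arrays with zero ln-scale SD (constant arrays) and
   nonpositive intensities are hard errors naming the offending
   gene/sample.

2. **Z-ratio contrasts.**  For age groups A vs B (B the reference), the
   per-gene difference of group-mean z-scores is standardized by the SD of
   those differences *across genes*, computed once per contrast.  The
   printed formula this implements does not say which SD divides the
   difference; the across-genes SD of differences is the established
   reading in the DIANE family of tools and makes the statistic
   self-calibrating (unit spread under the null).  The per-gene SD
   alternative remains an open interpretation; it is not implemented.
   Contrasts are defined against young (middle vs young, old vs young).
   Gene-level p-values default to a two-sided standard-normal test on the
   Z-ratio; a per-gene Welch t-test on z-scores is selectable
   (`method="t-test"`), since the original analysis does not state its
   gene-level test.  The significance filter is |Zratio| > 1.5 AND
   p < 0.05 AND mean raw intensity > 0, all strict, all configurable.

3. **PAGE enrichment.**  Gene scores entering PAGE are the contrast's
   Z-ratios (the per-gene score is the one genuinely open choice here; the
   Z-ratio is the natural candidate because it is the statistic the gene
   filter uses).  Sets are first restricted to symbols present on the
   array; sets with fewer than `min_set_size` (default 5) present members
   are dropped and reported — the normal approximation behind the p-value
   degrades for tiny m.  δ uses the sample SD.  P-values are two-sided;
   both up- and downregulated calls are made, at α = 0.05 with no
   multiple-testing correction by default and Benjamini–Hochberg by flag.

4. **Cross-species intersection.**  Pathway identity across species is by
   set *name*: one collection scored per species.  No ortholog mapping of
   member symbols is performed; symbols are case-folded (upper-cased) once
   at input so mouse/human casing differences cannot split a gene.  A
   pathway is conserved in a direction when every species calls it at the
   configured threshold in the primary contrast (old vs young); requiring
   consistency in the middle-age contrast as well is an option
   (`require_both_contrasts`).  Venn regions are computed exactly for 2–4
   species; a species missing a call list is a hard error rather than an
   empty set, because silently skipping one would silently change what
   "all species" means.

5. **Ordination.**  PCA of samples is computed per species (not pooled) in
   two spaces: gene-z space, and pathway-activity space where
   activity(set, sample) is the mean z of the set's present members in
   that sample — the single-sample analog of the PAGE mean member score,
   chosen as the simplest statistic consistent with stage 3.  PCA is
   gene-wise centering followed by SVD; component signs are fixed by
   making the largest-magnitude loading positive, so outputs are
   reproducible.  Group separation is summarized by the mean silhouette
   (Euclidean) of the age groups in the leading components.

## Synthetic cohorts

The generator emulates the study design: four species (mouse, rat,
monkey, human) with group sizes 5/5/5, 5/5/5, 6/6/6 and 5/4/7
(young/middle/old), a 2,000-gene universe and a 60-set collection by
default.  ln intensity = gene baseline + array scale offset + planted
shift + noise, exponentiated to strictly positive intensities.  Defaults:
baseline mean 5.0 ln units (raw ≈ 150), gene baseline SD 1.0, residual
noise SD 0.3, array scale SD 0.2 — ln-scale spreads in the range typical
of bead-array intensity data, with array-to-array scale variation large
enough that skipping normalization visibly corrupts contrasts.  Planted
effects shift the member genes of named sets additively on the ln scale
(default recovery scenario: 1.0 in old, 0.5 in middle, signed by
direction), either in all species (conserved) or in a listed subset.
Each species has its own RNG stream derived from the master seed by
hashing the species label, so adding a species never perturbs the others.
A JSON ground-truth ledger records exactly what was planted, per
(species, contrast, set).

What the simulator does *not* emulate: probe-level artifacts (background,
bead summarization), correlated gene-gene expression beyond set-level
shifts, ortholog divergence between species (all species share one
symbol universe), and sample-level covariates.  Passing recovery tests
therefore shows the analysis chain is correct and well calibrated under
its own assumptions — not that it is robust to platform-specific noise
structure in real arrays.

One realistic behaviour the simulator does reproduce: gene sets are drawn
independently and overlap, so a nominally null set sharing members with a
planted set inherits part of its signal *in every species*, occasionally
producing a correlated conserved false call at α = 0.05.  This is a
property of overlapping collections, not a defect of the statistic; the
multi-seed recovery rate (≈ 0.95 exact recovery across seeds) reflects
it, and BH correction or a stricter α suppresses it.

## Numerical choices

- Sample SD (n−1) in every SD: normalization, Z-ratio denominator, PAGE δ.
- Strict inequalities in the gene filter, matching its printed form.
- z-score columns are standardized to |mean| < 1e-9 and |SD−1| < 1e-9 by
  construction; scale invariance holds to 1e-12.
- PCA reconstruction with all components is exact to 1e-9; explained
  variance fractions are nonincreasing and sum to ≤ 1.
- Degenerate inputs fail loudly: constant arrays, zero-spread contrasts,
  zero-spread gene scores, empty collection/array overlap, missing
  species call lists.
- Duplicate probes: the validated containers and readers reject duplicate
  case-folded symbols; probe-level input can be collapsed to one row per
  symbol by averaging z-scores (`znorm.collapse_duplicate_symbols`)
  before container construction.

## Problem sizes in the test and acceptance runs

Unit and property tests use scaled-down universes (50–500 genes, 5–30
sets) where oracles are cheap.  The end-to-end recovery experiments use
the full study shape — four species at study group sizes, 2,000 genes,
60 sets, two conserved-down sets (ln shift 1.0) plus six species-specific
decoys — over 20 seeds; the power-monotonicity sweep uses 1,000 genes and
30 sets over 50 seeds per shift level; null calibration of the PAGE
statistic uses 10,000 random size-20 sets on 2,000 null scores; the
ordination contrast uses 500-gene cohorts with six sets planted at
ln shift 1.5 (old) / 0.75 (middle) against paired null cohorts.  These
sizes give the experiments the statistical resolution the assertions
need while keeping a full run in the tens of seconds.

## Known limitations

- The Z-ratio-as-PAGE-input choice and the across-genes SD reading are
  documented interpretations of an underspecified published procedure;
  both are stated above and isolated behind small functions.
- Conserved calls intersect binary significance decisions; no
  cross-species meta-analysis of effect sizes (e.g. Stouffer combination)
  is performed, by design.
- The normal-theory PAGE p-value ignores inter-gene correlation within
  sets; on real data (correlated members) it is anticonservative, which
  is one reason the conserved-in-all-species requirement, not any single
  p-value, carries the inference.
- `avg intensity > 0` is applied on the raw intensity scale; with
  strictly positive input it only bites when a background-subtracted
  matrix is supplied.
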