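# Methods

This note documents the models, conventions and design choices behind
`imgtx`: what each stage computes, which constants matter, what the
synthetic generators do and do not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer from the code.

## Scope and data model

The package implements a transcriptome–neuroimaging association analysis
for case–control resting-state fMRI: voxel-wise local-activity metrics
(ReHo, ALFF, fALFF), a two-group contrast with cluster-level family-wise
error (FWE) control, processing of donor microarray expression into a
normalized sample × gene matrix, gene-wise spatial correlation between
expression and the group-difference t-map, and the accompanying clinical
statistics.  All spatial data live on a voxel grid with a 4×4 affine to
MNI millimetres; inputs are assumed co-registered (no realignment,
slice-timing or spatial normalization is performed here).

## Preprocessing

Order: discard initial volumes (default 10) → single-pass ordinary
least-squares nuisance regression → Fourier bandpass.

* **Nuisance design.** Intercept, linear drift, the Friston-24 motion
  expansion (6 parameters, 1-volume lag, both squared), one indicator
  column per spike volume, and mean white-matter/CSF series.  Detrending
  is the drift column, so the bandpass cannot reintroduce drift.
  Rank-deficient designs are repaired by dropping dependent columns
  (QR with pivoting), with a warning.
* **Frame-wise displacement.** Power's convention: FD(i) = Σ|Δtrans| +
  50 mm · Σ|Δrot|; FD(1) = 0.  Spikes are volumes with FD strictly above
  0.5 mm and are regressed, not deleted.  The 50-mm radius is the
  de-facto standard that the 0.5-mm threshold presumes.
* **Bandpass.** Hard masking of rFFT bins with `low ≤ f ≤ high` (DC
  removed), defaults 0.01–0.1 Hz.  Hard cutoffs are exactly
  characterizable in tests (tones at bin centres pass or vanish
  identically) and idempotent.

## Local-activity metrics

* **ReHo** is Kendall's coefficient of concordance W between a voxel and
  its 26 neighbours, W = 12 S / (K²(n³ − n)) with S the variance of
  rank sums over time.  Ties get average ranks; no tie-correction term is
  applied (ties have measure zero in float data).  Any constant series in
  a neighbourhood makes W undefined there; the voxel is set to 0 and
  flagged in the log.  Edge voxels use the available in-mask neighbours
  (K < 27) so map support equals the mask.  ReHo expects band-limited
  input.
* **ALFF / fALFF.** The amplitude convention is `a_k = 2|X_k|/n` for the
  one-sided rFFT, so a pure tone of amplitude A at an exact bin has
  a_k = A.  ALFF is the mean a_k over bins with 0.01 ≤ f ≤ 0.1 Hz
  (DC excluded, band edges inclusive to match the bandpass); fALFF is the
  in-band amplitude sum over the total non-DC sum.  Both are computed on
  data that is regressed and detrended but **not** bandpassed — a
  bandpassed input would make fALFF identically 1.  ReHo, by contrast, is
  computed after bandpassing.
* **Standardization and smoothing.** Each map is divided by its in-mask
  global mean (mReHo/mALFF/mfALFF) and then smoothed with a 6-mm-FWHM
  Gaussian (σ = FWHM/2√(2 ln 2) per axis, converted to voxels through the
  affine); smoothing is deliberately the last step.

## Group inference

Voxel-wise pooled-variance two-sample t (df = n₁+n₂−2; zero-variance
voxels get t = 0).  Cluster inference replaces parametric random-field
correction with a permutation scheme, which is calibratable by
simulation: voxels two-sided supra-threshold at the cluster-defining
p (default 0.001) are grouped by 26-connectivity (matching the 27-voxel
ReHo neighbourhood), each sign separately; the null distribution of the
maximum cluster size over both signs is built from relabelled group
assignments (exhaustive when C(n, n₁) ≤ n_perm, otherwise n_perm random
assignments with the observed labelling included); each cluster's FWE p
is the fraction of null maxima at least its size.  The discreteness of
cluster sizes makes the test mildly conservative, which the calibration
test tolerates (binomial interval around the nominal 0.05).  Effect sizes
are Cohen's d on cluster-mean values with df-weighted pooled SD.

## Expression processing

Fixed order: intensity filter → probe selection → sample restriction →
normalization → differential-stability (DS) filter.

* **Intensity filter**: keep probes above background in ≥ 50% of samples,
  donors pooled; the exact-50% probe is retained.
* **Probe selection**: per gene (restricted to genes present on both
  platforms), probes are correlated with the RNA-seq reference over
  pooled (donor, structure) mean profiles; probes with r < 0.2 (or
  undefined r) are excluded and the best survivor is chosen.  Matching on
  structure labels within donor is this package's concretization — the
  upstream pipelines do not publish a sample-level matching rule.
* **Sample restriction**: left hemisphere AND cortical label AND
  gray-matter mask value > 0 at the nearest voxel; out-of-volume
  coordinates are dropped and counted in the log.
* **SRS normalization**: x ↦ 1/(1+exp(−(x−median)/(IQR/1.35))) followed
  by min–max rescaling to [0, 1]; applied per donor, within-sample across
  genes and then within-gene across samples.  1.35 is the
  normal-consistency constant for the IQR.  The transform is strictly
  monotone (rank-preserving); zero-IQR vectors map to constant 0.5.
* **DS**: per gene, expression is averaged within structure per donor;
  DS is the mean over donor pairs (≥ 3 shared structures) of the Spearman
  correlation between structure-mean vectors.  The regional unit is the
  bundle's structure label — no ontology mapping is attempted.  The top
  50% of genes by DS are retained, ties at the cut included.

## Spatial association

Each tissue sample receives the mean of the **uncorrected** t-map over
in-mask voxels whose centre lies within 3 mm of its MNI coordinate
(centre-within-radius is the exactly testable voxel-in-sphere rule;
samples with empty spheres are excluded).  Gene-wise Pearson correlations
with two-sided p are Bonferroni-thresholded at α/n_genes, and the final
set is the intersection of significant genes with the risk list (symbols
upper-cased).  The p-values treat samples as independent; spatial
autocorrelation of both maps and expression makes them optimistic, and no
spin-test or generative null is applied — deliberately, since the
emulated analysis does not use one.

## Clinical statistics

Shapiro–Wilk gate at α = 0.05 per group (the gate's alpha is this
package's choice): both normal → pooled t-test, else Mann–Whitney U;
constant samples count as non-normal.  Sex tables use Pearson chi-square
without continuity correction.  ROI–clinical correlations use Pearson
(both variables normal) or Spearman, flagged uncorrected at 0.05 and
corrected at 0.05/7.  The sensitivity model is OLS
`roi ~ group + covariates` with a single-df F (= t²) for the group term;
collinear covariates are dropped with a warning.  Missing values are
removed pairwise and each result reports its n and chosen test.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
pipeline assumes, and ground truth for recovery tests.

* **Cohort.** Voxel noise is AR(1) (φ = 0.3).  Each subject carries 12
  shared latent components with spatially smooth loadings normalized to
  unit norm per voxel, scaled by a subject-level amplitude
  0.5·(1 + 0.35·tanh z): local temporal coherence is therefore roughly
  uniform in space while its level varies across subjects — the baseline
  variability that global-mean standardization removes.  The amplitude
  spread is bounded (tanh, not lognormal) so that small-sample SD
  estimates of subject-level summaries, and hence empirical effect
  sizes, are stable.  A single global
  component was rejected during design: being rank-1 in time it is
  annihilated by WM/CSF mean regression, which would leave the data with
  no post-preprocessing coherence at all.  With several
  spatially-varying components, nuisance regression removes only a small
  subspace, as in real data.  Motion traces are smoothed random walks
  (median FD ≈ 0.1 mm) with occasional spikes, coupled into the signal
  through per-voxel random loadings; a per-voxel linear drift and a
  baseline of 1000 complete the signal model.  Tissue geometry is
  deliberately schematic (superellipsoid brain, small central CSF core,
  WM shell, GM remainder): realistic cortical geometry is out of scope,
  so spatial statements in tests are about masks, not anatomy.
* **Planted effect.** In one group, all voxels of a sphere share an extra
  latent series with mixing weight w.  The weight for a requested
  Cohen's d (of the group difference in subject-level mean in-sphere
  ReHo, computed on bandpass-filtered volumes) comes from a frozen pilot
  calibration: 120 subjects per weight on a 20³ grid of 3-mm voxels,
  240 volumes, 7.5-mm sphere; the fitted response
  d(w) = 10.68·w²/(3.00 + w²) is inverted onto an interpolation table.
  The contract is condition-dependent — at materially shorter scans the
  realized d drops because sampling noise enters the between-subject
  variance — so the calibration conditions are also the conditions of
  the recovery simulations.  Requested d beyond 2.5 exceeds the
  calibrated range and raises.
* **Expression bundle.** Sample coordinates are drawn uniformly from
  left-hemisphere (x < 0) in-mask voxel centres; small fractions of
  mirrored right-hemisphere and central "subcortical" decoy samples
  exercise the restriction stage.  Cortical structure labels come from a
  deterministic (y, z)-quantile parcellation, so structure profiles are
  comparable across donors.  Tracking genes follow
  r·z(target) + √(1−r²)·noise at the sample's nearest target-map voxel.
  Each gene's designated best probe carries the gene signal with small
  noise; decoy probes are either below background (caught by the
  intensity filter) or spatially uncorrelated with the RNA-seq reference
  (losing the probe-selection contest) — decoys never share the gene's
  sample-level noise, so the correct probe wins deterministically and
  recovery is exact by construction.  Gene baselines are floored so that
  designated best probes always survive the background filter.  The
  RNA-seq reference is the per-(donor, structure) mean gene signal plus
  noise; a small fraction of non-tracking genes is dropped from the
  RNA-seq platform to exercise the overlap rule.  Non-tracking genes are
  spatially unstructured; real transcriptomes have pervasive spatial
  autocorrelation, so passing recovery tests here demonstrates pipeline
  correctness, not robustness to correlated nulls.
* **Clinical table.** Gaussian scores with means/SDs plausible for an
  episodic-migraine cohort; the designated anxiety scale is shifted
  between groups by the requested number of pooled SDs, all other scores
  are exchangeable between groups.

## Simulation sizes

The test suite and `scripts/acceptance.py` run the statistical checks at
sizes chosen to make their expected sampling error small relative to the
asserted tolerances: 50 null cohorts (10+10 subjects, 16³ grid, 60
volumes, 200 permutations) for FWE calibration; 10 cohorts (15+15, 20³,
250 volumes) for planted-cluster recovery; 10 planted and 50 null bundles
(5013 genes, ~400 retained samples) for gene recovery; the acceptance
script uses the same conditions at reduced repetition counts and reports
the repetition count alongside each value.

## Known limitations

* The permutation FWE is conservative under heavy cluster-size ties.
* Generator distributions are stand-ins: no hemodynamic response model,
  no physiological noise, no realistic anatomy, no spatially structured
  null genes.
* Association p-values ignore spatial autocorrelation (by design, see
  above).
* The ALFF-before-bandpass split is a definitional necessity for fALFF,
  documented here rather than inferred from any upstream tool.
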