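# Methods

## Pipeline model

The analysis treats each subject's preprocessed BOLD volume as a collection
of voxel time series on a fixed grid; no registration, smoothing, filtering
or nuisance regression is performed here (those belong to upstream
preprocessing, and synthetic inputs are generated already "clean").

**Eigenvariate extraction.** A region's representative series is its major
eigenvariate: the first temporal principal component of the time × voxel
matrix of in-mask series, each voxel demeaned over time, computed by SVD.
The component is scaled to unit sample variance and its sign fixed so that
it correlates non-negatively with the mask's mean series (first nonzero
entry positive in the measure-zero case of exact orthogonality). Voxel-wise
variance normalisation before the SVD is available
(`normalize_voxels=True`) but off by default: the default weights voxels by
variance, which is what "maximum variance within the mask" implies.
Masks are confined to gray matter by thresholding a probability map at 0.2
(inclusive) before extraction.

**Segmentation.** For each hippocampal voxel the pipeline computes partial
correlations r₁ (with the combined anterior target eigenvariate,
controlling the posterior one) and r₂ (the converse) via the first-order
recursion r_xy·c = (r_xy − r_xc r_yc) / √((1−r_xc²)(1−r_yc²)), which equals
the residual-regression definition. Winner-take-all: anterior iff r₁ > r₂,
ties to posterior ("otherwise"-style tie rule; exact ties have measure
zero). Group divisions sum raw subtraction maps r₁ − r₂ over subjects
without per-subject weighting and binarize at 0, again ties to posterior.
Both hemispheres are classified against the same bilateral target
eigenvariate pair; hemisphere-specific segment nodes are obtained afterwards
by intersecting with hemisphere masks. Voxels with constant series are
excluded and reported, never silently labelled.

**Network.** 24 nodes in a fixed canonical order — anterior network block
first (HIPa, TP, PHa, FOC; left before right), then the posterior block
(HIPp, PHp, CGp, PCN, MFG, LG, TOF, Thal). Edges z_ij = max(0, atanh(r_ij))
with r clipped to |r| ≤ 1 − 1e-7 so duplicated series stay finite; negative
edges are removed per subject *before* any group averaging. By default the
hippocampal segment nodes come from the group-unbiased (all-subject)
division; per-group divisions are available (`division: group`).

**Inference.** "GLM" means Gaussian-identity (ordinary least squares with
covariates): the responses — Fisher-z edge weights, composite scores,
degrees — are continuous and approximately Gaussian, and no other family is
warranted. The design is intercept, patient indicator, centered age, male
indicator. Nodal degree k_i sums over all 23 other nodes of the joint
network (a per-network variant exists but is not default). NBS permutes
group labels only, keeping each subject's covariates attached; the
edge-level primary threshold is two-tailed p < 0.01 plus the sign of the
tested direction.

## NBS null: one shared permutation distribution for both directions

Both directions (patient>control, control>patient) are evaluated in a
single run against one permutation null: the maximal supra-threshold
component size over *both* signs in each permutation. With two independent
per-direction nulls, reporting "any significant component in either
direction" would operate at ≈ 1 − 0.95² ≈ 0.10 family-wise error; the
shared maximum restores joint control at the nominal 0.05, which is what
the calibration study verifies. Corrected p-values use the
(1 + #{null ≥ observed}) / (1 + n_perm) estimator — unbiased and never
exactly zero. Permutation indices are drawn from a seeded generator.

## Synthetic cohort

The generator emulates band-pass-filtered, nuisance-regressed BOLD at the
level that matters for this pipeline: second-order structure.

* **Latent node model.** 24 unit-variance Gaussian node signals with an
  equicorrelated block structure: within-network correlation `rho_intra`
  (default 0.5; patients add `delta_intra`, default 0.1), between-network
  `rho_inter` (default 0.2). The matrix is built as a factor model (shared
  global factor √rho_inter, per-network factor √(rho_within − rho_inter),
  idiosyncratic remainder), hence positive semidefinite by construction for
  0 ≤ rho_inter ≤ rho_intra < 1. Optional patient-only increments on named
  edges (`effect_edges`/`effect_size`) are applied on top and the result is
  re-checked for PSD, rejected otherwise.
* **Voxels.** Every voxel carries i.i.d. Gaussian noise of sd 1/snr
  (default snr 1.0, i.e. noise as strong as signal); voxels inside a node
  mask add that node's latent signal. Hippocampal voxels load on the
  anterior or posterior hippocampal latent of their hemisphere according to
  the planted partition: the grid's second axis is the long axis
  (posterior → anterior increasing), split at `anterior_fraction` (default
  1/3) of the hippocampal y-slices.
* **Timing and size.** T = 144 volumes (a 150-volume acquisition minus six
  discarded initial scans) at TR 2 s; default 20 subjects per group. The
  grid is a compact 24 × 28 × 24 layout with 3³-voxel target regions and a
  288-voxel bilateral hippocampus — large enough for every mask operation
  to be nontrivial, small enough that full-cohort voxel studies run in
  seconds.
* **Covariates.** Age ~ truncated normal (mean 37, sd 12, bounds 18–65);
  gender Bernoulli with p(male) = 0.7 — both in the range typical of
  case–control psychosis samples. An optional cognitive-style score couples
  to each subject's realized within-network Fisher-z strength at a
  configurable correlation (`score_coupling`), standardised within the
  cohort and rescaled to mean 45, sd 11, to exercise the brain–behaviour
  partial-correlation tests with known effect.
* **Determinism.** Per-subject generators are seeded from
  (seed, SHA-256(subject_id)); identical configurations yield bit-identical
  cohorts regardless of generation order.

What the generator does **not** emulate: hemodynamic response shapes,
scanner noise spectra and drifts, head motion, spatial autocorrelation of
noise, registration error, or realistic empirical edge-weight
distributions. Passing tests therefore demonstrate the pipeline's
correctness and statistical calibration under the stated second-order
model, not robustness to real-scanner artefacts.

## Simulation studies and problem sizes

* **Segmentation recovery** streams full voxel-level cohorts (20/group,
  T=144) and scores the group division against the planted labels, across
  snr ∈ {0.25, 1, 4}.
* **NBS calibration and power** generate subjects at the latent node-signal
  level and build matrices directly from those signals, skipping the
  voxel/eigenvariate stage (validated separately); this is what makes
  hundreds of replicates affordable. Null: 200 replicates, 20/group, 500
  permutations. Power: 100 replicates, 40/group, a +0.15 latent-correlation
  increment on the six edges among the four left anterior-network nodes.
* **Why +0.15 is the "large effect" default.** At n = 40/group the per-edge
  group t is ≈ 9 — detection of individual edges is essentially certain.
  Under a true effect the permutation null is contaminated: relabelings
  with imbalanced group mixing reproduce a diluted version of the planted
  component, and that contamination grows with the effect while the
  observed component stays capped at the six planted edges. Far larger
  increments therefore *reduce* corrected-inference power; +0.15 keeps the
  per-edge effect overwhelming while the null stays clean.

## Numerical conventions and degenerate inputs

* Correlations clipped at |r| ≤ 1 − 1e-7 before atanh.
* Ties in winner-take-all and in the group-sum binarization go to
  posterior; eigenvariate sign ties resolved by first nonzero entry.
* Constant voxel/eigenvariate series, empty masks after gray-matter
  confinement, collinear controls, rank-deficient designs, zero chi-squared
  margins, all-tied rank tests, and zero-variance normality inputs raise
  explicit errors naming the offending object.
* A perfectly fit or constant GLM response reports statistic 0, p 1.
* The KS normality screen estimates mean/sd from the sample and uses the
  standard KS reference distribution (the common software behaviour; a
  Lilliefors correction would be stricter). It only routes the choice
  between pooled-t and Mann–Whitney for demographic comparisons.
* Mann–Whitney U uses the tie-corrected normal approximation with
  continuity correction.
* Edge/metric tables are written with 17 significant digits and read back
  with round-trip float parsing, so re-running inference from cached files
  is bit-identical to the in-memory run.

## Known limitations

* NBS nuisance handling is simple label permutation (covariates stay with
  their subjects), not a residual-permutation scheme; with strong
  covariate–group confounding the null may be mis-calibrated.
* The Gaussian-identity GLM is the only implemented family.
* Segmentation assumes all inputs share one voxel grid; no resampling.
* Negative-correlation networks are out of scope (edges are zeroed).
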