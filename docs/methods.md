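# Methods

This note documents the models, conventions and numerical choices behind
`columnmorph`, and what the synthetic generator does and does not emulate.

## Shape alignment

Generalized Procrustes analysis translates every configuration to the
origin, scales it to unit centroid size (full-Procrustes scaling; a
`scale=False` flag gives the partial variant), and iteratively rotates each
configuration onto the running consensus by SVD-based orthogonal fits.
Rotations are proper (determinant +1). Convergence is declared when the
consensus moves by less than `tol = 1e-10` (Frobenius norm), with a cap of
100 iterations; the summed squared residual is non-increasing across
iterations. The orientation of the aligned set is arbitrary (it inherits
from the first configuration): all downstream statistics are rotation
invariant, and tests compare aligned sets modulo a common rotation.

**Object symmetry.** Vertebrae are bilaterally symmetric, so analyses use
the symmetric shape component: each configuration's mirror image (one
coordinate axis negated — the axis choice is immaterial because the joint
GPA re-rotates the mirrors — and paired landmarks relabelled) enters a
joint GPA with the originals, and the symmetric component is the mean of a
specimen's aligned original and aligned mirror. The mean of two unit-size
shapes has centroid size slightly below one, so the symmetric component is
re-normalised to unit centroid size; this makes the operation idempotent
and keeps the aligned-shape contract (centred, unit size) uniform. The
asymmetric component is available but unused downstream.

Species averaging (arithmetic mean of aligned configurations and of
centroid sizes per species × position) happens *after* alignment and
symmetry decomposition; the reverse order is possible by calling the
primitives directly.

## Disparity

Group disparity is the Procrustes variance: mean squared aligned-coordinate
distance to the group mean, divisor `n` (the convention of the standard
morphological-disparity implementations; `ddof=1` gives the unbiased
variant, and the choice is recorded in the output table's metadata).
Because regions carry different landmark counts (34 cervical, 32 thoracic,
36 lumbar), profiles divide by the landmark count K by default
("per-landmark" standardisation); a flag switches to the coordinate count
3K. Groups with restricted membership (T14–T16, L05–L07) are computed on
their restricted samples and carry `n_species` so plots and readers can
annotate the sampling difference.

## Phylogenetic machinery

The Brownian covariance **C** has entries equal to the shared root-to-MRCA
path length. Rate matrices come from phylogenetic independent contrasts
(mean outer product of the branch-length-standardised contrasts; full
matrix by default, diagonal optional), with the root state from the GLS
ancestral estimate. Simulation accumulates Gaussian increments with
covariance `rate · branch_length` from root to tips. PGLS premultiplies
data and design by C^(−1/2), computed by eigendecomposition with an
eigenvalue floor of 1e-12·λ_max. Allometry correction regresses flattened
shape on natural-log centroid size by GLS and keeps the residuals in the
original space (GLS-orthogonal to size); zero size variance downgrades to
GLS centring with a warning.

Phylogenetic shape analyses operate on PC scores retaining all non-zero
components (the species-level data have at most n−1 of them, far fewer
than 3K coordinates), which leaves every statistic unchanged (orthonormal
rotation) while keeping the linear algebra small.

## DTT and MDI

Subclade disparity is the average squared pairwise distance among the
subclade's tip vectors (equivalently 2/(n−1) · Σ‖xᵢ−x̄‖²; singletons are
0). The DTT curve is evaluated at every branching time (relative time 0 =
root, 1 = present): at each event the curve value is the mean relative
disparity of the internal-node clades whose stem lineage crosses the
preceding interval; the curve starts at 1 and a terminal point (1, 0) is
appended, since at the present every lineage is a singleton. MDI is the
trapezoidal integral of (observed − central simulated curve) over the full
[0, 1] interval; the central tendency is the mean of the simulated curves
(median optional) and the envelope is the pointwise 2.5%/97.5% band.
Defaults: 1000 BM simulations per MDI (the pipeline exposes `n_sim`; the
acceptance run uses 200 per group, which puts the Monte-Carlo error of a
single MDI well below the between-position differences of interest). Under
BM-generated data the MDI distribution is centred on zero (verified at
|mean| < 0.05 over 100 datasets).

## Procrustes ANOVA with RRPP

Sequential (hierarchical) sums of squares from orthonormal incremental
projections of the (optionally PGLS-transformed) data; F uses the
full-model residual mean square. Significance comes from residual
randomization: for each term, the reduced-model residuals are permuted
(999 permutations by default, observed arrangement counted in, so the
p-value floor is 1/(n_perm+1)); effect size Z is the standardised position
of log F in the permutation distribution. Term order for capability models
is fixed (terrestrial, cursorial, arboreal, aquatic, fossorial); total
model R² is order invariant, per-term sequential R² is not (documented
behaviour). One permutation schedule is shared across all candidate models
of an exhaustive search, making model selection deterministic given the
seed. Admissibility for the best-model search is "every term p < 0.1" on
the sequential p-values (marginal single-capability p-values populate the
significance grid); the chosen model maximises total R² among admissible
ones, and an empty selection is a result, not an error.

Morphological deviation for a capability is the norm of its full-model
coefficient row — the distance between fitted mean shapes with the
capability present vs absent, holding other terms fixed — back-projectable
to a landmark-space displacement field through the PCA loadings.

**Known limitation — measurement error.** PGLS whitening amplifies any
non-phylogenetic error variance by ~1/branch-length on short terminal
branches. Measured on this package's own generator: adding white
digitisation noise worth 2% of the shape variance raises the nominal-10%
false-positive rate of the phylogenetic ANOVA to ~19%, and 10% noise to
~52%. Real applications should average several specimens per species (the
species-averaging step exists for exactly this reason) and treat marginal
phylogenetic p-values on noisy data with caution. The generator's `null`
calibration scenario therefore uses negligible noise (sd 1e-4) so that it
measures the permutation machinery at its nominal level; the `paper_like`
scenario keeps realistic noise (sd 1e-3 of centroid size).

## Serial statistics

Within-region position ANOVAs use the species-averaged symmetric shapes
with position as a categorical factor (44 species × 5 cervical positions
gives the factor-df 4 / total-df 219 layout). The per-position metric
series (standardized disparity, MDI, best-model ecological R²) are
compared by GLS with AR1 errors along the fixed column order C03–C07,
T01–T14, L01–L07 (26 positions; T15/T16 are too sparsely sampled to enter)
or the 12 by-position keys. The AR1 coefficient is estimated by
*restricted* maximum likelihood: exact ML has the classic −(1+3φ)/n
small-sample bias, which at n = 26 and φ = 0.6 pulls the mean estimate to
~0.49 (17% low), while REML recovers ~0.55 (≈8%); REML is also the default
of the standard GLS implementations in this field. ML remains available
(`method="ML"`) for likelihood comparisons across fixed-effect structures.
Slope inference uses a t statistic with n − 2 df; a perfect fit reports
the p-value at the machine floor rather than zero.

## The synthetic generator

The generator emulates the study design, not vertebral anatomy:

- **Tree.** Pure-birth (dendropy), conditioned on the tip count, tips
  extended by the waiting time to the next speciation, scaled to a 60 Ma
  root age — roughly the age of crown Carnivora.
- **Counts.** Homeotic formulas drawn from {13T/7L: 0.42, 14T/6L: 0.30,
  15T/5L: 0.20, 16T/4L: 0.08} (thoracolumbar total fixed at 20, echoing
  the observed concentration on 13T/7L–15T/5L); the diaphragmatic vertebra
  sits three positions before the last thoracic (the typical anticlinal
  position).
- **Templates.** Stylised vertebra-like point clouds (midline body/spine
  arc plus paired ring, transverse-process and zygapophysis points),
  exactly symmetric, unit centroid size; 34/32/36 landmarks per region.
- **Shape evolution.** Displacements live in an orthonormal basis of
  symmetric fields orthogonal to the similarity modes, so injected effects
  survive superimposition essentially unchanged. Per position, species
  values follow OU (constrained) or BM (labile) on the tree; adjacent
  positions are coupled with serial correlation ρ = 0.6. Target tip
  standard deviations ramp from 0.030 (cervical) to 0.080 (last lumbars) —
  Procrustes units per unit centroid size. A per-position constraint
  factor (±50%) scales OU attraction up while scaling dispersal down,
  giving adjacent positions distinct regimes — the local-scale serial
  variation real columns show, and the inverse constraint–disparity
  coupling that the serial regressions are designed to detect.
- **Ecology.** Traditional categories drawn i.i.d. with carnivoran-like
  frequencies, then encoded into the five binary capabilities (respecting
  cursorial ⇒ terrestrial and the aquatic-without-terrestrial pinniped
  case). Capability effects are additive mean shifts along dedicated
  symmetric directions: aquatic 0.10 on every position (the strongest
  signal), cursorial 0.06 and fossorial/arboreal 0.05 around the
  thoracolumbar transition, terrestrial 0.03 on mid-thoracics.
- **Allometry and noise.** Brownian log centroid size (sd 0.25) with an
  allometric shape component (0.05 per log-size unit); specimens add
  i.i.d. digitisation noise and arbitrary position/orientation/size.

What passing tests on this generator show: the estimators recover known
disparity ratios, constraint orderings, injected ecological effects and
serial couplings under a model that matches the analyses' assumptions.
What they do not show: robustness to anatomically realistic covariation,
missing landmarks (unsupported by design), digitiser bias, fossil/tip-date
uncertainty, or ecological categories correlated with phylogeny.

## Problem sizes

Tests run the full workflow at 10–16 species and the pattern/structure
checks at the full 44-species scale with 100 DTT simulations per
vertebra; the acceptance script uses 44 species, 499 permutations and 200
simulations per group. These sizes put Monte-Carlo error comfortably below
the effect sizes being checked while keeping a complete run in the order
of a minute.
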