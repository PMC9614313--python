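# Methods

This note documents the models, numerical choices and limitations of
`pqctseg` — what each stage assumes, which constants matter, and what the
synthetic phantom does and does not establish about real scans.

## Data model and conventions

Images are 2-D density-calibrated rasters with isotropic pixel spacing
(default 0.5 mm, a typical in-plane pQCT resolution); label maps use the
fixed code set {0 air, 1 trabecular bone, 2 cortical bone, 3 muscle,
4 SAT}.  Pixel indices are 0-based with pixel-center sampling;
`(x, y) = (col·spacing + origin_x, row·spacing + origin_y)`.

All transforms use the pull-back (resampling) convention: they map points
of the fixed/target grid into the source image, so any warp is applied in a
single interpolation pass (linear for intensities, nearest-neighbour for
labels — labels are never blended, and a warp can never introduce a label
code absent from its input).  Out-of-view pixels are filled with 0 (air).
Displacement fields are stored in millimetres on the target grid.  The
affine-then-deformable composition used in label propagation is evaluated
analytically (`d(p) = M(p + u(p)) + t − p`), so propagation costs exactly
one nearest-neighbour resampling.

Density units are treated as abstract calibrated intensities; no
scanner-specific calibration is modelled.

## Mutual information

The reported similarity is the negative mutual information of a
`bins × bins` joint histogram (default 32) smoothed with an isotropic
Gaussian Parzen kernel (σ = 0.7 bins).  The isotropic smoothing makes the
estimate symmetric in its arguments to machine precision.  A constant image
has zero marginal entropy; MI is then defined as 0 and a warning is logged.

The FFD optimiser uses a separate MI estimator: the fixed image is
hard-binned, the moving image enters through a cubic B-spline Parzen
window, and the derivative with respect to each moving intensity is
analytic.  This estimator uses 64 bins rather than 32: with coarse Parzen
bins a dense deterministic optimiser can *raise* MI by exploiting the
smoothing that linear interpolation applies to the warped image, and it
drifts off the identity by a third of a pixel; at 64 bins the identity is a
true optimum (drift < 0.1 px).  This is the classic interpolation artifact
of histogram MI, handled elsewhere by stochastic sampling; here, where
determinism is a design goal, finer binning serves the same purpose.

## Affine registration

Parameters are a rotation / log-scale-x / log-scale-y / shear / translation
decomposition applied about the image center.  The decomposition matters:
with a raw 2×2 matrix, a rotation is a narrow coupled valley across four
parameters and both gradient descent and direction-set methods stall at a
fraction of the true angle.  Optimisation is regular-step gradient descent
(central differences in scaled parameter space; the step shrinks by 0.6 on
a gradient reversal or failed step) on a two-level pyramid, preceded by an
exhaustive rotation sweep (−18°..18°, 3° steps) at the coarsest level, and
followed by a deterministic Powell polish in the same scaled space.  On
64-px phantoms this recovers translations to ≲0.1 px and 10° rotations to
≲0.1°.

## Free-form deformation

The displacement field is the 2-D tensor product of 1-D cubic B-splines on
a uniform control lattice padded one cell beyond the image domain.  The
tensor product runs over the full 4×4 support (indices 0..3); cubic
B-splines satisfy partition of unity only with 4-point support, and the
basis reproduces linear functions, so an affine lattice has exactly zero
bending energy.  The regulariser is the standard second-order thin-plate
bending energy — the domain-normalised integral of
`f_xx² + 2 f_xy² + f_yy²` over both displacement components — with weight
λ_ρ = 0.01 against the (negative) MI term.

Both the MI force (chain rule through the warp: `dMI/dI · ∇(A∘τ)`,
projected onto the lattice by the basis matrices) and the bending-energy
gradient are analytic; L-BFGS-B (≤60 iterations per level) optimises the
coarse lattice (16 px cells) first, and the fine lattice (8 px) is
initialised by a separable least-squares fit to the coarse dense field.

## Symmetric diffeomorphic demons

The transform is the exponential of a stationary velocity field `v`,
computed by scaling and squaring with the number of squarings chosen so
each scaled step moves < 0.5 px; the inverse is `exp(−v)`.  Per iteration:
a forward force from `(S, A∘exp(v))`, a backward force from
`(A, S∘exp(−v))`, antisymmetric combination `(u_f − u_b)/2`, Gaussian
fluid smoothing of the update (σ = 2 px), first-order log-domain
composition `v ← v + ε·u` (ε = 1), and Gaussian elastic smoothing of `v`
(σ = 0.7 px).  Three pyramid levels, 80 iterations each; images are jointly
rescaled to [0, 1] and pre-smoothed (σ = 0.7 px) per level so the
normalisation constant is scale-free and detector noise does not dominate
the weak soft-tissue gradients.  The spatial-uncertainty normalisation
λ_ζ²/λ_h² is folded into one constant, default 5·10⁻⁴ (normalised
intensity² per mm²): small enough that weak-contrast boundaries
(muscle/SAT, contrast ≈ 0.02 after normalisation) still generate effective
forces, with stability provided by the fluid smoothing rather than the
denominator.  The symmetric mean-squared energy is tracked; on a sustained
increase the best state is restored.

The `demons_update` primitive follows the sign convention in which `u`
points opposite to the pull-back correction; `register_sdd` composes `−u`.

Inverse consistency `mean|τ∘τ⁻¹ − id|` is ≈ 10⁻³ px by construction
(exactness of `exp(v)∘exp(−v)` up to interpolation), and Jacobian
determinants stay positive on all recovery tests.

## Statistical atlas

Iteration 1 registers every subject affinely to a chosen reference subject
(configurable, default index 0) and averages; iterations 2..K (default
K = 5) register every subject nonlinearly (SDD by default) to the current
average and re-average.  Affine registration is not repeated after
iteration 1.  Pixels a subject maps outside its field of view are excluded
from that pixel's mean rather than averaged as zeros.  The per-iteration
mean-squared template change is recorded in the provenance; on well-posed
inputs it decays after nonlinear refinement starts (logged, not enforced).
The atlas is labelled automatically by propagating a labelled reference
template's tissue map through atlas-space registration — standing in for
expert labelling of the group template.

## STAPLE fusion

Rater performance is modelled one-vs-rest per class: sensitivity
`p_kl = Pr(e_k = l | T = l)` and specificity `q_kl = Pr(e_k ≠ l | T ≠ l)`.
The E-step computes per-pixel class posteriors by Bayes' rule from the
current sensitivities, spreading each rater's miss probability uniformly
over the remaining classes, with class priors fixed at the observed vote
frequencies; the M-step re-estimates `p` and `q` in closed form.  A full
confusion-matrix treatment was considered and rejected for the default: at
K = 3 raters it adds ~20 free parameters per rater with no measurable gain
on the phantom cohorts.  Initialisation `p = q = 0.9`; convergence when
`max(|Δp|, |Δq|) < 10⁻⁵` or 100 iterations.  The observed-data
log-likelihood is asserted non-decreasing every iteration.  The fused label
is the posterior arg-max with ties broken toward the lowest code.  A rater
with a constant decision map is clamped to `[0.01, 0.99]` to avoid a
degenerate likelihood.  On simulated raters drawn from this generative
model (sensitivities 0.95/0.85/0.75, 10⁴ pixels) EM recovers all
sensitivities within ±0.02.

The default multi-atlas configuration uses three raters — two individual
templates plus the statistical atlas — mirroring a three-template design in
which one template seeds atlas construction.

## Evaluation

DSC/TPR/PR with empty-denominator cases reported as missing (NaN), never
zero — an absent tissue is not a zero-quality segmentation.  Wilcoxon
rank-sum tests are exact (full enumeration) when the pooled sample size is
≤ 20 with no ties, and use the normal approximation with tie correction
otherwise; two identical constant samples give p = 1.  The
motion-stratified report compares grades 1–3 vs 4–5 per tissue and method:
stratum means, relative difference `(high − low)/low × 100` and the
rank-sum p-value.

Cross-validation bookkeeping is structural: the experiment pipeline draws
its template subjects (the two atlas raters and the statistical-atlas
reference) from a separate generator stream than its test subjects, so
scores are never computed on a subject that served as a template.

## Quantification

CSA is pixel count × spacing² (so CSAs over all codes partition the image
area exactly); density is the arithmetic mean over the tissue's pixels.
Mean density carries a partial-volume bias at boundaries with much brighter
neighbours (the point-spread blur mixes cortical intensity into the outer
trabecular pixels); interior (eroded) means recover the generating
distribution.  Age regressions are OLS with the slope p-value from the t
distribution; R² is the squared Pearson correlation by default (identical
to the OLS R² for a single predictor) with a Spearman option, since rank-
and product-moment conventions both circulate for this statistic.  CV-RMSD
is RMSD divided by the observed mean and errors out when the mean is zero.

## The phantom generator

Each structure is a Fourier-perturbed ellipse: skin ⊃ SAT ring ⊃ muscle ⊃
tibia (cortical ring ⊃ trabecular core), plus a fibula at the 38% and 66%
sites; the 4% site is a trabecular-dominant epiphysis with a thin shell.
Nominal sizes are laid out for a 64 mm field of view and scale with the
actual FOV so the leg always fits the frame.  Tissue intensities are drawn
per pixel from overlapping normals — air 0, SAT N(50, 25), muscle
N(80, 20), trabecular N(300, 60), cortical N(1100, 80), simulator
parameters chosen for the ordering and overlap pattern of calibrated
densities, not as claims about any scanner — followed by a σ = 0.7 px
point-spread blur and a small detector noise floor.

Motion artifacts of ordinal grade 1–5: grade 1 is the identity; higher
grades add (a) directional streak bands — bone intensity smeared along
random angles, modulated by transverse cosine bands, confined to the leg —
and (b) a rigidly shifted ghost of the bone *contour* (its edge band),
offset 1–4 px with grade.  Streak count, length and amplitude are linear in
grade, and with a fixed seed all grades share their leading streak
geometry, so artifact energy is strictly monotone in grade by construction.
No beam-hardening or sinogram-domain physics is modelled.

Known ground-truth warps are band-limited Gaussian random fields scaled to
a maximum displacement (never amplified), checked for positive Jacobian
determinant, with the inverse computed by fixed-point iteration and stored.

Cohorts draw ages from a clipped normal (70 ± 14 yr within 26–104) and
impose linear age trends *exactly at the boundary level*: the muscle,
tibia-outer and skin ellipse areas are offset linearly in age (each outer
trend absorbing the trends of the structures it contains), so the labelled
CSA of each tissue inherits its configured slope analytically; density
trends shift the tissue means.  Default trends mirror reported lower-leg
aging at this phantom's scale: muscle CSA −2.0 mm²/yr and cortical CSA
−0.3 mm²/yr (≈0.2–0.3 %/yr relative decline), trabecular density
−1.6 /yr, cortical density −1.8 /yr, muscle density −0.13 /yr, with no SAT
or trabecular-CSA trend.  Males get a constant +8% size and small density
offset so sex-stratified analyses see separated means.  Each subject's leg
is dithered by a sub-pixel random offset: without it, identical grid
placement makes the pixelisation error of the ellipse areas a deterministic
function of age and biases fitted slopes by several percent; with dither
the error is zero-mean and configured slopes are recovered within their
95% CIs.  Trend recovery is verified on motion-free cohorts, because streak
and ghost artifacts perturb *measured* density (a measurement effect that
exists in real corrupted scans too, independent of the generative trend).

## Problem sizes and defaults

The demonstration experiment uses 10 test subjects and 3 atlas raters at
128 px (64 mm FOV), K = 3 atlas iterations, SDD + STAPLE — chosen as the
smallest configuration in which every tissue, including the 6-px SAT ring,
is resolvable; at 64 px the SAT ring is ~3 px thick and its DSC is
resolution-floored near 0.75 regardless of registration quality.  Identity
checks run at 64 px where that floor does not apply (the identity map is
exact).  Trend regression uses n = 200 subjects.

## What the phantom does and does not show

Passing the phantom suite demonstrates that the pipeline's machinery is
correct and robust under the modelled conditions: overlapping intensity
distributions, smooth anatomical variability, and streak/ghost corruption
monotone in grade.  It does not establish performance on real pQCT:
real motion artifacts are reconstruction-domain and non-additive, real
anatomy varies topologically (vessel lumina, fascia, marrow
inhomogeneity), and real density calibration drifts.  Relative statements —
fusion helps, diffeomorphic demons degrades least under motion, thresholds
degrade most — are the transferable findings; absolute DSC values are
phantom-specific.

## Known limitations

* 2-D single-slice only; no DICOM ingestion.
* The demons normalisation constant is a single global scalar; a per-pixel
  `λ_ζ²(x)` variant is not implemented.
* STAPLE uses global class priors; spatially varying priors were prototyped
  and gave no measurable benefit at K = 3.
* The FFD field is not guaranteed invertible (no stored inverse);
  diffeomorphic guarantees apply to the demons engine only.
* An adapter to an external symmetric-normalisation (SyN) implementation is
  intentionally out of scope.
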