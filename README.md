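# pqctseg

Multi-atlas segmentation and quantification of muscle, bone and subcutaneous
adipose tissue in 2-D peripheral quantitative CT (pQCT) cross-sections of the
lower leg.

pQCT produces low-dose, density-calibrated slices of the limb at standard
sites along the tibia (4%, 38%, 66% of tibial length), but its limited
resolution, modest SNR and frequent subject-motion artifacts (streaks and
ghosting from the cortical bone) defeat density-threshold segmentation.
`pqctseg` implements a multi-atlas image segmentation (MAIS) framework for
these data: labelled atlas images are warped onto the subject by affine plus
deformable registration, their label maps are propagated through the
estimated transforms, and the propagated maps are fused into a consensus
segmentation.  The fused labels then feed tissue quantification
(cross-sectional area and mean density per tissue) and age-trend regression.

Because clinical pQCT cohorts are not publicly distributable, the package
ships a first-class synthetic phantom generator that reproduces the study
conditions: nested-tissue leg geometry per site, overlapping tissue density
distributions, smooth inter-subject shape variation, ordinal motion-artifact
grades 1–5, and age-structured cohorts with exactly known trends — so every
claim the package makes is testable against generated ground truth.

## The method

**Registration.** A transform `τ` warping atlas `A` onto subject `S` is
sought by minimising the energy

```
E(τ) = λ_ζ ζ(S, A∘τ) + λ_ρ ρ(τ)
```

with `ζ` the Mattes mutual-information similarity, `ρ` a regulariser, and
`λ_ζ = −1`, `λ_ρ = 0.01` by default.  Three engines are provided:

* **Affine** — mutual information maximised by regular-step gradient descent
  over a rotation / log-scale / shear / translation decomposition, on a
  two-level pyramid with an exhaustive coarse rotation sweep and a
  deterministic direction-set polish.
* **FFD** — hierarchical free-form deformation: the displacement field is a
  2-D tensor product of 1-D cubic B-splines on a uniform control lattice
  (coarse 16 px cells, then 8 px), with the thin-plate bending energy as
  `ρ`, optimised by L-BFGS-B with fully analytic gradients.
* **SDD** — log-domain symmetric diffeomorphic demons: the transform is the
  exponential of a stationary velocity field, updated from forward and
  backward demons forces `u(x) = −(S−A∘τ)·J / (‖J‖² + λ_ζ²/λ_h²)` combined
  antisymmetrically, with fluid-like smoothing of the update and
  elastic-like smoothing of the velocity.  Both `τ = exp(v)` and
  `τ⁻¹ = exp(−v)` are returned.

**Statistical atlas.** A group template is built by iterative averaging:
affine registration of all subjects to a chosen reference and averaging
(iteration 1), then nonlinear registration of all subjects to the current
average and re-averaging (iterations 2..K, default K = 5).

**Label fusion.** Propagated label maps are fused with STAPLE: an EM
algorithm that jointly estimates the consensus segmentation and each
rater's one-vs-rest sensitivity `p` and specificity `q` per tissue class.
The fused label at a pixel is the posterior arg-max.  A majority-vote
fusion and a fixed-threshold density baseline are included for comparison.

**Evaluation and quantification.** Dice similarity coefficient
(`DSC = 2|P∩R|/(|P|+|R|)`), sensitivity (TPR) and precision (PR) per tissue;
two-sided Wilcoxon rank-sum tests; motion-stratified comparison of grades
1–3 vs 4–5.  Per tissue: CSA = pixel count × spacing², mean density, and OLS
age-trend regression reporting slope, intercept, R², slope p-value and
CV-RMSD (root-mean-squared difference divided by the observed mean).

## Worked example

```python
from pqctseg import (PhantomSpec, generate_phantom, random_smooth_deformation,
                     warp_image, warp_labels, segment_single_atlas,
                     overlap_metrics)

atlas_img, atlas_lab = generate_phantom(PhantomSpec(site=66, seed=1,
                                                    image_size=128))
field = random_smooth_deformation(atlas_img.shape, atlas_img.spacing,
                                  seed=5, amplitude=3.0, scale=20.0)
subject_img = warp_image(atlas_img, field)       # unseen "subject"
subject_lab = warp_labels(atlas_lab, field)      # its ground truth

seg = segment_single_atlas(subject_img, atlas_img, atlas_lab, engine="sdd")
for tissue, name in [(1, "trabecular"), (2, "cortical"),
                     (3, "muscle"), (4, "SAT")]:
    dsc, tpr, pr = overlap_metrics(seg, subject_lab, tissue)
    print(f"{name:10s} DSC={dsc:.3f} TPR={tpr:.3f} PR={pr:.3f}")
```

prints

```
trabecular DSC=0.993 TPR=0.988 PR=0.998
cortical   DSC=0.989 TPR=0.990 PR=0.987
muscle     DSC=0.998 TPR=0.998 PR=0.998
SAT        DSC=0.989 TPR=0.993 PR=0.985
```

i.e. after warping the atlas by an unknown-to-the-registrar 3 mm smooth
deformation, symmetric diffeomorphic demons recovers every tissue with DSC
close to 1; SAT (the thin outer ring with the weakest intensity contrast) is
the hardest tissue, as in real scans.

The same workflow scales to cohorts through the CLI:

```bash
pqctseg simulate --n 10 --site 66 --seed 0 --out cohort/
pqctseg build-atlas --manifest cohort/cohort.csv --out atlas.nii.gz
pqctseg segment --subject cohort/sub-0000_image.nii.gz \
    --atlases atlases.csv --engine sdd --fusion staple --out seg.nii.gz
pqctseg run-experiment --seed 1 --out results/
```

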