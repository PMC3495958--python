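# Methods

## Model and assumptions

The segmentation treats white matter hyperintensities as regions whose
*contrast* against surrounding white matter exceeds the subject's own
GM–WM contrast, rather than as voxels above a fixed intensity. The chain
of assumptions:

* The FLAIR image is bias-corrected and shares one voxel grid with the
  GM/WM/CSF probability maps. Preprocessing (tissue segmentation,
  coregistration, bias correction) is consumed, not performed.
* Acquisitions are thick-slice axial, so every image-driven step
  (gradient, diffusion, watershed, region labelling and size counting) is
  2D, per slice; the slice axis is the third array axis. Only the
  tissue-mask cleanup (largest 6-connected component) is 3D, so cortical
  convolutions stay one component.
* The FLAIR intensity histogram has two main modes: background + CSF at
  low intensity, and normal GM + WM above it. The normal-tissue value ĩ
  is the second histogram maximum in ascending intensity order.
* Lesion contrast against WM exceeds the GM–WM contrast λ, so the
  Tukey-biweight diffusivity (zero for gradients ≥ λ) freezes lesion
  borders while flattening GM–WM transitions and noise.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ | estimated per subject | intensity | diffusivity support; merge threshold; enters T_WMH |
| dt | 0.1 | – | explicit diffusion time step (stability requires ≤ 0.25 with g ≤ ½) |
| iterations per block | 100 | – | diffusion run between two watersheds |
| max blocks | 50 | – | safeguard cap on the interleave |
| c0 | ½ | – | diffusivity normalisation g(0) |
| histogram bins | 256 | – | mode estimation |
| histogram smoothing | 2 | bins | Gaussian smoothing before peak-finding |
| peak prominence | 5% of tallest bin | – | what counts as a histogram mode |
| T_WMH | ĩ + 2λ | intensity | hyperintensity threshold (strictly above) |
| GM outlier quantile | 0.95 | – | "highest 5%" GM intensities (≥, linear interpolation) |
| WM overlap fraction | 0.5 | – | strictly more than half of a region inside corrected WM |
| S_FPmax | 20 | voxels | cortical false positives: strictly smaller and touching the GM/CSF interface |
| S_Brainstem | 50 | voxels | brainstem: strictly larger, crossing the mid-sagittal plane in a lower slice |
| lower slice fraction | 0.5 | – | which slices count as "lower" (inferior end from the affine) |

λ is estimated once from all interface voxels pooled over slices; a
per-slice mode exists (`compute_lambda(..., slicewise=True)`) but is off
by default, since a single subject-level contrast is the more stable
choice and per-slice interfaces can be small.

## Numerical choices

**Diffusion scheme.** Explicit 4-neighbour Perona–Malik updates, flux
`g(|d|)·d` per neighbour difference `d`, zero-flux boundaries. The
discrete scheme conserves the intensity sum exactly (divergence form),
obeys min/max bounds (dt·4·g ≤ 0.2 < 1), and is exactly equivariant under
joint scaling of image and λ. Neighbour differences, not central-difference
magnitudes, drive the flux; central differences (with replicated borders,
voxel units) are used for λ estimation and for the watershed input.

**Watershed stopping rule.** The interleave stops when two consecutive
watershed partitions are identical as *partitions* (label numbering is
arbitrary). With a float64 gradient this state is unattainable: the
regional minima of the nearly-flat diffused field keep drifting at
machine precision, and the flank gradients of preserved edges (which
never stop evolving laterally) creep across any fixed comparison. Two
classical-watershed measures make the rule attainable without touching
what is segmented:

* the flooded gradient is quantised in integer units of λ/64
  (`grad_levels`), so nearly-flat areas become exact zero plateaus with
  stable minima;
* the flooded gradient is saturated at λ/2 — the central-difference flank
  response of the smallest preserved step — so every preserved edge is a
  constant-height ridge whose split between basins is decided by
  deterministic plateau flooding rather than by slowly drifting values.

With these, convergence occurs within ~7–12 blocks on 96×96 slices; the
50-block cap is a safeguard that logs a warning rather than failing.

**Merging.** Order matters when recomputed means interact; ascending
mean-difference with recomputation after every merge is used, with a
deterministic (difference, label, label) tie-break. The merge test uses
means on the *original* FLAIR image, matching the labelling of the final
piecewise-constant image. A brute-force oracle over all merge orders (on
≤ 5 regions) confirms the terminal state — no adjacent pair below λ — is
always reached.

**Degenerate inputs.** Uniform images are rejected at λ estimation (zero
interface gradient) and at mode estimation (unimodal histogram); an empty
GM/WM interface and an empty post-cleanup WM mask are hard errors naming
the stage; an empty candidate set is a valid lesion-free result. An empty
mask into largest-component selection warns and passes through. Dice of
two empty masks is 1 by convention (logged).

**ICC and Bland–Altman.** ICC is the two-way mixed single-measures
coefficient; the consistency form ICC(3,1) is the default (shift
invariant), with the absolute-agreement form available. Bland–Altman
takes D = Seg − Ref against A = (Seg+Ref)/2: if the D-on-A regression is
significant (p ≤ 0.05, inclusive) the bias becomes the fitted line; if
|residuals| also regress significantly on A, the limits become
D̂(A) ± 1.96·√(π/2)·R̂(A) (the absolute-residual estimate of a
magnitude-dependent SD, since E|R| = √(2/π)·SD for centred normals);
otherwise D̂(A) ± 1.96·SD(residuals). The uniform-variability bias and
limits are always reported alongside.

## The phantom: what it emulates, and what it does not

Each case provides everything the pipeline consumes: FLAIR-like volume
with 0.9375×0.9375×5.5 mm voxels, soft GM/WM/CSF maps, a smoothed-WM
stand-in for an MNI WM prior, a mid-sagittal-plane mask, and ground
truth. Emulated features: concentric cortex/WM/ventricle anatomy scaled
along the slice axis; a CSF groove connecting ventricles to the
subarachnoid shell so CSF is a single 6-connected component; the two-mode
histogram; GM brighter than WM, CSF near zero; additive Gaussian noise;
partial volume via in-plane blurring of the tissue indicators; the
tendency of T1-driven segmentation to misclassify lesion borders as GM
(half of the rim probability mass is assigned to GM — a full
reassignment would push the blurred WM probability below 0.5 at
high-curvature rim voxels and move the ground truth outside the
binarised WM map); optional cortical-ribbon and brainstem bright
artifacts built to the exact geometry their filters target. Lesions are
voxel-exact (candidate voxels ranked by ellipsoidal radius), strictly
inside hemispheric WM with a one-voxel WM margin and at least four
voxels from the mid-sagittal plane — a narrower WM corridor between a
lesion and the midline groove has no watershed minimum of its own,
floods from the lesion basin, and the resulting plane-crossing region
would be removed by the brainstem rule.

Not emulated: cortical folding, Rician magnitude noise (Gaussian is used;
at the SNRs exercised the difference is immaterial to the contrast
logic), scanner-specific artifacts, genuine SPM segmentation behaviour,
and lesion texture (planted lesions are homogeneous). Passing phantom
tests therefore demonstrates the algorithmic contracts — contrast
estimation, edge-preserving flattening, convergence, threshold and
filter logic, volume bookkeeping — not clinical accuracy on real MRI,
where tissue maps are imperfect and lesions are heterogeneous. On the
default suite the agreement statistics are near-ceiling (mean SI ≈ 0.99,
ICC ≈ 1.0); clinical performance on patient data is substantially lower
for any method of this family.

Suite study conditions: 20 cases, lesion loads log-spaced 0.5–80 mL
(small to very large clinical burdens), noise σ cycling through
{1.5, 2.0, 2.5} (σ ≤ λ/5), lesion intensities cycling through
{142, 145, 150} (contrast ≥ 3λ against WM), alternating deep and
periventricular placement, artifacts planted in every other case.

## Known limitations

* A lesion region whose watershed basin reaches the mid-sagittal plane in
  a lower slice is removed by the brainstem rule; large genuine midline
  or pontine lesions are a known blind spot of that filter.
* Lesions thinner than ~3 voxels in-plane leave no interior gradient
  minimum and may not form their own basin.
* The GM-outlier repair of the WM mask depends on misclassified lesion
  voxels being 4-connected (through other outliers) to the main WM body;
  isolated misclassified islands stay outside the corrected mask and are
  only kept if the rest of their region carries the >50% overlap.
* λ is a global estimate; strong residual bias fields that change the
  GM–WM contrast across the volume would argue for the per-slice mode.
* `run_whasa` accepts the MNI WM prior for interface completeness but
  does not use it; it belongs to intensity-normalising baselines, not to
  this contrast-based method.
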