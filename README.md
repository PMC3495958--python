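# whasa

Contrast-based, fully automatic segmentation of **white matter
hyperintensities (WMH)** from bias-corrected FLAIR MRI and coregistered
tissue probability maps, together with a synthetic phantom generator and
the agreement statistics used to validate lesion segmentations
(Dice/Similarity Index, intraclass correlation, Bland–Altman analysis).

WMH are bright lesions of the cerebral white matter on T2/FLAIR images,
strongly associated with small vessel disease, stroke and dementia.
Quantifying their load usually requires slow manual delineation;
intensity-threshold methods are fragile across scanners. This package
implements a *contrast-based* alternative for researchers who need
automated WMH volumes in (possibly multicentre) FLAIR studies, and for
method developers who need a controlled synthetic test bed.

## The algorithm

Inputs (all in FLAIR space): the bias-corrected FLAIR image `mFLAIR`, the
tissue probability maps `M_GM`, `M_WM`, `M_CSF` produced by a tissue
segmentation tool such as SPM, an optional back-registered MNI WM prior,
and an optional mid-sagittal-plane mask `msP`.

1. **Contrast parameter λ** — `M_GM` and `M_WM` are binarised at 0.5,
   dilated in-plane (4-connected cross), and intersected to form the GM/WM
   interface; λ is the mean FLAIR gradient magnitude over that interface,
   i.e. the subject's own GM–WM contrast.
2. **Nonlinear diffusion** — slice-wise Perona–Malik diffusion
   `∂I/∂t = div(g(|∇I|) ∇I)` with Tukey's biweight diffusivity
   `g(s) = ½(1 − (s/λ)²)²` for `s < λ`, `0` otherwise. Contrasts at or
   above λ (lesion borders) are frozen; weaker contrasts (GM–WM, noise)
   are flattened.
3. **Interleaved watershed** — blocks of 100 diffusion iterations
   (time step 0.1) alternate with a watershed of the gradient of the
   diffused slice until two consecutive watershed partitions are
   identical.
4. **Piecewise-constant image** — each watershed region is labelled with
   its mean `mFLAIR` intensity; 4-adjacent regions whose means differ by
   less than λ are merged (smallest difference first, means recomputed).
5. **Selection** — the normal-tissue intensity ĩ is the second maximum of
   the FLAIR histogram (the first is background/CSF); regions with mean
   above `T_WMH = ĩ + 2λ` are candidate WMH. Three anatomical filters
   follow: candidates must lie >50% inside a corrected WM mask (the WM
   map repaired by geodesic dilation into hyperintense GM/CSF outliers);
   regions smaller than 20 voxels touching the GM/CSF interface are
   removed (cortical artifacts); regions larger than 50 voxels crossing
   the mid-sagittal plane in the lower slices are removed (brainstem).

The phantom module generates seeded, fully synthetic cases — elliptical
head/cortex/WM/ventricle anatomy with anisotropic voxels
(0.9375×0.9375×5.5 mm), a two-mode intensity histogram, planted
ellipsoidal lesions with voxel-exact volumes, optional cortical/brainstem
artifacts — so the entire pipeline is testable without clinical data.

## Worked example

```sh
whasa simulate --out-dir case0 --seed 1
whasa segment --flair case0/mflair.nii.gz --gm case0/m_gm.nii.gz \
    --wm case0/m_wm.nii.gz --csf case0/m_csf.nii.gz \
    --msp case0/msp.nii.gz --out case0/wmh.nii.gz --report case0/report.json
```

The segment step logs (for the default phantom, a 2 mL planted load
split over two deep-WM lesions):

```
INFO whasa: lambda=14.190 T_WMH=128.412 volume=1.98 mL
```

λ ≈ 14.2 is the estimated GM–WM contrast (the phantom's GM–WM step is 24
intensity units, and the mean central-difference response across a curved
boundary is a little over half the step). T_WMH = ĩ + 2λ ≈ 128 sits just
above the cortical GM intensity (124), so normal tissue is excluded while
the planted lesions (intensity 145) are recovered: the reported 1.98 mL
against 2.00 mL planted. The JSON report records λ, ĩ, T_WMH, per-slice
iteration counts, and region counts after each filter.

Or in Python:

```python
from whasa import phantom_suite, run_whasa, evaluate_suite

cases = phantom_suite(5, seed=1)
pairs = []
for c in cases:
    mask, report = run_whasa(c.mflair, c.m_gm, c.m_wm, c.m_csf, msp=c.msp)
    pairs.append((mask, c.truth_mask))
print(evaluate_suite(pairs).mean_si)
```

`whasa demo --out-dir demo --seed 1` runs the simulate → segment →
evaluate round trip and exits nonzero if agreement falls below its
thresholds; `whasa evaluate --pairs manifest.csv --out report.json`
computes SI/ICC/regression/Bland–Altman for arbitrary mask pairs.

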