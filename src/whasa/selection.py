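"""Selection of white-matter-hyperintensity regions from the
piecewise-constant image.

The chain is: estimate the normal GM+WM intensity mode i~ from the FLAIR
histogram (second histogram maximum; the first is the background/CSF mode),
threshold the piecewise-constant image at T_WMH = i~ + 2*lambda, then apply
three anatomical filters to the candidate regions:

1. WM-overlap filter against a corrected WM mask (the raw WM map is repaired
   by reclassifying hyperintense outliers of the GM and CSF maps through a
   conditional/geodesic dilation);
2. removal of small cortical false positives touching the GM/CSF interface
   (size < S_FPmax, 20 voxels);
3. removal of large bright areas crossing the mid-sagittal plane in the
   lower slices (brainstem; size > S_Brainstem, 50 voxels).

Candidate "areas" are 2D 4-connected components per slice, consistent with
the 2D slice-wise pipeline; all size thresholds are strict exactly as
stated ("more than 50%", "smaller than 20", "larger than 50").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import (CROSS_IN_PLANE_3D, SLICE_AXIS, BinaryMask, LabelMap,
                   Volume, binarize_probability, dilate_2d,
                   label_slices_4conn, largest_component_3d, tissue_interface)
from .diffusion import DiffusionParams, compute_lambda
from .watershed import PiecewiseResult, piecewise_segment

__all__ = [
    "SelectionParams",
    "estimate_normal_mode",
    "wmh_threshold",
    "select_hyperintense_regions",
    "correct_wm_mask",
    "filter_by_wm_overlap",
    "remove_cortical_false_positives",
    "remove_brainstem_false_positives",
    "run_whasa",
]


@dataclass
class SelectionParams:
    """Tunable parameters of the region-selection stage.

    ``s_fpmax`` and ``s_brainstem`` are region sizes in voxels (per 2D
    region); ``wm_overlap_fraction`` is the minimum fraction of a candidate
    region that must lie inside the corrected WM mask;
    ``gm_outlier_quantile`` defines "the highest 5%" GM intensities;
    ``lower_slice_fraction`` defines which slices count as "lower" for the
    brainstem rule; ``histogram_bins`` and ``histogram_smooth_sigma``
    control the mode estimation.
    """

    s_fpmax: int = 20
    s_brainstem: int = 50
    wm_overlap_fraction: float = 0.5
    gm_outlier_quantile: float = 0.95
    lower_slice_fraction: float = 0.5
    histogram_bins: int = 256
    histogram_smooth_sigma: float = 2.0

    def __post_init__(self):
        if self.s_fpmax <= 0 or self.s_brainstem <= 0:
            raise ValueError("size thresholds must be positive")
        for f in (self.wm_overlap_fraction, self.gm_outlier_quantile,
                  self.lower_slice_fraction):
            if not (0 < f < 1):
                raise ValueError("fractions must be in (0, 1)")


def estimate_normal_mode(mflair: Volume, bins: int = 256,
                         mask: np.ndarray = None,
                         smooth_sigma: float = 2.0,
                         min_prominence: float = 0.05) -> float:
    """Normal GM+WM intensity i~: the second maximum of the (lightly
    smoothed) FLAIR intensity histogram, in ascending intensity order.

    The first maximum is the background/CSF mode.  ``mask`` restricts the
    histogram to a region of interest (e.g. a loose brain mask); when None
    the whole volume is used.  Only peaks whose prominence exceeds
    ``min_prominence`` times the tallest smoothed bin count as modes, so
    sampling noise on a mode's flank cannot pose as a second maximum.
    Raises if the histogram has fewer than two such maxima (unimodal image).
    """
    vals = mflair.data[mask] if mask is not None else mflair.data.ravel()
    if vals.size == 0:
        raise ValueError("empty histogram domain")
    hist, edges = np.histogram(vals, bins=bins)
    smooth = gaussian_filter1d(hist.astype(np.float64), smooth_sigma)
    # local maxima (plateau-aware), including maxima at the histogram ends
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded,
                          prominence=min_prominence * smooth.max())
    peaks = peaks - 1
    if peaks.size < 2:
        raise ValueError("unimodal histogram; cannot locate "
                         "normal-tissue mode")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[peaks[1]])


def wmh_threshold(i_tilde: float, lam: float) -> float:
    """Hyperintensity threshold T_WMH = i~ + 2*lambda."""
    return float(i_tilde + 2.0 * lam)


def select_hyperintense_regions(pw: PiecewiseResult, t_wmh: float) -> BinaryMask:
    """Union of piecewise regions whose mean intensity is strictly above
    T_WMH."""
    keep = {rid for rid, m in pw.region_means.items() if m > t_wmh}
    if keep:
        lut = np.zeros(int(pw.labels.data.max()) + 1, dtype=bool)
        lut[list(keep)] = True
        data = lut[pw.labels.data]
    else:
        data = np.zeros(pw.labels.data.shape, dtype=bool)
    return BinaryMask(data=data, grid=pw.piecewise_image)


def correct_wm_mask(m_gm: Volume, m_wm: Volume, m_csf: Volume,
                    mflair: Volume,
                    gm_outlier_quantile: float = 0.95) -> BinaryMask:
    """Corrected WM mask: repair the WM map with hyperintense FLAIR outliers
    of the GM and CSF maps.

    Each probability map is binarised at 0.5 and reduced to its largest
    6-connected component (3D, so cortical convolutions stay one component).
    GM outliers are GM-mask voxels whose FLAIR intensity is in the highest
    5% of GM intensities (>= the 95th percentile, linear interpolation);
    CSF outliers are CSF-mask voxels brighter than the mean GM intensity
    (strict).  The WM mask is then dilated conditionally to the outliers --
    a per-slice 4-connected geodesic dilation iterated to convergence inside
    the outlier set -- so only outliers 4-reachable from WM through outliers
    are reclassified as WM.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = largest_component_3d(binarize_probability(m_gm)).data
        wm = largest_component_3d(binarize_probability(m_wm)).data
        csf = largest_component_3d(binarize_probability(m_csf)).data
    if not wm.any():
        raise ValueError("WM mask empty after binarisation and "
                         "largest-component selection")
    gm_vals = mflair.data[gm]
    outliers = np.zeros(wm.shape, dtype=bool)
    if gm_vals.size:
        gm_thr = np.percentile(gm_vals, 100.0 * gm_outlier_quantile)
        outliers |= gm & (mflair.data >= gm_thr)
        outliers |= csf & (mflair.data > gm_vals.mean())
    corrected = ndimage.binary_dilation(
        wm, structure=CROSS_IN_PLANE_3D, iterations=0, mask=wm | outliers)
    return BinaryMask(data=corrected, grid=mflair)


def _iter_regions(candidates: BinaryMask):
    """Yield (slice_index, voxel_index_tuple) for each per-slice 4-connected
    candidate region."""
    labels = label_slices_4conn(candidates).data
    for k in range(labels.shape[SLICE_AXIS]):
        sl = labels[:, :, k]
        for rid in np.unique(sl):
            if rid == 0:
                continue
            yield k, np.nonzero(sl == rid)


def filter_by_wm_overlap(candidates: BinaryMask, m_wm_corrected: BinaryMask,
                         fraction: float = 0.5) -> BinaryMask:
    """Keep candidate regions with strictly more than ``fraction`` of their
    voxels inside the corrected WM mask."""
    out = np.zeros(candidates.shape, dtype=bool)
    wm = m_wm_corrected.data
    for k, idx in _iter_regions(candidates):
        size = idx[0].size
        inside = int(wm[:, :, k][idx].sum())
        if inside > fraction * size:
            out[:, :, k][idx] = True
    return BinaryMask(data=out, grid=candidates.grid)


def remove_cortical_false_positives(candidates: BinaryMask, m_gm: Volume,
                                    m_csf: Volume,
                                    s_fpmax: int = 20) -> BinaryMask:
    """Remove regions that are both smaller than ``s_fpmax`` voxels (strict)
    and 4-connected to the GM/CSF interface in their slice."""
    iface = tissue_interface(binarize_probability(m_gm),
                             binarize_probability(m_csf))
    near_iface = dilate_2d(iface).data  # interface voxels + 4-neighbours
    out = np.zeros(candidates.shape, dtype=bool)
    for k, idx in _iter_regions(candidates):
        size = idx[0].size
        touches = bool(near_iface[:, :, k][idx].any())
        if size < s_fpmax and touches:
            continue
        out[:, :, k][idx] = True
    return BinaryMask(data=out, grid=candidates.grid)


def lower_slices(affine: np.ndarray, n_slices: int,
                 fraction: float = 0.5) -> np.ndarray:
    """Boolean flag per slice index: True for the inferior ``fraction`` of
    slices, with the inferior end resolved from the affine's z direction."""
    n_lower = int(np.floor(fraction * n_slices))
    k = np.arange(n_slices)
    z_world = affine[2, 2] * k + affine[2, 3]
    order = np.argsort(z_world, kind="stable")
    flags = np.zeros(n_slices, dtype=bool)
    flags[order[:n_lower]] = True
    return flags


def remove_brainstem_false_positives(candidates: BinaryMask,
                                     msp: BinaryMask,
                                     s_brainstem: int = 50,
                                     lower_slice_fraction: float = 0.5,
                                     affine: np.ndarray = None) -> BinaryMask:
    """Remove regions strictly larger than ``s_brainstem`` voxels that
    intersect the mid-sagittal-plane mask in a lower slice.

    If no msp mask is available the filter is skipped with a warning.
    """
    if msp is None:
        warnings.warn("no mid-sagittal-plane mask: brainstem false-positive "
                      "filter skipped", stacklevel=2)
        return BinaryMask(data=candidates.data.copy(), grid=candidates.grid)
    if affine is None:
        affine = (candidates.grid.affine if candidates.grid is not None
                  else np.eye(4))
    nz = candidates.shape[SLICE_AXIS]
    low = lower_slices(affine, nz, lower_slice_fraction)
    out = np.zeros(candidates.shape, dtype=bool)
    for k, idx in _iter_regions(candidates):
        size = idx[0].size
        crosses = bool(msp.data[:, :, k][idx].any())
        if size > s_brainstem and low[k] and crosses:
            continue
        out[:, :, k][idx] = True
    return BinaryMask(data=out, grid=candidates.grid)


def run_whasa(mflair: Volume, m_gm: Volume, m_wm: Volume, m_csf: Volume,
              wm_mni: Volume = None, msp: BinaryMask = None,
              diffusion_params: dict = None,
              selection_params: SelectionParams = None,
              lambda_override: float = None,
              return_piecewise: bool = False):
    """Run the full segmentation pipeline on one subject.

    Returns ``(mask, report)`` where ``report`` is a JSON-serialisable dict
    recording lambda, i~, T_WMH, per-slice diffusion blocks, region/voxel
    counts before and after each filter, and the final volume in mL.

    ``wm_mni`` is accepted for interface completeness but unused by the
    algorithm itself (it serves intensity-normalisation baselines, not this
    contrast-based pipeline).
    """
    sp = selection_params or SelectionParams()
    for name, v in (("GM", m_gm), ("WM", m_wm), ("CSF", m_csf)):
        if v.shape != mflair.shape:
            raise ValueError(f"{name} map not on the FLAIR grid")

    lam = (float(lambda_override) if lambda_override is not None
           else compute_lambda(mflair, m_gm, m_wm))
    dp_kwargs = dict(diffusion_params or {})
    params = DiffusionParams(lambda_contrast=lam, **dp_kwargs)

    pw = piecewise_segment(mflair, params)

    brain = (m_gm.data + m_wm.data + m_csf.data) > 0.5
    i_tilde = estimate_normal_mode(
        mflair, bins=sp.histogram_bins, mask=brain,
        smooth_sigma=sp.histogram_smooth_sigma)
    t_wmh = wmh_threshold(i_tilde, lam)

    cand = select_hyperintense_regions(pw, t_wmh)
    wm_corr = correct_wm_mask(m_gm, m_wm, m_csf, mflair,
                              gm_outlier_quantile=sp.gm_outlier_quantile)
    after_wm = filter_by_wm_overlap(cand, wm_corr, sp.wm_overlap_fraction)
    after_cortex = remove_cortical_false_positives(after_wm, m_gm, m_csf,
                                                   sp.s_fpmax)
    final = remove_brainstem_false_positives(
        after_cortex, msp, sp.s_brainstem, sp.lower_slice_fraction,
        affine=mflair.affine)
    final = BinaryMask(data=final.data, grid=mflair)

    def _stage(mask):
        return {"regions": _count_regions(mask), "voxels": int(mask.data.sum())}

    report = {
        "lambda": lam,
        "i_tilde": i_tilde,
        "t_wmh": t_wmh,
        "n_blocks_per_slice": list(map(int, pw.n_blocks)),
        "all_slices_converged": bool(all(pw.converged)),
        "stages": {
            "thresholded": _stage(cand),
            "wm_overlap": _stage(after_wm),
            "cortical_fp": _stage(after_cortex),
            "brainstem_fp": _stage(final),
        },
        "wmh_volume_ml": final.volume_ml(),
    }
    if return_piecewise:
        return final, report, pw
    return final, report


def _count_regions(mask: BinaryMask) -> int:
    return len(list(_iter_regions(mask)))
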