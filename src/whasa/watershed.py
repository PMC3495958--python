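"""Interleaved diffusion/watershed segmentation and contrast-based region
merging, producing a piecewise-constant image.

A steady state of the nonlinear diffusion is never reached exactly, so
diffusion blocks are alternated with watershed segmentations of the evolving
slice; the interleave stops when two consecutive watershed partitions are
strictly identical (compared as partitions, since watershed label numbering
is arbitrary).  Each final watershed region is labelled with its mean
intensity computed on the *original* FLAIR slice, and 4-adjacent regions
whose mean difference is below lambda are merged (smallest difference first,
means recomputed after every merge), leaving a piecewise-constant image
whose adjacent regions all differ by at least lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import watershed as _skimage_watershed

from .core import SLICE_AXIS, LabelMap, Volume
from .diffusion import DiffusionParams, diffuse_block, gradient_magnitude_2d

__all__ = [
    "PiecewiseResult",
    "watershed_2d",
    "partitions_identical",
    "interleaved_segmentation",
    "merge_regions",
    "piecewise_segment",
]


def watershed_2d(slice_2d: np.ndarray, grad_quantum: float = None,
                 grad_cap: float = None) -> np.ndarray:
    """Watershed partition of one slice.

    The watershed floods the in-plane gradient magnitude of the (diffused)
    slice, with catchment basins seeded at its regional minima; every voxel
    is assigned to a basin (no ridge label).  Deterministic for fixed input.

    ``grad_quantum`` quantises the gradient into integer levels before
    flooding (classical integer-valued watershed) and ``grad_cap`` saturates
    it.  Both exist to make the interleave's stopping rule attainable: the
    quantum turns residual machine-level ripples of nearly-flat diffused
    areas into exact zero plateaus (otherwise the regional minima of a
    smooth field drift indefinitely), and the cap -- set to lambda/2, the
    central-difference flank response of the smallest preserved step --
    turns every preserved edge into a constant-height ridge whose split
    between basins no longer depends on the slowly drifting flank values.
    Neither affects which basins exist, only the numerical stability of
    their boundaries.
    """
    grad = gradient_magnitude_2d(slice_2d)
    if grad_cap is not None:
        grad = np.minimum(grad, grad_cap)
    if grad_quantum is not None:
        grad = np.round(grad / grad_quantum).astype(np.int64)
    return _skimage_watershed(grad, connectivity=1)


def partitions_identical(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label images induce the same partition of the voxels
    (invariant to label renaming: co-membership is compared)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    # a and b induce the same partition iff neither strictly refines the
    # joint partition (a, b)
    pair = a.astype(np.int64) * (int(b.max()) + 1) + b.astype(np.int64)
    n_pair = np.unique(pair).size
    return np.unique(a).size == n_pair and np.unique(b).size == n_pair


def interleaved_segmentation(slice_2d: np.ndarray, params: DiffusionParams):
    """Alternate diffusion blocks with watershed until two consecutive
    watershed partitions are identical.

    Returns ``(diffused_slice, labels, n_blocks)``.  If ``params.max_blocks``
    is reached without convergence the last partition is returned and a
    warning is emitted (not a hard error).
    """
    I = np.asarray(slice_2d, dtype=np.float64)
    prev = None
    labels = None
    n_blocks = 0
    q = params.lambda_contrast / params.grad_levels
    cap = params.lambda_contrast / 2.0
    for _ in range(params.max_blocks):
        I = diffuse_block(I, params)
        labels = watershed_2d(I, grad_quantum=q, grad_cap=cap)
        n_blocks += 1
        if prev is not None and partitions_identical(prev, labels):
            return I, labels, n_blocks
        prev = labels
    warnings.warn(
        f"interleaved segmentation did not converge within "
        f"{params.max_blocks} blocks; returning last partition", stacklevel=2)
    return I, labels, n_blocks


def merge_regions(labels: np.ndarray, mflair_slice: np.ndarray, lam: float):
    """Merge 4-adjacent regions whose mean-intensity difference is below
    lambda (strict), smallest difference first.

    Region means are computed on the original FLAIR slice and recomputed
    after every merge, so chains of merges can bring formerly-distant means
    within lambda of a neighbour.  Terminates when every 4-adjacent pair of
    regions differs by at least lambda.

    Returns ``(merged_labels, means)`` where ``means`` maps each surviving
    label to its mean FLAIR intensity.
    """
    lab = np.asarray(labels)
    img = np.asarray(mflair_slice, dtype=np.float64)
    if lab.shape != img.shape:
        raise ValueError("labels and image shapes differ")
    nmax = int(lab.max()) + 1
    sums = np.bincount(lab.ravel(), weights=img.ravel(), minlength=nmax)
    counts = np.bincount(lab.ravel(), minlength=nmax)

    # region adjacency graph from 4-neighbour label changes
    adj = {int(i): set() for i in np.unique(lab) if i != 0}
    for u, v in _adjacent_label_pairs(lab):
        adj[u].add(v)
        adj[v].add(u)

    parent = {i: i for i in adj}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    mean = {i: sums[i] / counts[i] for i in adj}
    while True:
        best = None
        for i in adj:
            mi = mean[i]
            for j in adj[i]:
                if j <= i:
                    continue
                d = abs(mi - mean[j])
                if best is None or (d, i, j) < best:
                    best = (d, i, j)
        if best is None or best[0] >= lam:
            break
        _, i, j = best
        # merge j into i
        sums[i] += sums[j]
        counts[i] += counts[j]
        mean[i] = sums[i] / counts[i]
        parent[j] = i
        for k in adj.pop(j):
            adj[k].discard(j)
            if k != i:
                adj[k].add(i)
                adj[i].add(k)
        adj[i].discard(i)
        del mean[j]

    if adj:
        lut = np.arange(nmax)
        for i in range(nmax):
            if i in parent:
                lut[i] = find(i)
        merged = lut[lab]
    else:
        merged = lab.copy()
    return merged, {i: float(mean[i]) for i in mean}


def _adjacent_label_pairs(lab: np.ndarray):
    """Unique unordered pairs of distinct nonzero labels that touch with
    4-connectivity."""
    pairs = set()
    for a, b in ((lab[1:, :], lab[:-1, :]), (lab[:, 1:], lab[:, :-1])):
        diff = a != b
        u = a[diff].astype(np.int64)
        v = b[diff].astype(np.int64)
        keep = (u != 0) & (v != 0)
        lo = np.minimum(u[keep], v[keep])
        hi = np.maximum(u[keep], v[keep])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


@dataclass
class PiecewiseResult:
    """Piecewise-constant segmentation of a whole volume.

    ``labels`` carries per-slice region labels (unique across slices);
    ``region_means`` maps each label to its mean FLAIR intensity;
    ``piecewise_image`` replaces every voxel by its region mean;
    ``n_blocks`` lists the diffusion blocks executed per slice;
    ``converged`` flags per-slice interleave convergence.
    """

    labels: LabelMap
    region_means: dict
    piecewise_image: Volume
    n_blocks: list
    converged: list = field(default_factory=list)


def piecewise_segment(mflair: Volume, params: DiffusionParams) -> PiecewiseResult:
    """Run the interleaved diffusion/watershed and the contrast merge on
    every slice of a volume; assemble the piecewise-constant image."""
    nz = mflair.shape[SLICE_AXIS]
    lab3 = np.zeros(mflair.shape, dtype=np.int32)
    pw = np.zeros(mflair.shape)
    means_all = {}
    n_blocks = []
    converged = []
    offset = 0
    for k in range(nz):
        sl = mflair.data[:, :, k]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, labels, nb = interleaved_segmentation(sl, params)
        conv = not any("did not converge" in str(w.message) for w in caught)
        for w in caught:
            if "did not converge" in str(w.message):
                warnings.warn(f"slice {k}: {w.message}", stacklevel=2)
        merged, means = merge_regions(labels, sl, params.lambda_contrast)
        n_blocks.append(nb)
        converged.append(conv)
        # relabel consecutively with a volume-wide offset
        ids = sorted(means)
        remap = np.zeros(int(merged.max()) + 1, dtype=np.int32)
        pwlut = np.zeros(int(merged.max()) + 1)
        for new, old in enumerate(ids, start=1):
            remap[old] = new + offset
            pwlut[old] = means[old]
            means_all[new + offset] = means[old]
        lab3[:, :, k] = remap[merged]
        pw[:, :, k] = pwlut[merged]
        offset += len(ids)
    return PiecewiseResult(
        labels=LabelMap(data=lab3),
        region_means=means_all,
        piecewise_image=Volume(data=pw, affine=mflair.affine),
        n_blocks=n_blocks,
        converged=converged,
    )
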