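"""Synthetic FLAIR phantoms with the statistical structure the segmentation
pipeline assumes.

Each phantom emulates the inputs the pipeline consumes in FLAIR space:
a bias-corrected FLAIR-like volume with anisotropic voxels, soft tissue
probability maps (GM/WM/CSF), a smoothed-WM stand-in for a back-registered
MNI WM prior, a mid-sagittal-plane mask, and the ground-truth lesion mask.

Anatomy is a nested set of elliptical compartments per axial slice: an
outer CSF shell (subarachnoid space), a GM ribbon (cortex), a WM interior
and central CSF ventricles, connected to the shell by a thin posterior
CSF groove standing in for the interhemispheric fissure (this keeps CSF a
single 6-connected component, as in real anatomy).  Intensities follow the
expected FLAIR ordering -- CSF near zero, GM brighter than WM, lesions
brighter still -- with additive Gaussian noise, so the intensity histogram
has the expected two main modes (background/CSF and normal tissue).

Lesions are voxelised ellipsoids planted strictly inside WM with exact
voxel counts (candidate voxels ranked by ellipsoidal radius), so planted
volumes are accurate to one voxel.  The 1-voxel in-plane rim of each lesion
is assigned to the GM probability map rather than WM, mimicking the
systematic misclassification of hyperintensities by T1-driven tissue
segmentation; partial volume is emulated by in-plane Gaussian blurring of
the hard tissue indicators.

Optional artifacts reproduce the two false-positive families the selection
stage must remove: a small bright spot in the cortical ribbon touching the
GM/CSF interface, and a large bright midline blob in the lowest slices
(brainstem-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Volume

__all__ = ["PhantomConfig", "PhantomCase", "generate_phantom", "phantom_suite"]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic case.

    Intensity means are in arbitrary FLAIR units with the required ordering
    ``gm_mu > wm_mu > csf_mu`` and ``lesion_mu > gm_mu``.  The implied
    contrast parameter is roughly ``(gm_mu - wm_mu) / 2`` (mean central-
    difference response across the GM/WM step), so the default lesion
    contrast ``lesion_mu - wm_mu = 45`` is about 3-4 lambda.
    ``lesion_volume_ml`` is the total planted load, split over ``n_lesions``
    lesions of equal volume.
    """

    shape: tuple = (96, 96, 20)
    spacing: tuple = (0.9375, 0.9375, 5.5)
    background_mu: float = 0.0
    csf_mu: float = 10.0
    gm_mu: float = 124.0
    wm_mu: float = 100.0
    lesion_mu: float = 145.0
    noise_sigma: float = 2.0
    n_lesions: int = 2
    lesion_volume_ml: float = 2.0
    lesion_placement: str = "deep"  # "deep" | "periventricular" | "mixed"
    lesion_gm_rim: bool = True
    cortical_artifact: bool = False
    brainstem_artifact: bool = False
    bias_amplitude: float = 0.0  # fractional low-order multiplicative bias
    prob_blur_sigma: float = 1.0  # in-plane voxels, partial-volume emulation
    seed: int = 0

    def __post_init__(self):
        if not (self.gm_mu > self.wm_mu > self.csf_mu):
            raise ValueError("require gm_mu > wm_mu > csf_mu")
        if self.n_lesions > 0 and not self.lesion_mu > self.gm_mu:
            raise ValueError("require lesion_mu > gm_mu")
        if self.lesion_placement not in ("deep", "periventricular", "mixed"):
            raise ValueError(f"unknown placement {self.lesion_placement!r}")
        if min(self.shape) < 8:
            raise ValueError("phantom too small")


@dataclass
class PhantomCase:
    """One generated case: images, probability maps and ground truth."""

    mflair: Volume
    m_gm: Volume
    m_wm: Volume
    m_csf: Volume
    wm_mni: Volume
    msp: BinaryMask
    truth_mask: BinaryMask
    config: PhantomConfig
    #: hard anatomical masks, useful for fixtures (wm includes lesions)
    anatomy: dict = field(default_factory=dict, repr=False)


def _anatomy_masks(shape):
    """Hard tissue compartments: background(0)/CSF(1)/GM(2)/WM(3)."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    a0, b0 = 0.46 * nx, 0.40 * ny          # outer head semi-axes, voxels
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    tissue = np.zeros(shape, dtype=np.uint8)
    vent = np.zeros(shape, dtype=bool)
    for k in range(nz):
        scale = np.sqrt(max(0.25, 1.0 - ((k - cz) / (0.75 * nz)) ** 2))
        a, b = a0 * scale, b0 * scale
        r = np.sqrt(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2)
        head = r <= 1.0
        csf_shell = head & (r > 1.0 - 2.0 / b)
        gm_ring = head & ~csf_shell & (r > 1.0 - 5.0 / b)
        wm = head & ~csf_shell & ~gm_ring
        va, vb = max(3.0, 10.0 * scale), max(2.0, 6.0 * scale)
        vr = np.sqrt(((x - cx) / va) ** 2 + ((y - cy) / vb) ** 2)
        v = (vr <= 1.0) & wm
        sl = tissue[:, :, k]
        sl[csf_shell] = 1
        sl[gm_ring] = 2
        sl[wm & ~v] = 3
        sl[v] = 1
        vent[:, :, k] = v
        # posterior interhemispheric groove: 2-voxel-wide CSF channel along
        # the midline connecting the ventricles to the outer shell
        mid = int(round(cx))
        groove_cols = [mid - 1, mid]
        for col in groove_cols:
            ys = np.nonzero((y.ravel() > cy + vb - 1) & (sl[col, :] != 0))[0]
            sl[col, ys] = 1
    return tissue, vent


def _place_lesions(tissue, vent, config, rng, exclude=None):
    """Voxel-exact ellipsoidal lesions strictly inside WM.

    Returns the boolean truth mask.  A lesion that cannot be placed at its
    requested size is split into two half-volume lesions; an unplaceable
    minimal lesion raises.  ``exclude`` marks voxels lesions must avoid
    (e.g. the neighbourhood of planted artifacts, so lesions and artifacts
    stay separate structures).
    """
    shape = tissue.shape
    voxvol = float(np.prod(config.spacing))
    truth = np.zeros(shape, dtype=bool)
    if config.n_lesions == 0 or config.lesion_volume_ml <= 0:
        return truth
    wm = tissue == 3
    if exclude is not None:
        wm = wm & ~exclude
    # keep a one-voxel in-plane WM margin around every lesion so the
    # partial-volume blur of the rim cannot leak into GM/CSF territory
    from .core import CROSS_IN_PLANE_3D
    wm_margin = ndimage.binary_erosion(wm, structure=CROSS_IN_PLANE_3D)
    per_lesion = config.lesion_volume_ml / config.n_lesions
    queue = [per_lesion] * config.n_lesions
    modes = []
    for i in range(len(queue)):
        if config.lesion_placement == "mixed":
            modes.append("deep" if i % 2 == 0 else "periventricular")
        else:
            modes.append(config.lesion_placement)
    near_vent = ndimage.binary_dilation(vent, iterations=6)
    while queue:
        vol_ml = queue.pop(0)
        mode = modes.pop(0) if modes else "deep"
        n_target = max(1, int(round(vol_ml * 1000.0 / voxvol)))
        placed = _place_one(truth, wm_margin, near_vent, n_target, mode,
                            rng, shape)
        if not placed:
            if n_target <= 2:
                raise ValueError(
                    f"cannot place a {vol_ml:.3f} mL lesion inside WM")
            queue.extend([vol_ml / 2.0, vol_ml / 2.0])
            modes.extend([mode, mode])
    return truth


def _place_one(truth, wm, near_vent, n_target, mode, rng, shape):
    """Try to place one lesion of exactly ``n_target`` voxels; returns
    success."""
    # ellipsoid semi-axes in voxels: oblate, thin along the (thick) slice
    # axis; solve (4/3) pi r^2 (0.35 r) = n for the in-plane radius r
    r = max(1.0, (n_target * 3.0 / (4.0 * np.pi * 0.35)) ** (1.0 / 3.0))
    rz = max(0.75, 0.35 * r)
    free = wm & ~ndimage.binary_dilation(truth, iterations=2)
    # clearance: centre must be at least (r, r, rz) from anything non-free,
    # approximated with an anisotropic Euclidean distance transform
    edt = ndimage.distance_transform_edt(free, sampling=(1.0, 1.0, r / rz))
    allowed = edt > r
    # hemispheric WM only: a lesion may not cross the mid-sagittal plane
    # (in vivo the interhemispheric fissure separates the hemispheres)
    mid = shape[0] // 2
    xdist = np.abs(np.arange(shape[0]) - mid)
    allowed &= (xdist > r)[:, None, None]
    if mode == "periventricular":
        pv = allowed & near_vent
        if pv.any():
            allowed = pv
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        return False
    c = np.unravel_index(idx[rng.integers(idx.size)], shape)
    # rank candidate voxels by ellipsoidal radius, take exactly n_target
    ri = int(np.ceil(r)) + 1
    rzi = int(np.ceil(rz)) + 1
    x0, x1 = max(0, c[0] - ri), min(shape[0], c[0] + ri + 1)
    y0, y1 = max(0, c[1] - ri), min(shape[1], c[1] + ri + 1)
    z0, z1 = max(0, c[2] - rzi), min(shape[2], c[2] + rzi + 1)
    gx, gy, gz = np.mgrid[x0:x1, y0:y1, z0:z1]
    rho = (((gx - c[0]) / r) ** 2 + ((gy - c[1]) / r) ** 2
           + ((gz - c[2]) / rz) ** 2)
    ok = wm[x0:x1, y0:y1, z0:z1] & ~truth[x0:x1, y0:y1, z0:z1]
    # hemispheric WM: no lesion voxel within 4 voxels of the mid-sagittal
    # plane.  A narrower corridor of WM between a lesion and the midline
    # CSF groove has no watershed minimum of its own and floods from the
    # lesion basin, which would make the region cross the plane and be
    # (correctly, per the rule) removed as a brainstem false positive.
    ok &= np.abs(gx - mid) >= 4
    rho = np.where(ok, rho, np.inf)
    flat = np.argsort(rho, axis=None, kind="stable")[:n_target]
    # voxels blocked inside the nominal ellipsoid may be replaced by nearby
    # ones, but only up to 1.5x the nominal radius (rho is squared)
    if flat.size < n_target or not np.all(rho.ravel()[flat] <= 2.25):
        return False
    sub = np.zeros(rho.shape, dtype=bool)
    sub.ravel()[flat] = True
    truth[x0:x1, y0:y1, z0:z1] |= sub
    return True


def _lesion_rim_inplane(truth):
    """1-voxel in-plane border of each lesion cross-section; empty where the
    in-plane erosion would remove the whole cross-section."""
    from .core import CROSS_2D
    rim = np.zeros_like(truth)
    for k in range(truth.shape[2]):
        sl = truth[:, :, k]
        if not sl.any():
            continue
        core = ndimage.binary_erosion(sl, structure=CROSS_2D)
        lab, n = ndimage.label(sl, structure=CROSS_2D)
        for rid in range(1, n + 1):
            reg = lab == rid
            reg_core = reg & core
            if reg_core.any():
                rim[:, :, k] |= reg & ~reg_core
    return rim


def _cortical_artifact_mask(tissue, rng):
    """Small (< 20 voxel) bright spot spanning the cortical ribbon thickness
    in one mid-stack slice, touching the GM/CSF interface."""
    shape = tissue.shape
    k = shape[2] // 2
    gm = tissue[:, :, k] == 2
    csf = tissue[:, :, k] == 1
    from .core import CROSS_2D
    outer_edge = gm & ndimage.binary_dilation(csf, structure=CROSS_2D)
    idx = np.argwhere(outer_edge)
    # deterministic pick away from the midline groove
    mid = shape[0] // 2
    idx = idx[np.abs(idx[:, 0] - mid) > 6]
    if idx.size == 0:
        return np.zeros(shape, dtype=bool)
    c = idx[rng.integers(len(idx))]
    x = np.arange(shape[0])[:, None]
    y = np.arange(shape[1])[None, :]
    disk = ((x - c[0]) ** 2 + (y - c[1]) ** 2) <= 2.3 ** 2
    spot = disk & gm
    out = np.zeros(shape, dtype=bool)
    if 0 < spot.sum() < 20:
        out[:, :, k] = spot
    return out


def _brainstem_artifact_mask(tissue, config):
    """Large (> 50 voxel per slice) bright blob crossing the mid-sagittal
    plane in the two lowest slices, inside WM."""
    shape = tissue.shape
    out = np.zeros(shape, dtype=bool)
    mid = shape[0] // 2
    cy = (shape[1] - 1) / 2.0
    x = np.arange(shape[0])[:, None]
    y = np.arange(shape[1])[None, :]
    disk = ((x - mid) ** 2 + (y - (cy - 14)) ** 2) <= 5.2 ** 2
    for k in (0, 1):
        blob = disk & (tissue[:, :, k] == 3)
        if blob.sum() > 50:
            out[:, :, k] = blob
    return out


def _soft_maps(indicators, sigma):
    """In-plane Gaussian blur of tissue indicator weights (partial-volume
    emulation).  The weights sum to at most one per voxel, so the blurred
    maps do too."""
    out = []
    for ind in indicators:
        sm = ndimage.gaussian_filter(np.asarray(ind, dtype=np.float64),
                                     sigma=(sigma, sigma, 0.0))
        out.append(np.clip(sm, 0.0, 1.0))
    return out


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one fully deterministic phantom case from its config."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    tissue, vent = _anatomy_masks(shape)

    # artifacts first: lesions are then kept clear of them, so each planted
    # false positive remains its own structure rather than fusing with a
    # genuine lesion
    cortical = (_cortical_artifact_mask(tissue, rng)
                if config.cortical_artifact else np.zeros(shape, dtype=bool))
    brainstem = (_brainstem_artifact_mask(tissue, config)
                 if config.brainstem_artifact else np.zeros(shape, dtype=bool))
    exclude = None
    if cortical.any() or brainstem.any():
        exclude = ndimage.binary_dilation(cortical | brainstem, iterations=5)
    truth = _place_lesions(tissue, vent, config, rng, exclude=exclude)

    mu = np.full(shape, config.background_mu)
    mu[tissue == 1] = config.csf_mu
    mu[tissue == 2] = config.gm_mu
    mu[tissue == 3] = config.wm_mu
    mu[truth] = config.lesion_mu
    mu[cortical] = config.lesion_mu
    mu[brainstem] = config.lesion_mu

    img = mu + rng.normal(0.0, config.noise_sigma, size=shape)
    if config.bias_amplitude > 0:
        nx, ny, nz = shape
        xs = np.linspace(-1, 1, nx)[:, None, None]
        ys = np.linspace(-1, 1, ny)[None, :, None]
        zs = np.linspace(-1, 1, nz)[None, None, :]
        bias = 1.0 + config.bias_amplitude * (0.5 * xs + 0.3 * ys
                                              + 0.2 * zs - 0.3 * xs * ys)
        img = img * bias
    img = np.clip(img, 0.0, None)

    # tissue indicators for the probability maps; half of the probability
    # mass of the lesion in-plane rim goes to GM (emulated partial-volume
    # misclassification of hyperintensities by T1-driven segmentation,
    # which tends to label lesion borders as GM).  The split keeps the
    # blurred WM probability above 0.5 on the rim, so the ground truth
    # stays inside the binarised WM map.
    wm_ind = (tissue == 3).astype(np.float64)
    gm_ind = (tissue == 2).astype(np.float64)
    csf_ind = (tissue == 1).astype(np.float64)
    if config.lesion_gm_rim and truth.any():
        rim = _lesion_rim_inplane(truth)
        wm_ind[rim] = 0.5
        gm_ind[rim] += 0.5
    p_csf, p_gm, p_wm = _soft_maps([csf_ind, gm_ind, wm_ind],
                                   config.prob_blur_sigma)

    affine = np.diag([config.spacing[0], config.spacing[1],
                      config.spacing[2], 1.0])
    vol = lambda d: Volume(data=d, affine=affine)

    wm_mni = ndimage.gaussian_filter((tissue == 3).astype(np.float64),
                                     sigma=(2.0, 2.0, 0.0))
    msp = np.zeros(shape, dtype=bool)
    msp[shape[0] // 2, :, :] = True

    mflair = vol(img)
    return PhantomCase(
        mflair=mflair,
        m_gm=vol(p_gm),
        m_wm=vol(p_wm),
        m_csf=vol(p_csf),
        wm_mni=vol(np.clip(wm_mni, 0, 1)),
        msp=BinaryMask(data=msp, grid=mflair),
        truth_mask=BinaryMask(data=truth, grid=mflair),
        config=config,
        anatomy={"tissue": tissue, "ventricles": vent,
                 "cortical_artifact": cortical,
                 "brainstem_artifact": brainstem},
    )


def phantom_suite(n_cases: int, seed: int = 0,
                  base_config: PhantomConfig = None):
    """A deterministic suite of cases spanning lesion loads.

    Loads are log-spaced from 0.5 to 80 mL (covering small to very large
    clinical lesion burdens); noise and lesion contrast vary across cases;
    every other case carries both planted artifacts so the false-positive
    filters are exercised.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    base = base_config or PhantomConfig()
    loads = np.geomspace(0.5, 80.0, n_cases)
    sigmas = [1.5, 2.0, 2.5]
    lesion_mus = [142.0, 145.0, 150.0]
    cases = []
    for i, load in enumerate(loads):
        cfg = replace(
            base,
            lesion_volume_ml=float(load),
            n_lesions=int(np.clip(np.ceil(load / 8.0), 1, 10)),
            noise_sigma=sigmas[i % len(sigmas)],
            lesion_mu=lesion_mus[i % len(lesion_mus)],
            lesion_placement="mixed",
            cortical_artifact=(i % 2 == 0),
            brainstem_artifact=(i % 2 == 0),
            seed=(seed * 10007 + i) % (2 ** 31 - 1),
        )
        cases.append(generate_phantom(cfg))
    return cases
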