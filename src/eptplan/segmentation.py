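"""Automatic tissue segmentation.

Implements the automatic extraction methods the planning pipeline relies on:

* liver on CT — two-stage: a rough core found as the connected component
  holding the maximum of the Euclidean distance map of the soft-tissue band,
  refined with a region-based active contour;
* liver on MRI — region growing from a seed, adaptive-threshold cleanup,
  active-contour refinement;
* hepatic vessels — multiscale Hessian tubularity filtering restricted to
  the liver mask, followed by local thresholding around high-response seeds;
* bone on CT — global thresholding with morphological cleanup;
* canine brain on MRI — central-slice detection by connected-component
  analysis of eroded slices, then overlap-driven propagation to neighbours.

Tumors are deliberately not segmented automatically; they enter through the
manual contour path (:mod:`eptplan.contour_model`).

All algorithms are deterministic. Parameter values are package defaults
tuned on the synthetic phantoms, exposed via the params dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.segmentation import flood, morphological_chan_vese

from .core import ImageVolume, LabelMask

__all__ = [
    "VesselnessParams",
    "CTLiverParams",
    "MRILiverParams",
    "VesselParams",
    "BoneParams",
    "BrainParams",
    "segment_liver_ct",
    "segment_liver_mri",
    "frangi_vesselness",
    "segment_vessels",
    "segment_bone_ct",
    "segment_canine_brain",
    "find_central_brain_slice",
]


# ---------------------------------------------------------------------------
# parameter bundles


@dataclass
class VesselnessParams:
    """Multiscale tubularity filter settings (Hessian-eigenvalue based)."""

    scales_mm: Sequence[float] = (1.0, 2.0, 3.0)
    alpha: float = 0.5
    beta: float = 0.5
    c: float = 70.0  # structure-noise scale, in intensity units
    bright_on_dark: bool = True

    def __post_init__(self):
        s = list(self.scales_mm)
        if any(v <= 0 for v in s) or s != sorted(s):
            raise ValueError("scales must be ascending and positive")
        if min(self.alpha, self.beta, self.c) <= 0:
            raise ValueError("alpha, beta, c must be > 0")


@dataclass
class CTLiverParams:
    soft_tissue_band: Tuple[float, float] = (0.0, 200.0)
    active_contour_iters: int = 30
    smoothing: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0


@dataclass
class MRILiverParams:
    grow_tolerance: float = 120.0
    adaptive_window_mm: float = 30.0
    adaptive_offset: float = 60.0  # subtracted from the local mean
    active_contour_iters: int = 20
    smoothing: int = 1


@dataclass
class VesselParams:
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    seed_quantile: float = 0.995
    min_seed_response: float = 0.05
    neighborhood_mm: float = 4.0
    k_sd: float = -0.5  # local threshold = mean + k_sd * sd


@dataclass
class BoneParams:
    threshold_hu: float = 250.0
    closing_radius_mm: float = 2.0
    min_component_mm3: float = 500.0


@dataclass
class BrainParams:
    erosion_radius_mm: float = 4.0
    threshold: Optional[float] = None  # None → Otsu on the whole stack
    min_overlap: float = 0.3  # fraction of candidate component overlapping previous


# ---------------------------------------------------------------------------
# helpers


def _ball(radius_vox: Sequence[float]) -> np.ndarray:
    """Anisotropic ellipsoidal structuring element, radius per axis in voxels."""
    r = np.maximum(np.asarray(radius_vox, dtype=float), 1e-6)
    shape = (2 * np.ceil(r) + 1).astype(int)
    grids = np.meshgrid(*[np.arange(s) - s // 2 for s in shape], indexing="ij")
    return sum((g / rr) ** 2 for g, rr in zip(grids, r)) <= 1.0


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary)
    if n == 0:
        return binary
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _as_mask(binary, name, spacing) -> LabelMask:
    return LabelMask(binary.astype(np.int16), {1: name}, spacing=spacing)


# ---------------------------------------------------------------------------
# liver


def segment_liver_ct(vol: ImageVolume, params: CTLiverParams = None) -> LabelMask:
    """Two-stage CT liver extraction.

    Stage 1: threshold the soft-tissue HU band, take the Euclidean distance
    map of the candidate foreground and keep the connected component that
    contains the global distance maximum — the deepest soft-tissue body.
    Stage 2: refine the boundary with a region-based active contour
    initialized from stage 1. Returns a single 3D-connected component.
    """
    if vol.modality != "CT":
        raise ValueError("segment_liver_ct requires a CT volume")
    params = params or CTLiverParams()
    lo, hi = params.soft_tissue_band
    band = (vol.voxels >= lo) & (vol.voxels <= hi)
    if not band.any():
        raise ValueError("no liver candidate: soft-tissue band is empty")
    dist = ndimage.distance_transform_edt(band, sampling=vol.spacing)
    peak = np.unravel_index(np.argmax(dist), dist.shape)
    lab, _ = ndimage.label(band)
    core = lab == lab[peak]

    refined = morphological_chan_vese(
        vol.voxels, num_iter=params.active_contour_iters, init_level_set=core,
        smoothing=params.smoothing, lambda1=params.lambda1, lambda2=params.lambda2,
    ).astype(bool)
    # the active contour may latch onto other bright structures (bone, skin);
    # restrict to the vicinity of the soft-tissue band and keep the liver body
    allowed = ndimage.binary_dilation(band, iterations=2)
    refined = _largest_component(refined & allowed)
    if not refined.any():
        refined = core
    refined = ndimage.binary_fill_holes(refined)
    refined = _largest_component(refined)
    return _as_mask(refined, "liver", vol.spacing)


def segment_liver_mri(vol: ImageVolume, seed, params: MRILiverParams = None) -> LabelMask:
    """MRI liver extraction: region growing → adaptive threshold → active
    contour. The result is the connected component containing the seed."""
    if vol.modality != "MRI":
        raise ValueError("segment_liver_mri requires an MRI volume")
    params = params or MRILiverParams()
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, vol.shape)):
        raise IndexError(f"seed {seed} outside volume of shape {vol.shape}")

    grown = flood(vol.voxels, seed, tolerance=params.grow_tolerance)
    border = np.zeros_like(grown)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    leakage = grown[border].mean() > 0.5
    if leakage:
        import warnings

        warnings.warn("region growing leaked to >50% of the volume border")
        # refinement on a leaked region is meaningless; return the grown
        # component as-is so the caller can re-seed
        return _as_mask(grown, "liver", vol.spacing)

    # adaptive cleanup: keep voxels above a locally-windowed mean
    win = tuple(
        max(3, int(round(params.adaptive_window_mm / s)) | 1) for s in vol.spacing
    )
    local_mean = ndimage.uniform_filter(vol.voxels, size=win)
    cleaned = grown & (vol.voxels >= local_mean - params.adaptive_offset)
    cleaned = ndimage.binary_fill_holes(cleaned)
    if not cleaned[seed]:
        cleaned = grown

    refined = morphological_chan_vese(
        vol.voxels, num_iter=params.active_contour_iters, init_level_set=cleaned,
        smoothing=params.smoothing,
    ).astype(bool)
    refined = ndimage.binary_fill_holes(refined)
    lab, n = ndimage.label(refined)
    if n and lab[seed] > 0:
        result = lab == lab[seed]
    else:  # refinement lost the seed; fall back to the grown region
        result = ndimage.binary_fill_holes(cleaned)
        lab, n = ndimage.label(result)
        result = lab == lab[seed] if n and lab[seed] else result
    result = result.copy()
    result[seed] = True  # postcondition: output contains the seed voxel
    return _as_mask(result, "liver", vol.spacing)


# ---------------------------------------------------------------------------
# vesselness


def frangi_vesselness(vol: ImageVolume, vp: VesselnessParams = None) -> np.ndarray:
    """Multiscale Hessian tubularity response in [0, 1].

    Per scale σ the image is Gaussian-smoothed, the scale-normalized Hessian
    (γ = 2) is assembled, eigenvalues are sorted by magnitude
    |λ1| ≤ |λ2| ≤ |λ3|, and the response is::

        0                                                   if λ2 > 0 or λ3 > 0
        (1 − exp(−RA²/2α²)) · exp(−RB²/2β²) · (1 − exp(−S²/2c²))   otherwise

    with RA = |λ2|/|λ3|, RB = |λ1|/sqrt(|λ2 λ3|), S = sqrt(λ1²+λ2²+λ3²)
    (bright structures on dark background; the sign test flips for
    dark-on-bright). The final response is the maximum over scales.
    """
    vp = vp or VesselnessParams()
    img = np.asarray(vol.voxels, dtype=np.float64)
    if not vp.bright_on_dark:
        img = -img
    # remove the DC offset: the Hessian is offset-invariant analytically, but
    # the truncated derivative kernels leak a residual proportional to it
    img = img - img.mean()
    spacing = np.asarray(vol.spacing)
    response = np.zeros_like(img)
    for sigma_mm in vp.scales_mm:
        sigma_vox = sigma_mm / spacing
        H = np.empty(img.shape + (3, 3))
        for a in range(3):
            for b in range(a, 3):
                order = [0, 0, 0]
                order[a] += 1
                order[b] += 1
                d = ndimage.gaussian_filter(img, sigma=sigma_vox, order=order)
                # convert voxel-index derivatives to mm derivatives and
                # apply γ=2 scale normalization
                d *= sigma_mm ** 2 / (spacing[a] * spacing[b])
                H[..., a, b] = d
                H[..., b, a] = d
        lam = np.linalg.eigvalsh(H)  # ascending by value
        idx = np.argsort(np.abs(lam), axis=-1)
        lam = np.take_along_axis(lam, idx, axis=-1)
        l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]

        eps = 1e-10
        ra2 = (l2 / (l3 + np.where(l3 >= 0, eps, -eps))) ** 2
        rb2 = l1 ** 2 / (np.abs(l2 * l3) + eps)
        s2 = l1 ** 2 + l2 ** 2 + l3 ** 2
        v = (
            (1.0 - np.exp(-ra2 / (2 * vp.alpha ** 2)))
            * np.exp(-rb2 / (2 * vp.beta ** 2))
            * (1.0 - np.exp(-s2 / (2 * vp.c ** 2)))
        )
        v[(l2 > 0) | (l3 > 0)] = 0.0
        response = np.maximum(response, v)
    return np.clip(response, 0.0, 1.0)


def segment_vessels(vol: ImageVolume, liver: LabelMask,
                    params: VesselParams = None) -> LabelMask:
    """Hepatic vessel extraction inside the liver mask.

    Tubularity is computed on the liver region only; voxels whose response
    exceeds a high quantile seed the vessels; the final mask collects voxels
    in a neighborhood of the seeds whose intensity passes a locally computed
    threshold (mean + k·sd over the seed neighborhood). Result ⊆ liver.
    """
    params = params or VesselParams()
    liver_bin = liver.labels > 0
    if not liver_bin.any():
        raise ValueError("empty liver mask")

    masked = ImageVolume(
        np.where(liver_bin, vol.voxels, np.median(vol.voxels[liver_bin])),
        spacing=vol.spacing, origin=vol.origin, modality=vol.modality,
    )
    resp = frangi_vesselness(masked, params.vesselness)
    resp[~liver_bin] = 0.0

    inside = resp[liver_bin]
    cut = max(float(np.quantile(inside, params.seed_quantile)),
              params.min_seed_response)
    seeds = resp >= cut
    if not seeds.any():
        return _as_mask(np.zeros(vol.shape, dtype=bool), "vessel", vol.spacing)

    r_vox = [max(1, int(round(params.neighborhood_mm / s))) for s in vol.spacing]
    neighborhood = ndimage.binary_dilation(seeds, structure=_ball(r_vox))
    neighborhood &= liver_bin

    seed_vals = vol.voxels[seeds]
    thr = float(seed_vals.mean() + params.k_sd * seed_vals.std())
    vessels = neighborhood & (vol.voxels >= thr)
    vessels &= liver_bin
    return _as_mask(vessels, "vessel", vol.spacing)


# ---------------------------------------------------------------------------
# bone


def segment_bone_ct(vol: ImageVolume, params: BoneParams = None) -> LabelMask:
    """Threshold-based bone extraction with morphological cleanup."""
    if vol.modality != "CT":
        raise ValueError("segment_bone_ct requires a CT volume")
    params = params or BoneParams()
    binary = vol.voxels >= params.threshold_hu
    if binary.any():
        r_vox = [max(1, int(round(params.closing_radius_mm / s))) for s in vol.spacing]
        binary = ndimage.binary_closing(binary, structure=_ball(r_vox))
        lab, n = ndimage.label(binary)
        if n:
            min_vox = params.min_component_mm3 / vol.voxel_volume_mm3()
            sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                       index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_vox) + 1
            binary = np.isin(lab, keep)
    return _as_mask(binary, "bone", vol.spacing)


# ---------------------------------------------------------------------------
# canine brain


def _brain_foreground(vol: ImageVolume, params: BrainParams) -> np.ndarray:
    if params.threshold is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vol.voxels))
    else:
        thr = float(params.threshold)
    return vol.voxels >= thr


def find_central_brain_slice(vol: ImageVolume, params: BrainParams = None):
    """Central slice = slice whose largest eroded component has maximal area.

    Returns ``(index, per-slice largest eroded components, per-slice areas)``.
    """
    params = params or BrainParams()
    r_vox = [max(1, int(round(params.erosion_radius_mm / s))) for s in vol.spacing[:2]]
    selem = _ball(r_vox)
    fg = _brain_foreground(vol, params)
    nz = vol.shape[2]
    eroded_largest = []
    areas = np.zeros(nz)
    for k in range(nz):
        er = ndimage.binary_erosion(fg[:, :, k], structure=selem)
        lab, n = ndimage.label(er)
        if n == 0:
            eroded_largest.append(np.zeros(vol.shape[:2], dtype=bool))
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        comp = lab == (1 + int(np.argmax(sizes)))
        eroded_largest.append(comp)
        areas[k] = comp.sum()
    if areas.max() == 0:
        raise ValueError("no component found on any slice")
    return int(np.argmax(areas)), eroded_largest, areas


def segment_canine_brain(vol: ImageVolume, params: BrainParams = None) -> LabelMask:
    """Morphology-driven brain extraction from an MRI slice stack.

    Each slice is thresholded and eroded; the central slice is the one whose
    largest eroded component has maximal area. That component (dilated back)
    seeds the brain; the mask is propagated slice-by-slice outward, keeping
    on each neighbour the components that overlap the previous slice's mask
    by at least ``min_overlap`` of their area.
    """
    if vol.shape[2] < 5:
        raise ValueError("brain extraction needs at least 5 slices")
    params = params or BrainParams()
    r_vox = [max(1, int(round(params.erosion_radius_mm / s))) for s in vol.spacing[:2]]
    selem = _ball(r_vox)
    nz = vol.shape[2]
    fg = _brain_foreground(vol, params)
    central, eroded_largest, _ = find_central_brain_slice(vol, params)

    result = np.zeros(vol.shape, dtype=bool)
    result[:, :, central] = ndimage.binary_dilation(
        eroded_largest[central], structure=selem
    ) & fg[:, :, central]

    for direction in (1, -1):
        prev = result[:, :, central]
        k = central + direction
        while 0 <= k < nz:
            er = ndimage.binary_erosion(fg[:, :, k], structure=selem)
            lab, n = ndimage.label(er)
            keep = np.zeros(vol.shape[:2], dtype=bool)
            for comp_id in range(1, n + 1):
                comp = lab == comp_id
                overlap = (comp & prev).sum() / comp.sum()
                if overlap >= params.min_overlap:
                    keep |= comp
            if not keep.any():
                break
            slice_mask = ndimage.binary_dilation(keep, structure=selem) & fg[:, :, k]
            result[:, :, k] = slice_mask
            prev = slice_mask
            k += direction
    return _as_mask(result, "brain", vol.spacing)
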