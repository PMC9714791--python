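"""Inclusion-spot quantification in two-channel fluorescence images.

Pipeline: sliding-parabola background removal on the nuclear channel,
nuclei detection with an area floor, spot segmentation on a texture
(spot-enhancement) image with size / intensity / ring-contrast filters,
nuclear vs extranuclear assignment, and density per mm^2.

All images are processed as floating point normalized to [0, 1]; the
texture threshold applies to the [0, 1]-normalized texture response.
"""
from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "ImagePair",
    "SpotRecord",
    "to_float01",
    "remove_background",
    "detect_nuclei",
    "spot_texture",
    "segment_spots",
    "spot_density",
]


def to_float01(image: np.ndarray) -> np.ndarray:
    """Cast to float in [0, 1]: integer images by their dtype range,
    float images rescaled by their maximum when it exceeds 1."""
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    img = img.astype(float)
    peak = img.max() if img.size else 0.0
    if peak > 1.0:
        img = img / peak
    return np.clip(img, 0.0, None)


@dataclasses.dataclass(frozen=True)
class ImagePair:
    """Aligned nuclear-stain and aggregate-stain channels."""

    dapi: np.ndarray
    spot_channel: np.ndarray
    pixel_size_um: float = 0.32

    def __post_init__(self) -> None:
        if np.asarray(self.dapi).shape != np.asarray(self.spot_channel).shape:
            raise ValueError("channel shapes must match")
        if np.asarray(self.dapi).ndim != 2:
            raise ValueError("images must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclasses.dataclass(frozen=True)
class SpotRecord:
    centroid: Tuple[float, float]  # (row, col)
    area_px: int
    mean_intensity: float
    ring_contrast: float
    is_nuclear: bool


def _parabolic_morph(img: np.ndarray, coeff: float, half_width: int, erode: bool) -> np.ndarray:
    """Separable grayscale erosion/dilation with structuring function
    h(d) = coeff * d^2 (a 2-D parabola splits into two 1-D passes)."""
    out = img.copy()
    sign = 1.0 if erode else -1.0
    for axis in (0, 1):
        base = out.copy()
        for d in range(1, half_width + 1):
            h = coeff * d * d
            fwd = np.roll(base, d, axis=axis)
            bwd = np.roll(base, -d, axis=axis)
            # replicate edges instead of wrapping
            sl_f = [slice(None)] * 2
            sl_f[axis] = slice(0, d)
            sl_b = [slice(None)] * 2
            sl_b[axis] = slice(-d, None)
            edge_f = [slice(None)] * 2
            edge_f[axis] = slice(0, 1)
            edge_b = [slice(None)] * 2
            edge_b[axis] = slice(-1, None)
            fwd[tuple(sl_f)] = base[tuple(edge_f)]
            bwd[tuple(sl_b)] = base[tuple(edge_b)]
            if erode:
                out = np.minimum(out, np.minimum(fwd, bwd) + sign * h)
            else:
                out = np.maximum(out, np.maximum(fwd, bwd) + sign * h)
    return out


def remove_background(image: np.ndarray, curvature: float = 6.0) -> np.ndarray:
    """Subtract a slowly varying background estimated by a sliding
    (morphological opening with a) parabola.

    The parabola height is (d / (25 * curvature))^2 on the normalized
    intensity scale, so larger curvature settings give a wider, flatter
    probe.  Output is nonnegative.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("remove_background expects a 2-D image")
    if not curvature > 0:
        raise ValueError("curvature must be > 0")
    f = to_float01(img)
    span = float(f.max() - f.min())
    if span == 0.0:
        return np.zeros_like(f)
    coeff = 1.0 / (25.0 * curvature) ** 2
    half_width = int(np.ceil(np.sqrt(span / coeff)))
    half_width = max(1, min(half_width, max(f.shape)))
    background = _parabolic_morph(_parabolic_morph(f, coeff, half_width, erode=True), coeff, half_width, erode=False)
    return np.clip(f - background, 0.0, None)


def detect_nuclei(dapi: np.ndarray, min_area: int = 200) -> np.ndarray:
    """Label mask of nuclei: Otsu threshold, hole filling, connected
    components, and removal of components smaller than ``min_area``."""
    img = to_float01(np.asarray(dapi))
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a 2-D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= min_area)
    relabel = np.zeros(sizes.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1)
    return relabel[labels]


def spot_texture(spot_channel: np.ndarray, scale_px: float = 3.0) -> np.ndarray:
    """Spot-enhancement response at the given scale, normalized to [0, 1].

    Implemented as a scale-normalized center-surround (negated Laplacian
    of Gaussian) operator — a documented stand-in for the proprietary
    texture filter whose thresholds this pipeline reuses.  Bright
    blob-like structures of roughly ``scale_px`` width respond maximally.
    """
    if scale_px < 1:
        raise ValueError("scale_px must be >= 1")
    img = to_float01(np.asarray(spot_channel))
    if img.ndim != 2:
        raise ValueError("spot_texture expects a 2-D image")
    raw = ndi.gaussian_laplace(img, sigma=scale_px)
    # the truncated discrete kernel has a tiny DC gain; remove it so a
    # flat image maps to an exactly flat (zero) response
    dc = ndi.gaussian_laplace(np.ones_like(img), sigma=scale_px)
    response = -(scale_px**2) * (raw - img * dc)
    response = np.clip(response, 0.0, None)
    peak = response.max()
    if peak <= 1e-8:  # flat image up to numerical noise
        return np.zeros_like(response)
    return response / peak


def _ring_mean(raw: np.ndarray, spot_mask_all: np.ndarray, region, ring_width: int) -> float:
    sl = region.slice
    pad = ring_width + 1
    r0 = max(sl[0].start - pad, 0)
    r1 = min(sl[0].stop + pad, raw.shape[0])
    c0 = max(sl[1].start - pad, 0)
    c1 = min(sl[1].stop + pad, raw.shape[1])
    crop_mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    rr = region.coords[:, 0] - r0
    cc = region.coords[:, 1] - c0
    crop_mask[rr, cc] = True
    dilated = ndi.binary_dilation(crop_mask, iterations=ring_width)
    ring = dilated & ~spot_mask_all[r0:r1, c0:c1]
    vals = raw[r0:r1, c0:c1][ring]
    if vals.size == 0:
        return 0.0
    return float(vals.mean())


def segment_spots(
    pair: ImagePair,
    nuclei_mask: Optional[np.ndarray] = None,
    texture_cut: float = 0.2,
    min_area: int = 5,
    intensity_factor: float = 2.0,
    ring_factor: float = 1.3,
    ring_width: int = 4,
    texture_scale_px: float = 3.0,
) -> List[SpotRecord]:
    """Segment aggregate spots and apply the four retention filters.

    Candidates are connected components of texture > ``texture_cut``.
    A candidate is kept iff its area is >= ``min_area`` px, its mean
    raw intensity is >= ``intensity_factor`` times the global mean of
    the unfiltered spot channel, and its mean intensity is at least
    ``ring_factor``-fold the mean of a ``ring_width``-px-wide ring
    around it (other candidate spots excluded from the ring).  A spot is
    nuclear iff its centroid falls inside the nuclei mask.
    """
    raw = to_float01(np.asarray(pair.spot_channel))
    texture = spot_texture(raw, scale_px=texture_scale_px)
    candidate = texture > texture_cut
    labels = cc_label(candidate)
    if labels.max() == 0:
        return []
    global_mean = float(raw.mean())
    records: List[SpotRecord] = []
    for region in regionprops(labels, intensity_image=raw):
        if region.area < min_area:
            continue
        mean_int = float(region.intensity_mean)
        if mean_int < intensity_factor * global_mean:
            continue
        ring_mean = _ring_mean(raw, candidate, region, ring_width)
        ring_contrast = mean_int / ring_mean if ring_mean > 0 else np.inf
        if ring_contrast < ring_factor:
            continue
        cy, cx = region.centroid
        is_nuclear = False
        if nuclei_mask is not None:
            iy = int(np.clip(round(cy), 0, raw.shape[0] - 1))
            ix = int(np.clip(round(cx), 0, raw.shape[1] - 1))
            is_nuclear = bool(nuclei_mask[iy, ix] > 0)
        records.append(
            SpotRecord(
                centroid=(float(cy), float(cx)),
                area_px=int(region.area),
                mean_intensity=mean_int,
                ring_contrast=float(ring_contrast),
                is_nuclear=is_nuclear,
            )
        )
    return records


def spot_density(
    spots: Sequence[SpotRecord],
    region_mask: np.ndarray,
    pixel_size_um: float = 0.32,
) -> dict:
    """Nuclear / extranuclear / total spot densities per mm^2 of region."""
    area_px = int(np.count_nonzero(region_mask))
    if area_px == 0:
        raise ValueError("region mask has zero area")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    area_mm2 = area_px * (pixel_size_um * 1e-3) ** 2
    n_nuc = sum(1 for s in spots if s.is_nuclear)
    n_ext = len(spots) - n_nuc
    return {
        "n_nuclear": n_nuc,
        "n_extranuclear": n_ext,
        "n_total": len(spots),
        "area_mm2": area_mm2,
        "nuclear_per_mm2": n_nuc / area_mm2,
        "extranuclear_per_mm2": n_ext / area_mm2,
        "total_per_mm2": len(spots) / area_mm2,
    }
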