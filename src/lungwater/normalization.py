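"""Coil-shading normalization.

The surface-coil sensitivity multiplies the true water density by a smooth,
unknown positive field. To remove it, all solid tissues surrounding the
lungs are fit with a low-spatial-frequency normalization map that is
interpolated over the full field of view, and the image is divided by the
map. Because every solid tissue carries (by convention) 100 % water density,
the divided image is directly in units of relative lung water density with
the composite solid-tissue reference at 100 %.

The map fit is a masked smoothing-by-diffusion: values outside the solid
mask are iteratively in-painted by Gaussian low-pass passes at the
configured spatial-frequency cutoff, which extrapolates the solid-tissue
signal smoothly through the lungs and the air background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError, SegmentationError
from .grids import LWD_PERCENT, VoxelGrid

#: default spatial-frequency cutoff of the map fit (1/mm)
DEFAULT_CUTOFF = 1.0 / 60.0


@dataclass
class NormalizationMap:
    """Low-spatial-frequency fit of the solid-tissue signal."""

    field: np.ndarray
    cutoff: float  # 1/mm
    spacing: float  # mm

    def __post_init__(self) -> None:
        if self.field.min() <= 0:
            raise ParameterError("normalization map must be strictly positive")


def build_body_mask(volume: VoxelGrid, threshold_frac: float = 0.25) -> np.ndarray:
    """Binary body mask: threshold, fill holes, keep largest component.

    Raises :class:`SegmentationError` when no plausible body is found (for
    example on an all-air volume).
    """
    data = volume.data
    p99 = np.percentile(data, 99)
    candidate = data > threshold_frac * p99
    if not candidate.any():
        raise SegmentationError("no above-threshold voxels; cannot find the body")
    labeled, n = ndimage.label(candidate)
    if n == 0:
        raise SegmentationError("no connected body component")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    body = labeled == (int(np.argmax(sizes)) + 1)
    # close thin chest-wall gaps so the lungs are true holes, then fill
    n_close = max(1, int(round(6.0 / volume.spacing)))
    body = ndimage.binary_closing(body, iterations=n_close, border_value=0)
    body = ndimage.binary_fill_holes(body)
    if body.sum() < 0.05 * data.size:
        raise SegmentationError("largest component too small to be a torso")
    return body


def build_solid_mask(
    volume: VoxelGrid,
    body_mask: np.ndarray | None = None,
    ratio_threshold: float = 0.75,
    erosion_mm: float = 5.0,
    smooth_mm: float = 25.0,
    edge_keep_frac: float = 0.90,
) -> np.ndarray:
    """Mask of high-signal solid tissue, excluding air and lung parenchyma.

    Voxels are compared against a locally smoothed body signal so the
    decision is insensitive to coil shading. The mask is then eroded to
    avoid partial-volume edges, but edge voxels whose signal matches the
    local solid reference (within ``edge_keep_frac``) are reinstated: only
    genuinely partial-volume-depressed voxels stay excluded.
    """
    if body_mask is None:
        body_mask = build_body_mask(volume)
    data = volume.data
    sigma = smooth_mm / volume.spacing
    w = ndimage.gaussian_filter(body_mask.astype(float), sigma, mode="nearest")
    s = ndimage.gaussian_filter(data * body_mask, sigma, mode="nearest")
    local = np.divide(s, w, out=np.zeros_like(s), where=w > 1e-9)
    solid = body_mask & (data > ratio_threshold * local)
    if not solid.any():
        raise SegmentationError("no solid-tissue voxels found")

    n_erode = max(1, int(round(erosion_mm / volume.spacing)))
    eroded = ndimage.binary_erosion(solid, iterations=n_erode, border_value=0)
    ws = ndimage.gaussian_filter(solid.astype(float), sigma, mode="nearest")
    ss = ndimage.gaussian_filter(data * solid, sigma, mode="nearest")
    solid_local = np.divide(ss, ws, out=np.zeros_like(ss), where=ws > 1e-9)
    confident = solid & (data > edge_keep_frac * solid_local)
    solid = eroded | confident
    if not solid.any():
        raise SegmentationError("solid mask empty after erosion")
    return solid


def fit_normalization_map(
    volume: VoxelGrid,
    solid_mask: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    n_iter: int = 40,
) -> NormalizationMap:
    """Fit the low-spatial-frequency map to the solid-tissue signal.

    Iterative in-painting: masked values are kept, unmasked values replaced
    by the previous smooth estimate, and the composite is Gaussian low-pass
    filtered. The filter sigma is a quarter wavelength at the cutoff.
    """
    if solid_mask is None or not np.asarray(solid_mask).any():
        raise InputError("solid mask is empty")
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    data = volume.data
    mask = solid_mask.astype(bool)
    sigma = (0.25 / cutoff) / volume.spacing
    fieldval = np.full(data.shape, float(data[mask].mean()))
    for _ in range(n_iter):
        composite = np.where(mask, data, fieldval)
        fieldval = ndimage.gaussian_filter(composite, sigma, mode="nearest")
    fieldval = np.maximum(fieldval, 1e-9)
    return NormalizationMap(field=fieldval, cutoff=cutoff, spacing=volume.spacing)


def normalize(
    volume: VoxelGrid,
    nmap: NormalizationMap,
    clip: tuple[float, float] | None = (0.0, 120.0),
) -> VoxelGrid:
    """Divide by the normalization map, yielding relative LWD in percent.

    Noise can produce nonphysical values after division; by default the
    output is clipped to [0, 120] %. Pass ``clip=None`` to disable.
    """
    if nmap.field.shape != volume.shape:
        raise ParameterError("normalization map shape mismatch")
    if nmap.field.min() <= 0:
        raise ParameterError("normalization map must be strictly positive")
    lwd = 100.0 * volume.data / nmap.field
    if clip is not None:
        lwd = np.clip(lwd, clip[0], clip[1])
    return volume.with_data(lwd, units=LWD_PERCENT)
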