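"""Lung water metrics: LWD, lung volume, LWV, LWVi."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .grids import VoxelGrid
from .segmentation import lung_volume


@dataclass
class LungWaterResult:
    """Per-volume lung water metrics.

    lwv = (lwd / 100) · lung_volume holds exactly by definition;
    lwvi = lwv / bsa.
    """

    subject_id: str
    lwd: float  # %
    lung_volume: float  # mL
    lwv: float  # mL
    lwvi: float  # mL/m^2


def compute_lwd(lwd_volume: VoxelGrid, mask: np.ndarray) -> float:
    """Mean LWD (%) over the lung-parenchyma mask."""
    if not np.asarray(mask).any():
        raise InputError("empty lung mask")
    return float(lwd_volume.data[mask].mean())


def compute_lwv(lwd_volume: VoxelGrid, mask: np.ndarray, spacing: float) -> float:
    """Total lung water volume (mL): sum of per-voxel density x voxel volume."""
    if not np.asarray(mask).any():
        raise InputError("empty lung mask")
    vox_ml = spacing**3 / 1000.0
    return float(lwd_volume.data[mask].sum() / 100.0 * vox_ml)


def compute_lwvi(lwv: float, bsa: float) -> float:
    """LWV indexed to body surface area (mL/m^2)."""
    if not bsa > 0:
        raise ParameterError("BSA must be > 0")
    return lwv / bsa


def measure_lung_water(
    lwd_volume: VoxelGrid, mask: np.ndarray, bsa: float, subject_id: str = ""
) -> LungWaterResult:
    """All metrics for one normalized volume and lung mask."""
    vol = lung_volume(mask, lwd_volume.spacing)
    lwd = compute_lwd(lwd_volume, mask)
    lwv = compute_lwv(lwd_volume, mask, lwd_volume.spacing)
    return LungWaterResult(
        subject_id=subject_id,
        lwd=lwd,
        lung_volume=vol,
        lwv=lwv,
        lwvi=compute_lwvi(lwv, bsa),
    )
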