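"""Region-growing lung segmentation on the normalized volume.

Seeds are the two largest low-intensity connected components inside the
body; growth is 6-connected over voxels below the growth threshold, so the
grown region is exactly the seeds' connected components. Conduit vessels
(high-density tubes) are excluded, one-voxel holes closed, and small
components discarded. Because segmentation runs on the normalized volume it
is insensitive to coil shading.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .grids import VoxelGrid

#: 6-connectivity structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def segment_lungs(
    lwd_volume: VoxelGrid,
    body_mask: np.ndarray,
    grow_threshold: float = 70.0,
    vessel_threshold: float = 85.0,
    min_component_ml: float = 10.0,
    min_density_floor: float | None = None,
) -> np.ndarray:
    """Binary lung-parenchyma mask, excluding large vessels.

    Parameters
    ----------
    lwd_volume
        Normalized volume in percent LWD.
    body_mask
        Torso mask; lungs are sought strictly inside it.
    grow_threshold
        Region grows into voxels with LWD below this value (%). Healthy and
        congested parenchyma sit well below, blood near 100 %.
    vessel_threshold
        Voxels at or above this LWD (%) inside the grown region are removed
        as conduit vessels.
    min_component_ml
        Connected components smaller than this are discarded.
    min_density_floor
        Optional lower density bound (%); voxels below it (airways) are
        removed. Off by default.
    """
    data = lwd_volume.data
    vox_ml = lwd_volume.voxel_volume_ml
    candidate = body_mask & (data < grow_threshold)
    if not candidate.any():
        raise SegmentationError("no low-intensity seed region inside the body")

    labeled, n = ndimage.label(candidate, structure=_STRUCT6)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [int(i) + 1 for i in order[:2] if sizes[i] * vox_ml >= min_component_ml]
    if not keep:
        raise SegmentationError("no seed component above the minimum size")
    mask = np.isin(labeled, keep)

    # fill <=1-voxel holes, then drop vessels that survived
    mask = ndimage.binary_closing(mask, structure=_STRUCT6, iterations=1)
    mask &= data < vessel_threshold
    mask &= body_mask
    if min_density_floor is not None:
        mask &= data >= min_density_floor

    labeled, n = ndimage.label(mask, structure=_STRUCT6)
    if n == 0:
        raise SegmentationError("lung mask empty after vessel exclusion")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    big = np.flatnonzero(sizes * vox_ml >= min_component_ml) + 1
    if big.size == 0:
        raise SegmentationError("all lung components below the minimum size")
    return np.isin(labeled, big)


def lung_volume(mask: np.ndarray, spacing: float) -> float:
    """Total volume of the voxels in the lung mask, mL."""
    return float(np.count_nonzero(mask)) * spacing**3 / 1000.0


def save_overlay(lwd_volume: VoxelGrid, mask: np.ndarray, path) -> None:
    """QC figure: central coronal slice of the masked LWD map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    j = lwd_volume.shape[1] // 2
    sl = lwd_volume.data[:, j, :].T
    msk = mask[:, j, :].T
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].imshow(sl, origin="lower", cmap="gray")
    axes[0].set_title("normalized volume")
    masked = np.where(msk, sl, np.nan)
    axes[1].imshow(sl, origin="lower", cmap="gray")
    im = axes[1].imshow(masked, origin="lower", cmap="viridis", vmin=0, vmax=60)
    axes[1].set_title("masked LWD (%)")
    fig.colorbar(im, ax=axes[1], shrink=0.8)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
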