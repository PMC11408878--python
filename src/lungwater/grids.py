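"""Core in-memory containers for image-space data.

The package works on isotropic 3D scalar fields. Array axes are ordered
``(x, y, z)`` = (right-left, anterior-posterior, foot-head) and volumes are
written to NIfTI with an RAS affine built from the spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

#: unit tags carried by a VoxelGrid
SIGNAL_AU = "signal_au"
LWD_PERCENT = "lwd_percent"


class Tissue(IntEnum):
    """Integer labels of the digital-thorax tissue classes."""

    AIR = 0
    LUNG = 1
    VESSEL = 2
    LIVER = 3
    HEART = 4
    MUSCLE = 5
    FAT = 6
    OTHER_SOLID = 7


#: classes counted as solid water-density reference tissue (assigned 100%)
SOLID_TISSUES = (
    Tissue.VESSEL,
    Tissue.LIVER,
    Tissue.HEART,
    Tissue.MUSCLE,
    Tissue.FAT,
    Tissue.OTHER_SOLID,
)


@dataclass
class VoxelGrid:
    """3D scalar field with isotropic spacing.

    Parameters
    ----------
    data
        3D array; signal in arbitrary units or relative lung water density
        in percent, as tagged by ``units``.
    spacing
        Isotropic voxel edge length in mm.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``.
    units
        One of ``"signal_au"`` or ``"lwd_percent"``.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = SIGNAL_AU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 8:
            raise ParameterError("VoxelGrid requires a 3D array of shape >= (8, 8, 8)")
        if not self.spacing > 0:
            raise ParameterError(f"spacing must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("VoxelGrid data must be finite")
        if self.units not in (SIGNAL_AU, LWD_PERCENT):
            raise ParameterError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in mL."""
        return self.spacing**3 / 1000.0

    def copy(self) -> "VoxelGrid":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VoxelGrid":
        """New grid with identical geometry but different values."""
        return VoxelGrid(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            units=self.units if units is None else units,
        )

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header["descrip"] = f"units={self.units}".encode()
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, units: str | None = None) -> "VoxelGrid":
        img = nib.load(str(path))
        aff = img.affine
        spacing = float(aff[0, 0])
        if units is None:
            descrip = bytes(img.header["descrip"]).decode(errors="ignore")
            units = LWD_PERCENT if LWD_PERCENT in descrip else SIGNAL_AU
        return cls(
            data=np.asarray(img.get_fdata(), dtype=np.float64),
            spacing=spacing,
            origin=tuple(aff[:3, 3]),
            units=units,
        )


@dataclass
class TissueLabelMap:
    """Integer-labelled volume on the same grid as a paired :class:`VoxelGrid`."""

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ParameterError("TissueLabelMap requires a 3D array")
        if self.labels.max(initial=0) > max(Tissue):
            raise ParameterError("unknown tissue label present")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing**3 / 1000.0

    def mask(self, *tissues: Tissue) -> np.ndarray:
        """Boolean mask of the union of the given tissue classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for t in tissues:
            out |= self.labels == int(t)
        return out

    def volume_ml(self, *tissues: Tissue) -> float:
        return float(self.mask(*tissues).sum()) * self.voxel_volume_ml

    def save(self, path) -> None:
        aff = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), aff), str(path))

    @classmethod
    def load(cls, path) -> "TissueLabelMap":
        img = nib.load(str(path))
        aff = img.affine
        return cls(
            labels=np.asarray(img.get_fdata(), dtype=np.uint8),
            spacing=float(aff[0, 0]),
            origin=tuple(aff[:3, 3]),
        )


@dataclass
class NavigatorTrace:
    """Respiratory navigator samples across the repeated acquisitions.

    ``displacement`` is an arbitrary-unit diaphragm-position surrogate; by
    package convention larger displacement means more expired (diaphragm
    higher), so end-expiration sits at the trace maximum.
    """

    times_ms: np.ndarray
    displacement: np.ndarray
    repeat_index: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.repeat_index = np.asarray(self.repeat_index, dtype=np.int64)
        n = self.times_ms.size
        if self.displacement.size != n or self.repeat_index.size != n or n == 0:
            raise InputError("navigator arrays must be non-empty and equal length")
        if np.any(np.diff(self.times_ms) <= 0):
            raise InputError("navigator times must be strictly increasing")

    @property
    def n_repeats(self) -> int:
        return int(self.repeat_index.max()) + 1

    def samples_for(self, repeat: int) -> np.ndarray:
        return self.displacement[self.repeat_index == repeat]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "displacement": self.displacement,
                "repeat_index": self.repeat_index,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "NavigatorTrace":
        df = pd.read_csv(path)
        return cls(
            times_ms=df["time_ms"].to_numpy(),
            displacement=df["displacement"].to_numpy(),
            repeat_index=df["repeat_index"].to_numpy(),
        )


@dataclass
class GridSpec:
    """Physical extent and resolution of the simulation grid.

    The default 2.5 mm spacing matches the interpolated resolution of the
    acquisition the phantom emulates; coarser spacings trade accuracy for
    speed and are used throughout the test-suite.
    """

    spacing: float = 2.5
    fov_mm: tuple[float, float, float] = (420.0, 320.0, 360.0)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ParameterError("spacing must be > 0")
        if min(self.fov_mm) <= 0:
            raise ParameterError("field of view must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(f / self.spacing)) for f in self.fov_mm)  # type: ignore[return-value]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical coordinates (mm), centred on the grid."""
        nx, ny, nz = self.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        z = (np.arange(nz) - (nz - 1) / 2.0) * self.spacing
        return x[:, None, None], y[None, :, None], z[None, None, :]

    @property
    def origin(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        return (
            -(nx - 1) / 2.0 * self.spacing,
            -(ny - 1) / 2.0 * self.spacing,
            -(nz - 1) / 2.0 * self.spacing,
        )

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing**3 / 1000.0
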