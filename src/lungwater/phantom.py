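"""Procedural digital-thorax phantom.

Rasterizes a :class:`~lungwater.cohort.Subject` into a 3D proton-density
-weighted image series: a torso built from ellipsoids and tubes (muscle
interior, subcutaneous fat shell whose thickness grows with BMI, two lung
compartments cut by a flat diaphragm plane, heart, liver, spine, pulmonary
conduit vessels), multiplicative surface-coil shading, tidal respiratory
motion across repeated acquisitions, an explicit navigator displacement
trace, and additive Gaussian noise.

Water density convention: lungs carry the subject's ground-truth LWD (%),
every solid tissue carries 100 %, air carries 0. The lateral lung semi-axes
are solved by bisection so the lung label volume at end-expiration matches
the subject's ground-truth lung volume on the actual voxel grid.

Respiratory model: the navigator displacement is an arbitrary-unit surrogate
of diaphragm position, larger = more expired. During inspiration the
diaphragm plane (and the liver below it) drops by ``amplitude − d``,
enlarging the lungs, so lung volume varies inversely with diaphragm
elevation and is minimal at end-expiration (functional residual capacity).
Each repeat is a snapshot of the anatomy at the mean displacement over that
repeat's navigator samples, which are acquired in a burst centred in the
repeat's time window. Motion is simulated in image space; there is no
k-space model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import Subject
from .errors import GeometryError, ParameterError
from .grids import (
    LWD_PERCENT,
    SIGNAL_AU,
    GridSpec,
    NavigatorTrace,
    Tissue,
    TissueLabelMap,
    VoxelGrid,
)

#: signal assigned to solid tissue (a.u.); equals the 100 % density reference
SOLID_SIGNAL = 100.0


@dataclass
class AcquisitionSpec:
    """Timing, motion, shading and noise parameters of a simulated scan."""

    n_repeats: int = 7
    total_duration_s: float = 84.0
    burst_s: float = 1.5  # navigator/imaging burst per repeat
    navigator_interval_ms: float = 108.0
    amplitude_mm: float = 12.0  # tidal diaphragm excursion
    resp_period_s: float = 5.0
    resp_phase: float = 0.0  # radians
    noise_sd: float = 2.0  # a.u.; 2 % of the solid-tissue signal
    shading_low: float = 0.6
    shading_high: float = 1.4
    shading_corr_length_mm: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")
        if self.amplitude_mm < 0:
            raise ParameterError("respiratory amplitude must be >= 0")
        if not 0 < self.shading_low <= self.shading_high:
            raise ParameterError("shading range must be positive and ordered")
        if self.total_duration_s <= 0 or self.burst_s <= 0 or self.resp_period_s <= 0:
            raise ParameterError("durations must be > 0")
        if self.burst_s > self.total_duration_s / self.n_repeats:
            raise ParameterError("burst longer than the per-repeat window")


class ThoraxModel:
    """Parametric anatomy of one subject on a fixed grid.

    Solves the lung size once at end-expiration and can then rasterize the
    anatomy at any diaphragm drop (mm below the end-expiratory plane).
    """

    def __init__(self, subject: Subject, grid: GridSpec):
        self.subject = subject
        self.grid = grid
        self._x, self._y, self._z = grid.coords()

        s_body = float(np.clip((subject.weight / 70.0) ** 0.4, 0.85, 1.25))
        self.a_in = 125.0 * s_body  # inner (muscle) torso semi-axes, mm
        self.b_in = 85.0 * s_body
        self.fat_thickness = float(np.clip(2.0 + 1.3 * (subject.bmi - 20.0), 4.0, 40.0))
        self.chest_wall_mm = 8.0  # minimum muscle between lung and fat shell

        # diaphragm plane at end-expiration; rises with BMI (reduced FRC)
        self.z_dia = -40.0 + 0.6 * (subject.bmi - 24.0)
        # cranio-caudal lung semi-axis grows weakly with the target volume
        v = subject.true_lung_volume
        self.lung_c = float(np.clip(60.0 * (v / 1800.0) ** (1 / 3) + 60.0, 90.0, 130.0))
        self.lung_zc = self.z_dia + 0.58 * self.lung_c
        self.lung_yc = -5.0

        # heart between the lungs, scaled with LVEDV
        s_heart = (subject.lvedv / 134.0) ** (1.0 / 3.0)
        self._heart = ((-30.0, 5.0, 5.0), (52.0 * s_heart, 48.0 * s_heart, 55.0 * s_heart))

        # a small rib cage cannot hold a large FRC volume: widen the torso
        # until the target fits (big lungs go with a big chest), else fail
        for _ in range(8):
            self._update_derived()
            self._check_fov()
            if self._lung_label_volume(self._max_lung_scale(), 0.0) >= v:
                break
            self.a_in *= 1.06
            self.b_in *= 1.06
        else:
            raise GeometryError(f"cannot fit {v:.0f} mL lungs inside the torso")

        self.lung_scale = self._solve_lung_scale()

    def _update_derived(self) -> None:
        self.a_out = self.a_in + self.fat_thickness
        self.b_out = self.b_in + self.fat_thickness
        self._lung_ab0 = (0.32 * self.a_in, 0.62 * self.b_in)
        self.lung_xc = 0.50 * self.a_in

    def _check_fov(self) -> None:
        if self.a_out + self.grid.spacing > self.grid.fov_mm[0] / 2 or \
           self.b_out + self.grid.spacing > self.grid.fov_mm[1] / 2:
            raise GeometryError(
                f"torso (semi-axes {self.a_out:.0f}x{self.b_out:.0f} mm) does not "
                f"fit the {self.grid.fov_mm} mm field of view"
            )

    def _max_lung_scale(self) -> float:
        """Bisection upper bound; the chest-wall margin clips the mask anyway."""
        return 3.0

    def _chest_cavity(self) -> np.ndarray:
        """Inner body shrunk by the chest-wall margin; lungs stay inside it."""
        a = self.a_in - self.chest_wall_mm
        b = self.b_in - self.chest_wall_mm
        m = ((self._x / a) ** 2 + (self._y / b) ** 2) <= 1.0
        return np.broadcast_to(m, self.grid.shape)

    # -- geometry primitives --------------------------------------------
    def _ellipsoid(self, center, semi) -> np.ndarray:
        cx, cy, cz = center
        a, b, c = semi
        return (
            ((self._x - cx) / a) ** 2
            + ((self._y - cy) / b) ** 2
            + ((self._z - cz) / c) ** 2
        ) <= 1.0

    def _inner_body(self) -> np.ndarray:
        m = ((self._x / self.a_in) ** 2 + (self._y / self.b_in) ** 2) <= 1.0
        return np.broadcast_to(m, self.grid.shape)

    def _outer_body(self) -> np.ndarray:
        m = ((self._x / self.a_out) ** 2 + (self._y / self.b_out) ** 2) <= 1.0
        return np.broadcast_to(m, self.grid.shape)

    def _heart_mask(self) -> np.ndarray:
        return self._ellipsoid(*self._heart)

    def _vessel_mask(self, lung: np.ndarray) -> np.ndarray:
        """Conduit vessels: tubes running laterally into each lung."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for sign in (-1.0, 1.0):
            for zc, radius in ((40.0, 7.0), (5.0, 5.0)):
                tube = (
                    ((self._y - self.lung_yc) ** 2 + (self._z - zc) ** 2)
                    <= radius**2
                ) & (sign * self._x >= 0) & (sign * self._x <= self.lung_xc + 20.0)
                m |= tube
        return m & lung

    def _lung_mask(self, scale: float, diaphragm_drop: float) -> np.ndarray:
        a0, b0 = self._lung_ab0
        a, b = a0 * scale, b0 * scale
        plane = self.z_dia - diaphragm_drop
        lungs = np.zeros(self.grid.shape, dtype=bool)
        for sign in (-1.0, 1.0):
            lungs |= self._ellipsoid(
                (sign * self.lung_xc, self.lung_yc, self.lung_zc),
                (a, b, self.lung_c),
            )
        lungs &= self._z >= plane
        lungs &= self._chest_cavity()
        lungs &= ~self._heart_mask()
        return lungs

    def _lung_label_volume(self, scale: float, drop: float) -> float:
        lungs = self._lung_mask(scale, drop)
        lungs &= ~self._vessel_mask(lungs)
        return float(lungs.sum()) * self.grid.voxel_volume_ml

    def _solve_lung_scale(self) -> float:
        target = self.subject.true_lung_volume
        lo, hi = 0.3, self._max_lung_scale()
        if self._lung_label_volume(hi, 0.0) < target:
            raise GeometryError(
                f"cannot fit {target:.0f} mL lungs inside the torso"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if self._lung_label_volume(mid, 0.0) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # -- rasterization ---------------------------------------------------
    def rasterize(self, diaphragm_drop: float = 0.0) -> tuple[TissueLabelMap, VoxelGrid]:
        """Label map and ground-truth density grid at a given diaphragm drop."""
        if diaphragm_drop < 0:
            raise ParameterError("diaphragm drop must be >= 0")
        g = self.grid
        labels = np.zeros(g.shape, dtype=np.uint8)
        outer = self._outer_body()
        inner = self._inner_body()
        labels[outer] = Tissue.FAT
        labels[inner] = Tissue.MUSCLE

        spine = np.broadcast_to(
            (self._x**2 + (self._y - 0.80 * self.b_in) ** 2) <= 16.0**2,
            g.shape,
        ) & inner
        labels[spine] = Tissue.OTHER_SOLID

        plane = self.z_dia - diaphragm_drop
        liver = self._ellipsoid(
            (55.0, 0.0, plane - 55.0), (80.0, 70.0, 60.0)
        ) & inner & (self._z < plane)
        labels[liver] = Tissue.LIVER

        lungs = self._lung_mask(self.lung_scale, diaphragm_drop)
        labels[lungs] = Tissue.LUNG

        heart = self._heart_mask() & inner
        labels[heart] = Tissue.HEART

        vessels = self._vessel_mask(lungs)
        labels[vessels] = Tissue.VESSEL

        density = np.where(
            labels == Tissue.LUNG,
            self.subject.true_lwd,
            np.where(labels == Tissue.AIR, 0.0, SOLID_SIGNAL),
        )
        lmap = TissueLabelMap(labels, spacing=g.spacing, origin=g.origin)
        dgrid = VoxelGrid(density, spacing=g.spacing, origin=g.origin, units=LWD_PERCENT)
        return lmap, dgrid


def rasterize_subject(
    subject: Subject, grid: GridSpec | None = None, diaphragm_drop: float = 0.0
) -> tuple[TissueLabelMap, VoxelGrid]:
    """Rasterize a subject at end-expiration (or a given diaphragm drop)."""
    return ThoraxModel(subject, grid or GridSpec()).rasterize(diaphragm_drop)


def make_shading_field(
    grid: GridSpec,
    low: float = 0.6,
    high: float = 1.4,
    corr_length_mm: float = 60.0,
    seed: int = 0,
) -> VoxelGrid:
    """Smooth, strictly positive multiplicative coil-sensitivity field.

    A seeded band-limited random field (white noise low-passed at the
    correlation length) plus an anterior-posterior linear trend, rescaled to
    ``[low, high]``.
    """
    if not 0 < low <= high:
        raise ParameterError("shading bounds must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    sigma_vox = corr_length_mm / grid.spacing
    smooth = gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    _, y, _ = grid.coords()
    raw = smooth + 1.5 * (y / (grid.fov_mm[1] / 2)) * np.ones(grid.shape)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        fielddata = np.full(grid.shape, 0.5 * (low + high))
    else:
        fielddata = low + (raw - lo) * (high - low) / (hi - lo)
    return VoxelGrid(fielddata, spacing=grid.spacing, origin=grid.origin, units=SIGNAL_AU)


def apply_coil_shading(volume: VoxelGrid, shading: VoxelGrid) -> VoxelGrid:
    """Voxelwise product of a volume with a strictly positive shading field."""
    if shading.shape != volume.shape:
        raise ParameterError("shading field shape mismatch")
    if shading.data.min() <= 0:
        raise ParameterError("shading field must be strictly positive")
    return volume.with_data(volume.data * shading.data, units=SIGNAL_AU)


@dataclass
class BreathingSeries:
    """Output of :func:`simulate_breathing`: one signal volume per repeat."""

    repeats: list[VoxelGrid]
    label_maps: list[TissueLabelMap]
    trace: NavigatorTrace
    displacements: np.ndarray  # per-repeat snapshot displacement (a.u. = mm)
    shading: VoxelGrid | None = None


def simulate_breathing(
    subject: Subject,
    grid: GridSpec,
    spec: AcquisitionSpec,
    shading: VoxelGrid | None = None,
    model: ThoraxModel | None = None,
) -> BreathingSeries:
    """Simulate the repeated free-breathing acquisition of one subject.

    Navigator displacement d(t) = A·(1 + cos(2π t/T + φ))/2 ∈ [0, A]; each
    repeat's anatomy is frozen at the mean displacement over its navigator
    burst, with the diaphragm dropped by ``A − d`` (fully dropped at
    end-inspiration, at the end-expiratory baseline when d = A). Gaussian
    noise is added independently per repeat.
    """
    model = model or ThoraxModel(subject, grid)
    rng = np.random.default_rng(spec.seed)

    window = spec.total_duration_s / spec.n_repeats
    times_all: list[np.ndarray] = []
    repeat_idx: list[np.ndarray] = []
    disp_all: list[np.ndarray] = []
    snapshots = np.zeros(spec.n_repeats)

    def d_of_t(t_s: np.ndarray) -> np.ndarray:
        if spec.amplitude_mm == 0:
            return np.zeros_like(t_s)
        return spec.amplitude_mm * 0.5 * (
            1.0 + np.cos(2.0 * math.pi * t_s / spec.resp_period_s + spec.resp_phase)
        )

    for r in range(spec.n_repeats):
        center = (r + 0.5) * window
        t0 = center - spec.burst_s / 2.0
        n_samples = max(1, int(spec.burst_s * 1000.0 / spec.navigator_interval_ms))
        t = t0 + np.arange(n_samples) * spec.navigator_interval_ms / 1000.0
        d = d_of_t(t)
        times_all.append(t * 1000.0)
        repeat_idx.append(np.full(n_samples, r, dtype=int))
        disp_all.append(d)
        snapshots[r] = float(d.mean())

    trace = NavigatorTrace(
        times_ms=np.concatenate(times_all),
        displacement=np.concatenate(disp_all),
        repeat_index=np.concatenate(repeat_idx),
    )

    repeats: list[VoxelGrid] = []
    label_maps: list[TissueLabelMap] = []
    for r in range(spec.n_repeats):
        drop = spec.amplitude_mm - snapshots[r]
        lmap, density = model.rasterize(diaphragm_drop=drop)
        signal = density.data.copy()
        if shading is not None:
            if shading.data.min() <= 0:
                raise ParameterError("shading field must be strictly positive")
            signal = signal * shading.data
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape) \
            if spec.noise_sd > 0 else signal
        repeats.append(
            VoxelGrid(signal, spacing=grid.spacing, origin=grid.origin, units=SIGNAL_AU)
        )
        label_maps.append(lmap)

    return BreathingSeries(
        repeats=repeats,
        label_maps=label_maps,
        trace=trace,
        displacements=snapshots,
        shading=shading,
    )
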