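"""Shared fixtures: a reference subject and its processed phantom.

Session-scoped so the (comparatively expensive) rasterization, breathing
simulation and normalization run once. Tests use 5 mm spacing throughout
for speed; spacing is a parameter everywhere in the package.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import lungwater as lw
from lungwater.cohort import Subject, compute_bsa, compute_gt
from lungwater.pipeline import AnalysisConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_subject(**overrides) -> Subject:
    """A typical reference subject; override any field."""
    height, weight = 1.72, 71.0
    base = dict(
        id="T0001",
        group="control",
        sex="M",
        age=50.0,
        height=height,
        weight=weight,
        bmi=weight / height**2,
        bsa=compute_bsa(height, weight),
        sbp=130.0,
        hypertension=False,
        diabetes=False,
        cad=False,
        nyha=1,
        lvm=90.0,
        lvedv=134.0,
        rvedv=140.0,
        ra_area=14.0,
        la_volume=75.0,
        gt=compute_gt(90.0, 134.0),
        gls=-18.0,
        native_t1=1020.0,
        ecv=25.5,
        true_lwd=30.0,
        true_lung_volume=1700.0,
    )
    base.update(overrides)
    if {"height", "weight"} & overrides.keys() and "bmi" not in overrides:
        base["bmi"] = base["weight"] / base["height"] ** 2
    return Subject(**base)


@pytest.fixture(scope="session")
def grid5() -> lw.GridSpec:
    return lw.GridSpec(spacing=5.0)


@pytest.fixture(scope="session")
def subject() -> Subject:
    return make_subject()


@pytest.fixture(scope="session")
def phantom(subject, grid5):
    model = lw.ThoraxModel(subject, grid5)
    lmap, dens = model.rasterize()
    return model, lmap, dens


@pytest.fixture(scope="session")
def shading(grid5) -> lw.VoxelGrid:
    return lw.make_shading_field(grid5, low=0.6, high=1.4, seed=11)


@pytest.fixture(scope="session")
def series(subject, grid5, shading, phantom):
    model, _, _ = phantom
    spec = lw.AcquisitionSpec(seed=21, resp_period_s=4.7, resp_phase=0.9)
    return lw.simulate_breathing(subject, grid5, spec, shading=shading, model=model)


@pytest.fixture(scope="session")
def frc(series) -> lw.VoxelGrid:
    return lw.select_frc_phase(series.repeats, series.trace, frc_fraction=0.3)


@pytest.fixture(scope="session")
def processed(frc):
    """Body mask, solid mask, normalization map, normalized volume, lung mask."""
    body = lw.build_body_mask(frc)
    solid = lw.build_solid_mask(frc, body_mask=body)
    nmap = lw.fit_normalization_map(frc, solid)
    lwd_vol = lw.normalize(frc, nmap)
    mask = lw.segment_lungs(lwd_vol, body)
    return {
        "body": body,
        "solid": solid,
        "nmap": nmap,
        "lwd_vol": lwd_vol,
        "mask": mask,
    }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0
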