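"""End-to-end orchestration: simulate -> gate -> normalize -> segment ->
quantify -> analyze, with a JSON config, per-run manifest and logging.

A single config seed fans out into independent per-subject substreams
(hash of seed + subject id), so any subject is reproducible on its own and
two runs with the same config are byte-identical in all CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .cohort import (
    CohortParams,
    Subject,
    cohort_to_frame,
    frame_to_cohort,
    sample_cohort,
)
from .errors import InputError
from .gating import select_frc_phase
from .grids import GridSpec, NavigatorTrace, VoxelGrid
from .metrics import LungWaterResult, measure_lung_water
from .normalization import (
    DEFAULT_CUTOFF,
    build_body_mask,
    build_solid_mask,
    fit_normalization_map,
    normalize,
)
from .phantom import (
    AcquisitionSpec,
    BreathingSeries,
    ThoraxModel,
    make_shading_field,
    simulate_breathing,
)
from .segmentation import segment_lungs
from .stats import (
    compare_groups,
    diagnostic_performance_at_cutoff,
    roc_youden,
    stepwise_multivariable,
    univariable_scan,
)

log = logging.getLogger("lungwater")

RESULT_COLUMNS = ["subject_id", "lwd", "lung_volume", "lwv", "lwvi"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
class GridConfig(BaseModel):
    spacing_mm: float = Field(2.5, gt=0)
    fov_mm: tuple[float, float, float] = (420.0, 320.0, 360.0)

    def to_spec(self) -> GridSpec:
        return GridSpec(spacing=self.spacing_mm, fov_mm=self.fov_mm)


class AcquisitionConfig(BaseModel):
    n_repeats: int = Field(7, ge=1)
    total_duration_s: float = Field(84.0, gt=0)
    burst_s: float = Field(1.5, gt=0)
    navigator_interval_ms: float = Field(108.0, gt=0)
    amplitude_mm: float = Field(12.0, ge=0)
    resp_period_mean_s: float = Field(5.0, gt=0)
    resp_period_jitter_s: float = Field(0.8, ge=0)
    noise_sd: float = Field(2.0, ge=0)
    shading_low: float = Field(0.6, gt=0)
    shading_high: float = Field(1.4, gt=0)
    shading_corr_length_mm: float = Field(60.0, gt=0)


class AnalysisConfig(BaseModel):
    frc_fraction: float = Field(0.3, gt=0, le=1)
    norm_cutoff_per_mm: float = Field(DEFAULT_CUTOFF, gt=0)
    grow_threshold: float = Field(70.0, gt=0)
    vessel_threshold: float = Field(85.0, gt=0)


class SimulateConfig(BaseModel):
    seed: int = 0
    n_control: int = Field(15, ge=0)
    n_risk: int = Field(155, ge=0)
    grid: GridConfig = GridConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_json_file(cls, path) -> "SimulateConfig":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except ValidationError as exc:
            raise InputError(f"invalid config: {exc}") from exc

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


def subject_seed(seed: int, subject_id: str) -> int:
    """Deterministic per-subject substream seed, below 2^31."""
    h = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# in-memory per-subject pipeline
# ---------------------------------------------------------------------------
def simulate_subject_series(
    subject: Subject,
    grid: GridSpec,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
) -> BreathingSeries:
    """Phantom + shading + breathing for one subject, seeded independently."""
    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(subject_seed(seed, subject.id))
    period = acq.resp_period_mean_s + rng.uniform(
        -acq.resp_period_jitter_s, acq.resp_period_jitter_s
    )
    spec = AcquisitionSpec(
        n_repeats=acq.n_repeats,
        total_duration_s=acq.total_duration_s,
        burst_s=acq.burst_s,
        navigator_interval_ms=acq.navigator_interval_ms,
        amplitude_mm=acq.amplitude_mm,
        resp_period_s=period,
        resp_phase=float(rng.uniform(0, 2 * math.pi)),
        noise_sd=acq.noise_sd,
        shading_low=acq.shading_low,
        shading_high=acq.shading_high,
        shading_corr_length_mm=acq.shading_corr_length_mm,
        seed=int(rng.integers(2**31)),
    )
    shading = make_shading_field(
        grid,
        low=acq.shading_low,
        high=acq.shading_high,
        corr_length_mm=acq.shading_corr_length_mm,
        seed=int(rng.integers(2**31)),
    )
    model = ThoraxModel(subject, grid)
    return simulate_breathing(subject, grid, spec, shading=shading, model=model)


def process_series(
    repeats: list[VoxelGrid],
    trace: NavigatorTrace,
    bsa: float,
    subject_id: str = "",
    analysis: AnalysisConfig | None = None,
) -> LungWaterResult:
    """Gate -> normalize -> segment -> quantify for one repeat series."""
    cfg = analysis or AnalysisConfig()
    frc = select_frc_phase(repeats, trace, frc_fraction=cfg.frc_fraction)
    body = build_body_mask(frc)
    solid = build_solid_mask(frc, body_mask=body)
    nmap = fit_normalization_map(frc, solid, cutoff=cfg.norm_cutoff_per_mm)
    lwd_vol = normalize(frc, nmap)
    mask = segment_lungs(
        lwd_vol,
        body,
        grow_threshold=cfg.grow_threshold,
        vessel_threshold=cfg.vessel_threshold,
    )
    return measure_lung_water(lwd_vol, mask, bsa, subject_id=subject_id)


def quantify_subject(
    subject: Subject,
    grid: GridSpec,
    acq: AcquisitionConfig | None = None,
    analysis: AnalysisConfig | None = None,
    seed: int = 0,
) -> LungWaterResult:
    """Convenience: simulate one subject and run the full estimation chain."""
    series = simulate_subject_series(subject, grid, acq, seed=seed)
    return process_series(
        series.repeats, series.trace, subject.bsa, subject.id, analysis
    )


# ---------------------------------------------------------------------------
# batch runners (file based)
# ---------------------------------------------------------------------------
def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: SimulateConfig, outdir) -> Path:
    """Write the cohort CSV, per-subject NIfTI repeat series and navigator
    CSVs, and a manifest with content hashes. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_log(outdir, config)

    params = CohortParams.default(seed=config.seed)
    subjects = sample_cohort(params, config.n_control, config.n_risk)
    cohort_csv = outdir / "cohort.csv"
    cohort_to_frame(subjects).to_csv(cohort_csv, index=False)
    (outdir / "cohort_params.json").write_text(params.to_json())
    (outdir / "config.json").write_text(config.model_dump_json(indent=2))

    grid = config.grid.to_spec()
    files: dict[str, str] = {}
    for rel in ("cohort.csv", "cohort_params.json", "config.json"):
        files[rel] = _sha256(outdir / rel)
    for subject in subjects:
        sdir = outdir / "subjects" / subject.id
        sdir.mkdir(parents=True, exist_ok=True)
        series = simulate_subject_series(
            subject, grid, config.acquisition, seed=config.seed
        )
        for r, vol in enumerate(series.repeats):
            p = sdir / f"repeat_{r:02d}.nii"
            vol.save(p)
            files[str(p.relative_to(outdir))] = _sha256(p)
        nav = sdir / "navigator.csv"
        series.trace.save(nav)
        files[str(nav.relative_to(outdir))] = _sha256(nav)
        log.info("simulated %s (%d repeats)", subject.id, len(series.repeats))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": dict(sorted(files.items())),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def run_quantify(indir, out_csv=None, analysis: AnalysisConfig | None = None) -> pd.DataFrame:
    """Quantify every simulated subject under ``indir``.

    Per-subject failures are recorded (column ``status``) without aborting
    the batch.
    """
    indir = Path(indir)
    cohort = pd.read_csv(indir / "cohort.csv")
    subjects = frame_to_cohort(cohort)
    rows = []
    for subject in subjects:
        sdir = indir / "subjects" / subject.id
        try:
            reps = sorted(sdir.glob("repeat_*.nii"))
            if not reps:
                raise InputError(f"no repeat volumes under {sdir}")
            nav = sdir / "navigator.csv"
            if not nav.exists():
                raise InputError(f"missing navigator file {nav}")
            repeats = [VoxelGrid.load(p) for p in reps]
            trace = NavigatorTrace.load(nav)
            res = process_series(repeats, trace, subject.bsa, subject.id, analysis)
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "lwd": res.lwd,
                    "lung_volume": res.lung_volume,
                    "lwv": res.lwv,
                    "lwvi": res.lwvi,
                    "status": "ok",
                }
            )
        except Exception as exc:  # per-subject isolation: record, keep going
            log.warning("subject %s failed: %s", subject.id, exc)
            rows.append(
                {
                    "subject_id": subject.id,
                    "lwd": np.nan,
                    "lung_volume": np.nan,
                    "lwv": np.nan,
                    "lwvi": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["status"])
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


#: covariate sets mirrored from the published regression tables
LWD_COVARIATES = [
    "age", "male_sex", "bmi", "bsa", "hypertension", "diabetes", "cad",
    "nyha", "sbp", "ra_area", "la_volume", "lavi", "lvedv", "rvedv",
    "lvm", "gt", "gls", "native_t1", "ecv", "lwv",
]
LWV_COVARIATES = [
    "age", "male_sex", "bmi", "bsa", "hypertension", "diabetes", "cad",
    "nyha", "sbp", "ra_area", "la_volume", "lavi", "lvedv", "rvedv",
    "lvm", "gt", "gls", "native_t1", "ecv",
]

TABLE1_CONTINUOUS = [
    "age", "sbp", "bsa", "bmi", "ra_area", "la_volume", "lvedv", "rvedv",
    "lvm", "gt", "gls", "lung_volume", "lwd", "lwv", "lwvi",
]


def run_analyze(
    results: pd.DataFrame | str,
    cohort: pd.DataFrame | str,
    outdir=None,
    cutoff: float | None = None,
) -> dict:
    """Cohort statistics on the joined per-subject results.

    Emits a group-comparison table, ROC/Youden summary with diagnostic
    performance at the selected (or overridden) cut-off, and univariable +
    stepwise regression tables for LWD and LWV.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.read_csv(results)
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    if "status" in results.columns:
        results = results[results["status"] == "ok"]
    orphans = set(results["subject_id"]) ^ set(cohort["id"])
    merged = cohort.merge(
        results.drop(columns=["status"], errors="ignore"),
        left_on="id",
        right_on="subject_id",
        how="inner",
    )
    if merged.empty:
        raise InputError(f"join produced no rows; orphan ids: {sorted(orphans)}")

    merged["male_sex"] = (merged["sex"] == "M").astype(float)
    merged["lavi"] = merged["la_volume"] / merged["bsa"]
    for col in ("hypertension", "diabetes", "cad"):
        merged[col] = merged[col].astype(float)

    # Table-1-style group comparisons on the estimated metrics + covariates
    table1_rows = []
    for var in TABLE1_CONTINUOUS:
        cmp = compare_groups(
            merged[var].to_numpy(), merged["group"].to_numpy(), "continuous", var
        )
        table1_rows.append(
            {"variable": var, "test": cmp.test_used, "p_value": cmp.p_value,
             **_flatten_summary(cmp.summaries)}
        )
    cmp_sex = compare_groups(
        merged["sex"].to_numpy(), merged["group"].to_numpy(), "categorical", "sex"
    )
    table1_rows.append(
        {"variable": "male_sex", "test": cmp_sex.test_used,
         "p_value": cmp_sex.p_value, **_flatten_summary(cmp_sex.summaries)}
    )
    table1 = pd.DataFrame(table1_rows)

    # ROC for estimated LWD: at-risk is the positive class
    labels = (merged["group"] == "at_risk").to_numpy()
    roc = roc_youden(merged["lwd"].to_numpy(), labels)
    used_cutoff = roc.youden_cutoff if cutoff is None else float(cutoff)
    perf = diagnostic_performance_at_cutoff(
        merged["lwd"].to_numpy(), labels, used_cutoff
    )
    roc_df = pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )

    reg_lwd = stepwise_multivariable(
        merged[LWD_COVARIATES + ["lwd"]], outcome="lwd"
    )
    reg_lwv = stepwise_multivariable(
        merged[LWV_COVARIATES + ["lwv"]], outcome="lwv"
    )

    report = {
        "schema_version": 1,
        "n": int(len(merged)),
        "groups": merged["group"].value_counts().to_dict(),
        "roc": {
            "auc": roc.auc,
            "auc_ci_95": list(roc.auc_ci_95),
            "youden_cutoff": roc.youden_cutoff,
            "youden_index": roc.youden_index,
            "cutoff_used": used_cutoff,
        },
        "diagnostic_performance": {
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "ppv": perf.ppv,
            "npv": perf.npv,
            "lr_pos": perf.lr_pos,
            "inv_lr_neg": perf.inv_lr_neg,
            "prevalence": perf.prevalence,
        },
        "lwd_regression": _regression_dict(reg_lwd),
        "lwv_regression": _regression_dict(reg_lwv),
        "group_means": {
            g: {
                "lwd": float(merged.loc[merged["group"] == g, "lwd"].mean()),
                "lwv": float(merged.loc[merged["group"] == g, "lwv"].mean()),
            }
            for g in merged["group"].unique()
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table1.to_csv(outdir / "table1_comparison.csv", index=False)
        roc_df.to_csv(outdir / "roc_curve.csv", index=False)
        reg_lwd.univariable.to_csv(outdir / "table2_lwd_univariable.csv")
        reg_lwd.retained.to_csv(outdir / "table2_lwd_multivariable.csv")
        reg_lwv.univariable.to_csv(outdir / "table4_lwv_univariable.csv")
        reg_lwv.retained.to_csv(outdir / "table4_lwv_multivariable.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _flatten_summary(summaries: dict) -> dict:
    out = {}
    for g, s in summaries.items():
        for k, v in s.items():
            out[f"{g}_{k}"] = v
    return out


def _regression_dict(reg) -> dict:
    return {
        "global_r2": reg.global_r2,
        "retained": {
            str(c): {
                "t": float(reg.retained.loc[c, "t"]),
                "p_value": float(reg.retained.loc[c, "p_value"]),
            }
            for c in reg.retained.index
        },
        "excluded_collinear": [list(pair) for pair in reg.excluded_collinear],
        "univariable": {
            str(c): {
                "r_squared": _nan_to_none(reg.univariable.loc[c, "r_squared"]),
                "p_value": _nan_to_none(reg.univariable.loc[c, "p_value"]),
            }
            for c in reg.univariable.index
        },
    }


def _nan_to_none(v):
    v = float(v)
    return None if math.isnan(v) else v


def _setup_run_log(outdir: Path, config: SimulateConfig) -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info(
        "run start: version=%s seed=%d config_hash=%s",
        __version__, config.seed, config.config_hash(),
    )
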