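"""Synthetic cohort generator.

Draws subject-level clinical covariates and ground-truth lung parameters for
two groups — healthy controls and patients at risk of heart failure — with
the marginal distributions and key associations of the study population the
package emulates:

* lung water density (LWD) is coupled to body mass index through a latent
  linear model so the induced univariable R² matches a configurable target
  (default 0.323, i.e. r ≈ 0.568);
* lung volume decreases with BMI (target R² 0.09) and increases with height;
* cardiac size variables (LV mass, ventricular volumes, atrial size) share a
  latent body-size factor driven by height/sex;
* lung water volume is emergent: LWV = LWD × lung volume / 100.

Variables reported as median [IQR] are drawn lognormal with log-moments
matched to the printed quartiles; variables reported as mean ± SD are drawn
Gaussian (LWD truncated to its physical range).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ParameterError

# standard-normal quartile, ln(q3/q1) = 2 * z25 * sigma for a lognormal
_Z25 = 0.6744897501960817

Group = Literal["control", "at_risk"]


@dataclass(frozen=True)
class Normal:
    """Gaussian marginal, reported as mean ± SD."""

    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not self.sd > 0:
            raise ParameterError(f"{name}: SD must be > 0, got {self.sd}")

    def from_z(self, z: np.ndarray) -> np.ndarray:
        return self.mean + self.sd * z


@dataclass(frozen=True)
class LogNormal:
    """Lognormal marginal parameterized by the printed median [q1-q3]."""

    median: float
    q1: float
    q3: float

    def validate(self, name: str) -> None:
        if not (0 < self.q1 < self.median < self.q3):
            raise ParameterError(f"{name}: need 0 < q1 < median < q3")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return (math.log(self.q3) - math.log(self.q1)) / (2 * _Z25)

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    def from_z(self, z: np.ndarray) -> np.ndarray:
        return np.exp(self.mu + self.sigma * z)


@dataclass(frozen=True)
class GroupMarginals:
    """Per-group marginal distributions of the simulated covariates."""

    age: LogNormal
    male_fraction: float
    sbp: Normal
    bmi: LogNormal
    hypertension: float
    diabetes: float
    cad: float
    nyha_ii: float
    ra_area: LogNormal
    la_volume: LogNormal
    lvedv: LogNormal
    rvedv: LogNormal
    lvm: LogNormal
    gls: Normal
    native_t1: LogNormal
    ecv: LogNormal
    lung_volume: LogNormal
    lwd: Normal

    def validate(self, group: str) -> None:
        for name in ("age", "bmi", "ra_area", "la_volume", "lvedv", "rvedv",
                     "lvm", "native_t1", "ecv", "lung_volume"):
            getattr(self, name).validate(f"{group}.{name}")
        self.sbp.validate(f"{group}.sbp")
        self.gls.validate(f"{group}.gls")
        self.lwd.validate(f"{group}.lwd")
        for name in ("male_fraction", "hypertension", "diabetes", "cad", "nyha_ii"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{group}.{name}: prevalence must be in [0, 1]")


@dataclass(frozen=True)
class CohortParams:
    """Full parameter set of the cohort generator.

    ``r_lwd_bmi`` is the within-group correlation between LWD and BMI
    (default sqrt(0.323)); ``r2_lungvol_bmi`` the variance share of
    log-lung-volume explained (negatively) by BMI; ``r_lungvol_height`` and
    ``r_size_height`` latent loadings of lung volume and cardiac size
    variables on standardized height.
    """

    groups: dict[str, GroupMarginals]
    height_m: dict[str, Normal] = field(
        default_factory=lambda: {"M": Normal(1.71, 0.06), "F": Normal(1.60, 0.06)}
    )
    r_lwd_bmi: float = math.sqrt(0.323)
    r2_lungvol_bmi: float = 0.09
    r_lungvol_height: float = 0.40
    r_size_height: float = 0.40
    lwd_bounds: tuple[float, float] = (1.0, 99.0)
    seed: int = 0

    def validate(self) -> None:
        for g, m in self.groups.items():
            m.validate(g)
        for s, h in self.height_m.items():
            h.validate(f"height[{s}]")
        for name in ("r_lwd_bmi", "r_lungvol_height", "r_size_height"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ParameterError(f"{name} must be in (-1, 1), got {r}")
        if not 0 <= self.r2_lungvol_bmi < 1:
            raise ParameterError("r2_lungvol_bmi must be in [0, 1)")
        if self.r2_lungvol_bmi + self.r_lungvol_height**2 >= 1:
            raise ParameterError("lung-volume latent loadings exceed unit variance")

    @classmethod
    def default(cls, seed: int = 0) -> "CohortParams":
        """Parameters calibrated to the study cohort's baseline table."""
        control = GroupMarginals(
            age=LogNormal(48, 38, 55),
            male_fraction=8 / 15,
            sbp=Normal(131, 19),
            bmi=LogNormal(21.6, 19.5, 26.5),
            hypertension=0.0,
            diabetes=0.0,
            cad=0.0,
            nyha_ii=0.0,
            ra_area=LogNormal(12, 11, 13),
            la_volume=LogNormal(70, 64, 81),
            lvedv=LogNormal(131, 120, 144),
            rvedv=LogNormal(142, 122, 153),
            lvm=LogNormal(76, 69, 98),
            gls=Normal(-18.2, 1.7),
            native_t1=LogNormal(1022, 1008, 1038),
            ecv=LogNormal(25.6, 23.8, 27.2),
            lung_volume=LogNormal(1861, 1604, 2405),
            lwd=Normal(27.2, 4.3),
        )
        at_risk = GroupMarginals(
            age=LogNormal(60, 50, 65),
            male_fraction=110 / 155,
            sbp=Normal(142, 18),
            bmi=LogNormal(27.0, 23.8, 30.1),
            hypertension=143 / 155,
            diabetes=62 / 155,
            cad=37 / 155,
            nyha_ii=15 / 155,
            ra_area=LogNormal(20, 16, 23),
            la_volume=LogNormal(86, 73, 104),
            lvedv=LogNormal(134, 112, 158),
            rvedv=LogNormal(134, 110, 156),
            lvm=LogNormal(97, 80, 117),
            gls=Normal(-15.6, 3.3),
            native_t1=LogNormal(1022, 1008, 1038),
            ecv=LogNormal(25.6, 23.8, 27.2),
            lung_volume=LogNormal(1708, 1416, 2037),
            lwd=Normal(30.4, 5.0),
        )
        return cls(groups={"control": control, "at_risk": at_risk}, seed=seed)

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        def tag(obj):
            if isinstance(obj, Normal):
                return {"dist": "normal", "mean": obj.mean, "sd": obj.sd}
            if isinstance(obj, LogNormal):
                return {"dist": "lognormal", "median": obj.median, "q1": obj.q1, "q3": obj.q3}
            raise TypeError(type(obj))

        import dataclasses

        d = {
            "groups": {
                g: {
                    f.name: (
                        tag(getattr(m, f.name))
                        if isinstance(getattr(m, f.name), (Normal, LogNormal))
                        else getattr(m, f.name)
                    )
                    for f in dataclasses.fields(m)
                }
                for g, m in self.groups.items()
            },
            "height_m": {s: tag(h) for s, h in self.height_m.items()},
            "r_lwd_bmi": self.r_lwd_bmi,
            "r2_lungvol_bmi": self.r2_lungvol_bmi,
            "r_lungvol_height": self.r_lungvol_height,
            "r_size_height": self.r_size_height,
            "lwd_bounds": list(self.lwd_bounds),
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortParams":
        def untag(obj):
            if isinstance(obj, dict) and "dist" in obj:
                if obj["dist"] == "normal":
                    return Normal(obj["mean"], obj["sd"])
                return LogNormal(obj["median"], obj["q1"], obj["q3"])
            return obj

        d = json.loads(text)
        groups = {
            g: GroupMarginals(**{k: untag(v) for k, v in m.items()})
            for g, m in d["groups"].items()
        }
        return cls(
            groups=groups,
            height_m={s: untag(h) for s, h in d["height_m"].items()},
            r_lwd_bmi=d["r_lwd_bmi"],
            r2_lungvol_bmi=d["r2_lungvol_bmi"],
            r_lungvol_height=d["r_lungvol_height"],
            r_size_height=d["r_size_height"],
            lwd_bounds=tuple(d["lwd_bounds"]),
            seed=d["seed"],
        )


@dataclass
class Subject:
    """Covariates and ground-truth lung parameters of one simulated individual."""

    id: str
    group: str
    sex: str
    age: float
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2
    bsa: float  # m^2
    sbp: float  # mmHg
    hypertension: bool
    diabetes: bool
    cad: bool
    nyha: int  # NYHA functional class (1 or 2)
    lvm: float  # g
    lvedv: float  # mL
    rvedv: float  # mL
    ra_area: float  # cm^2
    la_volume: float  # mL
    gt: float  # mm, global LV wall thickness
    gls: float  # %
    native_t1: float  # ms
    ecv: float  # %
    true_lwd: float  # %, ground-truth mean parenchymal water density
    true_lung_volume: float  # mL at end-expiration


def compute_bsa(height_m: float, weight_kg: float) -> float:
    """Body surface area (m²) by the Du Bois formula.

    BSA = 0.007184 · height(cm)^0.725 · weight(kg)^0.425
    """
    if not (height_m > 0 and weight_kg > 0):
        raise ParameterError("height and weight must be > 0")
    return 0.007184 * (height_m * 100.0) ** 0.725 * weight_kg**0.425


def compute_gt(lvm_g: float, lvedv_ml: float) -> float:
    """Global LV wall thickness (mm): 0.05 + 1.60 · LVM^0.84 · LVEDV^(−0.49)."""
    if not (lvm_g > 0 and lvedv_ml > 0):
        raise ParameterError("LV mass and LVEDV must be > 0")
    return 0.05 + 1.60 * lvm_g**0.84 * lvedv_ml**-0.49


def sample_cohort(
    params: CohortParams, n_control: int, n_risk: int
) -> list[Subject]:
    """Draw a cohort of ``n_control`` controls and ``n_risk`` at-risk subjects.

    Deterministic for a given ``params.seed``; group sample moments converge
    to the configured marginals as n grows.
    """
    if n_control < 0 or n_risk < 0:
        raise ParameterError("group sizes must be >= 0")
    params.validate()
    rng = np.random.default_rng(params.seed)
    subjects: list[Subject] = []
    for group, n, prefix in (
        ("control", n_control, "C"),
        ("at_risk", n_risk, "R"),
    ):
        subjects.extend(_sample_group(params, group, n, prefix, rng))
    return subjects


def _sample_group(
    params: CohortParams, group: str, n: int, prefix: str, rng: np.random.Generator
) -> list[Subject]:
    m = params.groups[group]
    if n == 0:
        return []

    male = rng.random(n) < m.male_fraction
    sex = np.where(male, "M", "F")
    z_height = rng.standard_normal(n)
    height = np.where(
        male, params.height_m["M"].from_z(z_height), params.height_m["F"].from_z(z_height)
    )

    z_bmi = rng.standard_normal(n)
    bmi = m.bmi.from_z(z_bmi)
    weight = bmi * height**2
    bsa = 0.007184 * (height * 100.0) ** 0.725 * weight**0.425

    # LWD coupled to BMI: lwd = mu + beta*(bmi - E[bmi]) + eps, with beta and
    # var(eps) solved from the correlation target so marginal mean/SD hold.
    r = params.r_lwd_bmi
    beta = r * m.lwd.sd / m.bmi.sd
    eps = rng.standard_normal(n) * m.lwd.sd * math.sqrt(1 - r**2)
    lwd = m.lwd.mean + beta * (bmi - m.bmi.mean) + eps
    lwd = np.clip(lwd, *params.lwd_bounds)

    # lung volume: negative BMI loading, positive height loading in log space
    w_b = math.sqrt(params.r2_lungvol_bmi)
    w_h = params.r_lungvol_height
    w_e = math.sqrt(1 - w_b**2 - w_h**2)
    u = -w_b * z_bmi + w_h * z_height + w_e * rng.standard_normal(n)
    lung_volume = m.lung_volume.from_z(u)

    def size_latent() -> np.ndarray:
        w = params.r_size_height
        return w * z_height + math.sqrt(1 - w**2) * rng.standard_normal(n)

    ra_area = m.ra_area.from_z(size_latent())
    la_volume = m.la_volume.from_z(size_latent())
    lvedv = m.lvedv.from_z(size_latent())
    rvedv = m.rvedv.from_z(size_latent())
    lvm = m.lvm.from_z(size_latent())

    age = m.age.from_z(rng.standard_normal(n))
    sbp = m.sbp.from_z(rng.standard_normal(n))
    gls = m.gls.from_z(rng.standard_normal(n))
    native_t1 = m.native_t1.from_z(rng.standard_normal(n))
    ecv = m.ecv.from_z(rng.standard_normal(n))

    hypertension = rng.random(n) < m.hypertension
    diabetes = rng.random(n) < m.diabetes
    cad = rng.random(n) < m.cad
    nyha = np.where(rng.random(n) < m.nyha_ii, 2, 1)

    out = []
    for i in range(n):
        out.append(
            Subject(
                id=f"{prefix}{i:04d}",
                group=group,
                sex=str(sex[i]),
                age=float(age[i]),
                height=float(height[i]),
                weight=float(weight[i]),
                bmi=float(bmi[i]),
                bsa=float(bsa[i]),
                sbp=float(sbp[i]),
                hypertension=bool(hypertension[i]),
                diabetes=bool(diabetes[i]),
                cad=bool(cad[i]),
                nyha=int(nyha[i]),
                lvm=float(lvm[i]),
                lvedv=float(lvedv[i]),
                rvedv=float(rvedv[i]),
                ra_area=float(ra_area[i]),
                la_volume=float(la_volume[i]),
                gt=compute_gt(float(lvm[i]), float(lvedv[i])),
                gls=float(gls[i]),
                native_t1=float(native_t1[i]),
                ecv=float(ecv[i]),
                true_lwd=float(lwd[i]),
                true_lung_volume=float(lung_volume[i]),
            )
        )
    return out


#: fixed column order of the cohort CSV
COHORT_COLUMNS = [
    "id", "group", "sex", "age", "height", "weight", "bmi", "bsa", "sbp",
    "hypertension", "diabetes", "cad", "nyha", "lvm", "lvedv", "rvedv",
    "ra_area", "la_volume", "gt", "gls", "native_t1", "ecv",
    "true_lwd", "true_lung_volume",
]


def cohort_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(s) for s in subjects], columns=COHORT_COLUMNS)
    return df


def frame_to_cohort(df: pd.DataFrame) -> list[Subject]:
    return [Subject(**row) for row in df[COHORT_COLUMNS].to_dict("records")]
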