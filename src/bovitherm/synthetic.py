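"""Synthetic cohort generator with a known generative CBT model.

The generator emulates the schema of the study table (one row per cow
observation: environment, animal covariates, infrared ROI temperatures,
rectal CBT) with a documented generative model so that every downstream
stage -- preprocessing, feature engineering, benchmarking, tuning, and
attribution -- can be tested against known ground truth.

Generative CBT model (all coefficients live in :class:`GeneratorConfig`)::

    CBT = b0 + b_irt * max(0, IRTave_TK - irt_knee)
             + b_tz * TZ + b_bp * BP
             - b_dol * max(0, DOL - dol_knee) / dol_knee
             + Normal(0, noise_sd_cbt)

clipped to the thermometer range [32.0, 42.0] degC.  Trunk IRT is generated
first (driven by air temperature) and drives CBT directly, which makes it
the most informative ROI by construction; the remaining ROIs receive a
weaker, indirect CBT coupling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermal

__all__ = [
    "SCHEMA_VERSION",
    "ROIS",
    "EnvRecord",
    "GeneratorConfig",
    "gen_environment",
    "gen_cbt",
    "gen_cohort",
    "generative_cbt_mean",
    "theoretical_r2_ceiling",
    "write_cohort",
    "read_cohort",
]

SCHEMA_VERSION = "bovitherm-cohort-v1"

ROIS = ("TK", "HL", "FL", "UD", "HD", "EY", "FA", "ER", "NK")

CBT_MIN, CBT_MAX = 32.0, 42.0  # thermometer measurement range

#: sampling windows (hours of day) during which observations are taken
SAMPLING_WINDOWS = ((8.0, 12.0), (14.0, 18.0))

TZ_LABELS = ("A.M.", "P.M.")
BP_LABELS = ("standing", "lying down")


def _default_coefficients() -> dict:
    return {
        "b0": 38.4,
        "b_irt": 0.12,   # degC per degC of trunk IRT above the knee
        "b_tz": 0.10,    # P.M. offset, degC
        "b_bp": 0.08,    # lying-down offset, degC
        "b_dol": 0.15,   # late-lactation decline, degC per dol_knee days
        "irt_knee": 34.0,
        "dol_knee": 200.0,
    }


def _default_irt_intercepts() -> dict:
    # per-ROI baseline surface temperature at Ta = 0
    return {
        "TK": 21.0, "HL": 18.5, "FL": 18.0, "UD": 20.5, "HD": 19.5,
        "EY": 22.0, "FA": 19.0, "ER": 16.5, "NK": 19.0,
    }


def _default_irt_cbt_coefs() -> dict:
    # indirect CBT coupling of the non-trunk ROIs; the trunk's coupling is
    # implicit (and strongest) because CBT is generated from trunk IRT.
    return {
        "HL": 0.35, "FL": 0.30, "UD": 0.55, "HD": 0.45,
        "EY": 0.60, "FA": 0.40, "ER": 0.25, "NK": 0.45,
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Identical config + seed produces a byte-identical table.
    """

    n_days: int = 30
    cows_per_day_range: tuple[int, int] = (90, 120)
    seed: int = 0
    noise_sd_cbt: float = 0.25
    missing_rate_my: float = 0.05
    missing_rate_irt: float = 0.05
    outlier_rate: float = 0.005
    outlier_factor: float = 1.5
    coefficients: dict = field(default_factory=_default_coefficients)

    # environment model
    ta_mean: float = 27.0
    ta_amplitude: float = 5.0
    ta_peak_hour: float = 15.0
    ta_day_sd: float = 1.5
    ta_obs_sd: float = 0.5
    rh_mean: float = 60.0
    rh_slope: float = 2.5      # percent RH lost per degC above ta_mean
    rh_sd: float = 5.0
    u_mean: float = 0.8
    u_sigma: float = 0.6       # lognormal shape; 0 => deterministic U
    qsr_peak: float = 800.0
    qsr_sd: float = 40.0
    tbg_qsr_coef: float = 3.0  # degC per kW/m^2 of solar radiation
    tbg_sd: float = 0.3

    # infrared model
    irt_ta_coef: float = 0.5
    irt_sd_tk: float = 1.5
    irt_sd: float = 1.0
    irt_intercepts: dict = field(default_factory=_default_irt_intercepts)
    irt_cbt_coefs: dict = field(default_factory=_default_irt_cbt_coefs)
    irtmax_offset_range: tuple[float, float] = (0.5, 2.5)

    # animal covariates
    my_mean: float = 28.0
    my_sd: float = 6.0
    dol_range: tuple[int, int] = (5, 400)
    parity_rate: float = 1.2
    lying_prob: float = 0.4

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        lo, hi = self.cows_per_day_range
        if lo > hi or lo < 1:
            raise ValueError("cows_per_day_range must satisfy 1 <= low <= high")
        for name in ("missing_rate_my", "missing_rate_irt", "outlier_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd_cbt < 0:
            raise ValueError("noise_sd_cbt must be >= 0")

    def without_noise(self) -> "GeneratorConfig":
        """Copy with every environment noise amplitude set to zero."""
        return dataclasses.replace(
            self, ta_day_sd=0.0, ta_obs_sd=0.0, rh_sd=0.0, u_sigma=0.0,
            qsr_sd=0.0, tbg_sd=0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cows_per_day_range"] = list(self.cows_per_day_range)
        d["irtmax_offset_range"] = list(self.irtmax_offset_range)
        d["dol_range"] = list(self.dol_range)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d.pop("schema_version", None)
        for key in ("cows_per_day_range", "irtmax_offset_range", "dol_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EnvRecord:
    """One timestamped environmental observation plus derived dew point."""

    day: int
    hour: float
    Ta: float
    Tbg: float
    RH: float
    U: float
    Qsr: float
    Tdp: float


def _in_sampling_window(hour: float) -> bool:
    return any(lo <= hour <= hi for lo, hi in SAMPLING_WINDOWS)


def _env_rng(config: GeneratorConfig, day_index: int, hour: float) -> np.random.Generator:
    # deterministic per (seed, day, hour) stream
    return np.random.default_rng([config.seed, int(day_index), int(round(hour * 3600))])


def _day_rng(config: GeneratorConfig, day_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(day_index)])


def gen_environment(
    day_index: int,
    hour: float,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> EnvRecord:
    """Generate one environmental observation inside a sampling window.

    ``hour`` must fall within 8:00-12:00 or 14:00-18:00.  Air temperature
    follows a diurnal sinusoid (peak at ``ta_peak_hour``) plus day-level and
    observation noise; RH is anti-correlated with Ta; U is right-skewed;
    Qsr peaks at midday; Tbg tracks Ta plus a solar-load term.
    """
    if not _in_sampling_window(hour):
        raise ValueError(
            f"hour {hour} outside sampling windows {SAMPLING_WINDOWS}"
        )
    if rng is None:
        rng = _env_rng(config, day_index, hour)
    day_offset = float(_day_rng(config, day_index).normal(0.0, config.ta_day_sd)) \
        if config.ta_day_sd > 0 else 0.0

    phase = 2.0 * np.pi * (hour - config.ta_peak_hour) / 24.0
    ta = config.ta_mean + config.ta_amplitude * np.cos(phase) + day_offset
    if config.ta_obs_sd > 0:
        ta += rng.normal(0.0, config.ta_obs_sd)

    rh = config.rh_mean - config.rh_slope * (ta - config.ta_mean)
    if config.rh_sd > 0:
        rh += rng.normal(0.0, config.rh_sd)
    rh = float(np.clip(rh, 20.0, 100.0))

    u = config.u_mean
    if config.u_sigma > 0:
        u *= float(np.exp(rng.normal(0.0, config.u_sigma)))

    qsr = config.qsr_peak * max(0.0, np.cos(2.0 * np.pi * (hour - 12.0) / 24.0))
    if config.qsr_sd > 0:
        qsr += rng.normal(0.0, config.qsr_sd)
    qsr = float(max(qsr, 0.0))

    tbg = ta + config.tbg_qsr_coef * qsr / 1000.0
    if config.tbg_sd > 0:
        tbg += rng.normal(0.0, config.tbg_sd)

    return EnvRecord(
        day=int(day_index), hour=float(hour), Ta=float(ta), Tbg=float(tbg),
        RH=rh, U=float(u), Qsr=qsr, Tdp=float(thermal.dew_point(ta, rh)),
    )


def _coerce_binary(value, labels: tuple[str, str], name: str) -> float:
    if isinstance(value, str):
        norm = value.strip().lower()
        for code, label in enumerate(labels):
            if norm == label.lower():
                return float(code)
        raise ValueError(f"unrecognized {name} label: {value!r}")
    value = float(value)
    if value not in (0.0, 1.0):
        raise ValueError(f"{name} must be 0/1 or one of {labels}")
    return value


def gen_cbt(obs, config: GeneratorConfig, rng: np.random.Generator | None = None) -> float:
    """Core body temperature (degC) from the generative model.

    ``obs`` is any mapping with IRTave_TK, TZ, BP and DOL (TZ/BP may be
    labels or already-encoded 0/1).  Noise is drawn from ``rng`` when given,
    otherwise from a generator seeded by ``config.seed``.
    """
    for key in ("IRTave_TK", "TZ", "BP", "DOL"):
        if key not in obs or pd.isna(obs[key]):
            raise ValueError(f"gen_cbt requires a non-missing {key!r}")
    c = config.coefficients
    tz = _coerce_binary(obs["TZ"], TZ_LABELS, "TZ")
    bp = _coerce_binary(obs["BP"], BP_LABELS, "BP")
    cbt = (
        c["b0"]
        + c["b_irt"] * max(0.0, float(obs["IRTave_TK"]) - c["irt_knee"])
        + c["b_tz"] * tz
        + c["b_bp"] * bp
        - c["b_dol"] * max(0.0, float(obs["DOL"]) - c["dol_knee"]) / c["dol_knee"]
    )
    if config.noise_sd_cbt > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        cbt += float(rng.normal(0.0, config.noise_sd_cbt))
    return float(np.clip(cbt, CBT_MIN, CBT_MAX))


def generative_cbt_mean(table: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Noise-free generative CBT evaluated row-wise (clipped)."""
    c = config.coefficients
    tz = table["TZ"].map({TZ_LABELS[0]: 0.0, TZ_LABELS[1]: 1.0}).fillna(
        pd.to_numeric(table["TZ"], errors="coerce")
    ).to_numpy(float)
    bp = table["BP"].map({BP_LABELS[0]: 0.0, BP_LABELS[1]: 1.0}).fillna(
        pd.to_numeric(table["BP"], errors="coerce")
    ).to_numpy(float)
    irt = table["IRTave_TK"].to_numpy(float)
    dol = table["DOL"].to_numpy(float)
    cbt = (
        c["b0"]
        + c["b_irt"] * np.maximum(0.0, irt - c["irt_knee"])
        + c["b_tz"] * tz
        + c["b_bp"] * bp
        - c["b_dol"] * np.maximum(0.0, dol - c["dol_knee"]) / c["dol_knee"]
    )
    return np.clip(cbt, CBT_MIN, CBT_MAX)


# column order of the written cohort table
_META_COLUMNS = ["day", "hour"]
_ENV_COLUMNS = ["Ta", "Tbg", "RH", "U", "Qsr"]
_ANIMAL_COLUMNS = ["TZ", "BP", "MY", "DOL", "PA"]


def cohort_columns() -> list[str]:
    cols = _META_COLUMNS + _ENV_COLUMNS + _ANIMAL_COLUMNS
    cols += [f"IRTave_{r}" for r in ROIS] + [f"IRTmax_{r}" for r in ROIS]
    cols.append("CBT")
    return cols


def gen_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort table and its pre-corruption truth table.

    Returns ``(table, truth)``: ``table`` has missingness injected into
    milk-yield and IRT columns and multiplicative outliers in continuous
    columns; ``truth`` is the clean table (identical row order/index).
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    lo, hi = config.cows_per_day_range
    for day in range(1, config.n_days + 1):
        n_cows = int(rng.integers(lo, hi + 1))
        for _ in range(n_cows):
            window = SAMPLING_WINDOWS[int(rng.integers(0, 2))]
            hour = float(rng.uniform(window[0], window[1]))
            env = gen_environment(day, hour, config)
            tz_code = 0 if hour < 13.0 else 1

            my = float(max(rng.normal(config.my_mean, config.my_sd), 3.0))
            dol = int(rng.integers(config.dol_range[0], config.dol_range[1] + 1))
            pa = int(min(1 + rng.poisson(config.parity_rate), 8))
            bp_code = int(rng.random() < config.lying_prob)

            irt_tk = (
                config.irt_intercepts["TK"]
                + config.irt_ta_coef * env.Ta
                + rng.normal(0.0, config.irt_sd_tk)
            )
            row = {
                "day": day, "hour": hour,
                "Ta": env.Ta, "Tbg": env.Tbg, "RH": env.RH, "U": env.U,
                "Qsr": env.Qsr,
                "TZ": TZ_LABELS[tz_code], "BP": BP_LABELS[bp_code],
                "MY": my, "DOL": dol, "PA": pa,
                "IRTave_TK": irt_tk,
            }
            cbt = gen_cbt(row, config, rng)
            for roi in ROIS:
                if roi != "TK":
                    row[f"IRTave_{roi}"] = (
                        config.irt_intercepts[roi]
                        + config.irt_ta_coef * env.Ta
                        + config.irt_cbt_coefs[roi] * (cbt - config.coefficients["b0"])
                        + rng.normal(0.0, config.irt_sd)
                    )
                lo_off, hi_off = config.irtmax_offset_range
                row[f"IRTmax_{roi}"] = row[f"IRTave_{roi}"] + float(
                    rng.uniform(lo_off, hi_off)
                )
            row["CBT"] = cbt
            rows.append(row)

    truth = pd.DataFrame(rows, columns=cohort_columns())
    table = truth.copy()

    # multiplicative outliers in continuous columns (never CBT, never
    # categorical); applied before missingness so a masked cell wins
    continuous = _ENV_COLUMNS + ["MY"] + [f"IRTave_{r}" for r in ROIS] + [
        f"IRTmax_{r}" for r in ROIS
    ]
    if config.outlier_rate > 0:
        for col in continuous:
            mask = rng.random(len(table)) < config.outlier_rate
            table.loc[mask, col] = table.loc[mask, col] * config.outlier_factor

    # missingness confined to milk yield and IRT columns
    if config.missing_rate_my > 0:
        mask = rng.random(len(table)) < config.missing_rate_my
        table.loc[mask, "MY"] = np.nan
    if config.missing_rate_irt > 0:
        for roi in ROIS:
            for prefix in ("IRTave", "IRTmax"):
                mask = rng.random(len(table)) < config.missing_rate_irt
                table.loc[mask, f"{prefix}_{roi}"] = np.nan

    return table, truth


def theoretical_r2_ceiling(truth: pd.DataFrame, config: GeneratorConfig) -> float:
    """Upper bound on achievable R^2 given the generative noise variance."""
    var = float(np.var(truth["CBT"].to_numpy(float)))
    if var <= 0:
        return 0.0
    return 1.0 - config.noise_sd_cbt**2 / var


def write_cohort(table: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write a cohort table as CSV; config (with schema version) as sidecar JSON."""
    table.to_csv(path, index=False)
    if config is not None:
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
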