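"""Synthetic plasma-Nf cohort generator and clinimetric scoring.

No patient-level plasma Nf data set with all three subunits is publicly
available, so downstream stages are exercised on synthetic cohorts that
reproduce the statistical structure the analysis assumes: right-skewed
(log-normal) per-assay concentrations, arbitrary per-assay calibrator scale
factors (the "systematic error" that one-point calibration cancels), control
particle medians at the physiological 7:3:2 stoichiometry and ALS medians at
the adaptive 24:2.4:1.6 stoichiometry, plus ALSFRS-r clinimetrics for
progression-rate analyses.

Clinimetric helpers implement the standard ALS scoring conventions:
progression rate (48 - ALSFRS-r)/months, the slow/intermediate/fast rate
categories and the early/intermediate/late disease stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    ADAPTIVE_STOICHIOMETRY,
    ASSAYS,
    AVOGADRO,
    MOLAR_MASS_DA,
    PHYSIOLOGICAL_STOICHIOMETRY,
)

GROUPS = ("control", "ALS")
ONSET_SITES = ("bulbar", "limb", "both")

CSV_COLUMNS = [
    "subject_id",
    "group",
    "conc_nfl",
    "conc_nfm",
    "conc_nfh_smi35",
    "conc_nfh_smi34",
    "onset_site",
    "alsfrs_baseline",
    "alsfrs_followup",
    "months_onset_to_baseline",
    "months_onset_to_last_visit",
]

#: Default per-assay calibrator distortion factors.  Arbitrary by design:
#: they emulate immunoassays calibrated against unrelated protein standards,
#: which is exactly what one-point stoichiometric calibration must cancel.
DEFAULT_ASSAY_SCALE = {
    "NfL": 1.0,
    "NfM": 0.35,
    "NfH_SMI35": 2.0,
    "NfH_SMI34": 2.0,
}

#: Dispersion of the log-normal concentration law (natural-log sd).  A log-sd
#: of 0.4 (controls) corresponds to a geometric SD of ~1.5, typical of plasma
#: NfL in healthy adults; disease cohorts are wider (log-sd 0.6, GSD ~1.8).
DEFAULT_LOG_SD = {"control": 0.4, "ALS": 0.6}

#: Clinimetric sampling parameters: ALSFRS-r baseline mean/sd (cohort mean
#: ~34), onset-to-baseline months (log-normal around ~17 months diagnostic
#: latency), onset-site proportions ~(0.25, 0.73, 0.02) for bulbar/limb/both,
#: months between baseline and last visit, and per-category Poisson mean
#: ALSFRS-r decline used for the follow-up score.
DEFAULT_CLINIMETRIC_PARAMS = {
    "alsfrs_baseline_mean": 34.0,
    "alsfrs_baseline_sd": 8.0,
    "onset_months_median": 17.0,
    "onset_months_log_sd": 0.6,
    "onset_site_probs": (0.25, 0.733, 0.017),
    "followup_interval_months_mean": 9.0,
    "followup_decline_poisson_mean": {"slow": 2.0, "intermediate": 5.0, "fast": 9.0},
}


def _true_control_conc_medians(nfl_g_per_l: float = 5e-11) -> dict:
    """Underlying control concentration medians (g/L), before assay scaling.

    Anchored at a plasma NfL median of 50 pg/mL; NfM and NfH follow so that
    the underlying *particle* medians sit at the physiological 7:3:2.
    """
    nfl_particles = nfl_g_per_l / MOLAR_MASS_DA["NfL"] * AVOGADRO
    tL, tM, tH = PHYSIOLOGICAL_STOICHIOMETRY
    out = {"NfL": nfl_g_per_l}
    out["NfM"] = nfl_particles * tM / tL / AVOGADRO * MOLAR_MASS_DA["NfM"]
    for assay in ("NfH_SMI35", "NfH_SMI34"):
        out[assay] = nfl_particles * tH / tL / AVOGADRO * MOLAR_MASS_DA[assay]
    return out


def default_conc_medians() -> dict:
    """Per-group, per-assay concentration medians (g/L), before assay scaling.

    ALS medians are control medians scaled per isoform by the adaptive/
    physiological share ratio (24/7, 2.4/3, 1.6/2), so that the calibrated
    ALS particle medians land on the adaptive stoichiometry.  The generator
    multiplies draws by ``assay_scale`` separately.
    """
    base = _true_control_conc_medians()
    aL, aM, aH = ADAPTIVE_STOICHIOMETRY
    tL, tM, tH = PHYSIOLOGICAL_STOICHIOMETRY
    shift = {
        "NfL": aL / tL,
        "NfM": aM / tM,
        "NfH_SMI35": aH / tH,
        "NfH_SMI34": aH / tH,
    }
    return {
        "control": {a: base[a] for a in ASSAYS},
        "ALS": {a: base[a] * shift[a] for a in ASSAYS},
    }


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    ``conc_median`` maps group -> assay -> median concentration in g/L before
    assay distortion; each draw is log-normal around that median and then
    multiplied by ``assay_scale[assay]``.  ``seed`` fully determines output.
    """

    n_control: int = 29
    n_als: int = 60
    conc_median: dict = field(default_factory=default_conc_medians)
    conc_log_sd: dict = field(
        default_factory=lambda: {
            g: {a: DEFAULT_LOG_SD[g] for a in ASSAYS} for g in GROUPS
        }
    )
    assay_scale: dict = field(default_factory=lambda: dict(DEFAULT_ASSAY_SCALE))
    clinimetric_params: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINIMETRIC_PARAMS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 3 or self.n_als < 3:
            raise ValueError("need n >= 3 per group")
        for g in GROUPS:
            for a in ASSAYS:
                if self.conc_median[g][a] <= 0:
                    raise ValueError(f"median for {g}/{a} must be positive")
                if self.conc_log_sd[g][a] < 0:
                    raise ValueError(f"log-sd for {g}/{a} must be >= 0")
        for a in ASSAYS:
            if self.assay_scale[a] <= 0:
                raise ValueError(f"assay_scale for {a} must be positive")


@dataclass
class ConcentrationRecord:
    """One subject's per-assay plasma concentrations plus clinimetrics."""

    subject_id: str
    group: str
    conc: dict  # assay -> g/L
    onset_site: str | None = None
    alsfrs_baseline: int | None = None
    alsfrs_followup: int | None = None
    months_onset_to_baseline: float | None = None
    months_onset_to_last_visit: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for a, c in self.conc.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"{self.subject_id}: {a} concentration invalid")
        if self.group == "control":
            if self.onset_site is not None or self.alsfrs_baseline is not None:
                raise ValueError("controls carry no onset/ALSFRS fields")


# ---------------------------------------------------------------------------
# Clinimetric scoring


def progression_rate(alsfrs: int, months: float) -> float:
    """Disease progression rate in ALSFRS-r points/month: (48 - score)/months."""
    if not 0 <= alsfrs <= 48:
        raise ValueError("ALSFRS-r score must be in [0, 48]")
    if months <= 0:
        raise ValueError("months must be positive")
    return (48 - alsfrs) / months


def progression_category(rate: float) -> str:
    """Classify a progression rate: <0.5 slow, 0.5-1.0 intermediate, >1.0 fast."""
    if rate < 0:
        raise ValueError("progression rate must be >= 0")
    if rate < 0.5:
        return "slow"
    if rate <= 1.0:
        return "intermediate"
    return "fast"


def disease_stage(alsfrs: int) -> str:
    """ALSFRS-r stage: early (40-48), intermediate (25-39), late (<= 24)."""
    if not 0 <= alsfrs <= 48:
        raise ValueError("ALSFRS-r score must be in [0, 48]")
    if alsfrs >= 40:
        return "early"
    if alsfrs >= 25:
        return "intermediate"
    return "late"


# ---------------------------------------------------------------------------
# Generation


def _draw_concentrations(
    rng: np.random.Generator, config: CohortConfig, group: str, n: int
) -> dict:
    out = {}
    for a in ASSAYS:
        median = config.conc_median[group][a]
        sd = config.conc_log_sd[group][a]
        # log-normal parameterised by its median: exp(N(ln median, sd)),
        # then distorted by the per-assay calibrator scale factor
        draws = (
            np.exp(rng.normal(np.log(median), sd, size=n))
            if sd > 0
            else np.full(n, median)
        )
        out[a] = draws * config.assay_scale[a]
    return out


def generate_cohort(config: CohortConfig) -> list[ConcentrationRecord]:
    """Draw a full synthetic cohort; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    cp = config.clinimetric_params
    records: list[ConcentrationRecord] = []

    conc = _draw_concentrations(rng, config, "control", config.n_control)
    for i in range(config.n_control):
        records.append(
            ConcentrationRecord(
                subject_id=f"CTRL{i + 1:03d}",
                group="control",
                conc={a: float(conc[a][i]) for a in ASSAYS},
            )
        )

    conc = _draw_concentrations(rng, config, "ALS", config.n_als)
    sites = rng.choice(ONSET_SITES, size=config.n_als, p=cp["onset_site_probs"])
    alsfrs = np.clip(
        np.rint(
            rng.normal(
                cp["alsfrs_baseline_mean"], cp["alsfrs_baseline_sd"], config.n_als
            )
        ),
        0,
        48,
    ).astype(int)
    months = np.exp(
        rng.normal(np.log(cp["onset_months_median"]), cp["onset_months_log_sd"],
                   config.n_als)
    )
    interval = rng.exponential(cp["followup_interval_months_mean"], config.n_als)
    for i in range(config.n_als):
        rate = progression_rate(int(alsfrs[i]), float(months[i]))
        decline_mean = cp["followup_decline_poisson_mean"][progression_category(rate)]
        followup = int(max(0, alsfrs[i] - rng.poisson(decline_mean)))
        records.append(
            ConcentrationRecord(
                subject_id=f"ALS{i + 1:03d}",
                group="ALS",
                conc={a: float(conc[a][i]) for a in ASSAYS},
                onset_site=str(sites[i]),
                alsfrs_baseline=int(alsfrs[i]),
                alsfrs_followup=followup,
                months_onset_to_baseline=float(months[i]),
                months_onset_to_last_visit=float(months[i] + interval[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# I/O


def cohort_to_dataframe(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "conc_nfl": r.conc["NfL"],
                "conc_nfm": r.conc["NfM"],
                "conc_nfh_smi35": r.conc["NfH_SMI35"],
                "conc_nfh_smi34": r.conc["NfH_SMI34"],
                "onset_site": r.onset_site,
                "alsfrs_baseline": r.alsfrs_baseline,
                "alsfrs_followup": r.alsfrs_followup,
                "months_onset_to_baseline": r.months_onset_to_baseline,
                "months_onset_to_last_visit": r.months_onset_to_last_visit,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(records: Sequence[ConcentrationRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[ConcentrationRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        is_ctrl = row["group"] == "control"

        def opt(col, cast=float):
            v = row[col]
            return None if pd.isna(v) else cast(v)

        records.append(
            ConcentrationRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                conc={
                    "NfL": float(row["conc_nfl"]),
                    "NfM": float(row["conc_nfm"]),
                    "NfH_SMI35": float(row["conc_nfh_smi35"]),
                    "NfH_SMI34": float(row["conc_nfh_smi34"]),
                },
                onset_site=None if is_ctrl else opt("onset_site", str),
                alsfrs_baseline=None if is_ctrl else opt("alsfrs_baseline", int),
                alsfrs_followup=None if is_ctrl else opt("alsfrs_followup", int),
                months_onset_to_baseline=None
                if is_ctrl
                else opt("months_onset_to_baseline"),
                months_onset_to_last_visit=None
                if is_ctrl
                else opt("months_onset_to_last_visit"),
            )
        )
    return records


def config_from_yaml(path) -> CohortConfig:
    """Load a CohortConfig from a YAML file; missing keys keep defaults."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for f in dataclasses.fields(CohortConfig):
        if f.name in data:
            kwargs[f.name] = data[f.name]
    return CohortConfig(**kwargs)
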