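"""Particle-count conversion and one-point stoichiometric calibration.

Plasma neurofilament immunoassays are calibrated against arbitrary protein
standards, so their mass-concentration outputs carry per-assay scale factors
that make raw NfL:NfM:NfH ratios meaningless.  Converting each concentration
to a particle count (via molar mass and Avogadro's number) and rescaling the
three channels so that the *control* cohort's median counts sit at the known
physiological stoichiometry 7:3:2 cancels those arbitrary scales.  The same
factors applied to the patient cohort then yield an assay-independent
in-vivo stoichiometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AA_COUNT,
    AVOGADRO,
    ISOFORMS,
    MOLAR_MASS_DA,
    PHYSIOLOGICAL_STOICHIOMETRY,
)

NfhMode = Literal["sum", "smi35_only", "smi34_only"]


@dataclass(frozen=True)
class IsoformSpec:
    """Physical constants of one isoform assay channel."""

    name: str
    molar_mass: float  # Da, treated as g/mol
    aa_count: int
    target_share: float

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.aa_count <= 0:
            raise ValueError("aa_count must be positive")
        if self.target_share <= 0:
            raise ValueError("target_share must be positive")


DEFAULT_ISOFORM_SPECS = {
    "NfL": IsoformSpec("NfL", MOLAR_MASS_DA["NfL"], AA_COUNT["NfL"], 7.0),
    "NfM": IsoformSpec("NfM", MOLAR_MASS_DA["NfM"], AA_COUNT["NfM"], 3.0),
    "NfH_SMI35": IsoformSpec(
        "NfH_SMI35", MOLAR_MASS_DA["NfH_SMI35"], AA_COUNT["NfH"], 2.0
    ),
    "NfH_SMI34": IsoformSpec(
        "NfH_SMI34", MOLAR_MASS_DA["NfH_SMI34"], AA_COUNT["NfH"], 2.0
    ),
}


@dataclass
class ParticleProfile:
    """Per-subject particle counts for the three isoform channels.

    Raw counts are particles per litre; after calibration the counts are
    dimensionless stoichiometric shares.
    """

    subject_id: str
    counts: dict = field(default_factory=dict)  # isoform -> count
    calibrated: bool = False
    group: str | None = None

    def __post_init__(self):
        for iso, c in self.counts.items():
            if iso not in ISOFORMS:
                raise ValueError(f"unknown isoform {iso!r}")
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"count for {iso} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[i] for i in ISOFORMS], dtype=float)


@dataclass(frozen=True)
class CalibrationFactors:
    """One-point stoichiometric correction factors (x, y, z) for NfL, NfM, NfH."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("calibration factors must be positive and finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def to_molarity(conc: float, spec: IsoformSpec) -> float:
    """Convert a mass concentration in g/L to molarity (mol/L).

    Parameters
    ----------
    conc : concentration in g/L, must be >= 0.
    spec : isoform whose molar mass (Da == g/mol) divides the concentration.
    """
    if conc < 0 or not np.isfinite(conc):
        raise ValueError("concentration must be finite and >= 0")
    return conc / spec.molar_mass


def to_particles(molarity: float) -> float:
    """Convert molarity (mol/L) to a particle count per litre."""
    if molarity < 0 or not np.isfinite(molarity):
        raise ValueError("molarity must be finite and >= 0")
    return molarity * AVOGADRO


def combine_nfh(
    smi35: float | None, smi34: float | None, mode: NfhMode = "smi35_only"
) -> float:
    """Collapse the two NfH phosphoform assay channels into one NfH count.

    The analysis reports a single NfH channel; which assay (or combination)
    feeds it is an explicit, logged choice.
    """
    if smi35 is None and smi34 is None:
        raise ValueError("both NfH channels missing")
    if mode == "sum":
        return (smi35 or 0.0) + (smi34 or 0.0)
    if mode == "smi35_only":
        if smi35 is None:
            raise ValueError("SMI35 channel missing")
        return smi35
    if mode == "smi34_only":
        if smi34 is None:
            raise ValueError("SMI34 channel missing")
        return smi34
    raise ValueError(f"unknown NfH combination mode {mode!r}")


def profile_from_concentrations(
    subject_id: str,
    conc: dict,
    *,
    group: str | None = None,
    nfh_mode: NfhMode = "smi35_only",
    specs: dict | None = None,
    pg_per_ml: bool = False,
) -> ParticleProfile:
    """Build an uncalibrated ParticleProfile from per-assay g/L concentrations.

    ``conc`` maps assay names (NfL, NfM, NfH_SMI35, NfH_SMI34) to g/L values;
    ``pg_per_ml=True`` applies the 1e-9 conversion from pg/mL first.
    """
    specs = specs or DEFAULT_ISOFORM_SPECS
    scale = 1e-9 if pg_per_ml else 1.0

    def particles(assay: str) -> float | None:
        c = conc.get(assay)
        if c is None or (isinstance(c, float) and np.isnan(c)):
            return None
        return to_particles(to_molarity(c * scale, specs[assay]))

    nfl = particles("NfL")
    nfm = particles("NfM")
    if nfl is None or nfm is None:
        raise ValueError(f"subject {subject_id}: NfL and NfM are required")
    nfh = combine_nfh(particles("NfH_SMI35"), particles("NfH_SMI34"), nfh_mode)
    return ParticleProfile(
        subject_id=subject_id,
        counts={"NfL": nfl, "NfM": nfm, "NfH": nfh},
        calibrated=False,
        group=group,
    )


def calibration_factors(
    control_profiles: Sequence[ParticleProfile],
    targets: Sequence[float] = PHYSIOLOGICAL_STOICHIOMETRY,
) -> CalibrationFactors:
    """Derive one-point correction factors from control-cohort medians.

    x = target_L / median(NfL counts), and likewise y, z for NfM, NfH.  The
    sample median (mean of the two middle order statistics for even n) is
    used because plasma Nf distributions are right-skewed.
    """
    if len(control_profiles) < 3:
        raise ValueError("need at least 3 control profiles for calibration")
    arr = np.array([p.as_array() for p in control_profiles])
    medians = np.median(arr, axis=0)
    if np.any(medians <= 0):
        raise ValueError("zero or negative control median; cannot calibrate")
    x, y, z = np.asarray(targets, dtype=float) / medians
    return CalibrationFactors(x=x, y=y, z=z)


def apply_calibration(
    profile: ParticleProfile, factors: CalibrationFactors
) -> ParticleProfile:
    """Rescale an uncalibrated profile by the per-isoform factors."""
    if profile.calibrated:
        raise ValueError(f"profile {profile.subject_id} is already calibrated")
    f = factors.as_array()
    counts = {iso: profile.counts[iso] * f[k] for k, iso in enumerate(ISOFORMS)}
    return replace(profile, counts=counts, calibrated=True)


def cohort_stoichiometry(
    profiles: Sequence[ParticleProfile],
) -> tuple[float, float, float]:
    """Per-isoform medians of calibrated counts, as an (NfL, NfM, NfH) triple.

    No renormalisation is applied: for a calibrated control cohort this is
    (7, 3, 2) by construction, and for other cohorts the triple is directly
    comparable to that reference.
    """
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    if not all(p.calibrated for p in profiles):
        raise ValueError("all profiles must be calibrated")
    arr = np.array([p.as_array() for p in profiles])
    med = np.median(arr, axis=0)
    return float(med[0]), float(med[1]), float(med[2])


def density_summary(
    values: Iterable[float], bandwidth: float | str = "auto", grid_size: int = 512
) -> np.ndarray:
    """Gaussian kernel density estimate on a regular grid spanning the data.

    Returns an array of shape (grid_size, 2) with columns (value, density).
    ``bandwidth`` is either "auto" (Scott's rule) or a positive factor passed
    to :class:`scipy.stats.gaussian_kde`.
    """
    from scipy.stats import gaussian_kde

    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    bw = None if bandwidth == "auto" else float(bandwidth)
    kde = gaussian_kde(vals, bw_method=bw)
    pad = 3.0 * vals.std(ddof=1) if vals.std(ddof=1) > 0 else 1.0
    grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_size)
    dens = kde(grid)
    return np.column_stack([grid, dens])


class StoichCalibrator:
    """One-point stoichiometric calibrator.

    ``fit`` derives (x, y, z) from a control cohort's median particle counts;
    ``apply``/``apply_cohort`` rescale profiles with the fitted factors.
    """

    def __init__(self, targets: Sequence[float] = PHYSIOLOGICAL_STOICHIOMETRY):
        self.targets = tuple(float(t) for t in targets)
        self.factors_: CalibrationFactors | None = None

    def fit(self, control_profiles: Sequence[ParticleProfile]) -> "StoichCalibrator":
        self.factors_ = calibration_factors(control_profiles, self.targets)
        return self

    def apply(self, profile: ParticleProfile) -> ParticleProfile:
        if self.factors_ is None:
            raise RuntimeError("calibrator is not fitted")
        return apply_calibration(profile, self.factors_)

    def apply_cohort(
        self, profiles: Sequence[ParticleProfile]
    ) -> list[ParticleProfile]:
        return [self.apply(p) for p in profiles]


def profiles_from_records(
    records, *, nfh_mode: NfhMode = "smi35_only", specs: dict | None = None
) -> list[ParticleProfile]:
    """Convert ConcentrationRecords (see :mod:`nfstoich.cohort`) to profiles."""
    return [
        profile_from_concentrations(
            r.subject_id, r.conc, group=r.group, nfh_mode=nfh_mode, specs=specs
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# I/O


def profiles_from_cohort_csv(
    path, *, nfh_mode: NfhMode = "smi35_only", pg_per_ml: bool = False
) -> list[ParticleProfile]:
    """Read a cohort CSV (see :mod:`nfstoich.cohort`) into particle profiles."""
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        conc = {
            "NfL": row["conc_nfl"],
            "NfM": row["conc_nfm"],
            "NfH_SMI35": row["conc_nfh_smi35"],
            "NfH_SMI34": row["conc_nfh_smi34"],
        }
        profiles.append(
            profile_from_concentrations(
                str(row["subject_id"]),
                conc,
                group=str(row["group"]),
                nfh_mode=nfh_mode,
                pg_per_ml=pg_per_ml,
            )
        )
    return profiles


def profiles_to_csv(profiles: Sequence[ParticleProfile], path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "group": [p.group for p in profiles],
            "nfl": [p.counts["NfL"] for p in profiles],
            "nfm": [p.counts["NfM"] for p in profiles],
            "nfh": [p.counts["NfH"] for p in profiles],
            "calibrated": [p.calibrated for p in profiles],
        }
    )
    df.to_csv(path, index=False)


def calibration_report(
    factors: CalibrationFactors,
    control: Sequence[ParticleProfile],
    als: Sequence[ParticleProfile],
) -> dict:
    """JSON-serialisable calibration report with factors and stoichiometries."""
    return {
        "factors": {"x": factors.x, "y": factors.y, "z": factors.z},
        "control": list(cohort_stoichiometry(control)),
        "als": list(cohort_stoichiometry(als)) if len(als) else None,
    }


def write_calibration_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
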