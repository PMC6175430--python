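"""End-to-end pipeline: simulate -> calibrate -> cost -> brush -> stats.

Each stochastic stage receives a deterministic sub-seed derived by hashing
(global seed, stage name), so enabling or re-ordering stages never perturbs
another stage's random stream and a (config, seed) pair fully determines the
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import brush as brush_mod
from . import calibration as calib
from . import cohort as cohort_mod
from . import cost as cost_mod
from . import stats as stats_mod
from .constants import ADAPTIVE_STOICHIOMETRY, PHYSIOLOGICAL_STOICHIOMETRY, constants_table


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "nfstoich_run"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "calibrate": True,
            "cost": True,
            "brush": True,
            "stats": True,
        }
    )
    cohort_csv: str | None = None  # input CSV when simulate is disabled
    nfh_mode: str = "smi35_only"
    pg_per_ml: bool = False
    luxury_anchor: str = "max"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    #: Brush stage parameters.  The pipeline default runs a reduced system
    #: (single backbone, length-scaled arms, short sweeps) per mixture and
    #: phosphorylation state; full-scale runs go through the brush API or
    #: the `brush` subcommand with an explicit config.
    brush: dict = field(
        default_factory=lambda: {
            "length_scale": 0.1,
            "n_backbones": 1,
            "sweeps_equil": 200,
            "sweeps_prod": 200,
            "sample_every": 20,
            "phospho_states": [False, True],
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                if f.name in ("stages", "brush"):
                    merged = dict(getattr(cls(), f.name))
                    merged.update(data[f.name])
                    kwargs[f.name] = merged
                else:
                    kwargs[f.name] = data[f.name]
        return cls(**kwargs)


def _brush_config(run: RunConfig, stoichiometry, phosphorylated: bool,
                  seed: int) -> brush_mod.BrushConfig:
    b = run.brush
    specs = brush_mod.load_sidearm_specs(b.get("sidearm_table"))
    scale = float(b.get("length_scale", 1.0))
    if scale != 1.0:
        specs = {k: brush_mod.coarsen_sidearm_spec(v, scale) for k, v in specs.items()}
    kwargs = {
        k: v
        for k, v in b.items()
        if k not in ("length_scale", "phospho_states", "sidearm_table")
    }
    return brush_mod.BrushConfig(
        stoichiometry=tuple(stoichiometry),
        phosphorylated=phosphorylated,
        seed=seed,
        arm_specs=specs,
        **kwargs,
    )


def run_pipeline(run: RunConfig) -> dict:
    """Execute the enabled stages in order and write the combined report.

    Returns the report dict; artifacts (cohort CSV, calibrated profiles CSV,
    per-subject cost CSV, brush sample CSVs, report.json) land in
    ``run.outdir``.
    """
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "constants": constants_table(),
        "seed": run.seed,
        "flags": {
            "nfh_mode": run.nfh_mode,
            "pg_per_ml": run.pg_per_ml,
            "luxury_anchor": run.luxury_anchor,
        },
        "stages": {},
    }
    stages = run.stages

    # --- simulate ---------------------------------------------------------
    cohort_path = run.cohort_csv
    if stages.get("simulate"):
        cfg = cohort_mod.CohortConfig(
            seed=derive_seed(run.seed, "simulate"), **run.cohort
        )
        records = cohort_mod.generate_cohort(cfg)
        cohort_path = outdir / "cohort.csv"
        cohort_mod.write_cohort_csv(records, cohort_path)
        report["stages"]["simulate"] = {
            "n_control": cfg.n_control,
            "n_als": cfg.n_als,
            "seed": cfg.seed,
            "csv": Path(cohort_path).name,
        }
    elif stages.get("calibrate") or stages.get("cost") or stages.get("stats"):
        if cohort_path is None or not Path(cohort_path).exists():
            raise FileNotFoundError(
                "simulate disabled and no existing cohort_csv provided"
            )

    # --- calibrate --------------------------------------------------------
    calibrated = None
    if stages.get("calibrate"):
        profiles = calib.profiles_from_cohort_csv(
            cohort_path, nfh_mode=run.nfh_mode, pg_per_ml=run.pg_per_ml
        )
        controls = [p for p in profiles if p.group == "control"]
        calibrator = calib.StoichCalibrator().fit(controls)
        calibrated = calibrator.apply_cohort(profiles)
        calib.profiles_to_csv(calibrated, outdir / "calibrated_profiles.csv")
        ctrl = [p for p in calibrated if p.group == "control"]
        als = [p for p in calibrated if p.group == "ALS"]
        report["stages"]["calibrate"] = calib.calibration_report(
            calibrator.factors_, ctrl, als
        )

    # --- cost -------------------------------------------------------------
    if stages.get("cost"):
        if calibrated is None:
            raise RuntimeError("cost stage requires the calibrate stage")
        table = cost_mod.cohort_cost_table(calibrated, anchor=run.luxury_anchor)
        cost_mod.per_subject_cost_table(
            calibrated, anchor=run.luxury_anchor
        ).to_csv(outdir / "subject_costs.csv", index=False)
        report["stages"]["cost"] = {
            f"{row.scenario}/{row.group}": {
                "atp_mean": row.atp_mean,
                "atp_sd": row.atp_sd,
                "time_h_mean": row.time_h_mean,
                "time_h_sd": row.time_h_sd,
                "n": int(row.n),
            }
            for row in table.itertuples()
        }

    # --- brush ------------------------------------------------------------
    if stages.get("brush"):
        mixtures = {
            "control": PHYSIOLOGICAL_STOICHIOMETRY,
            "adaptive": ADAPTIVE_STOICHIOMETRY,
        }
        brush_report = {}
        cells = {}
        for mix_name, stoich in mixtures.items():
            for phospho in run.brush.get("phospho_states", [False, True]):
                seed = derive_seed(run.seed, f"brush:{mix_name}:{phospho}")
                cfg = _brush_config(run, stoich, phospho, seed)
                summary = brush_mod.run_simulation(cfg)
                tag = f"{mix_name}_{'p' if phospho else 'np'}"
                brush_mod.write_samples_csv(
                    summary, outdir / f"brush_{tag}_samples.csv"
                )
                brush_report[tag] = brush_mod.summary_report(summary)
                for sp in brush_mod.SPECIES:
                    samp = summary.species_samples(sp)
                    if len(samp):
                        cells[(mix_name, sp, phospho)] = samp
        if len(cells) >= 2:
            contrasts = brush_mod.gyration_contrasts(cells)
            brush_report["contrasts"] = {
                "omnibus": stats_mod.stats_report(
                    {"gyration": contrasts["omnibus"]}
                )["gyration"],
                "pairwise": contrasts["contrasts"].to_dict(orient="records"),
            }
        report["stages"]["brush"] = brush_report

    # --- stats ------------------------------------------------------------
    if stages.get("stats"):
        if calibrated is None:
            raise RuntimeError("stats stage requires the calibrate stage")
        results = {}
        ctrl = [p for p in calibrated if p.group == "control"]
        als = [p for p in calibrated if p.group == "ALS"]
        for k, iso in enumerate(("NfL", "NfM", "NfH")):
            x = np.array([p.as_array()[k] for p in ctrl])
            y = np.array([p.as_array()[k] for p in als])
            results[f"{iso}_control_vs_als"] = stats_mod.two_group_test(x, y)

        df = pd.read_csv(cohort_path)
        als_rows = df[df["group"] == "ALS"].set_index("subject_id")
        cats, als_with_cats = [], []
        for p in als:
            row = als_rows.loc[p.subject_id]
            if pd.notna(row["alsfrs_baseline"]) and pd.notna(
                row["months_onset_to_baseline"]
            ):
                rate = cohort_mod.progression_rate(
                    int(row["alsfrs_baseline"]),
                    float(row["months_onset_to_baseline"]),
                )
                cats.append(cohort_mod.progression_category(rate))
                als_with_cats.append(p)
        if len(set(cats)) >= 2:
            prog = stats_mod.progression_association(als_with_cats, cats)
            for iso, res in prog.items():
                results[f"{iso}_progression"] = res

        if stages.get("cost"):
            costs = cost_mod.per_subject_cost_table(
                calibrated, anchor=run.luxury_anchor
            )
            vals, labels = [], []
            for _, r in costs.iterrows():
                if r["group"] == "control":
                    vals.append(r["atp_adaptive"])
                    labels.append("control_adaptive")
                else:
                    vals.append(r["atp_adaptive"])
                    labels.append("als_adaptive")
                    vals.append(r["atp_luxury"])
                    labels.append("als_luxury")
            results["atp_scenarios"] = stats_mod.multi_group_glm(vals, labels)
        report["stages"]["stats"] = stats_mod.stats_report(results)

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
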