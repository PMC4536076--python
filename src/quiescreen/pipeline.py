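"""End-to-end orchestration: simulate -> QC -> hit calling -> dose-response ->
selectivity -> kinetics -> qPCR, with persisted artifacts and a run summary.

Every artifact a stage consumes is written to the output directory, so each
stage is individually re-runnable from its persisted inputs; given the same
config and seed the result tables are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .doseresponse import fit_table
from .exceptions import ConfigError
from .hits import HitCriteria, call_primary, call_secondary, confirmed_sets, reconcile
from .kinetics import PeakAreaSeries, fit_kinetics
from .plate_io import read_plate_table, write_plate_table, write_run_summary
from .qc import compute_plate_stats, normalize_wells
from .qpcr import ddct_fold, delta_ct, detection_filter
from .selectivity import classify_table, specificity_profile
from .simulate import (
    ScreenSimConfig,
    generate_screen_plates,
    generate_secondary_plates,
)

logger = logging.getLogger("quiescreen")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (YAML-serialisable)."""

    seed: int = 0
    outdir: str = "quiescreen_out"
    # stage toggles / inputs
    simulate: bool = True
    primary_plate_files: dict[str, str] = field(default_factory=dict)
    secondary_plate_files: dict[str, str] = field(default_factory=dict)
    dose_response_file: str | None = None
    kinetics_file: str | None = None
    ct_file: str | None = None
    # simulation parameters (used when simulate=True)
    n_compounds: int = 1120
    well_cv: float = 0.07
    pos_ctrl_kill_fraction: float = 0.9
    actives: dict = field(default_factory=dict)
    # thresholds
    pct_threshold: float = 5.0
    sd_multiplier_primary: float = 5.0
    sd_multiplier_secondary_quiescent: float = 5.0
    sd_multiplier_secondary_proliferating: float = 3.0
    increase_threshold_pct: float = 200.0
    confirm_concentration_uM: float = 50.0
    censor_max_uM: float = 100.0
    detection_threshold_cycles: float = 21.0
    housekeeping_gene: str = "18S"
    calibrator_sample: str = "proliferating"

    def __post_init__(self):
        for name in (
            "pct_threshold",
            "sd_multiplier_primary",
            "sd_multiplier_secondary_quiescent",
            "sd_multiplier_secondary_proliferating",
            "confirm_concentration_uM",
            "censor_max_uM",
            "detection_threshold_cycles",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for files in (self.primary_plate_files, self.secondary_plate_files):
            for cond, path in files.items():
                if not Path(path).exists():
                    raise ConfigError(f"input file for {cond!r} not found: {path}")
        for path in (self.dose_response_file, self.kinetics_file, self.ct_file):
            if path and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _hit_criteria(cfg: RunConfig) -> tuple[HitCriteria, dict[str, HitCriteria]]:
    primary = HitCriteria(
        pct_threshold=cfg.pct_threshold,
        sd_multiplier=cfg.sd_multiplier_primary,
        increase_threshold_pct=cfg.increase_threshold_pct,
    )
    secondary = {
        "quiescent": HitCriteria(
            pct_threshold=cfg.pct_threshold,
            sd_multiplier=cfg.sd_multiplier_secondary_quiescent,
        ),
        "proliferating": HitCriteria(
            pct_threshold=cfg.pct_threshold,
            sd_multiplier=cfg.sd_multiplier_secondary_proliferating,
        ),
    }
    return primary, secondary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the run report (also written to
    ``<outdir>/run_summary.json``).  Any stage error aborts with a
    stage-named message; artifacts written so far are retained."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "stages": {},
    }
    try:
        _run_screen(cfg, out, report)
        _run_dose_response(cfg, out, report)
        _run_kinetics(cfg, out, report)
        _run_qpcr(cfg, out, report)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        report["error"] = str(exc)
        write_run_summary(out / "run_summary.json", report)
        raise
    write_run_summary(out / "run_summary.json", report)
    return report


def _run_screen(cfg: RunConfig, out: Path, report: dict) -> None:
    # ---- inputs: simulated or read from disk -------------------------------
    if cfg.simulate:
        sim_cfg = ScreenSimConfig(
            n_compounds=cfg.n_compounds,
            well_cv=cfg.well_cv,
            pos_ctrl_kill_fraction=cfg.pos_ctrl_kill_fraction,
            actives={
                cid: {cond: tuple(v) for cond, v in conds.items()}
                for cid, conds in cfg.actives.items()
            },
            seed=cfg.seed,
        )
        primary_tables, truth = generate_screen_plates(sim_cfg)
        truth.to_csv(out / "truth.csv", index=False)
        primary_hit_ids = sorted(truth.loc[truth["active"], "compound_id"].unique())
        secondary_tables = generate_secondary_plates(sim_cfg, primary_hit_ids)
        for cond, table in primary_tables.items():
            write_plate_table(table, out / f"plates_primary_{cond}.csv")
        for cond, table in secondary_tables.items():
            write_plate_table(table, out / f"plates_secondary_{cond}.csv")
        report["stages"]["simulate"] = {
            "n_compounds": cfg.n_compounds,
            "n_true_actives": len(primary_hit_ids),
        }
    else:
        if not cfg.primary_plate_files:
            return  # no screen stage configured
        primary_tables = {
            cond: read_plate_table(path) for cond, path in cfg.primary_plate_files.items()
        }
        secondary_tables = {
            cond: read_plate_table(path)
            for cond, path in cfg.secondary_plate_files.items()
        }

    primary_criteria, secondary_criteria = _hit_criteria(cfg)
    prim_calls, sec_calls = [], []
    for cond, table in primary_tables.items():
        qc = compute_plate_stats(table)
        for r in qc.itertuples(index=False):
            logger.info(
                "primary %s plate %s: Z'=%.3f passed=%s", cond, r.plate_id, r.z_prime, r.passed
            )
        qc.to_csv(out / f"qc_primary_{cond}.csv", index=False)
        norm = normalize_wells(table, qc)
        norm.to_csv(out / f"normalized_primary_{cond}.csv", index=False)
        prim_calls.append(call_primary(norm, qc, primary_criteria))
        report["stages"].setdefault("qc", {})[f"primary_{cond}"] = {
            "n_plates": len(qc),
            "n_failed": int((~qc["passed"]).sum()),
            "median_z_prime": float(qc["z_prime"].median()),
        }
    primary = pd.concat(prim_calls, ignore_index=True)
    primary.to_csv(out / "hits_primary.csv", index=False)

    for cond, table in secondary_tables.items():
        qc = compute_plate_stats(table)
        qc.to_csv(out / f"qc_secondary_{cond}.csv", index=False)
        norm = normalize_wells(table, qc)
        sec_calls.append(call_secondary(norm, qc, secondary_criteria))
        report["stages"].setdefault("qc", {})[f"secondary_{cond}"] = {
            "n_plates": len(qc),
            "n_failed": int((~qc["passed"]).sum()),
            "median_z_prime": float(qc["z_prime"].median()),
        }
    secondary = (
        pd.concat(sec_calls, ignore_index=True)
        if sec_calls
        else pd.DataFrame(columns=primary.columns)
    )
    secondary.to_csv(out / "hits_secondary.csv", index=False)

    confirmed = reconcile(primary, secondary, cfg.confirm_concentration_uM)
    confirmed.to_csv(out / "confirmed.csv", index=False)
    sets = confirmed_sets(confirmed)
    report["stages"]["hit_calling"] = {
        "n_primary_hits": {
            cond: int(grp["is_hit"].sum())
            for cond, grp in primary.groupby("condition")
        },
        "n_confirmed": {k: len(v) for k, v in sets.items()},
        "n_untested": int((confirmed["status"] == "untested").sum()),
    }


def _run_dose_response(cfg: RunConfig, out: Path, report: dict) -> None:
    if not cfg.dose_response_file:
        return
    df = pd.read_csv(cfg.dose_response_file)
    fits = fit_table(df)
    fits.to_csv(out / "dose_response_fits.csv", index=False)
    # selectivity classification needs paired P/Q fits per compound
    pivot = fits.pivot_table(
        index="compound_id", columns="condition", values="reported_ec50", aggfunc="first"
    )
    if {"proliferating", "quiescent"} <= set(pivot.columns):
        pairs = pivot.rename(
            columns={"proliferating": "ec50_p", "quiescent": "ec50_q"}
        ).reset_index()[["compound_id", "ec50_p", "ec50_q"]]
        classified = classify_table(pairs)
        classified.to_csv(out / "selectivity.csv", index=False)
        for r in classified[classified["boundary_flag"]].itertuples(index=False):
            logger.warning(
                "boundary classification for %s (ratio %s)", r.compound_id, r.ratio_or_bound
            )
        report["stages"]["selectivity"] = classified["group"].value_counts().to_dict()
    long = fits.rename(columns={"condition": "context"})
    profile = specificity_profile(long)
    profile.potency.to_csv(out / "specificity_potency.csv")
    profile.censored.to_csv(out / "specificity_censored.csv")
    report["stages"]["dose_response"] = {
        "n_fits": len(fits),
        "n_censored": int((fits["censored"] == "above_range").sum()),
        "n_not_converged": int((~fits["converged"]).sum()),
    }


def _run_kinetics(cfg: RunConfig, out: Path, report: dict) -> None:
    if not cfg.kinetics_file:
        return
    df = pd.read_csv(cfg.kinetics_file)
    series = PeakAreaSeries.from_dataframe(df)
    res = fit_kinetics(series)
    payload = {
        "a0": res.params.a0,
        "k1_per_h": res.params.k1,
        "k2_per_h": res.params.k2,
        "half_life_parent_h": res.half_life_parent,
        "half_life_parent_se_h": res.half_life_parent_se,
        "converged": res.converged,
        "rss": res.rss,
    }
    (out / "kinetics_fit.json").write_text(json.dumps(payload, indent=2))
    report["stages"]["kinetics"] = payload


def _run_qpcr(cfg: RunConfig, out: Path, report: dict) -> None:
    if not cfg.ct_file:
        return
    df = pd.read_csv(cfg.ct_file)
    exp_col = "experiment" if "experiment" in df.columns else None
    folds = ddct_fold(
        df,
        housekeeping=cfg.housekeeping_gene,
        calibrator=cfg.calibrator_sample,
        experiment_col=exp_col,
    )
    folds.to_csv(out / "qpcr_folds.csv", index=False)
    dct = delta_ct(df, housekeeping=cfg.housekeeping_gene, experiment_col=exp_col)
    retained = detection_filter(dct, cfg.detection_threshold_cycles)
    report["stages"]["qpcr"] = {
        "n_genes": int(folds["gene"].nunique()),
        "n_retained_by_detection_filter": len(retained),
    }
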