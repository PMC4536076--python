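"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the measurement model the analysis assumes, not the
underlying cell biology: a 96-well ATP-luminescence plate carries 12
negative-control (vehicle) wells, 4 positive-control (fully cytotoxic) wells
and 80 compound wells; well luminescence is baseline x viability x
multiplicative lognormal noise.  The default library size of 1120 compounds
fills 14 plates per condition.  Proliferating and quiescent conditions are
seeded at different cell densities, hence distinct baseline luminescence.

Every generator is a pure function of (config, seed): the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import FourPLParams, four_pl
from .exceptions import ConfigError
from .kinetics import KineticsParams, PeakAreaSeries, abc_concentrations
from .plate_io import COLUMNS as PLATE_COLUMNS, PlateTable, ROWS

#: five sampling times (hours) of the default stability time course
STABILITY_TIMES_H = (2.0 / 60.0, 2.0, 4.0, 6.0, 24.0)

#: default dose grid: 10-point 3-fold dilution from 100 uM
def default_dose_grid(top: float = 100.0, n_points: int = 10, dilution: float = 3.0):
    return tuple(top / dilution**i for i in range(n_points))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


# fixed control-well positions (the published layout gives counts only; the
# positions are a package convention): column 1 and A12-D12 negative,
# E12-H12 positive, compounds in columns 2-11
NEG_WELLS = tuple((r, 1) for r in ROWS) + tuple((r, 12) for r in "ABCD")
POS_WELLS = tuple((r, 12) for r in "EFGH")
COMPOUND_WELLS = tuple((r, c) for c in range(2, 12) for r in ROWS)


@dataclass
class ScreenSimConfig:
    """Study conditions of the simulated primary/secondary screen."""

    n_compounds: int = 1120
    n_neg: int = 12
    n_pos: int = 4
    n_compound_wells: int = 80
    #: per-condition baseline luminescence (RLU); quiescent plates are seeded
    #: denser (40k vs 30k cells/well), hence the higher baseline
    baseline: dict[str, float] = field(
        default_factory=lambda: {"proliferating": 750_000.0, "quiescent": 1_000_000.0}
    )
    well_cv: float = 0.07
    pos_ctrl_kill_fraction: float = 0.9
    #: multiplicative row/column gradient amplitude (0 = off); at amplitude g
    #: the signal ramps linearly by +/- g/2 across rows and across columns,
    #: emulating evaporation/temperature edge effects to stress-test QC
    edge_gradient: float = 0.0
    screen_concentration_uM: float = 50.0
    #: compound -> condition -> (viability at 50 uM, viability at 5 uM)
    actives: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_neg + self.n_pos + self.n_compound_wells != 96:
            raise ConfigError("plate layout must sum to 96 wells")
        if self.well_cv < 0:
            raise ConfigError("well_cv must be >= 0")
        for cid, conds in self.actives.items():
            for cond, viab in conds.items():
                if not all(0 <= v <= 1 for v in viab):
                    raise ConfigError(
                        f"viability fractions must lie in [0,1] ({cid}, {cond})"
                    )

    def compound_ids(self) -> list[str]:
        return [f"PW-{i + 1:04d}" for i in range(self.n_compounds)]

    def viability(self, compound_id: str, condition: str, concentration: float) -> float:
        conds = self.actives.get(compound_id, {})
        if condition not in conds:
            return 1.0
        v50, v5 = conds[condition]
        return v50 if concentration >= 50.0 else v5


def _make_plate(
    cfg: ScreenSimConfig,
    rng: np.random.Generator,
    plate_id: str,
    condition: str,
    compound_wells: list[tuple[str, float, tuple[str, int]]],
) -> list[dict]:
    base = cfg.baseline[condition]
    records = []
    for row, col in NEG_WELLS[: cfg.n_neg]:
        records.append((plate_id, row, col, "neg_ctrl", "DMSO", 1.0, condition, base))
    for row, col in POS_WELLS[: cfg.n_pos]:
        lum = base * (1.0 - cfg.pos_ctrl_kill_fraction)
        records.append((plate_id, row, col, "pos_ctrl", "ophiobolin_A", 50.0, condition, lum))
    for cid, conc, (row, col) in compound_wells:
        lum = base * cfg.viability(cid, condition, conc)
        records.append((plate_id, row, col, "compound", cid, conc, condition, lum))
    noise = _lognormal_factor(rng, cfg.well_cv, len(records))

    def gradient(row: str, col: int) -> float:
        if cfg.edge_gradient == 0.0:
            return 1.0
        g = cfg.edge_gradient
        return (1.0 + g * (ROWS.index(row) / 7.0 - 0.5)) * (
            1.0 + g * ((col - 1) / 11.0 - 0.5)
        )

    return [
        {
            "plate_id": p, "row": r, "col": c, "role": role,
            "compound_id": cid, "concentration_uM": conc,
            "condition": cond, "luminescence": lum * gradient(r, c) * nz,
        }
        for (p, r, c, role, cid, conc, cond, lum), nz in zip(records, noise)
    ]


def truth_table(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Ground-truth active flags and viabilities per compound x condition."""
    rows = []
    for cid in cfg.compound_ids():
        for cond in cfg.baseline:
            v50, v5 = cfg.actives.get(cid, {}).get(cond, (1.0, 1.0))
            rows.append(
                {
                    "compound_id": cid,
                    "condition": cond,
                    "active": (cid in cfg.actives and cond in cfg.actives[cid]),
                    "viability_50uM": v50,
                    "viability_5uM": v5,
                }
            )
    return pd.DataFrame(rows)


def generate_screen_plates(
    cfg: ScreenSimConfig,
) -> tuple[dict[str, PlateTable], pd.DataFrame]:
    """Primary-screen plates (one well per compound) for every condition.

    Returns ({condition: PlateTable}, truth table).  1120 compounds at 80
    per plate fill 14 plates per condition.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = cfg.compound_ids()
    tables = {}
    for cond in cfg.baseline:
        records = []
        for p, start in enumerate(range(0, len(ids), cfg.n_compound_wells)):
            batch = ids[start : start + cfg.n_compound_wells]
            wells = [
                (cid, cfg.screen_concentration_uM, COMPOUND_WELLS[i])
                for i, cid in enumerate(batch)
            ]
            pid = f"{cond[:1].upper()}-{p + 1:02d}"
            records += _make_plate(cfg, rng, pid, cond, wells)
        tables[cond] = PlateTable(
            pd.DataFrame(records), {"stage": "primary", "condition": cond, "seed": cfg.seed}
        )
    return tables, truth_table(cfg)


def generate_secondary_plates(
    cfg: ScreenSimConfig,
    compounds: list[str],
    concentrations: tuple[float, float] = (50.0, 5.0),
    n_replicates: int = 2,
) -> dict[str, PlateTable]:
    """Secondary-screen plates: each listed compound in duplicate at two
    concentrations, same layout and noise model as the primary plates."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    per_plate = cfg.n_compound_wells
    jobs = [
        (cid, conc)
        for cid in compounds
        for conc in concentrations
        for _ in range(n_replicates)
    ]
    tables = {}
    for cond in cfg.baseline:
        records = []
        for p, start in enumerate(range(0, len(jobs), per_plate)):
            batch = jobs[start : start + per_plate]
            wells = [
                (cid, conc, COMPOUND_WELLS[i]) for i, (cid, conc) in enumerate(batch)
            ]
            pid = f"{cond[:1].upper()}-sec-{p + 1:02d}"
            records += _make_plate(cfg, rng, pid, cond, wells)
        df = pd.DataFrame(records, columns=PLATE_COLUMNS)
        tables[cond] = PlateTable(
            df, {"stage": "secondary", "condition": cond, "seed": cfg.seed}
        )
    return tables


def generate_dose_response(
    truth: FourPLParams,
    concentrations=None,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    compound_id: str = "compound",
    condition: str = "quiescent",
) -> tuple[pd.DataFrame, FourPLParams]:
    """Noisy dose-response table from a known 4PL truth.

    responses = four_pl(x, truth) x lognormal(1, cv).  Default design is the
    triplicate 10-point 3-fold dilution from 100 uM.
    """
    conc = np.array(concentrations if concentrations is not None else default_dose_grid())
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        y = four_pl(conc, truth) * _lognormal_factor(rng, cv, conc.shape)
        for c, v in zip(conc, y):
            rows.append(
                {
                    "compound_id": compound_id,
                    "condition": condition,
                    "concentration_uM": c,
                    "replicate": rep,
                    "response_pct": v,
                }
            )
    return pd.DataFrame(rows), truth


def generate_kinetics_series(
    truth: KineticsParams,
    times=STABILITY_TIMES_H,
    cv: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[PeakAreaSeries, KineticsParams]:
    """Noisy peak-area series from a known sequential-kinetics truth.

    areas = response_factor x closed-form amount x lognormal(1, cv), sampled
    at the five default stability timepoints (2 min, 2, 4, 6, 24 h).
    """
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    A, B, C = abc_concentrations(t, truth)
    fA, fB, fC = truth.response_factors
    areas = {
        "bisacodyl": fA * A * _lognormal_factor(rng, cv, t.shape),
        "monoester": fB * B * _lognormal_factor(rng, cv, t.shape),
        "ddpm": fC * C * _lognormal_factor(rng, cv, t.shape),
    }
    return PeakAreaSeries(t, areas), truth


def generate_ct_table(
    fold_truth: dict[str, dict[str, float]],
    housekeeping: str = "18S",
    housekeeping_ct: float = 10.0,
    calibrator: str = "proliferating",
    delta_ct_calibrator: float = 15.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Ct table whose ddCt analysis recovers known fold changes.

    ``fold_truth`` maps gene -> sample -> fold relative to the calibrator;
    gene Ct = housekeeping Ct + dCt_calibrator - log2(fold) + noise, with a
    noise-free housekeeping gene constant across samples by construction.
    """
    rng = np.random.default_rng(seed)
    samples = sorted({s for folds in fold_truth.values() for s in folds} | {calibrator})
    rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"gene": housekeeping, "sample": sample, "replicate": rep, "ct": housekeeping_ct}
            )
    for gene, folds in fold_truth.items():
        for sample in samples:
            fold = 1.0 if sample == calibrator else folds.get(sample, 1.0)
            ct = housekeeping_ct + delta_ct_calibrator - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "sample": sample, "replicate": rep, "ct": ct + noise}
                )
    return pd.DataFrame(rows), fold_truth
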