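"""Primary and secondary hit calling on normalized screen plates.

A compound well is a primary cytotoxicity hit when either criterion fires
(strict inequalities; boundary equality is a non-hit):

* percent branch — relative ATP < 5 % of the plate's negative-control mean;
* SD branch — luminescence < mu_neg - 5 * sigma_neg of its plate.

Secondary screening retests hits in duplicate at 50 and 5 uM; duplicates are
averaged on the relative-ATP scale before thresholding.  Quiescent-condition
plates keep the 5-SD multiplier; proliferating plates use 3 SD because of
their higher variability.  Compounds on plates failing the Z' gate are
reported as untested ("excluded"), never as non-hits.

ATP-increase candidates are called with a symmetric convention
(relative ATP > 200 % or luminescence > mu_neg + k*sigma_neg) — an artifact
convention of this package, since increasers were tracked upstream without a
stated criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .exceptions import AmbiguityError

HIT_COLUMNS = [
    "compound_id",
    "condition",
    "stage",
    "concentration_uM",
    "plate_id",
    "relative_atp_pct",
    "met_pct",
    "met_sd",
    "is_hit",
    "n_wells",
    "excluded_reason",
]


@dataclass(frozen=True)
class HitCriteria:
    """Thresholds for one condition/stage.

    ``pct_threshold`` is on the relative-ATP scale (percent of control),
    ``sd_multiplier`` counts negative-control SDs below (or above, for
    ``direction='increase'``) the negative-control mean.
    """

    pct_threshold: float = 5.0
    sd_multiplier: float = 5.0
    direction: str = "decrease"
    increase_threshold_pct: float = 200.0

    def __post_init__(self):
        if not 0 < self.pct_threshold < 100:
            raise ValueError("pct_threshold must lie in (0, 100)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.direction not in ("decrease", "increase"):
            raise ValueError("direction must be 'decrease' or 'increase'")


#: secondary-screen defaults per condition
SECONDARY_CRITERIA = {
    "quiescent": HitCriteria(sd_multiplier=5.0),
    "proliferating": HitCriteria(sd_multiplier=3.0),
}


def _sd_threshold_pct(qc_row: pd.Series, k: float, direction: str) -> float:
    # the SD criterion expressed on the relative-ATP scale of that plate
    sign = -1.0 if direction == "decrease" else 1.0
    return 100.0 * (1.0 + sign * k * qc_row["sigma_neg"] / qc_row["mu_neg"])


def _evaluate(rel: float, sd_pct: float, crit: HitCriteria) -> tuple[bool, bool]:
    if crit.direction == "decrease":
        met_pct = rel < crit.pct_threshold
        met_sd = rel < sd_pct
    else:
        met_pct = rel > crit.increase_threshold_pct
        met_sd = rel > sd_pct
    return bool(met_pct), bool(met_sd)


def call_primary(
    norm: pd.DataFrame, qc: pd.DataFrame, criteria: HitCriteria | None = None
) -> pd.DataFrame:
    """Single-point hit calls for the primary screen (one well per compound).

    ``norm`` is the output of :func:`quiescreen.qc.normalize_wells`.  A
    compound appearing on more than one well within a condition raises
    :class:`AmbiguityError` — each molecule is tested once at this stage.
    """
    criteria = criteria or HitCriteria()
    stats = qc.set_index("plate_id")
    wells = norm[norm["role"] == "compound"]
    dup = wells.duplicated(subset=["compound_id", "condition"], keep=False)
    if dup.any():
        names = sorted(wells.loc[dup, "compound_id"].unique())
        raise AmbiguityError(
            f"compounds on >1 primary well (each molecule is tested once): {names[:10]}"
        )
    calls = []
    for w in wells.itertuples(index=False):
        qrow = stats.loc[w.plate_id]
        excluded = None if qrow["passed"] else "plate_failed_qc"
        met_pct, met_sd = _evaluate(
            w.relative_atp, _sd_threshold_pct(qrow, criteria.sd_multiplier, criteria.direction), criteria
        )
        calls.append(
            {
                "compound_id": w.compound_id,
                "condition": w.condition,
                "stage": "primary",
                "concentration_uM": w.concentration_uM,
                "plate_id": w.plate_id,
                "relative_atp_pct": w.relative_atp,
                "met_pct": met_pct,
                "met_sd": met_sd,
                "is_hit": bool((met_pct or met_sd) and excluded is None),
                "n_wells": 1,
                "excluded_reason": excluded,
            }
        )
    return pd.DataFrame(calls, columns=HIT_COLUMNS)


def call_secondary(
    norm: pd.DataFrame,
    qc: pd.DataFrame,
    criteria_by_condition: dict[str, HitCriteria] | None = None,
) -> pd.DataFrame:
    """Duplicate-well hit calls per compound x condition x concentration.

    Duplicates are averaged on the relative-ATP scale before the criteria
    are applied; the per-plate SD threshold (on the relative scale) is
    likewise averaged over the wells' plates.  A missing duplicate produces
    a warning and a single-well call flagged in ``excluded_reason``.
    """
    criteria_by_condition = criteria_by_condition or SECONDARY_CRITERIA
    stats = qc.set_index("plate_id")
    wells = norm[norm["role"] == "compound"]
    calls = []
    for (cid, cond, conc), grp in wells.groupby(
        ["compound_id", "condition", "concentration_uM"], sort=True
    ):
        crit = criteria_by_condition.get(cond, HitCriteria())
        qrows = stats.loc[grp["plate_id"]]
        if not qrows["passed"].all():
            excluded = "plate_failed_qc"
        elif len(grp) < 2:
            warnings.warn(
                f"missing duplicate for {cid} ({cond}, {conc} uM); "
                "calling on the single well",
                stacklevel=2,
            )
            excluded = "missing_duplicate"
        else:
            excluded = None
        rel = float(grp["relative_atp"].mean())
        sd_pct = float(
            qrows.apply(_sd_threshold_pct, axis=1, k=crit.sd_multiplier, direction=crit.direction).mean()
        )
        met_pct, met_sd = _evaluate(rel, sd_pct, crit)
        calls.append(
            {
                "compound_id": cid,
                "condition": cond,
                "stage": "secondary",
                "concentration_uM": conc,
                "plate_id": ";".join(sorted(grp["plate_id"].unique())),
                "relative_atp_pct": rel,
                "met_pct": met_pct,
                "met_sd": met_sd,
                "is_hit": bool((met_pct or met_sd) and excluded != "plate_failed_qc"),
                "n_wells": len(grp),
                "excluded_reason": excluded,
            }
        )
    return pd.DataFrame(calls, columns=HIT_COLUMNS)


def reconcile(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    confirm_concentration: float = 50.0,
) -> pd.DataFrame:
    """Confirmed-compound table: a compound is confirmed for a condition iff
    it is a primary hit and a secondary hit at the confirmation concentration
    (50 uM by default) for that condition.

    The returned frame has one row per compound x condition with
    ``primary_hit``, ``secondary_hit``, ``confirmed`` and ``status``
    ('confirmed', 'not_confirmed' or 'untested' when either stage was
    excluded by plate QC).
    """
    prim = primary.set_index(["compound_id", "condition"])
    sec50 = secondary[secondary["concentration_uM"] == confirm_concentration]
    sec = sec50.set_index(["compound_id", "condition"])
    rows = []
    for key in prim.index:
        p = prim.loc[key]
        if key in sec.index:
            s = sec.loc[key]
            sec_hit = bool(s["is_hit"])
            sec_excl = s["excluded_reason"] == "plate_failed_qc"
        else:
            sec_hit, sec_excl = False, False
        untested = p["excluded_reason"] == "plate_failed_qc" or sec_excl
        confirmed = bool(p["is_hit"] and sec_hit and not untested)
        rows.append(
            {
                "compound_id": key[0],
                "condition": key[1],
                "primary_hit": bool(p["is_hit"]),
                "secondary_hit": sec_hit,
                "confirmed": confirmed,
                "status": "untested" if untested else ("confirmed" if confirmed else "not_confirmed"),
            }
        )
    return pd.DataFrame(rows)


def confirmed_sets(reconciled: pd.DataFrame) -> dict[str, set[str]]:
    """Per-condition confirmed compound sets plus their intersection."""
    out: dict[str, set[str]] = {}
    for cond, grp in reconciled.groupby("condition"):
        out[cond] = set(grp.loc[grp["confirmed"], "compound_id"])
    if len(out) > 1:
        out["intersection"] = set.intersection(*[v for k, v in out.items()])
    return out
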