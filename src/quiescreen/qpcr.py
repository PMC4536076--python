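"""Relative gene-expression quantification: dCt, ddCt and 2^-ddCt folds.

Conventions (Livak method, amplification efficiency fixed at 2):

* replicate Ct values are averaged arithmetically within each experiment;
* dCt = Ct_gene - Ct_housekeeping per sample (housekeeping default 18S);
* ddCt = dCt_sample - dCt_calibrator, fold = 2^(-ddCt), per experiment;
* across independent experiments the *folds* are averaged, not the ddCts
  (so a printed mean fold need not equal 2^(-mean ddCt)).

An array detection filter retains only genes whose dCt is <= a threshold
(default 21 cycles, inclusive) in at least one condition; larger dCts mark
low-expression genes with poor signal-to-noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DETECTION_THRESHOLD_CYCLES = 21.0


def _mean_ct(table: pd.DataFrame, experiment_col: str | None) -> pd.DataFrame:
    keys = ["gene", "sample"]
    if experiment_col:
        keys = [experiment_col] + keys
    return table.groupby(keys, sort=True)["ct"].mean().reset_index()


def delta_ct(
    table: pd.DataFrame,
    housekeeping: str = "18S",
    experiment_col: str | None = None,
) -> pd.DataFrame:
    """Replicate-averaged dCt per gene x sample (x experiment).

    Raises :class:`ValidationError` naming the sample if the housekeeping
    gene is missing for it.
    """
    for col in ("gene", "sample", "ct"):
        if col not in table.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    mean = _mean_ct(table, experiment_col)
    hk = mean[mean["gene"] == housekeeping]
    genes = mean[mean["gene"] != housekeeping]
    keys = ["sample"] + ([experiment_col] if experiment_col else [])
    hk_idexed = hk.set_index(keys)["ct"]
    missing = set(map(tuple, genes[keys].drop_duplicates().itertuples(index=False))) - set(
        hk_idexed.index if experiment_col else [(s,) for s in hk_idexed.index]
    )
    if missing:
        names = sorted({m[0] for m in missing})
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} missing for samples: {names}"
        )
    if experiment_col:
        ref = genes.set_index(keys).index.map(hk_idexed)
    else:
        ref = genes["sample"].map(hk_idexed)
    out = genes.copy()
    out["delta_ct"] = out["ct"].to_numpy() - np.asarray(ref, dtype=float)
    return out.drop(columns=["ct"])


def ddct_fold(
    table: pd.DataFrame,
    housekeeping: str = "18S",
    calibrator: str = "proliferating",
    experiment_col: str | None = None,
) -> pd.DataFrame:
    """Fold changes 2^(-ddCt) per gene x sample relative to the calibrator.

    When ``experiment_col`` names a column of independent experiments the
    ddCt and fold are computed within each experiment and the folds averaged
    across experiments (``fold_change`` = mean fold, ``fold_sd`` its SD,
    ``delta_delta_ct`` the mean ddCt).  Without it a single-experiment result
    is returned.  The calibrator sample has ddCt = 0 and fold = 1 exactly.
    """
    dct = delta_ct(table, housekeeping=housekeeping, experiment_col=experiment_col)
    cal = dct[dct["sample"] == calibrator]
    if cal.empty:
        raise ValidationError(f"calibrator sample {calibrator!r} not present")
    keys = ["gene"] + ([experiment_col] if experiment_col else [])
    cal_idx = cal.set_index(keys)["delta_ct"]
    ref = dct.set_index(keys).index.map(cal_idx)
    if pd.isna(np.asarray(ref, dtype=float)).any():
        bad = sorted(dct.loc[pd.isna(np.asarray(ref, dtype=float)), "gene"].unique())
        raise ValidationError(f"calibrator {calibrator!r} missing for genes: {bad}")
    dct = dct.copy()
    dct["delta_delta_ct"] = dct["delta_ct"].to_numpy() - np.asarray(ref, dtype=float)
    dct["fold"] = np.exp2(-dct["delta_delta_ct"])

    agg = (
        dct.groupby(["gene", "sample"], sort=True)
        .agg(
            delta_ct=("delta_ct", "mean"),
            delta_delta_ct=("delta_delta_ct", "mean"),
            fold_change=("fold", "mean"),
            fold_sd=("fold", "std"),
            n_experiments=("fold", "size"),
        )
        .reset_index()
    )
    return agg


def detection_filter(
    delta_cts: pd.DataFrame,
    threshold: float = DETECTION_THRESHOLD_CYCLES,
) -> list[str]:
    """Genes whose minimum dCt over conditions is <= ``threshold`` (inclusive).

    ``delta_cts`` is long (gene, sample/condition, delta_ct) as returned by
    :func:`delta_ct`, or wide with genes as the index.  Returns the retained
    gene names, sorted.
    """
    if "delta_ct" in getattr(delta_cts, "columns", []):
        mins = delta_cts.groupby("gene")["delta_ct"].min()
    else:
        mins = delta_cts.min(axis=1)
    return sorted(mins.index[mins <= threshold])
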