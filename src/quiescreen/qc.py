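"""Per-plate control statistics, Z' factor and relative-ATP normalization.

The Z' factor summarises the separation between the negative-control
(vehicle, DMSO) and positive-control (fully cytotoxic, ophiobolin A)
luminescence distributions on a plate::

    Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|

Z' <= 1 always; a plate passes QC iff Z' > 0.5 (strict).  Relative ATP in a
well is its luminescence as a percentage of the same plate's negative-control
mean, the viability proxy used by every downstream stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import NormalizationError
from .plate_io import PlateTable

Z_PRIME_GATE = 0.5

QC_COLUMNS = [
    "plate_id",
    "n_neg",
    "n_pos",
    "mu_neg",
    "sigma_neg",
    "mu_pos",
    "sigma_pos",
    "z_prime",
    "passed",
]


def z_prime(mu_neg: float, sigma_neg: float, mu_pos: float, sigma_pos: float) -> float:
    """Z' factor of one plate; NaN when the control means coincide
    (the statistic is undefined — division by zero)."""
    window = abs(mu_pos - mu_neg)
    if window == 0:
        return float("nan")
    return 1.0 - 3.0 * (sigma_pos + sigma_neg) / window


def compute_plate_stats(table: PlateTable, ddof: int = 1) -> pd.DataFrame:
    """Control statistics and Z' per plate.

    Control-well SDs use the sample convention (``ddof=1``) by default: the
    12 negative / 4 positive wells are samples of plate noise.  ``ddof=0``
    (population SD) is available since the convention used upstream of the
    published medians is unstated.

    Plates whose control means coincide get ``z_prime = NaN`` and fail;
    ``passed`` is the strict gate ``z_prime > 0.5``.
    """
    rows = []
    for pid in table.plate_ids:
        wells = table.wells(pid)
        neg = wells.loc[wells["role"] == "neg_ctrl", "luminescence"].to_numpy(float)
        pos = wells.loc[wells["role"] == "pos_ctrl", "luminescence"].to_numpy(float)
        if len(neg) < 2 or len(pos) < 2:
            raise NormalizationError(
                f"plate {pid}: need >=2 wells of each control role "
                f"(got {len(neg)} neg, {len(pos)} pos)"
            )
        mu_n, mu_p = float(np.mean(neg)), float(np.mean(pos))
        sd_n = float(np.std(neg, ddof=ddof))
        sd_p = float(np.std(pos, ddof=ddof))
        zp = z_prime(mu_n, sd_n, mu_p, sd_p)
        rows.append(
            {
                "plate_id": pid,
                "n_neg": len(neg),
                "n_pos": len(pos),
                "mu_neg": mu_n,
                "sigma_neg": sd_n,
                "mu_pos": mu_p,
                "sigma_pos": sd_p,
                "z_prime": zp,
                "passed": bool(np.isfinite(zp) and zp > Z_PRIME_GATE),
            }
        )
    return pd.DataFrame(rows, columns=QC_COLUMNS)


def normalize_wells(table: PlateTable, qc: pd.DataFrame) -> pd.DataFrame:
    """Relative ATP (% of plate negative-control mean) for every well.

    Controls are normalized too, so QC plots can be regenerated from the
    output; by construction the mean over a plate's neg_ctrl wells is 100.
    The returned frame is the well table plus ``relative_atp`` and
    ``plate_passed`` columns.
    """
    stats = qc.set_index("plate_id")
    missing = set(table.plate_ids) - set(stats.index)
    if missing:
        raise NormalizationError(f"no QC record for plates: {sorted(missing)}")
    bad = stats.loc[list(table.plate_ids)]
    nonpos = bad[bad["mu_neg"] <= 0]
    if len(nonpos):
        raise NormalizationError(
            f"mu_neg <= 0 on plates {sorted(nonpos.index)}; cannot normalize"
        )
    df = table.data.copy()
    mu = df["plate_id"].map(stats["mu_neg"])
    df["relative_atp"] = 100.0 * df["luminescence"] / mu
    df["plate_passed"] = df["plate_id"].map(stats["passed"]).astype(bool)
    return df
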