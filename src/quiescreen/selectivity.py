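"""Selectivity classification and cell-panel specificity profiles.

Compounds are classified by the ratio of their EC50 on proliferating cells
to that on quiescent cells (``ratio = EC50_P / EC50_Q``):

* group 3 — quiescent-selective: ratio >= 2 ("at least two-fold lower" on
  quiescent cells);
* group 2 — proliferating-selective: ratio <= 0.5 (more than two-fold lower
  on proliferating cells; the boundary 0.5 itself is assigned here so the
  classifiable compounds are always partitioned);
* group 1 — non-selective: 0.5 < ratio < 2.

Censored EC50s ("> 100") propagate as interval arithmetic on the ratio: a
group is assigned only when the whole interval satisfies its rule, otherwise
the compound is unclassified.  Ratios computed from rounded published values
that land near the two-fold boundary (within [1.9, 2.1] or its reciprocal
band) are flagged rather than forced into a group, since published
classifications were made from unrounded estimates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ratio bands (and reciprocals) that trigger boundary flagging
BOUNDARY_BAND = (1.9, 2.1)
BOUNDARY_BAND_RECIP = (1.0 / 2.1, 1.0 / 1.9)  # (0.476, 0.526)

_BOUND_RE = re.compile(r"^\s*>\s*([0-9.eE+-]+)\s*$")


def parse_ec50(value) -> tuple[float, bool]:
    """Return (value_uM, censored).  Accepts a number or a '> 100' bound."""
    if isinstance(value, str):
        m = _BOUND_RE.match(value)
        if not m:
            raise ValueError(f"unparseable EC50: {value!r} (expected number or '> bound')")
        return float(m.group(1)), True
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"EC50 must be a positive finite number, got {value!r}")
    return v, False


@dataclass
class SelectivityRecord:
    compound_id: str | None
    ec50_p: float | str
    ec50_q: float | str
    ratio_lower: float
    ratio_upper: float
    group: str  # group1 | group2 | group3 | unclassified
    boundary_flag: bool

    @property
    def ratio(self) -> float:
        """Point ratio when both EC50s are point estimates, else NaN."""
        return self.ratio_lower if self.ratio_lower == self.ratio_upper else float("nan")

    @property
    def ratio_or_bound(self) -> str:
        if self.ratio_lower == self.ratio_upper:
            return f"{self.ratio_lower:g}"
        if math.isinf(self.ratio_upper):
            return f"> {self.ratio_lower:g}"
        if self.ratio_lower == 0:
            return f"< {self.ratio_upper:g}"
        return f"({self.ratio_lower:g}, {self.ratio_upper:g})"


def classify_group(ec50_p, ec50_q, compound_id: str | None = None) -> SelectivityRecord:
    """Classify one compound from its proliferating and quiescent EC50s.

    Each EC50 may be a point estimate (uM) or a censored bound ("> 100").
    Both censored -> unclassified (the ratio interval is (0, inf)).
    """
    vp, cens_p = parse_ec50(ec50_p)
    vq, cens_q = parse_ec50(ec50_q)

    if cens_p and cens_q:
        lo, hi = 0.0, math.inf
    elif cens_p:  # ratio > vp_bound / vq
        lo, hi = vp / vq, math.inf
    elif cens_q:  # ratio < vp / vq_bound
        lo, hi = 0.0, vp / vq
    else:
        lo = hi = vp / vq

    if lo >= 2.0:
        group = "group3"
    elif hi <= 0.5 and hi > 0:
        group = "group2"
    elif 0.5 < lo and hi < 2.0:
        group = "group1"
    else:
        group = "unclassified"

    flag = False
    for endpoint in (lo, hi):
        if math.isfinite(endpoint) and endpoint > 0:
            if BOUNDARY_BAND[0] <= endpoint <= BOUNDARY_BAND[1]:
                flag = True
            if BOUNDARY_BAND_RECIP[0] <= endpoint <= BOUNDARY_BAND_RECIP[1]:
                flag = True
    return SelectivityRecord(compound_id, ec50_p, ec50_q, lo, hi, group, flag)


def classify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vector version over a frame with columns compound_id, ec50_p, ec50_q."""
    rows = []
    for r in df.itertuples(index=False):
        rec = classify_group(r.ec50_p, r.ec50_q, compound_id=r.compound_id)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "ec50_p": rec.ec50_p,
                "ec50_q": rec.ec50_q,
                "ratio_or_bound": rec.ratio_or_bound,
                "group": rec.group,
                "boundary_flag": rec.boundary_flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpecificityProfile:
    """Potency (1/EC50, uM^-1) of each compound across cell contexts.

    Censored entries are encoded as potency 0 with ``censored`` True — they
    are a distinct "inactive in tested range" category, not a measured zero.
    """

    potency: pd.DataFrame  # compounds x contexts
    censored: pd.DataFrame  # same shape, bool mask
    groups: pd.Series | None = None  # compound -> group label, if available

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.35 * len(self.potency) + 1))
        im = ax.imshow(self.potency.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(self.potency.columns)), self.potency.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(self.potency)), self.potency.index)
        ax.figure.colorbar(im, ax=ax, label="potency 1/EC50 (uM$^{-1}$)")
        return ax


def specificity_profile(
    fits: pd.DataFrame,
    compound_col: str = "compound_id",
    context_col: str = "context",
    ec50_col: str = "reported_ec50",
    groups: pd.Series | None = None,
) -> SpecificityProfile:
    """Build the compounds x contexts potency matrix from a long fit table.

    ``ec50_col`` holds point estimates or censored bounds; potency is the
    reciprocal EC50 for points and 0 (masked censored) for bounds.
    """
    pot = {}
    cens = {}
    for r in fits.itertuples(index=False):
        cid, ctx = getattr(r, compound_col), getattr(r, context_col)
        v, c = parse_ec50(getattr(r, ec50_col))
        pot[(cid, ctx)] = 0.0 if c else 1.0 / v
        cens[(cid, ctx)] = c
    idx = pd.MultiIndex.from_tuples(pot.keys(), names=[compound_col, context_col])
    potency = pd.Series(list(pot.values()), index=idx).unstack(context_col)
    censored = (
        pd.Series(list(cens.values()), index=idx).unstack(context_col).fillna(False).astype(bool)
    )
    potency = potency.fillna(np.nan)
    return SpecificityProfile(potency, censored, groups=groups)
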