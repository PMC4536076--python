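"""Four-parameter logistic (4PL/Hill) dose-response model with censored EC50.

The model, on the linear response scale (response is typically relative ATP
in % of control)::

    y(x) = [S_max + S_min * (x/EC50)^n] / [1 + (x/EC50)^n]
         =  S_min + (S_max - S_min) / (1 + (x/EC50)^n)

``S_max`` is the response at zero dose, ``S_min`` the response at saturating
dose, ``EC50`` the midpoint concentration (uM) and ``n`` the Hill
coefficient.  For cytotoxicity data the curve decreases (S_max >= S_min).

Fitting is deterministic nonlinear least squares on the untransformed
response; the EC50 is parameterised internally as log10(EC50) for
conditioning, with bounds n in [0.3, 10] and EC50 within a decade of the
tested range to prevent pathological fits on flat data.  Replicates enter as
individual points with uniform weights.  When the midpoint is not crossed
within the tested range the EC50 is reported as a censored bound
("> <max tested>") rather than a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InsufficientDesignError


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of the four-parameter logistic curve."""

    s_max: float
    s_min: float
    ec50: float  # uM, > 0
    hill_n: float  # > 0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_max, self.s_min, self.ec50, self.hill_n])


def four_pl(x, params: FourPLParams):
    """Evaluate the 4PL curve at concentrations ``x`` (uM, >= 0).

    y(0) = s_max; y -> s_min as x -> inf; strictly decreasing in x when
    s_max > s_min.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    r = (x / params.ec50) ** params.hill_n
    y = (params.s_max + params.s_min * r) / (1.0 + r)
    return y if y.ndim else float(y)


def _four_pl_theta(x, theta):
    s_max, s_min, log_ec50, n = theta
    r = np.power(10.0, n * (np.log10(np.maximum(x, 1e-300)) - log_ec50))
    r = np.where(x == 0, 0.0, r)
    return (s_max + s_min * r) / (1.0 + r)


@dataclass
class DoseResponseResults:
    """Fit results for one compound/context.

    ``reported_ec50`` is the potency as it should be quoted: the point
    estimate (uM) when the midpoint falls inside the tested range, or the
    bound string ``"> <max>"`` when censored.
    """

    params: FourPLParams
    bse: dict[str, float]
    rss: float
    dof: int
    nobs: int
    converged: bool
    censored: str = "none"  # none | above_range
    reported_ec50: float | str | None = None
    tested_range: tuple[float, float] | None = None
    wrong_direction: bool = False
    compound_id: str | None = None
    condition: str | None = None

    @property
    def sigma2(self) -> float:
        return self.rss / self.dof if self.dof > 0 else float("nan")

    def predict(self, x):
        return four_pl(x, self.params)

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 45,
        ]
        if self.compound_id:
            lines.append(f"compound: {self.compound_id}  condition: {self.condition or '-'}")
        lines += [
            f"n obs: {self.nobs}   dof: {self.dof}   RSS: {self.rss:.4g}",
            f"converged: {self.converged}   censored: {self.censored}",
            f"S_max  {p.s_max:10.4g}  (se {se.get('s_max', float('nan')):.3g})",
            f"S_min  {p.s_min:10.4g}  (se {se.get('s_min', float('nan')):.3g})",
            f"EC50   {p.ec50:10.4g} uM  (se {se.get('ec50', float('nan')):.3g})",
            f"Hill n {p.hill_n:10.4g}  (se {se.get('hill_n', float('nan')):.3g})",
            f"reported EC50: {self.reported_ec50}",
        ]
        if self.wrong_direction:
            lines.append("WARNING: fitted response increases with dose "
                         "(wrong direction for a cytotoxicity readout)")
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 200):
        """Data-free curve plot over the tested range (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.tested_range or (self.params.ec50 / 100, self.params.ec50 * 100)
        x = np.logspace(np.log10(lo), np.log10(hi), n_points)
        ax.semilogx(x, self.predict(x))
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("response")
        return ax


class DoseResponseModel:
    """4PL model bound to one compound's (concentration, response) data.

    Parameters
    ----------
    concentration, response : array-like
        Paired observations; replicates appear as repeated concentrations.
    """

    def __init__(self, concentration, response, compound_id=None, condition=None):
        x = np.asarray(concentration, dtype=float)
        y = np.asarray(response, dtype=float)
        if x.shape != y.shape:
            raise ValueError("concentration and response must have equal length")
        if np.any(x < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(x, kind="stable")
        self.x, self.y = x[order], y[order]
        self.compound_id, self.condition = compound_id, condition
        pos = self.x[self.x > 0]
        distinct = np.unique(self.x)
        if len(distinct) < 4:
            raise InsufficientDesignError(
                f"need >=4 distinct concentrations, got {len(distinct)}"
            )
        if len(pos) and np.log10(pos.max() / pos.min()) < 2.0 - 1e-9:
            raise InsufficientDesignError(
                "tested concentrations must span >= 2 log10 units"
            )
        self.tested_range = (float(pos.min()), float(pos.max()))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        concentration_col: str = "concentration_uM",
        response_col: str = "response_pct",
        **kw,
    ) -> "DoseResponseModel":
        return cls(df[concentration_col], df[response_col], **kw)

    def _initial(self) -> np.ndarray:
        # deterministic: plateaus from the two extreme doses, EC50 at the
        # geometric mean of the tested range, unit slope
        distinct = np.unique(self.x)
        lo2, hi2 = distinct[:2], distinct[-2:]
        s_max = float(np.mean(self.y[np.isin(self.x, lo2)]))
        s_min = float(np.mean(self.y[np.isin(self.x, hi2)]))
        log_ec50 = float(np.mean(np.log10(self.tested_range)))
        return np.array([s_max, s_min, log_ec50, 1.0])

    def fit(self, censor: bool = True) -> DoseResponseResults:
        lo, hi = self.tested_range
        if np.ptp(self.y) == 0:
            # flat curve: no midpoint crossing, EC50 censored above range
            val = float(self.y[0])
            res = DoseResponseResults(
                params=FourPLParams(val, val, np.sqrt(lo * hi), 1.0),
                bse={}, rss=0.0, dof=len(self.y) - 4, nobs=len(self.y),
                converged=True, tested_range=self.tested_range,
                compound_id=self.compound_id, condition=self.condition,
            )
            return censor_ec50(res, self.tested_range) if censor else res

        bounds = (
            [-np.inf, -np.inf, np.log10(lo / 10.0), 0.3],
            [np.inf, np.inf, np.log10(hi * 10.0), 10.0],
        )
        theta0 = np.clip(self._initial(), bounds[0], bounds[1])
        sol = least_squares(
            lambda th: _four_pl_theta(self.x, th) - self.y,
            theta0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        s_max, s_min, log_ec50, n = sol.x
        ec50 = float(10.0 ** log_ec50)
        rss = float(2.0 * sol.cost)
        dof = len(self.y) - 4
        bse = self._standard_errors(sol, rss, dof, ec50)
        res = DoseResponseResults(
            params=FourPLParams(float(s_max), float(s_min), ec50, float(n)),
            bse=bse, rss=rss, dof=dof, nobs=len(self.y),
            converged=bool(sol.success),
            tested_range=self.tested_range,
            wrong_direction=bool(s_min > s_max),
            compound_id=self.compound_id, condition=self.condition,
        )
        return censor_ec50(res, self.tested_range) if censor else res

    @staticmethod
    def _standard_errors(sol, rss, dof, ec50) -> dict[str, float]:
        if dof <= 0:
            return {}
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        except np.linalg.LinAlgError:
            return {}
        cov = jtj_inv * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return {
            "s_max": float(se[0]),
            "s_min": float(se[1]),
            # delta method: EC50 = 10^theta  =>  se = ln(10) * EC50 * se_theta
            "ec50": float(np.log(10.0) * ec50 * se[2]),
            "hill_n": float(se[3]),
        }


def fit_four_pl(
    concentration, response, compound_id=None, condition=None, censor: bool = True
) -> DoseResponseResults:
    """Convenience wrapper: build the model and fit in one call."""
    return DoseResponseModel(
        concentration, response, compound_id=compound_id, condition=condition
    ).fit(censor=censor)


def censor_ec50(
    fit: DoseResponseResults, tested_range: tuple[float, float]
) -> DoseResponseResults:
    """Apply the reporting convention for potencies outside the tested range.

    The EC50 is reported as the bound ``"> max"`` when the point estimate
    exceeds the highest tested concentration or when the fitted curve never
    crosses the midpoint (S_max + S_min)/2 within the range (flat curves).
    """
    lo, hi = tested_range
    p = fit.params
    flat = p.s_max == p.s_min
    if flat or p.ec50 > hi:
        return replace(
            fit,
            censored="above_range",
            reported_ec50=f"> {hi:g}",
            tested_range=tested_range,
        )
    return replace(
        fit, censored="none", reported_ec50=p.ec50, tested_range=tested_range
    )


def fit_table(df: pd.DataFrame, censor: bool = True) -> pd.DataFrame:
    """Fit every (compound_id, condition) group of a long dose-response table.

    Expected columns: compound_id, condition, concentration_uM, response_pct
    (replicate/cell_line columns pass through the grouping if present).
    """
    rows = []
    keys = ["compound_id", "condition"]
    if "cell_line" in df.columns:
        keys.insert(1, "cell_line")
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        res = DoseResponseModel.from_dataframe(
            grp, compound_id=key[0], condition=key[-1]
        ).fit(censor=censor)
        row = dict(zip(keys, key))
        row.update(
            s_max=res.params.s_max,
            s_min=res.params.s_min,
            ec50=res.params.ec50,
            hill_n=res.params.hill_n,
            se_ec50=res.bse.get("ec50"),
            rss=res.rss,
            converged=res.converged,
            censored=res.censored,
            reported_ec50=res.reported_ec50,
            wrong_direction=res.wrong_direction,
        )
        rows.append(row)
    return pd.DataFrame(rows)
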