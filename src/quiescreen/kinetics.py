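"""Sequential first-order hydrolysis kinetics: diester -> monoester -> diol.

Bisacodyl (the diester prodrug, HPLC retention 1.78 min) hydrolyses in
culture medium to its monoester (1.56 min) and then to DDPM, the active
bi-phenolic metabolite (1.35 min).  With first-order rate constants k1 and
k2 (h^-1) and initial amount a0, the closed form is::

    A(t) = a0 exp(-k1 t)
    B(t) = a0 k1/(k2-k1) (exp(-k1 t) - exp(-k2 t))      (k1 != k2)
         = a0 k1 t exp(-k1 t)                            (k1 == k2)
    C(t) = a0 - A(t) - B(t)

Mass is conserved (A+B+C = a0) and the intermediate is transient, peaking at
t* = ln(k1/k2)/(k1-k2).  Peak areas are modelled as response_factor x amount;
factors default to 1 (calibrated areas) and may optionally be estimated.

Half-life t1/2 = ln(2)/k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InsufficientDesignError

SPECIES = ("bisacodyl", "monoester", "ddpm")

#: HPLC retention-time annotations (minutes) used as species labels
RETENTION_MIN = {"bisacodyl": 1.78, "monoester": 1.56, "ddpm": 1.35}

# relative k1/k2 gap below which the removable singularity branch is used
_DEGENERATE_RTOL = 1e-9


def half_life(k: float) -> float:
    """t1/2 = ln(2)/k for a first-order rate constant k (> 0, h^-1)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2.0) / k


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the sequential first-order hydrolysis model."""

    a0: float
    k1: float  # h^-1, diester -> monoester
    k2: float  # h^-1, monoester -> diol (DDPM)
    response_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rate constants must be positive")
        if any(f <= 0 for f in self.response_factors):
            raise ValueError("response factors must be positive")

    @property
    def half_life_parent(self) -> float:
        return half_life(self.k1)

    @property
    def half_life_intermediate(self) -> float:
        return half_life(self.k2)

    @property
    def t_intermediate_max(self) -> float:
        """Time of the transient monoester maximum."""
        if math.isclose(self.k1, self.k2, rel_tol=_DEGENERATE_RTOL):
            return 1.0 / self.k1
        return math.log(self.k1 / self.k2) / (self.k1 - self.k2)


def abc_concentrations(t, params: KineticsParams):
    """Amounts (A, B, C) of parent, intermediate and final product at ``t`` hours."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    a0, k1, k2 = params.a0, params.k1, params.k2
    A = a0 * np.exp(-k1 * t)
    if math.isclose(k1, k2, rel_tol=_DEGENERATE_RTOL):
        B = a0 * k1 * t * np.exp(-k1 * t)
    else:
        B = a0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    B = np.maximum(B, 0.0)
    C = np.maximum(a0 - A - B, 0.0)
    return A, B, C


@dataclass
class PeakAreaSeries:
    """Chromatographic peak areas of the three species over time (hours)."""

    times: np.ndarray
    areas: dict[str, np.ndarray]  # species -> areas aligned with times
    retention_annotation: dict[str, float] = field(
        default_factory=lambda: dict(RETENTION_MIN)
    )

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        unknown = set(self.areas) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        self.areas = {s: np.asarray(a, dtype=float) for s, a in self.areas.items()}
        for s, a in self.areas.items():
            if a.shape != self.times.shape:
                raise ValueError(f"areas[{s!r}] not aligned with times")
            if np.any(a < 0):
                raise ValueError(f"negative peak areas for {s!r}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_h",
        species_col: str = "species",
        area_col: str = "peak_area",
        species_map: dict[str, str] | None = None,
    ) -> "PeakAreaSeries":
        """Build from a long table (time_h, species, peak_area).

        ``species_map`` translates file species names (e.g. retention-time
        labels) to the canonical names.
        """
        df = df.copy()
        if species_map:
            df[species_col] = df[species_col].map(lambda s: species_map.get(s, s))
        times = np.sort(df[time_col].unique())
        areas = {}
        for sp, grp in df.groupby(species_col):
            grp = grp.sort_values(time_col)
            if not np.array_equal(grp[time_col].to_numpy(float), times):
                raise ValueError(f"species {sp!r} not observed at all timepoints")
            areas[sp] = grp[area_col].to_numpy(float)
        return cls(times, areas)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sp, a in self.areas.items():
            for t, v in zip(self.times, a):
                rows.append({"time_h": t, "species": sp, "peak_area": v})
        return pd.DataFrame(rows)


@dataclass
class HydrolysisResults:
    """Estimates from a sequential-kinetics fit."""

    params: KineticsParams
    bse: dict[str, float]
    rss: float
    dof: int
    nobs: int
    converged: bool
    species_fitted: tuple[str, ...]
    parent_only: bool = False

    @property
    def half_life_parent(self) -> float:
        return self.params.half_life_parent

    @property
    def half_life_parent_se(self) -> float:
        # delta method through t1/2 = ln2/k1: |d t1/2 / d k1| = ln2/k1^2
        se_k1 = self.bse.get("k1")
        if se_k1 is None:
            return float("nan")
        return math.log(2.0) / self.params.k1**2 * se_k1

    def summary(self) -> str:
        p = self.params
        lines = [
            "Sequential first-order hydrolysis fit",
            "=" * 45,
            f"species fitted: {', '.join(self.species_fitted)}",
            f"n obs: {self.nobs}   dof: {self.dof}   RSS: {self.rss:.4g}",
            f"converged: {self.converged}",
            f"a0  {p.a0:10.4g}  (se {self.bse.get('a0', float('nan')):.3g})",
            f"k1  {p.k1:10.4g} /h  (se {self.bse.get('k1', float('nan')):.3g})"
            f"   t1/2 = {p.half_life_parent:.3g} h (se {self.half_life_parent_se:.3g})",
        ]
        if not self.parent_only:
            lines.append(
                f"k2  {p.k2:10.4g} /h  (se {self.bse.get('k2', float('nan')):.3g})"
                f"   t1/2 = {p.half_life_intermediate:.3g} h"
            )
        else:
            lines.append("k2 not identifiable (parent species only)")
        return "\n".join(lines)

    def plot(self, series: PeakAreaSeries | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tmax = series.times.max() if series is not None else 4 * self.params.half_life_parent
        t = np.linspace(0, tmax, 300)
        A, B, C = abc_concentrations(t, self.params)
        f = self.params.response_factors
        for curve, fac, name in zip((A, B, C), f, SPECIES):
            ax.plot(t, fac * curve, label=name)
        if series is not None:
            for sp, a in series.areas.items():
                ax.plot(series.times, a, "o", label=f"{sp} (obs)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("peak area")
        ax.legend()
        return ax


class HydrolysisModel:
    """Sequential-kinetics model bound to one peak-area time series."""

    def __init__(self, series: PeakAreaSeries):
        if len(series.times) < 4:
            raise InsufficientDesignError(
                f"need >=4 timepoints, got {len(series.times)}"
            )
        self.series = series
        self.species = tuple(s for s in SPECIES if s in series.areas)
        self.parent_only = self.species == ("bisacodyl",)
        if self.parent_only:
            warnings.warn(
                "only the parent species is observed: k2 and the intermediate/"
                "product response factors are not identifiable; fitting a "
                "single exponential for k1",
                stacklevel=2,
            )
        elif len(self.species) < 2:
            raise InsufficientDesignError(
                "need the parent or >=2 species to identify the model"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "HydrolysisModel":
        return cls(PeakAreaSeries.from_dataframe(df, **kw))

    def _stack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.series.times
        ts, ys, idx = [], [], []
        for i, sp in enumerate(SPECIES):
            if sp in self.series.areas:
                ts.append(t)
                ys.append(self.series.areas[sp])
                idx.append(np.full(t.shape, i))
        return np.concatenate(ts), np.concatenate(ys), np.concatenate(idx)

    def fit(
        self,
        estimate_response_factors: bool = False,
        log_residuals: bool = False,
    ) -> HydrolysisResults:
        """Joint least squares of f_s * species_s(t) against the areas.

        ``log_residuals=True`` fits on the log scale (multiplicative noise);
        zero observations are floored at a small fraction of the series
        maximum in that case.  Deterministic: initial values come from the
        data (log-linear regression of the parent decay).
        """
        t_all, y_all, sp_idx = self._stack()
        a_parent = self.series.areas.get("bisacodyl")
        ymax = float(y_all.max()) if y_all.max() > 0 else 1.0

        # deterministic initialisation
        if a_parent is not None and np.count_nonzero(a_parent > 0) >= 2:
            mask = a_parent > 0
            slope, intercept = np.polyfit(
                self.series.times[mask], np.log(a_parent[mask]), 1
            )
            k1_0 = max(-slope, 1e-3)
            a0_0 = float(np.exp(intercept))
        else:
            k1_0, a0_0 = 0.2, ymax
        k2_0 = 2.0 * k1_0

        if self.parent_only:
            names = ["a0", "k1"]
            theta0 = np.log([a0_0, k1_0])

            def model(theta):
                a0, k1 = np.exp(theta)
                return a0 * np.exp(-k1 * t_all)

        else:
            names = ["a0", "k1", "k2"]
            theta0 = np.log([a0_0, k1_0, k2_0])
            if estimate_response_factors:
                # f for parent fixed at 1 (sets the scale); estimate the rest
                extra = [s for s in self.species if s != "bisacodyl"]
                names += [f"f_{s}" for s in extra]
                theta0 = np.concatenate([theta0, np.zeros(len(extra))])

            def model(theta):
                a0, k1, k2 = np.exp(theta[:3])
                factors = dict(zip(SPECIES, (1.0, 1.0, 1.0)))
                if estimate_response_factors:
                    extra = [s for s in self.species if s != "bisacodyl"]
                    for s, th in zip(extra, theta[3:]):
                        factors[s] = float(np.exp(th))
                p = KineticsParams(a0, k1, max(k2, 1e-12))
                A, B, C = abc_concentrations(t_all, p)
                preds = np.stack([A, B, C])
                fac = np.array([factors[s] for s in SPECIES])
                return fac[sp_idx] * preds[sp_idx, np.arange(len(t_all))]

        if log_residuals:
            floor = 1e-6 * ymax

            def resid(theta):
                return np.log(np.maximum(model(theta), floor)) - np.log(
                    np.maximum(y_all, floor)
                )

        else:

            def resid(theta):
                return model(theta) - y_all

        method = "lm" if len(y_all) >= len(theta0) else "trf"
        sol = least_squares(resid, theta0, method=method,
                            xtol=1e-13, ftol=1e-13, gtol=1e-13)
        est = np.exp(sol.x)  # every parameter is log-transformed
        rss = float(2.0 * sol.cost)
        dof = len(y_all) - len(sol.x)
        bse = self._standard_errors(sol, names, rss, dof)

        factors = [1.0, 1.0, 1.0]
        if not self.parent_only and estimate_response_factors:
            extra = [s for s in self.species if s != "bisacodyl"]
            for s, v in zip(extra, est[3:]):
                factors[SPECIES.index(s)] = float(v)
        params = KineticsParams(
            a0=float(est[0]),
            k1=float(est[1]),
            k2=float(est[2]) if not self.parent_only else float(est[1]),
            response_factors=tuple(factors),
        )
        return HydrolysisResults(
            params=params,
            bse=bse,
            rss=rss,
            dof=dof,
            nobs=len(y_all),
            converged=bool(sol.success),
            species_fitted=self.species,
            parent_only=self.parent_only,
        )

    @staticmethod
    def _standard_errors(sol, names, rss, dof) -> dict[str, float]:
        if dof <= 0:
            return {}
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (rss / dof)
        except np.linalg.LinAlgError:
            return {}
        se_theta = np.sqrt(np.clip(np.diag(cov), 0, None))
        out = {}
        for i, name in enumerate(names):
            # parameters are log-transformed: se(exp(theta)) ~ exp(theta)*se_theta
            out[name] = float(np.exp(sol.x[i]) * se_theta[i])
        return out


def fit_kinetics(
    series: PeakAreaSeries,
    estimate_response_factors: bool = False,
    log_residuals: bool = False,
) -> HydrolysisResults:
    """Convenience wrapper: build the model and fit in one call."""
    return HydrolysisModel(series).fit(
        estimate_response_factors=estimate_response_factors,
        log_residuals=log_residuals,
    )
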