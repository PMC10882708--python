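"""Initial-rate extraction and Michaelis–Menten parameter estimation.

Four estimators are provided for (Km_app, vmax) from initial-rate data:
the three classical linearizations (Lineweaver–Burk: 1/v vs 1/c,
Hanes–Woolf: c/v vs c, Eadie–Hofstee: v vs v/c) and direct nonlinear
least squares on v = vmax*c/(Km+c).  On noise-free data all four agree
exactly; under realistic noise the linearizations distort the error
structure (Lineweaver–Burk most severely, by over-weighting the lowest
rates) and the nonlinear fit is the headline estimate, with the
linearizations retained as diagnostics.

Standard errors of transformed parameters are propagated from the
regression covariance by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .transcript import BASES

LINEAR_METHODS = ("lineweaver_burk", "hanes_woolf", "eadie_hofstee")
ALL_METHODS = LINEAR_METHODS + ("nonlinear",)


@dataclass(frozen=True)
class InitialRateDataset:
    """Observed initial rates at several substrate levels of one NTP.

    ``levels`` and ``rates`` are parallel arrays (μM, μM/min); duplicate
    levels are treated as replicates.  Fewer than 3 distinct levels is
    flagged (fits still run but are degenerate).
    """

    base: str
    levels: np.ndarray
    rates: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        rt = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "rates", rt)
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}")
        if lv.shape != rt.shape or lv.ndim != 1:
            raise ValueError("levels and rates must be 1-D arrays of equal length")
        if np.any(lv <= 0):
            raise ValueError("substrate levels must be > 0")
        if not (np.all(np.isfinite(lv)) and np.all(np.isfinite(rt))):
            raise ValueError("non-finite values in dataset")
        if self.n_distinct < 3:
            warnings.warn(
                f"only {self.n_distinct} distinct substrate levels; "
                "fits will be degenerate",
                stacklevel=2,
            )

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.levels))


@dataclass
class FitResult:
    """Estimated (Km_app, vmax) with uncertainties and diagnostics."""

    base: str
    method: str
    Km: float
    Km_se: float
    vmax: float
    vmax_se: float
    adj_R2: float
    residuals: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if np.isfinite(self.Km) and self.Km <= 0:
            self.flags.append("nonpositive_Km")
        if np.isfinite(self.vmax) and self.vmax <= 0:
            self.flags.append("nonpositive_vmax")


def extract_initial_rate(
    t: np.ndarray,
    c_product: np.ndarray,
    c_substrate0: float | None = None,
    stoich: float | None = None,
    r2_min: float = 0.99,
    max_consumed_frac: float = 0.10,
) -> tuple[float, float, dict]:
    """Initial slope of a product time course (μM/min).

    Selects the longest prefix of >= 3 points whose OLS fit has
    R² >= ``r2_min`` and — when the initial substrate level
    ``c_substrate0`` and the per-transcript substrate stoichiometry
    ``stoich`` (= f_i * n_mRNA) are given — whose endpoint has consumed
    less than ``max_consumed_frac`` of the substrate.  Falls back to the
    first 3 points with a warning flag when no prefix qualifies.

    Returns (rate, standard error, info) where info records the window
    length and any flags.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c_product, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("t and c_product must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")

    def ols(k):
        X = sm.add_constant(t[:k])
        res = sm.OLS(c[:k], X).fit()
        return res

    best_k = None
    for k in range(len(t), 2, -1):
        if c_substrate0 is not None and stoich is not None:
            consumed = (c[k - 1] - c[0]) * stoich
            if consumed >= max_consumed_frac * c_substrate0:
                continue
        res = ols(k)
        # R² of a flat (zero-slope) series is 0/0; treat a zero-variance
        # window as perfectly linear.
        ssr = float(np.sum(res.resid**2))
        sst = float(np.sum((c[:k] - c[:k].mean()) ** 2))
        r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
        if r2 >= r2_min or sst == 0:
            best_k = k
            break

    flags = []
    if best_k is None:
        best_k = 3
        flags.append("window_fallback_first3")
    res = ols(best_k)
    rate = float(res.params[1])
    se = float(res.bse[1])
    return rate, se, {"window_n": best_k, "flags": flags}


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var >= 0 else np.nan


def _adj_r2_on_v(d: InitialRateDataset, Km: float, vmax: float, n_params: int = 2) -> float:
    """Adjusted R² of the MM curve evaluated on the original v scale."""
    pred = vmax * d.levels / (Km + d.levels)
    resid = d.rates - pred
    n = len(d.rates)
    sst = float(np.sum((d.rates - d.rates.mean()) ** 2))
    if sst == 0 or n <= n_params:
        return np.nan
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def _linear_fit(d: InitialRateDataset, x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b0, b1 = res.params
    cov = np.asarray(res.cov_params())
    flags = []
    if len(d.levels) <= 2:
        flags.append("degenerate_no_dof")
        cov = np.full((2, 2), np.nan)
    return res, float(b0), float(b1), cov, flags


def fit_lineweaver_burk(d: InitialRateDataset) -> FitResult:
    """OLS of 1/v on 1/c; vmax = 1/intercept, Km = slope/intercept."""
    if np.any(d.rates <= 0):
        raise ValueError("Lineweaver-Burk requires strictly positive rates")
    res, b0, b1, cov, flags = _linear_fit(d, 1.0 / d.levels, 1.0 / d.rates)
    if b0 <= 0:
        raise ValueError(
            f"degenerate Lineweaver-Burk fit: intercept {b0:.3g} <= 0"
        )
    vmax = 1.0 / b0
    Km = b1 / b0
    vmax_se = _delta_se(np.array([-1.0 / b0**2, 0.0]), cov)
    Km_se = _delta_se(np.array([-b1 / b0**2, 1.0 / b0]), cov)
    return FitResult(
        base=d.base, method="lineweaver_burk", Km=Km, Km_se=Km_se,
        vmax=vmax, vmax_se=vmax_se, adj_R2=_adj_r2_on_v(d, Km, vmax),
        residuals=np.asarray(res.resid), flags=flags,
    )


def fit_hanes_woolf(d: InitialRateDataset) -> FitResult:
    """OLS of c/v on c; vmax = 1/slope, Km = intercept/slope."""
    if np.any(d.rates <= 0):
        raise ValueError("Hanes-Woolf requires strictly positive rates")
    res, b0, b1, cov, flags = _linear_fit(d, d.levels, d.levels / d.rates)
    if b1 <= 0:
        raise ValueError(f"degenerate Hanes-Woolf fit: slope {b1:.3g} <= 0")
    vmax = 1.0 / b1
    Km = b0 / b1
    vmax_se = _delta_se(np.array([0.0, -1.0 / b1**2]), cov)
    Km_se = _delta_se(np.array([1.0 / b1, -b0 / b1**2]), cov)
    return FitResult(
        base=d.base, method="hanes_woolf", Km=Km, Km_se=Km_se,
        vmax=vmax, vmax_se=vmax_se, adj_R2=_adj_r2_on_v(d, Km, vmax),
        residuals=np.asarray(res.resid), flags=flags,
    )


def fit_eadie_hofstee(d: InitialRateDataset) -> FitResult:
    """OLS of v on v/c; vmax = intercept, Km = -slope."""
    if np.any(d.rates <= 0):
        raise ValueError("Eadie-Hofstee requires strictly positive rates")
    res, b0, b1, cov, flags = _linear_fit(d, d.rates / d.levels, d.rates)
    vmax = b0
    Km = -b1
    vmax_se = _delta_se(np.array([1.0, 0.0]), cov)
    Km_se = _delta_se(np.array([0.0, -1.0]), cov)
    if vmax <= 0:
        raise ValueError(f"degenerate Eadie-Hofstee fit: intercept {b0:.3g} <= 0")
    return FitResult(
        base=d.base, method="eadie_hofstee", Km=Km, Km_se=Km_se,
        vmax=vmax, vmax_se=vmax_se, adj_R2=_adj_r2_on_v(d, Km, vmax),
        residuals=np.asarray(res.resid), flags=flags,
    )


def fit_nonlinear(
    d: InitialRateDataset,
    init: tuple[float, float] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Nonlinear least squares on v = vmax*c/(Km+c).

    Starting values default to the Hanes–Woolf estimate (falling back
    to moment-style guesses when that fit is degenerate).  With
    ``weighted=True`` residuals are weighted by 1/v², approximating a
    constant-CV error model.
    """
    if init is None:
        try:
            hw = fit_hanes_woolf(d)
            init = (max(hw.Km, 1e-6), max(hw.vmax, 1e-9))
        except ValueError:
            init = (float(np.median(d.levels)), float(np.max(d.rates)))
    sigma = d.rates**2 if weighted else None

    def mm(c, Km, vmax):
        return vmax * c / (Km + c)

    try:
        popt, pcov = curve_fit(
            mm, d.levels, d.rates, p0=init, sigma=sigma,
            absolute_sigma=False, maxfev=20000,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        )
    except RuntimeError as e:
        raise RuntimeError(
            f"nonlinear MM fit failed to converge (start Km={init[0]:.4g}, "
            f"vmax={init[1]:.4g}): {e}"
        ) from e
    Km, vmax = popt
    perr = np.sqrt(np.diag(pcov))
    flags = []
    if len(d.levels) <= 2:
        flags.append("degenerate_no_dof")
        perr = np.array([np.nan, np.nan])
    return FitResult(
        base=d.base, method="nonlinear", Km=float(Km), Km_se=float(perr[0]),
        vmax=float(vmax), vmax_se=float(perr[1]),
        adj_R2=_adj_r2_on_v(d, Km, vmax),
        residuals=d.rates - mm(d.levels, *popt), flags=flags,
    )


_FITTERS = {
    "lineweaver_burk": fit_lineweaver_burk,
    "hanes_woolf": fit_hanes_woolf,
    "eadie_hofstee": fit_eadie_hofstee,
    "nonlinear": fit_nonlinear,
}


def fit(d: InitialRateDataset, method: str) -> FitResult:
    """Dispatch to one of the four estimators by name."""
    try:
        return _FITTERS[method](d)
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")


def estimate_all(
    datasets: dict[str, InitialRateDataset],
    methods: tuple[str, ...] = ALL_METHODS,
    adj_r2_floor: float = 0.97,
) -> pd.DataFrame:
    """Run every estimator on every per-NTP dataset.

    Returns one row per (base, method) with estimates, standard errors,
    adjusted R² and a review flag for fits below ``adj_r2_floor``.
    """
    rows = []
    for base, d in datasets.items():
        for m in methods:
            r = fit(d, m)
            rows.append(
                {
                    "base": base, "method": m, "Km_uM": r.Km, "Km_se_uM": r.Km_se,
                    "vmax_uM_per_min": r.vmax, "vmax_se_uM_per_min": r.vmax_se,
                    "adj_R2": r.adj_R2,
                    "flag_low_R2": bool(np.isfinite(r.adj_R2) and r.adj_R2 < adj_r2_floor),
                    "flags": ";".join(r.flags),
                }
            )
    return pd.DataFrame(rows)
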