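"""Chromatographic calibration, quantification and peak arithmetic.

mRNA and NTP amounts are quantified by external calibration: a line is
fitted through (injected mass, peak area) standards, and unknowns are
read off the inverse line (times any dilution applied to stay inside
the calibrated range).  Transcript integrity is summarized as the
truncated-mRNA percentage, the early-eluting peak's share of the total
mRNA peak area in an IP-RP separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class CalibrationCurve:
    """Least-squares calibration line area = slope·mass + intercept."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    mass_range: tuple[float, float]
    duplicate_agreement: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 or np.isnan(self.r2)):
            raise ValueError("R^2 must lie in [0, 1]")


def calibrate(
    mass: np.ndarray,
    area: np.ndarray,
    analyte: str = "mRNA",
    through_origin: bool = False,
) -> CalibrationCurve:
    """Fit the calibration line through standards (duplicates allowed).

    Reports R² and, when any level was measured more than once, a
    duplicate-agreement statistic (mean relative half-range within
    levels).  At least 3 distinct levels are required.
    """
    mass = np.asarray(mass, dtype=float)
    area = np.asarray(area, dtype=float)
    if mass.shape != area.shape or mass.ndim != 1:
        raise ValueError("mass and area must be 1-D arrays of equal length")
    distinct = np.unique(mass)
    if len(distinct) < 3:
        raise ValueError(f"need >= 3 distinct levels, got {len(distinct)}")

    X = mass[:, None] if through_origin else sm.add_constant(mass)
    res = sm.OLS(area, X).fit()
    if through_origin:
        slope, intercept = float(res.params[0]), 0.0
        # centred R^2 so forced-origin fits are comparable
        sst = float(np.sum((area - area.mean()) ** 2))
        r2 = np.nan if sst == 0 else 1.0 - float(np.sum(res.resid**2)) / sst
    else:
        intercept, slope = map(float, res.params)
        r2 = float(res.rsquared)

    flags = []
    if np.std(area) == 0:
        flags.append("zero_variance_response")
        r2 = np.nan
    elif not np.isnan(r2):
        r2 = min(max(float(r2), 0.0), 1.0)

    dup = None
    groups = pd.Series(area).groupby(pd.Series(mass))
    reps = groups.agg(["min", "max", "mean", "count"])
    reps = reps[reps["count"] > 1]
    if len(reps):
        rel = 0.5 * (reps["max"] - reps["min"]) / reps["mean"].abs()
        dup = float(rel.mean())

    return CalibrationCurve(
        analyte=analyte, slope=slope, intercept=intercept, r2=r2,
        mass_range=(float(distinct.min()), float(distinct.max())),
        duplicate_agreement=dup, flags=flags,
    )


def quantify(
    area: float, curve: CalibrationCurve, dilution: float = 1.0
) -> tuple[float, list[str]]:
    """Invert the calibration line and undo the dilution.

    Returns (mass, flags); ``out_of_calibrated_range`` is flagged when
    the *undiluted-injection* prediction falls outside the calibrated
    mass range.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot quantify")
    if dilution <= 0:
        raise ValueError("dilution factor must be > 0")
    injected = (area - curve.intercept) / curve.slope
    flags = []
    lo, hi = curve.mass_range
    if not (lo <= injected <= hi):
        flags.append("out_of_calibrated_range")
    return injected * dilution, flags


def truncated_fraction(peaks: pd.DataFrame) -> float:
    """Truncated-mRNA percentage from an integrated peak table.

    100 · A_truncated / (A_truncated + A_intact), with the areas taken
    from rows labelled ``truncated`` and ``intact``.
    """
    areas = peaks.set_index("label")["area"]
    for label in ("truncated", "intact"):
        if label not in areas.index:
            raise ValueError(f"peak table missing label {label!r}")
    a_t = float(areas["truncated"])
    a_i = float(areas["intact"])
    if a_t < 0 or a_i < 0:
        raise ValueError("peak areas must be >= 0")
    total = a_t + a_i
    if total == 0:
        raise ValueError("both peak areas are zero")
    return 100.0 * a_t / total


def integrate_peaks(
    t: np.ndarray,
    signal: np.ndarray,
    windows: list[tuple[float, float]] | None = None,
    labels: list[str] | None = None,
    min_prominence_frac: float = 0.05,
) -> pd.DataFrame:
    """Baseline-subtracted trapezoidal peak areas of a chromatogram.

    With explicit ``windows`` each (start, end) window is integrated
    after subtracting a linear baseline between its endpoints.  Without
    windows, two-peak mode applies: the two most prominent maxima are
    located and split at the valley minimum between them (window edges
    at the trace ends); a signal with no detectable peaks yields an
    empty table.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or len(t) < 3:
        raise ValueError("need matching 1-D arrays with >= 3 samples")

    if windows is None:
        from scipy.signal import find_peaks

        span = float(y.max() - y.min())
        if span <= 0:
            return pd.DataFrame(columns=["label", "t_start", "t_end", "area"])
        idx, props = find_peaks(y, prominence=min_prominence_frac * span)
        if len(idx) == 0:
            return pd.DataFrame(columns=["label", "t_start", "t_end", "area"])
        if len(idx) == 1:
            windows = [(t[0], t[-1])]
        else:
            top2 = idx[np.argsort(props["prominences"])[-2:]]
            i1, i2 = sorted(top2)
            valley = i1 + int(np.argmin(y[i1 : i2 + 1]))
            windows = [(t[0], t[valley]), (t[valley], t[-1])]
        if labels is None:
            labels = (
                ["peak"] if len(windows) == 1 else ["truncated", "intact"]
            )
    if labels is None:
        labels = [f"peak{i+1}" for i in range(len(windows))]
    if len(labels) != len(windows):
        raise ValueError("labels and windows lengths differ")

    rows = []
    for (a, b), label in zip(windows, labels):
        m = (t >= a) & (t <= b)
        if m.sum() < 2:
            continue
        tw, yw = t[m], y[m]
        base = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
        area = float(np.trapezoid(yw - base, tw))
        rows.append({"label": label, "t_start": a, "t_end": b, "area": max(area, 0.0)})
    return pd.DataFrame(rows)
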