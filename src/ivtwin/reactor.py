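"""Segmented slug-flow operation of a plug flow reactor (PFR).

In segmented flow, aqueous reaction plugs ("slugs") separated by an
immiscible oil phase travel through a tubular reactor; each slug behaves
like an independent micro-batch with residence time τ.  Injecting a new
candidate slug every Δt minutes pipelines the reactions: over an
operating horizon T the reactor finishes floor((T − τ)/Δt) slugs, versus
floor(T/τ) sequential batches on the same equipment.

This module schedules injections, detects slugs in detector traces
(conductivity or UV), computes residence-time statistics from paired
inlet/outlet events, and evaluates consumption/yield bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcript import BASES


@dataclass(frozen=True)
class ReactorConfig:
    """Operating point of the segmented-flow PFR.

    tau_min: residence time τ (min); dt_min: injection interval Δt
    (min); horizon_min: operating window T (min); flow_mL_per_min is
    informational (τ is a direct input because tube geometry and flow
    do not pin it down exactly).
    """

    tau_min: float
    dt_min: float
    horizon_min: float
    flow_mL_per_min: float | None = None
    fill_policy: str = "prefilled_oil"

    def __post_init__(self) -> None:
        if not self.tau_min > 0:
            raise ValueError("tau_min must be > 0")
        if not self.dt_min > 0:
            raise ValueError("dt_min must be > 0")
        if self.horizon_min < self.tau_min:
            raise ValueError("horizon_min must be >= tau_min")


@dataclass
class SlugSchedule:
    """Injection/outlet events of a slug train.

    ``events`` has columns slug_id, t_in_min, t_out_min, candidate.
    Every outlet is injection + τ and injections are spaced by Δt.
    """

    events: pd.DataFrame
    cfg: ReactorConfig

    def __post_init__(self) -> None:
        e = self.events
        if len(e):
            if not np.allclose(
                e["t_out_min"], e["t_in_min"] + self.cfg.tau_min, atol=1e-9
            ):
                raise ValueError("outlet times must equal injection + tau")
            if len(e) > 1 and not np.all(np.diff(e["t_in_min"]) > 0):
                raise ValueError("injection times must be strictly increasing")

    @property
    def n_slugs(self) -> int:
        return len(self.events)

    @property
    def injection_times(self) -> np.ndarray:
        return self.events["t_in_min"].to_numpy()

    @property
    def outlet_times(self) -> np.ndarray:
        return self.events["t_out_min"].to_numpy()


def build_schedule(cfg: ReactorConfig, n_requested: int | None = None) -> SlugSchedule:
    """Schedule slug injections at Δt, 2Δt, 3Δt, …

    The reactor is pre-filled with oil, so the first slug enters one
    interval after start-up rather than at t = 0.  A slug counts as
    produced iff its outlet time (injection + τ) falls within the
    horizon, giving floor((T − τ)/Δt) produced slugs; ``n_requested``
    caps the count.
    """
    count = math.floor((cfg.horizon_min - cfg.tau_min) / cfg.dt_min + 1e-9)
    if count <= 0:
        warnings.warn(
            f"horizon {cfg.horizon_min} min fits no slug "
            f"(tau={cfg.tau_min}, dt={cfg.dt_min})",
            stacklevel=2,
        )
        count = 0
    if n_requested is not None:
        count = min(count, n_requested)
    t_in = cfg.dt_min * np.arange(1, count + 1)
    events = pd.DataFrame(
        {
            "slug_id": np.arange(1, count + 1),
            "t_in_min": t_in,
            "t_out_min": t_in + cfg.tau_min,
            "candidate": [f"candidate-{i:02d}" for i in range(1, count + 1)],
        }
    )
    return SlugSchedule(events=events, cfg=cfg)


def productivity_factor(cfg: ReactorConfig) -> float:
    """Segmented-flow throughput relative to sequential batches.

    Ratio of the segmented slug count to the sequential batch count
    floor(T/τ) on the same horizon (floored at 1 batch).
    """
    segmented = build_schedule(cfg).n_slugs
    sequential = max(math.floor(cfg.horizon_min / cfg.tau_min + 1e-9), 1)
    return segmented / sequential


@dataclass(frozen=True)
class DetectorTrace:
    """Uniformly sampled detector signal (conductivity or UV)."""

    t_min: np.ndarray
    signal: np.ndarray
    channel: str = "conductivity"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("trace needs matching 1-D time/signal arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace must be uniformly sampled")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("trace contains non-finite values")

    @property
    def sampling_interval(self) -> float:
        return float(self.t_min[1] - self.t_min[0])


def detect_slugs(
    trace: DetectorTrace,
    min_duration_min: float = 0.5,
    hysteresis_frac: float = 0.10,
) -> dict:
    """Detect slugs as threshold crossings with hysteresis.

    The threshold is the midpoint between a robust baseline (median)
    and a robust peak level (95th percentile); the signal must exceed
    threshold + h to open a slug and fall below threshold − h to close
    it, with h = ``hysteresis_frac`` of the baseline-to-peak span.
    Slugs shorter than ``min_duration_min`` are discarded.

    Returns a dict with ``events`` (DataFrame slug_id, t_start_min,
    t_end_min), ``count``, ``spacing_mean_min`` and ``spacing_sd_min``
    (spacing between consecutive slug starts; NaN when < 2 slugs).
    """
    s = trace.signal
    baseline = float(np.median(s))
    peak = float(np.percentile(s, 95))
    span = peak - baseline
    if span <= 0:
        events = pd.DataFrame(columns=["slug_id", "t_start_min", "t_end_min"])
        return {"events": events, "count": 0,
                "spacing_mean_min": np.nan, "spacing_sd_min": np.nan}
    thr = baseline + 0.5 * span
    h = hysteresis_frac * span

    starts, ends = [], []
    inside = False
    for i in range(len(s)):
        if not inside and s[i] > thr + h:
            inside = True
            starts.append(trace.t_min[i])
        elif inside and s[i] < thr - h:
            inside = False
            ends.append(trace.t_min[i])
    if inside:  # slug still open at trace end
        ends.append(trace.t_min[-1])

    keep = [
        (a, b) for a, b in zip(starts, ends) if (b - a) >= min_duration_min
    ]
    events = pd.DataFrame(
        {
            "slug_id": np.arange(1, len(keep) + 1),
            "t_start_min": [a for a, _ in keep],
            "t_end_min": [b for _, b in keep],
        }
    )
    spacing = np.diff(events["t_start_min"].to_numpy()) if len(keep) >= 2 else np.array([])
    return {
        "events": events,
        "count": len(keep),
        "spacing_mean_min": float(spacing.mean()) if spacing.size else np.nan,
        "spacing_sd_min": float(spacing.std(ddof=1)) if spacing.size >= 2 else (0.0 if spacing.size == 1 else np.nan),
    }


def residence_stats(inlet_times: np.ndarray, outlet_times: np.ndarray) -> dict:
    """Residence-time and spacing-deviation statistics of paired events.

    Pairs inlet/outlet events in order; residence time is the pairwise
    difference and the spacing deviation is |Δ_outlet − Δ_inlet| per
    adjacent slug pair (how much the injection spacing shifted in
    transit).  A single slug yields a defined mean but an undefined sd,
    reported as NaN with a flag.
    """
    t_in = np.asarray(inlet_times, dtype=float)
    t_out = np.asarray(outlet_times, dtype=float)
    if t_in.shape != t_out.shape or t_in.ndim != 1:
        raise ValueError(
            f"inlet/outlet event counts differ: {t_in.shape} vs {t_out.shape}"
        )
    if len(t_in) == 0:
        raise ValueError("no events to pair")
    res = t_out - t_in
    if np.any(res < 0):
        raise ValueError("outlet before inlet: events are not order-preserving")
    flags = []
    if len(res) < 2:
        flags.append("single_slug_sd_undefined")
    dev = np.abs(np.diff(t_out) - np.diff(t_in))
    return {
        "residence_mean_min": float(res.mean()),
        "residence_sd_min": float(res.std(ddof=1)) if len(res) >= 2 else np.nan,
        "spacing_dev_mean_min": float(dev.mean()) if dev.size else np.nan,
        "spacing_dev_sd_min": float(dev.std(ddof=1)) if dev.size >= 2 else np.nan,
        "n": len(res),
        "flags": flags,
    }


def consumption_pct(
    initial: dict[str, float], final: dict[str, float]
) -> dict[str, float]:
    """Percent NTP consumed per base plus the across-base mean.

    100 * (initial − final) / initial per base; raises when any final
    concentration exceeds its initial value.
    """
    out = {}
    for b in BASES:
        c0, c1 = float(initial[b]), float(final[b])
        if c0 <= 0:
            raise ValueError(f"initial[{b}] must be > 0")
        if c1 > c0 * (1 + 1e-12):
            raise ValueError(
                f"negative consumption for {b}: final {c1} > initial {c0}"
            )
        out[b] = 100.0 * (c0 - c1) / c0
    out["mean"] = float(np.mean([out[b] for b in BASES]))
    return out


def relative_change(before: float, after: float) -> float:
    """Signed percent change 100·(before − after)/before.

    E.g. a truncated-mRNA fraction falling from 82% to 55.3% is a
    relative reduction of 32.6%.
    """
    if before == 0:
        raise ValueError("before must be nonzero")
    return 100.0 * (before - after) / before
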