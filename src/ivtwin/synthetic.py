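"""Synthetic-data generators for every pipeline input.

Every generator is a pure function of (configuration, seed) and returns
the generating truth alongside the data, so downstream tests and demos
never reverse-engineer it.  The fixture catalog encodes the reference
study conditions: per-NTP initial-rate experiments at 2.5/5/7.5/10 mM
with apparent Michaelis constants of 140.4 (ATP), 71.5 (CTP), 165.5
(GTP) and 101.5 (UTP) μM at vmax 0.358 μM/min; a 4284-nt BNT162b2-sized
transcript; and a 10 mM-NTP production run reaching ~10 g/L mRNA.

Default measurement noise is multiplicative with a 2% CV, matching the
~2% run-to-run reproducibility of the segmented-flow experiments the
package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParams, PPiaseParams, rate_simple
from .reactor import DetectorTrace, SlugSchedule
from .simulate import ReactionState, simulate_batch
from .transcript import BASES, TranscriptSpec

#: substrate levels (μM) of the reference initial-rate assay
ASSAY_LEVELS_UM = (2500.0, 5000.0, 7500.0, 10000.0)

#: apparent Michaelis constants (μM) used as generator truth per fixture
FIXTURE_KM = {"A": 140.4, "C": 71.5, "G": 165.5, "U": 101.5}
FIXTURE_VMAX = 0.358  # μM mRNA / min


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: optional additive sd (μM) and/or
    multiplicative coefficient of variation."""

    additive_sd: float = 0.0
    cv: float = 0.02

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.cv < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(additive_sd=0.0, cv=0.0)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.cv > 0:
            out = out * (1.0 + self.cv * rng.standard_normal(out.shape))
        if self.additive_sd > 0:
            out = out + self.additive_sd * rng.standard_normal(out.shape)
        return np.clip(out, 0.0, None)


def bnt_like_transcript() -> TranscriptSpec:
    """A BNT162b2-sized construct: 4284 nt; composition chosen with U
    least frequent (the exact composition is a package choice)."""
    return TranscriptSpec(
        name="bnt-like", n_mRNA=4284,
        f={"A": 0.30, "C": 0.27, "G": 0.27, "U": 0.16},
    )


def alt_transcript() -> TranscriptSpec:
    """A shorter construct of different composition, playing the role of
    an independent cross-validation transcript."""
    return TranscriptSpec(
        name="alt-transcript", n_mRNA=1800,
        f={"A": 0.28, "C": 0.22, "G": 0.26, "U": 0.24},
    )


def reference_params() -> KineticParams:
    """Apparent-constant kinetic parameter set of the reference study."""
    return KineticParams(vmax=FIXTURE_VMAX, Km=dict(FIXTURE_KM))


def optimum_op() -> dict:
    """The optimal-operating-point production run: 10 mM of each NTP,
    the BNT-sized transcript and the reference kinetics — a batch whose
    stoichiometric plateau sits at the ~10 g/L mRNA scale."""
    return {
        "params": reference_params(),
        "ppiase": PPiaseParams.default(),
        "transcript": bnt_like_transcript(),
        "init": ReactionState(t=0.0, c_NTP={b: 10000.0 for b in BASES}),
        "t_grid": np.linspace(0.0, 180.0, 181),
    }


FIXTURES = {
    "paper-ATP": {"base": "A", "Km": FIXTURE_KM["A"], "vmax": FIXTURE_VMAX},
    "paper-CTP": {"base": "C", "Km": FIXTURE_KM["C"], "vmax": FIXTURE_VMAX},
    "paper-GTP": {"base": "G", "Km": FIXTURE_KM["G"], "vmax": FIXTURE_VMAX},
    "paper-UTP": {"base": "U", "Km": FIXTURE_KM["U"], "vmax": FIXTURE_VMAX},
}


def gen_progress_curves(
    params: KineticParams,
    transcript: TranscriptSpec,
    ntp0: dict[str, float],
    times: np.ndarray,
    noise: NoiseSpec = NoiseSpec.none(),
    seed: int = 0,
    ppiase: PPiaseParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulated, sampled and optionally noise-corrupted time courses.

    Returns (table, truth): the table has the trajectory CSV columns;
    ``truth`` records the generating parameters, noise and seed.
    """
    if ppiase is None:
        ppiase = PPiaseParams.default()
    init = ReactionState(t=float(times[0]), c_NTP=dict(ntp0))
    traj = simulate_batch(init, params, ppiase, transcript, np.asarray(times, dtype=float))
    table = traj.data.copy()
    rng = np.random.default_rng(seed)
    for col in table.columns:
        if col == "t_min":
            continue
        table[col] = noise.apply(table[col].to_numpy(), rng)
    truth = {
        "params": params, "ppiase": ppiase, "transcript": transcript,
        "ntp0": dict(ntp0), "noise": noise, "seed": seed,
    }
    return table, truth


def gen_initial_rate_dataset(
    fixture: str | dict,
    levels: tuple[float, ...] = ASSAY_LEVELS_UM,
    replicates: int = 1,
    noise: NoiseSpec = NoiseSpec.none(),
    seed: int = 0,
) -> tuple["pd.DataFrame", dict]:
    """Initial-rate observations from plain-MM generator truth.

    ``fixture`` is a catalog name ("paper-ATP" …) or an explicit dict
    with keys base, Km, vmax.  Rates are vmax·c/(Km+c) with noise.
    Returns (table, truth); the table has columns base, c_uM,
    v_uM_per_min, replicate.
    """
    truth = dict(FIXTURES[fixture]) if isinstance(fixture, str) else dict(fixture)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, replicates + 1):
        for c in levels:
            v = rate_simple(c, truth["Km"], truth["vmax"])
            v = float(noise.apply(np.array([v]), rng)[0])
            rows.append({"base": truth["base"], "c_uM": c,
                         "v_uM_per_min": v, "replicate": r})
    table = pd.DataFrame(rows)
    truth.update({"levels": tuple(levels), "replicates": replicates,
                  "noise": noise, "seed": seed})
    return table, truth


def gen_doe_dataset(
    coef: dict[str, float],
    design,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Responses from a known quadratic surface on coded units.

    ``coef`` maps term names (Intercept, x1, x2:x3, x1^2, …) to true
    coefficients; unlisted terms are zero.  Additive Gaussian noise of
    sd ``noise_sd``.
    """
    from .doe import FULL_TERMS, _model_matrix

    terms = tuple(t for t in FULL_TERMS)
    X = _model_matrix(design.coded, terms)
    beta = np.array([coef.get(c, 0.0) for c in X.columns])
    y = X.to_numpy() @ beta
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(len(y))
    truth = {"coef": dict(coef), "noise_sd": noise_sd, "seed": seed}
    return y, truth


def gen_trace(
    schedule: SlugSchedule,
    baseline: float = 1.0,
    amplitude: float = 10.0,
    slug_duration_min: float = 3.0,
    sample_dt_min: float = 0.02,
    noise_sd: float = 0.0,
    drift_per_min: float = 0.0,
    seed: int = 0,
    use_outlet: bool = False,
    smooth_sd_min: float = 0.05,
) -> tuple[DetectorTrace, dict]:
    """Detector trace of a slug train: smoothed rectangular pulses.

    One pulse of the given duration per scheduled slug (injection times
    by default, outlet times with ``use_outlet``), convolved with a
    Gaussian kernel to emulate detector dispersion, plus linear drift
    and additive Gaussian noise.
    """
    t_events = schedule.outlet_times if use_outlet else schedule.injection_times
    if len(t_events) == 0:
        raise ValueError("schedule has no slugs")
    t0 = 0.0
    t1 = float(t_events[-1] + slug_duration_min + 10 * smooth_sd_min + 1.0)
    t = np.arange(t0, t1 + sample_dt_min, sample_dt_min)
    s = np.full_like(t, baseline)
    for te in t_events:
        s[(t >= te) & (t < te + slug_duration_min)] += amplitude

    if smooth_sd_min > 0:
        half = int(np.ceil(4 * smooth_sd_min / sample_dt_min))
        k = np.exp(-0.5 * ((np.arange(-half, half + 1) * sample_dt_min) / smooth_sd_min) ** 2)
        k /= k.sum()
        s = np.convolve(s, k, mode="same")

    s = s + drift_per_min * t
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        s = s + noise_sd * rng.standard_normal(len(s))

    trace = DetectorTrace(t_min=t, signal=s)
    truth = {
        "n_slugs": len(t_events), "events_min": np.asarray(t_events, dtype=float),
        "baseline": baseline, "amplitude": amplitude,
        "slug_duration_min": slug_duration_min, "noise_sd": noise_sd,
        "drift_per_min": drift_per_min, "seed": seed,
    }
    return trace, truth
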