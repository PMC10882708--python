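"""Monte Carlo propagation of parameter precision into simulation bands.

The determination precision of the fitted kinetic constants (their
standard errors) is propagated by simulating the batch model under
randomized parameter combinations: each draw perturbs every parameter
independently with a normal deviation of its standard error (truncated
at a small positive floor), and the pointwise min/max of the simulated
trajectories forms an uncertainty envelope.  The nominal parameter set
is always included as draw 0, so the band contains the nominal
trajectory by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import KineticParams, PPiaseParams
from .simulate import ReactionState, Trajectory, simulate_batch
from .transcript import BASES, TranscriptSpec

#: observables for which bands are computed
BAND_COLUMNS = ["c_mRNA_uM"] + [f"c_{b}TP_uM" for b in BASES] + ["c_PPi_uM"]

TRUNCATION_FLOOR_FRAC = 1e-6  # floor = frac * |mean| per parameter


@dataclass(frozen=True)
class ParamDistribution:
    """Mean kinetic parameters with per-parameter standard errors.

    ``vmax_se`` and ``Km_se`` (per base) are the determination standard
    errors; parameters without a reported SE (inhibition constants,
    promoter constants) are held fixed at their mean.  Sampling is
    independent normal per parameter, truncated at a small positive
    floor.
    """

    mean: KineticParams
    vmax_se: float = 0.0
    Km_se: dict[str, float] = field(default_factory=lambda: {b: 0.0 for b in BASES})

    def __post_init__(self) -> None:
        if self.vmax_se < 0:
            raise ValueError("vmax_se must be >= 0")
        for b in BASES:
            if self.Km_se.get(b, 0.0) < 0:
                raise ValueError(f"Km_se[{b}] must be >= 0")

    def scaled(self, factor: float) -> "ParamDistribution":
        """All standard errors multiplied by ``factor`` (for sensitivity
        studies under common random numbers)."""
        return ParamDistribution(
            mean=self.mean,
            vmax_se=self.vmax_se * factor,
            Km_se={b: self.Km_se.get(b, 0.0) * factor for b in BASES},
        )


@dataclass
class EnvelopeBand:
    """Per-time lower/upper bounds for each observable.

    ``data`` is tidy: columns t_min, observable, lower, upper.
    """

    data: pd.DataFrame
    n_draws: int
    seed: int
    nominal: Trajectory

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if np.any(self.data["lower"].to_numpy() > self.data["upper"].to_numpy() + 1e-12):
            raise ValueError("band has lower > upper")

    def band(self, observable: str) -> pd.DataFrame:
        out = self.data[self.data["observable"] == observable]
        if out.empty:
            raise KeyError(f"no band for observable {observable!r}")
        return out.reset_index(drop=True)

    def width(self, observable: str) -> np.ndarray:
        b = self.band(observable)
        return (b["upper"] - b["lower"]).to_numpy()


def _standard_normals(n: int, seed: int) -> np.ndarray:
    """Common-random-number deviates: row k holds the z-scores for draw k
    (vmax then Km per base).  Draw 0 is reserved for the nominal set."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 1 + len(BASES)))


def sample_params(
    dist: ParamDistribution, n: int, seed: int
) -> list[KineticParams]:
    """Draw ``n`` independent parameter sets (draw 0 = nominal mean).

    Each perturbed parameter is clipped at a positive floor of
    ``1e-6 * mean`` so every draw stays a valid parameter set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    z = _standard_normals(n, seed)
    out = []
    m = dist.mean
    for k in range(n):
        if k == 0:
            out.append(m)
            continue
        vmax = m.vmax + dist.vmax_se * z[k, 0]
        vmax = max(vmax, TRUNCATION_FLOOR_FRAC * m.vmax)
        Km = {}
        for i, b in enumerate(BASES):
            val = m.Km[b] + dist.Km_se.get(b, 0.0) * z[k, 1 + i]
            Km[b] = max(val, TRUNCATION_FLOOR_FRAC * m.Km[b])
        out.append(replace(m, vmax=vmax, Km=Km))
    return out


def mc_envelope(
    init: ReactionState,
    dist: ParamDistribution,
    ppiase: PPiaseParams,
    transcript: TranscriptSpec,
    t_grid: np.ndarray,
    n: int = 30,
    seed: int = 0,
    mode: str = "minmax",
) -> EnvelopeBand:
    """Simulate ``n`` parameter draws and return envelope bands.

    ``mode="minmax"`` (default) takes the pointwise min/max across
    draws; ``mode="quantile"`` the pointwise 5th/95th percentiles.
    A draw whose simulation fails is retried once with tighter solver
    tolerances; a second failure propagates with the draw index named.
    """
    if mode not in ("minmax", "quantile"):
        raise ValueError(f"unknown mode {mode!r}")
    draws = sample_params(dist, n, seed)
    trajectories = []
    for k, p in enumerate(draws):
        try:
            tr = simulate_batch(init, p, ppiase, transcript, t_grid)
        except RuntimeError:
            try:
                tr = simulate_batch(
                    init, p, ppiase, transcript, t_grid,
                    solver_opts={"method": "BDF", "rtol": 1e-10, "atol": 1e-12},
                )
            except RuntimeError as e:
                raise RuntimeError(f"Monte Carlo draw {k} failed twice: {e}") from e
        trajectories.append(tr)

    rows = []
    t = trajectories[0].t
    for col in BAND_COLUMNS:
        stack = np.vstack([tr[col] for tr in trajectories])
        if mode == "minmax":
            lower, upper = stack.min(axis=0), stack.max(axis=0)
        else:
            lower = np.percentile(stack, 5, axis=0)
            upper = np.percentile(stack, 95, axis=0)
        rows.append(
            pd.DataFrame(
                {"t_min": t, "observable": col, "lower": lower, "upper": upper}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    return EnvelopeBand(data=data, n_draws=n, seed=seed, nominal=trajectories[0])
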