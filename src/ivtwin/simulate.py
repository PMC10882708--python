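"""Mass balances and batch simulation of in vitro transcription.

State variables: the four free NTP concentrations, pyrophosphate (PPi),
full-length transcript (mRNA) and the template/promoter (constant under
runoff transcription).  Per synthesised transcript, ``f_i * n_mRNA``
molecules of NTP i are consumed and ``n_mRNA`` molecules of PPi are
released; supplemented pyrophosphatase hydrolyses PPi:

    d c_mRNA / dt  =  v
    d c_NTP,i / dt = -f_i * n_mRNA * v
    d c_PPi / dt   =  n_mRNA * v - v_PPiase(c_PPi)
    d c_D / dt     =  0

with v the extended Michaelis–Menten transcription rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticParams, PPiaseParams, rate_full, rate_ppiase
from .transcript import BASES, TranscriptSpec

logger = logging.getLogger(__name__)

#: column order of the packed state vector
STATE_COLUMNS = ["c_ATP_uM", "c_CTP_uM", "c_GTP_uM", "c_UTP_uM", "c_PPi_uM", "c_mRNA_uM"]


@dataclass(frozen=True)
class ReactionState:
    """Reaction-mixture composition at one time point (μM, min)."""

    t: float
    c_NTP: dict[str, float]
    c_PPi: float = 0.0
    c_mRNA: float = 0.0
    c_D: float | None = None

    def __post_init__(self) -> None:
        missing = [b for b in BASES if b not in self.c_NTP]
        if missing:
            raise ValueError(f"c_NTP missing bases: {missing}")
        vals = [self.c_NTP[b] for b in BASES] + [self.c_PPi, self.c_mRNA]
        if self.c_D is not None:
            vals.append(self.c_D)
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("state contains non-finite concentrations")
        if np.any(arr < 0):
            raise ValueError("state contains negative concentrations")

    def pack(self) -> np.ndarray:
        return np.array(
            [self.c_NTP[b] for b in BASES] + [self.c_PPi, self.c_mRNA], dtype=float
        )


@dataclass
class Trajectory:
    """Simulated (or sampled) time course.

    ``data`` holds one row per time point with columns ``t_min`` plus
    :data:`STATE_COLUMNS`; ``meta`` records parameters, solver options
    and, for noisy realisations, the seed.
    """

    data: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data["t_min"].to_numpy()
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.data["t_min"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def state_at(self, i: int) -> ReactionState:
        row = self.data.iloc[i]
        return ReactionState(
            t=row["t_min"],
            c_NTP={b: row[f"c_{b}TP_uM"] for b in BASES},
            c_PPi=row["c_PPi_uM"],
            c_mRNA=row["c_mRNA_uM"],
            c_D=self.meta.get("c_D"),
        )


def ode_rhs(
    state: ReactionState,
    params: KineticParams,
    ppiase: PPiaseParams,
    transcript: TranscriptSpec,
) -> dict[str, float]:
    """Time derivatives (μM/min) of every state variable."""
    v = rate_full(state.c_NTP, params, c_PPi=state.c_PPi, c_D=state.c_D)
    n = transcript.n_mRNA
    d = {f"c_{b}TP_uM": -transcript.f[b] * n * v for b in BASES}
    d["c_mRNA_uM"] = v
    d["c_PPi_uM"] = n * v - rate_ppiase(state.c_PPi, ppiase)
    d["c_D_uM"] = 0.0
    return d


def _rhs_packed(y, params, ppiase, transcript, c_D, frac, n):
    c = {b: max(y[i], 0.0) for i, b in enumerate(BASES)}
    c_PPi = max(y[4], 0.0)
    v = rate_full(c, params, c_PPi=c_PPi, c_D=c_D)
    dy = np.empty(6)
    dy[:4] = -frac * n * v
    dy[4] = n * v - rate_ppiase(c_PPi, ppiase)
    dy[5] = v
    return dy


def simulate_batch(
    init: ReactionState,
    params: KineticParams,
    ppiase: PPiaseParams,
    transcript: TranscriptSpec,
    t_grid: np.ndarray,
    solver_opts: dict[str, Any] | None = None,
) -> Trajectory:
    """Integrate the batch IVT mass balances on a fixed output grid.

    Uses a stiff-safe implicit solver (LSODA) with tight tolerances
    (rtol 1e-8, atol 1e-10 μM by default); concentrations are clipped
    to zero after integration and the number of clipped entries is
    recorded in ``meta['n_clipped']`` with a warning.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be a 1-D array with >= 2 points")
    if abs(t_grid[0] - init.t) > 1e-12:
        raise ValueError(f"t_grid must start at init.t={init.t}, got {t_grid[0]}")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    opts = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}
    if solver_opts:
        opts.update(solver_opts)

    frac = transcript.fractions
    n = transcript.n_mRNA
    y0 = init.pack()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LSODA chatter on very stiff steps
        sol = solve_ivp(
            lambda t, y: _rhs_packed(y, params, ppiase, transcript, init.c_D, frac, n),
            (t_grid[0], t_grid[-1]),
            y0,
            t_eval=t_grid,
            **opts,
        )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed at t={sol.t[-1] if len(sol.t) else t_grid[0]:.4g} min "
            f"(last state {sol.y[:, -1] if sol.y.size else y0}): {sol.message}"
        )

    y = sol.y.T
    n_clipped = int(np.sum(y < 0))
    if n_clipped:
        logger.warning("clipped %d negative concentration values to 0", n_clipped)
    y = np.clip(y, 0.0, None)

    data = pd.DataFrame(y, columns=STATE_COLUMNS)
    data.insert(0, "t_min", sol.t)
    meta = {
        "params": params,
        "ppiase": ppiase,
        "transcript": transcript.name,
        "n_mRNA": n,
        "c_D": init.c_D,
        "solver": dict(opts),
        "n_clipped": n_clipped,
    }
    return Trajectory(data=data, meta=meta)
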