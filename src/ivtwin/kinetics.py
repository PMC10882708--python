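"""Lumped Michaelis–Menten rate laws for T7 in vitro transcription.

The transcription velocity is modelled with an extended Michaelis–Menten
law: a product of per-NTP saturation terms, an optional promoter
saturation term, an initiation bracket on the GTP term (GTP starts every
transcript, so low GTP slows initiation beyond its elongation role), and
competitive-inhibition corrections in which every NTP and pyrophosphate
(PPi) compete for the nucleotide binding site:

    v = vmax * P_D * T_G * T_A * T_C * T_U

    T_i = c_i / (Km_i * alpha_i + c_i)                      i in {A, C, U}
    T_G = c_G / (Km_G * alpha_G * [1 + Kd_GTP / c_G] + c_G)
    alpha_i = 1 + sum_{j != i} c_j / Ki_j + c_PPi / Ki_PPi
    P_D = c_D / (Km_D + c_D)   (1 when the template is saturating)

When *apparent* Michaelis constants (measured with the other NTPs in
excess) are used, the competitive-inhibition sums must be dropped — the
inhibition is already absorbed into Km_app.  ``KineticParams`` therefore
treats ``Ki``, ``Ki_PPi`` and ``Kd_GTP`` as optional: ``None`` removes
the corresponding term, which is the package default and the mode in
which whole-reaction simulations with fitted apparent constants run.

Pyrophosphate removal by supplemented pyrophosphatase follows a plain
Michaelis–Menten law in c_PPi (:func:`rate_ppiase`).

Units package-wide: time min, concentrations μM, rates μM/min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .transcript import BASES

logger = logging.getLogger(__name__)


def _as_base_dict(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [b for b in BASES if b not in value]
        if missing:
            raise ValueError(f"{name} missing bases: {missing}")
        return {b: float(value[b]) for b in BASES}
    return {b: float(value) for b in BASES}


@dataclass(frozen=True)
class KineticParams:
    """Constants of the extended Michaelis–Menten transcription law.

    Parameters
    ----------
    vmax:
        Maximum mRNA production rate, μM transcript / min.
    Km:
        Michaelis constant per NTP, μM.  A scalar is broadcast to all
        four bases.  When fitted with the other NTPs in excess these are
        *apparent* constants and the inhibition terms below should stay
        ``None``.
    Ki:
        Competitive-inhibition constant per NTP, μM, or ``None`` to drop
        NTP cross-inhibition (apparent mode, the default).
    Km_D:
        Michaelis constant of the promoter/template, μM, or ``None`` to
        treat the template as saturating (runoff transcription with
        excess template, the default).
    Kd_GTP:
        Dissociation constant of initial GTP binding, μM, or ``None``
        to drop the initiation bracket.
    Ki_PPi:
        Competitive-inhibition constant of pyrophosphate, μM, or
        ``None`` to drop PPi product inhibition.
    """

    vmax: float
    Km: dict[str, float]
    Ki: dict[str, float] | None = None
    Km_D: float | None = None
    Kd_GTP: float | None = None
    Ki_PPi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "Km", _as_base_dict(self.Km, "Km"))
        if self.Ki is not None:
            object.__setattr__(self, "Ki", _as_base_dict(self.Ki, "Ki"))
        if not (self.vmax > 0 and math.isfinite(self.vmax)):
            raise ValueError(f"vmax must be finite and > 0, got {self.vmax}")
        for b in BASES:
            if not self.Km[b] > 0:
                raise ValueError(f"Km[{b}] must be > 0")
            if self.Ki is not None and not self.Ki[b] > 0:
                raise ValueError(f"Ki[{b}] must be > 0")
        for nm in ("Km_D", "Kd_GTP", "Ki_PPi"):
            v = getattr(self, nm)
            if v is not None and not v > 0:
                raise ValueError(f"{nm} must be > 0 when given")

    def with_(self, **changes) -> "KineticParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PPiaseParams:
    """Pyrophosphatase kinetics: v = k_PPiase * c_PPase * c_PPi / (Km_PPi + c_PPi).

    k_PPiase is the rate constant per unit of volumetric enzyme activity
    (μM PPi / min per U/μL), c_PPase the supplemented activity (U/μL)
    and Km_PPi the Michaelis constant of pyrophosphate (μM).  The rate
    constant and Km_PPi are typically taken from the enzymology
    literature rather than refit; :func:`PPiaseParams.default` supplies
    documented defaults and logs their use.
    """

    k_PPiase: float
    c_PPase: float
    Km_PPi: float = 50.0

    def __post_init__(self) -> None:
        if self.k_PPiase < 0 or self.c_PPase < 0:
            raise ValueError("k_PPiase and c_PPase must be >= 0")
        if not self.Km_PPi > 0:
            raise ValueError("Km_PPi must be > 0")

    @classmethod
    def default(cls, c_PPase: float = 0.002) -> "PPiaseParams":
        """Literature-style defaults: Km_PPi = 50 μM and k_PPiase = 1e6
        μM/min per U/μL — the enzyme-unit definition (1 U hydrolyzes
        1 μmol substrate/min, i.e. 1 U/μL sustains 1e6 μM/min at
        saturation).  At the reference 0.002 U/μL the hydrolysis
        capacity (2000 μM/min) outruns peak PPi release, keeping free
        PPi below 1% of its ppiase-free level in the reference
        simulation."""
        logger.warning(
            "PPiaseParams.default used: k_PPiase=1e6 uM/min per U/uL, "
            "Km_PPi=50 uM (literature-style defaults, not fitted here)"
        )
        return cls(k_PPiase=1e6, c_PPase=c_PPase, Km_PPi=50.0)

    @classmethod
    def off(cls) -> "PPiaseParams":
        """No pyrophosphatase activity."""
        return cls(k_PPiase=0.0, c_PPase=0.0, Km_PPi=50.0)


def _check_conc(c, name: str) -> None:
    arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")


def rate_simple(c: float, Km_app: float, vmax: float):
    """Plain Michaelis–Menten rate v = vmax * c / (Km_app + c).

    This is the reduced law valid for initial rates when all NTPs but
    one are in excess and pyrophosphatase keeps PPi near zero; Km_app
    absorbs any competitive inhibition by the excess species.
    """
    _check_conc(c, "c")
    if not Km_app > 0:
        raise ValueError("Km_app must be > 0")
    if not vmax > 0:
        raise ValueError("vmax must be > 0")
    c = np.asarray(c, dtype=float)
    out = vmax * c / (Km_app + c)
    return float(out) if out.ndim == 0 else out


def rate_ppiase(c_PPi: float, p: PPiaseParams) -> float:
    """PPi hydrolysis rate (μM/min) of the supplemented pyrophosphatase."""
    _check_conc(c_PPi, "c_PPi")
    return p.k_PPiase * p.c_PPase * c_PPi / (p.Km_PPi + c_PPi)


def _alpha(conc: dict[str, float], c_PPi: float, params: KineticParams, skip: str) -> float:
    """Competitive-inhibition factor for the saturation term of base ``skip``."""
    a = 1.0
    if params.Ki is not None:
        a += sum(conc[j] / params.Ki[j] for j in BASES if j != skip)
    if params.Ki_PPi is not None:
        a += c_PPi / params.Ki_PPi
    return a


def rate_full(
    c_NTP: dict[str, float],
    params: KineticParams,
    c_PPi: float = 0.0,
    c_D: float | None = None,
) -> float:
    """Transcription rate (μM mRNA/min) under the extended MM law.

    Parameters
    ----------
    c_NTP:
        Free NTP concentration per base, μM.
    params:
        Kinetic constants; optional terms are dropped when ``None``.
    c_PPi:
        Pyrophosphate concentration, μM.
    c_D:
        Molar template/promoter concentration, μM.  ``None`` (default)
        treats the promoter term as saturated, appropriate for runoff
        transcription with excess template.
    """
    conc = _as_base_dict(c_NTP, "c_NTP")
    _check_conc(list(conc.values()), "c_NTP")
    _check_conc(c_PPi, "c_PPi")
    if c_D is not None:
        _check_conc(c_D, "c_D")

    v = params.vmax
    for b in BASES:
        c = conc[b]
        a = _alpha(conc, c_PPi, params, skip=b)
        if b == "G" and params.Kd_GTP is not None:
            # c/(Km*a*(1+Kd/c)+c) rewritten as c^2/(Km*a*(c+Kd)+c^2)
            # so the c_G -> 0 limit evaluates to 0 without dividing by 0.
            v *= c * c / (params.Km[b] * a * (c + params.Kd_GTP) + c * c)
        else:
            v *= c / (params.Km[b] * a + c)
    if params.Km_D is not None and c_D is not None:
        v *= c_D / (params.Km_D + c_D)
    return v


def reduce_to_apparent(
    params: KineticParams,
    varied: str,
    excess: dict[str, float],
    c_PPi: float = 0.0,
    c_D: float | None = None,
    c_ref: float = 10000.0,
) -> tuple[float, float]:
    """Reduce the full law to plain MM in one varied NTP.

    With the three other NTPs fixed at their excess concentrations the
    full law is, to first order, ``vmax_app * c / (Km_app + c)`` in the
    varied concentration ``c``.  Km_app is the effective half-saturation
    constant: ``Km_varied * alpha_varied`` (times the exact initiation
    correction for GTP, evaluated as the half-saturation root of the
    bracketed denominator).  vmax_app anchors the reduced curve to the
    full law at the reference concentration ``c_ref`` (default 10000 μM,
    a typical top assay level), absorbing the excess-NTP saturation
    factors.  The reduction is exact when NTP cross-inhibition is off
    (``Ki is None``); with finite Ki the varied NTP feeds back on the
    excess terms and agreement degrades gracefully.

    Returns
    -------
    (Km_app, vmax_app) in μM and μM/min.
    """
    if varied not in BASES:
        raise ValueError(f"varied must be one of {BASES}")
    for b in BASES:
        if b != varied and b not in excess:
            raise ValueError(f"excess concentrations must cover {b}")

    conc_ref = {b: (c_ref if b == varied else float(excess[b])) for b in BASES}
    a = _alpha(conc_ref, c_PPi, params, skip=varied)
    Km_eff = params.Km[varied] * a
    if varied == "G" and params.Kd_GTP is not None:
        # half-saturation of c^2/(Km*a*(c+Kd)+c^2): positive root of
        # c^2 - Km*a*c - Km*a*Kd = 0
        Kd = params.Kd_GTP
        Km_eff = 0.5 * (Km_eff + math.sqrt(Km_eff**2 + 4.0 * Km_eff * Kd))

    v_ref = rate_full(conc_ref, params, c_PPi=c_PPi, c_D=c_D)
    vmax_app = v_ref * (Km_eff + c_ref) / c_ref
    return Km_eff, vmax_app
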