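"""File formats: trajectory/rate-table/band/schedule CSV, YAML/JSON
configuration blocks, and an optional FASTA transcript reader.

CSV dialect is fixed package-wide: comma separator, "." decimal, UTF-8,
header row mandatory; floats are written with 12 significant digits so
read/write round-trips are lossless at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParams, PPiaseParams
from .reactor import ReactorConfig
from .doe import FactorSpec
from .simulate import STATE_COLUMNS, Trajectory
from .transcript import BASES, TranscriptSpec

FLOAT_FORMAT = "%.12g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_trajectory(traj: Trajectory, path) -> None:
    write_csv(traj.data[["t_min"] + STATE_COLUMNS], path)


def read_trajectory(path) -> Trajectory:
    df = read_csv(path)
    missing = [c for c in ["t_min"] + STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    return Trajectory(data=df, meta={"source": str(path)})


def write_sidecar(truth: dict, path) -> None:
    """JSON metadata sidecar with generator truth; dataclasses and
    arrays are rendered to plain types."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=default), encoding="utf-8")


# ---------------------------------------------------------------- config

def transcript_from_config(block: dict) -> TranscriptSpec:
    kwargs = {
        "name": block["name"],
        "n_mRNA": int(block["n_mRNA"]),
        "f": {b: float(block["f"][b]) for b in BASES},
    }
    if "residue_masses" in block:
        kwargs["residue_masses"] = {
            b: float(block["residue_masses"][b]) for b in BASES
        }
    return TranscriptSpec(**kwargs)


def params_from_config(block: dict) -> KineticParams:
    return KineticParams(
        vmax=float(block["vmax"]),
        Km={b: float(block["Km"][b]) for b in BASES},
        Ki=({b: float(block["Ki"][b]) for b in BASES} if block.get("Ki") else None),
        Km_D=(float(block["Km_D"]) if block.get("Km_D") else None),
        Kd_GTP=(float(block["Kd_GTP"]) if block.get("Kd_GTP") else None),
        Ki_PPi=(float(block["Ki_PPi"]) if block.get("Ki_PPi") else None),
    )


def ppiase_from_config(block: dict | None) -> PPiaseParams:
    if not block:
        return PPiaseParams.default()
    return PPiaseParams(
        k_PPiase=float(block["k_PPiase"]),
        c_PPase=float(block["c_PPase"]),
        Km_PPi=float(block.get("Km_PPi", 50.0)),
    )


def reactor_from_config(block: dict) -> ReactorConfig:
    return ReactorConfig(
        tau_min=float(block["tau_min"]),
        dt_min=float(block["dt_min"]),
        horizon_min=float(block["horizon_min"]),
        flow_mL_per_min=(
            float(block["flow_mL_per_min"]) if block.get("flow_mL_per_min") else None
        ),
    )


def factors_from_config(blocks: list[dict]) -> list[FactorSpec]:
    return [
        FactorSpec(
            name=b["name"], low=float(b["low"]), high=float(b["high"]),
            units=b.get("units", ""),
        )
        for b in blocks
    ]


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration.

    Recognized top-level blocks: transcript, kinetics, kinetics_se,
    ppiase, reactor, factors; unknown blocks pass through untouched.
    """
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    out = dict(raw)
    if "transcript" in raw:
        out["transcript"] = transcript_from_config(raw["transcript"])
    if "kinetics" in raw:
        out["kinetics"] = params_from_config(raw["kinetics"])
    if "ppiase" in raw:
        out["ppiase"] = ppiase_from_config(raw["ppiase"])
    if "reactor" in raw:
        out["reactor"] = reactor_from_config(raw["reactor"])
    if "factors" in raw:
        out["factors"] = factors_from_config(raw["factors"])
    return out


# ---------------------------------------------------------------- fasta

def transcript_from_fasta(path, name: str | None = None) -> TranscriptSpec:
    """Derive length and base composition from the first FASTA record.

    Bases are counted on the given strand; T and U both count as U.
    """
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"no FASTA record found in {path}") from None
    return TranscriptSpec.from_sequence(name or record.id, str(record.seq))
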