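"""Transcript description and molar/mass unit conversions.

The kinetic model needs only two sequence-level summaries of the mRNA
construct: its length ``n_mRNA`` in nucleotides and the relative base
composition ``f_i`` (fraction of A, C, G and U residues).  Together they
set the stoichiometry that couples NTP consumption to transcript
production: every synthesised transcript consumes ``f_i * n_mRNA``
molecules of NTP ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = ("A", "C", "G", "U")

#: Molar mass (g/mol) of one incorporated ribonucleotide-monophosphate
#: residue, i.e. the NMP moiety left in the chain after pyrophosphate
#: release.  Values include the phosphodiester contribution.
DEFAULT_RESIDUE_MASSES = {"A": 329.2, "C": 305.2, "G": 345.2, "U": 306.2}


@dataclass(frozen=True)
class TranscriptSpec:
    """An mRNA construct: length and per-base composition.

    Parameters
    ----------
    name:
        Label for provenance.
    n_mRNA:
        Transcript length in nucleotides (>= 1).
    f:
        Mapping base -> fraction of that base in the transcript.  Must
        cover A, C, G, U and sum to 1 within 1e-9.
    residue_masses:
        Molar mass (g/mol) of an incorporated residue per base.
    """

    name: str
    n_mRNA: int
    f: dict[str, float]
    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_MASSES)
    )

    def __post_init__(self) -> None:
        if self.n_mRNA < 1:
            raise ValueError(f"n_mRNA must be >= 1, got {self.n_mRNA}")
        missing = [b for b in BASES if b not in self.f]
        if missing:
            raise ValueError(f"composition missing bases: {missing}")
        fvals = np.array([self.f[b] for b in BASES], dtype=float)
        if np.any(fvals < 0) or np.any(fvals > 1):
            raise ValueError("base fractions must lie in [0, 1]")
        if abs(fvals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"base fractions must sum to 1 (got {fvals.sum():.12f})"
            )

    @property
    def fractions(self) -> np.ndarray:
        """Composition as an array ordered (A, C, G, U)."""
        return np.array([self.f[b] for b in BASES], dtype=float)

    @property
    def mean_residue_mass(self) -> float:
        """Composition-weighted residue mass, g/mol."""
        return float(
            sum(self.f[b] * self.residue_masses[b] for b in BASES)
        )

    @property
    def molar_mass(self) -> float:
        """Molar mass of the full transcript, g/mol."""
        return self.n_mRNA * self.mean_residue_mass

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, residue_masses: dict[str, float] | None = None
    ) -> "TranscriptSpec":
        """Build a spec by counting bases of an RNA/DNA sequence string.

        T and U are both counted as U (the coding-strand DNA sequence
        describes the transcript).  Characters outside ACGTU raise.
        """
        seq = sequence.upper().replace("T", "U")
        seq = "".join(seq.split())
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"sequence contains non-ACGTU characters: {sorted(bad)}")
        n = len(seq)
        f = {b: seq.count(b) / n for b in BASES}
        kwargs = {}
        if residue_masses is not None:
            kwargs["residue_masses"] = residue_masses
        return cls(name=name, n_mRNA=n, f=f, **kwargs)


def molar_to_mass(c_uM: float, transcript: TranscriptSpec) -> float:
    """Convert a transcript concentration from μM to g/L.

    g/L = c[mol/L] * M[g/mol] = c_uM * 1e-6 * n_mRNA * mean residue mass.
    """
    if c_uM < 0:
        raise ValueError("concentration must be >= 0")
    return c_uM * 1e-6 * transcript.molar_mass


def mass_to_molar(rho_g_per_L: float, transcript: TranscriptSpec) -> float:
    """Convert a transcript concentration from g/L to μM (inverse of
    :func:`molar_to_mass`)."""
    if rho_g_per_L < 0:
        raise ValueError("concentration must be >= 0")
    return rho_g_per_L / (1e-6 * transcript.molar_mass)
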