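"""In-silico tryptic digestion and observable-peptide counting.

Trypsin cleaves C-terminal to K or R; the Keil exception suppresses
cleavage when the next residue is proline.  The count of theoretically
observable fully cleaved peptides is the denominator of the protein
abundance index (PAI), so it is computed here once and consumed by the
quantification module.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import chem

__all__ = [
    "Peptide",
    "ObservabilityWindow",
    "DEFAULT_WINDOW",
    "cleavage_sites",
    "digest",
    "observable_peptides",
    "n_observable",
]


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with 1-based inclusive coordinates in its chain."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mass_mono: float
    mass_avg: float

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class ObservabilityWindow:
    """Closed mass and length windows a peptide must fall into to count
    as theoretically observable."""

    min_mass: float = 500.0
    max_mass: float = 4500.0
    min_length: int = 6
    max_length: int = 50

    def __post_init__(self):
        if not self.min_mass < self.max_mass:
            raise ValueError("min_mass must be < max_mass")
        if not self.min_length < self.max_length:
            raise ValueError("min_length must be < max_length")

    def contains(self, peptide: Peptide, mass_scale: str = "average") -> bool:
        m = peptide.mass_avg if mass_scale == "average" else peptide.mass_mono
        return (
            self.min_mass <= m <= self.max_mass
            and self.min_length <= len(peptide.sequence) <= self.max_length
        )


# Typical acquisition range of an ion-trap/Orbitrap shotgun run.
DEFAULT_WINDOW = ObservabilityWindow()


def cleavage_sites(sequence: str, keil: bool = True) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (keil and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    chain_sequence: str,
    max_missed: int = 2,
    keil: bool = True,
) -> list[Peptide]:
    """All tryptic peptides with 0..max_missed internal missed cleavages.

    Peptides are returned ordered by start position, then by missed
    cleavage count.  Concatenating the fully cleaved (0 missed) peptides
    reconstructs the input chain.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    chem._check_sequence(chain_sequence)
    sites = cleavage_sites(chain_sequence, keil=keil)
    # segment boundaries: start indices of fully cleaved peptides
    starts = [0] + [i + 1 for i in sites]
    ends = [i for i in sites] + [len(chain_sequence) - 1]  # inclusive
    n_seg = len(starts)
    peptides = []
    for i in range(n_seg):
        for j in range(i, min(i + max_missed + 1, n_seg)):
            s, e = starts[i], ends[j]
            seq = chain_sequence[s : e + 1]
            peptides.append(
                Peptide(
                    sequence=seq,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=j - i,
                    mass_mono=chem.mass(seq, kind="monoisotopic"),
                    mass_avg=chem.mass(seq, kind="average"),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def observable_peptides(
    peptides: list[Peptide],
    window: ObservabilityWindow = DEFAULT_WINDOW,
    mass_scale: str = "average",
    include_missed: bool = False,
) -> list[Peptide]:
    """Peptides inside the observability window.

    By default only fully cleaved peptides are retained, because the
    PAI denominator counts non-redundant observable peptides and
    missed-cleavage variants would double-count sequence.  Set
    ``include_missed=True`` for sensitivity analysis.
    """
    return [
        p
        for p in peptides
        if (include_missed or p.missed_cleavages == 0)
        and window.contains(p, mass_scale)
    ]


def n_observable(
    chain_sequence: str,
    window: ObservabilityWindow = DEFAULT_WINDOW,
    mass_scale: str = "average",
    keil: bool = True,
) -> int:
    """N_obsbl: the PAI denominator for one chain."""
    return len(
        observable_peptides(digest(chain_sequence, 0, keil=keil), window, mass_scale)
    )
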