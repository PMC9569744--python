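"""emPAI quantification and protein-identification acceptance filters.

PAI = n_obs / n_obsbl, the number of distinct identified peptides over
the number of theoretically observable tryptic peptides; emPAI =
10^PAI - 1, which is roughly proportional to protein molar amount.
Identification acceptance follows the standard plasma-proteomics rule:
at least two unique peptides per protein, each passing a confidence
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PsmRow",
    "SearchParams",
    "ProteinQuant",
    "count_observed",
    "empai",
    "accept_proteins",
    "molar_fraction",
]


@dataclass(frozen=True)
class PsmRow:
    """One peptide-identification row from a search-engine export."""

    section_id: str
    accession: str
    peptide: str
    mod_string: str = ""
    score: float = 0.0
    is_unique: bool = True
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("empty peptide")
        if not math.isfinite(self.score):
            raise ValueError("non-finite score")


@dataclass(frozen=True)
class SearchParams:
    """Search-engine metadata recorded for provenance (never used to search)."""

    enzyme: str = "trypsin"
    max_missed: int = 2
    fixed_mods: tuple[str, ...] = ("carbamidomethyl (C)",)
    variable_mods: tuple[str, ...] = (
        "oxidation (M)",
        "phospho (S/T)",
        "acetyl (K)",
    )
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.01

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class ProteinQuant:
    """Per-(protein, section) quantification result."""

    accession: str
    section_id: str
    n_obs: int
    n_obsbl: int
    pai: float
    empai: float


def count_observed(
    psm_rows: list[PsmRow],
    accession: str,
    section_id: str,
    collapse_mods: bool = True,
) -> int:
    """Number of distinct identified peptides for a protein in a section.

    Modification states are collapsed by default (PAI counts parent
    peptides; counting modified forms separately would inflate the
    apparent abundance of heavily modified proteoforms).
    """
    seen = set()
    for row in psm_rows:
        if row.accession == accession and row.section_id == section_id:
            key = row.peptide if collapse_mods else (row.peptide, row.mod_string)
            seen.add(key)
    return len(seen)


def empai(n_obs: int, n_obsbl: int) -> tuple[float, float]:
    """(PAI, emPAI) for observed vs observable peptide counts."""
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    if n_obsbl < 1:
        raise ValueError(
            "protein has no theoretically observable peptides (n_obsbl = 0); "
            "emPAI is undefined"
        )
    pai = n_obs / n_obsbl
    return pai, 10.0**pai - 1.0


def accept_proteins(
    psm_rows: list[PsmRow],
    min_unique: int = 2,
    score_threshold: float = 0.0,
) -> set[str]:
    """Accessions with >= min_unique distinct unique peptides passing the
    score threshold.  The two-unique-peptide rule is the identification
    acceptance criterion; everything else is excluded from patterns."""
    unique_peps: dict[str, set[str]] = {}
    for row in psm_rows:
        if row.is_unique and row.score >= score_threshold:
            unique_peps.setdefault(row.accession, set()).add(row.peptide)
    return {acc for acc, peps in unique_peps.items() if len(peps) >= min_unique}


def quantify_sections(
    psm_rows: list[PsmRow],
    n_obsbl_by_accession: dict[str, int],
    accepted: set[str] | None = None,
    collapse_mods: bool = True,
) -> list[ProteinQuant]:
    """Per-(accession, section) emPAI table for accepted proteins."""
    pairs = sorted(
        {
            (r.accession, r.section_id)
            for r in psm_rows
            if accepted is None or r.accession in accepted
        }
    )
    out = []
    for acc, sec in pairs:
        n_obs = count_observed(psm_rows, acc, sec, collapse_mods=collapse_mods)
        pai, em = empai(n_obs, n_obsbl_by_accession[acc])
        out.append(
            ProteinQuant(
                accession=acc, section_id=sec, n_obs=n_obs,
                n_obsbl=n_obsbl_by_accession[acc], pai=pai, empai=em,
            )
        )
    return out


def molar_fraction(empai_values: list[float]) -> list[float]:
    """Normalize emPAI values to mol percentages (sum to 100)."""
    if any(v < 0 for v in empai_values):
        raise ValueError("emPAI values must be >= 0")
    total = sum(empai_values)
    if total <= 0:
        raise ValueError("all emPAI values are zero; mol% undefined")
    return [100.0 * v / total for v in empai_values]
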