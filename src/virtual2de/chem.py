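"""Sequence-level physical chemistry of proteoforms.

Masses, net charge as a function of pH, isoelectric points, and the
construction of proteoforms (a mature chain plus a complement of
post-translational modifications) with the pI and Mw shifts those
modifications induce.

The charge model is the classical Henderson-Hasselbalch sum over
ionizable groups: side chains of D, E, C, Y (acidic), H, K, R (basic),
the two termini, and any ionizable groups contributed (or removed) by
modifications.  Three pKa sets are shipped; the Bjellqvist set, with its
residue-specific terminal pKa values, is the default because it is the
set behind the ExPASy-style theoretical pI values used throughout gel
electrophoresis work.

Average masses are the default mass scale for gel (Mw) coordinates;
monoisotopic masses are available for peptide-level bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

from pyteomics import mass as _ptmass

__all__ = [
    "CANONICAL_AA",
    "WATER_AVG",
    "WATER_MONO",
    "ChainRange",
    "ProteinRecord",
    "ModKind",
    "Modification",
    "IonizableDelta",
    "phospho",
    "acetyl",
    "oxidation",
    "carbamidomethyl",
    "glyco",
    "GLYCAN_MONOMER_AVG",
    "GLYCAN_MONOMER_MONO",
    "PkaSet",
    "load_pka_set",
    "available_pka_sets",
    "mass",
    "net_charge",
    "isoelectric_point",
    "NoIsoelectricPointError",
    "Proteoform",
    "make_proteoform",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

WATER_AVG = _ptmass.calculate_mass(formula="H2O", average=True)
WATER_MONO = _ptmass.calculate_mass(formula="H2O")

# Residue (i.e. water-free) masses derived from the pyteomics atomic
# mass tables, so both scales share one elemental source of truth.
RESIDUE_AVG = {
    aa: _ptmass.calculate_mass(sequence=aa, average=True) - WATER_AVG
    for aa in CANONICAL_AA
}
RESIDUE_MONO = {
    aa: _ptmass.calculate_mass(sequence=aa) - WATER_MONO for aa in CANONICAL_AA
}


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_AVG:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1} "
                "(U/O/B/Z/X are rejected rather than approximated)"
            )


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChainRange:
    """A mature-chain range within a precursor, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid chain range {self.name}: {self.start}-{self.end}")

    def extract(self, sequence: str) -> str:
        if self.end > len(sequence):
            raise ValueError(
                f"chain {self.name} ({self.start}-{self.end}) exceeds sequence "
                f"length {len(sequence)}"
            )
        return sequence[self.start - 1 : self.end]


@dataclass
class ProteinRecord:
    """A database protein: sequence plus chain annotations and site counts."""

    accession: str
    entry_name: str
    sequence: str
    chains: list[ChainRange] = field(default_factory=list)
    site_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        _check_sequence(self.sequence)
        for ch in self.chains:
            if ch.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: chain {ch.name} ends at {ch.end} but "
                    f"sequence has {len(self.sequence)} residues"
                )

    def chain(self, name: str) -> ChainRange:
        for ch in self.chains:
            if ch.name == name:
                return ch
        raise KeyError(
            f"{self.accession} has no chain {name!r}; "
            f"known: {[c.name for c in self.chains]}"
        )

    def chain_sequence(self, name: str) -> str:
        return self.chain(name).extract(self.sequence)


class ModKind(str, Enum):
    phospho = "phospho"
    acetyl = "acetyl"
    carbamidomethyl = "carbamidomethyl"
    oxidation = "oxidation"
    glyco = "glyco"


@dataclass(frozen=True)
class IonizableDelta:
    """An ionizable group added (copies > 0) or removed (copies < 0)."""

    group_type: str  # "acidic" | "basic"
    pka: float
    copies: int = 1

    def __post_init__(self):
        if self.group_type not in ("acidic", "basic"):
            raise ValueError(f"group_type must be acidic|basic, got {self.group_type}")
        if not 0.0 < self.pka < 14.0:
            raise ValueError(f"pKa {self.pka} outside (0, 14)")


# Average / monoisotopic glycan monomer residue masses.
GLYCAN_MONOMER_AVG = {"Hex": 162.14, "HexNAc": 203.20, "NeuAc": 291.26, "Fuc": 146.14}
GLYCAN_MONOMER_MONO = {
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "NeuAc": 291.0954,
    "Fuc": 146.0579,
}

# Default pKa values of modification-borne groups: the two phosphate
# ionizations and the sialic-acid carboxyl.
PHOSPHO_PKAS = (1.2, 6.5)
NEUAC_PKA = 2.6
LYSINE_SIDECHAIN_PKA = 10.0  # removed by N-epsilon acetylation


@dataclass(frozen=True)
class Modification:
    kind: ModKind
    count: int = 1
    glycan_composition: tuple[tuple[str, int], ...] = ()
    mass_delta_avg: float = 0.0
    mass_delta_mono: float = 0.0
    ionizable_deltas: tuple[IonizableDelta, ...] = ()

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("modification count must be >= 0")
        if self.glycan_composition and self.kind is not ModKind.glyco:
            raise ValueError("glycan_composition only allowed for glyco modifications")

    def mass_delta(self, kind: str) -> float:
        """Total mass delta (count included) on the given scale."""
        per = self.mass_delta_avg if kind == "average" else self.mass_delta_mono
        return per * self.count


def phospho(count: int = 1) -> Modification:
    """HPO3 addition; contributes two acidic groups per phosphate."""
    return Modification(
        kind=ModKind.phospho,
        count=count,
        mass_delta_avg=79.98,
        mass_delta_mono=79.96633,
        ionizable_deltas=tuple(
            IonizableDelta("acidic", pka) for pka in PHOSPHO_PKAS
        ),
    )


def acetyl(count: int = 1) -> Modification:
    """Lysine N-epsilon acetylation; removes one lysine basic group."""
    return Modification(
        kind=ModKind.acetyl,
        count=count,
        mass_delta_avg=42.04,
        mass_delta_mono=42.01057,
        ionizable_deltas=(IonizableDelta("basic", LYSINE_SIDECHAIN_PKA, copies=-1),),
    )


def oxidation(count: int = 1) -> Modification:
    return Modification(
        kind=ModKind.oxidation, count=count, mass_delta_avg=16.00,
        mass_delta_mono=15.99491,
    )


def carbamidomethyl(count: int = 1) -> Modification:
    return Modification(
        kind=ModKind.carbamidomethyl, count=count, mass_delta_avg=57.05,
        mass_delta_mono=57.02146,
    )


def glyco(composition: dict[str, int], count: int = 1) -> Modification:
    """An N- or O-glycan given as a monomer composition.

    Neutral sugars change mass only; every NeuAc additionally carries
    one acidic (carboxyl) group, which is what drives the acidic spot
    trains of sialylated glycoproteins.
    """
    comp = tuple(sorted(composition.items()))
    for monomer, n in comp:
        if monomer not in GLYCAN_MONOMER_AVG:
            raise ValueError(f"unknown glycan monomer {monomer!r}")
        if n < 0:
            raise ValueError("glycan monomer counts must be >= 0")
    avg = sum(GLYCAN_MONOMER_AVG[m] * n for m, n in comp)
    mono = sum(GLYCAN_MONOMER_MONO[m] * n for m, n in comp)
    n_neuac = dict(comp).get("NeuAc", 0)
    deltas = (
        (IonizableDelta("acidic", NEUAC_PKA, copies=n_neuac),) if n_neuac else ()
    )
    return Modification(
        kind=ModKind.glyco, count=count, glycan_composition=comp,
        mass_delta_avg=avg, mass_delta_mono=mono, ionizable_deltas=deltas,
    )


# ---------------------------------------------------------------------------
# pKa sets


@dataclass(frozen=True)
class PkaSet:
    """A named table of side-chain and terminal pKa values.

    ``nterm_pkas`` / ``cterm_pkas`` map a residue to its
    position-specific terminal pKa; the ``'*'`` entry is the default for
    residues without a specific value (the Bjellqvist convention).
    """

    name: str
    side_chain_pkas: dict[str, float]
    nterm_pkas: dict[str, float]
    cterm_pkas: dict[str, float]

    def nterm(self, residue: str) -> float:
        return self.nterm_pkas.get(residue, self.nterm_pkas["*"])

    def cterm(self, residue: str) -> float:
        return self.cterm_pkas.get(residue, self.cterm_pkas["*"])


_ACIDIC_SIDE = frozenset("DECY")
_BASIC_SIDE = frozenset("HKR")

_PKA_CACHE: dict[str, PkaSet] = {}


def _read_pka_table() -> dict[str, PkaSet]:
    raw: dict[str, dict[str, dict[str, float]]] = {}
    text = (
        resources.files("virtual2de").joinpath("data/pka_sets.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        set_name, group, residue, pka = line.split("\t")
        raw.setdefault(set_name, {"side": {}, "nterm": {}, "cterm": {}})
        raw[set_name][group][residue] = float(pka)
    return {
        name: PkaSet(
            name=name,
            side_chain_pkas=tables["side"],
            nterm_pkas=tables["nterm"],
            cterm_pkas=tables["cterm"],
        )
        for name, tables in raw.items()
    }


def available_pka_sets() -> list[str]:
    if not _PKA_CACHE:
        _PKA_CACHE.update(_read_pka_table())
    return sorted(_PKA_CACHE)


def load_pka_set(name: str = "bjellqvist") -> PkaSet:
    if not _PKA_CACHE:
        _PKA_CACHE.update(_read_pka_table())
    try:
        return _PKA_CACHE[name]
    except KeyError:
        raise KeyError(
            f"unknown pKa set {name!r}; available: {available_pka_sets()}"
        ) from None


# ---------------------------------------------------------------------------
# operations


def mass(
    sequence: str,
    mods: list[Modification] | tuple[Modification, ...] = (),
    kind: str = "average",
) -> float:
    """Mass of a (modified) polypeptide in Da.

    Sum of residue masses on the selected scale, plus one water, plus
    the mass deltas of all modifications.  ``kind`` is ``"average"``
    (default; the scale used for gel Mw coordinates) or
    ``"monoisotopic"``.
    """
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"kind must be average|monoisotopic, got {kind!r}")
    _check_sequence(sequence)
    table = RESIDUE_AVG if kind == "average" else RESIDUE_MONO
    water = WATER_AVG if kind == "average" else WATER_MONO
    total = sum(table[aa] for aa in sequence) + water
    return total + sum(m.mass_delta(kind) for m in mods)


def _ionizable_groups(
    sequence: str,
    mods: tuple[Modification, ...],
    pka_set: PkaSet,
) -> list[tuple[str, float, float]]:
    """Collapse molecule to (group_type, pKa, copies) triples."""
    groups: dict[tuple[str, float], float] = {}

    def add(group_type: str, pka: float, copies: float) -> None:
        key = (group_type, pka)
        groups[key] = groups.get(key, 0.0) + copies

    for aa in _ACIDIC_SIDE | _BASIC_SIDE:
        n = sequence.count(aa)
        if n and aa in pka_set.side_chain_pkas:
            kind = "acidic" if aa in _ACIDIC_SIDE else "basic"
            add(kind, pka_set.side_chain_pkas[aa], n)
    add("basic", pka_set.nterm(sequence[0]), 1)
    add("acidic", pka_set.cterm(sequence[-1]), 1)
    for m in mods:
        for d in m.ionizable_deltas:
            add(d.group_type, d.pka, d.copies * m.count)
    return [(t, p, c) for (t, p), c in groups.items() if c != 0.0]


def net_charge(
    sequence: str,
    mods: list[Modification] | tuple[Modification, ...] = (),
    pH: float = 7.0,
    pka_set: PkaSet | None = None,
) -> float:
    """Net charge (elementary units) at a given pH.

    Q(pH) = sum_basic n_i / (1 + 10^(pH - pKa_i))
          - sum_acidic n_i / (1 + 10^(pKa_i - pH))
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    _check_sequence(sequence)
    pka_set = pka_set or load_pka_set()
    q = 0.0
    for group_type, pka, copies in _ionizable_groups(sequence, tuple(mods), pka_set):
        if group_type == "basic":
            q += copies / (1.0 + 10.0 ** (pH - pka))
        else:
            q -= copies / (1.0 + 10.0 ** (pka - pH))
    return q


class NoIsoelectricPointError(ValueError):
    """The molecule's net charge does not change sign on [0, 14]."""


def isoelectric_point(
    sequence: str,
    mods: list[Modification] | tuple[Modification, ...] = (),
    pka_set: PkaSet | None = None,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: the unique root of net_charge on [0, 14].

    Found by bisection to ``tol`` pH units.  Net charge is strictly
    decreasing in pH whenever the molecule has at least one ionizable
    group, so the root (when the sign changes over the interval) is
    unique.  Report to 2 decimals when comparing with printed values.
    """
    pka_set = pka_set or load_pka_set()
    mods = tuple(mods)
    lo, hi = 0.0, 14.0
    q_lo = net_charge(sequence, mods, lo, pka_set)
    q_hi = net_charge(sequence, mods, hi, pka_set)
    if q_lo < 0.0 or q_hi > 0.0:
        raise NoIsoelectricPointError(
            f"no isoelectric point: Q(0)={q_lo:.3f}, Q(14)={q_hi:.3f}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mods, mid, pka_set) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class Proteoform:
    """A specific chain with a specific modification complement."""

    parent: str  # accession
    chain: ChainRange
    mods: tuple[Modification, ...]
    pI: float
    Mw: float  # average mass, Da
    abundance_weight: float | None = None

    def __post_init__(self):
        if not 0.0 < self.pI < 14.0:
            raise ValueError(f"pI {self.pI} outside (0, 14)")
        if self.Mw <= 0:
            raise ValueError("Mw must be positive")
        if self.abundance_weight is not None and not 0.0 <= self.abundance_weight <= 1.0:
            raise ValueError("abundance_weight must lie in [0, 1]")


_SITE_KIND_KEYS = {
    ModKind.phospho: "phospho",
    ModKind.acetyl: "acetyl",
    ModKind.glyco: "glyco",
    ModKind.oxidation: "oxidation",
    ModKind.carbamidomethyl: "carbamidomethyl",
}


def make_proteoform(
    record: ProteinRecord,
    chain_name: str,
    mods: list[Modification] | tuple[Modification, ...] = (),
    pka_set: PkaSet | None = None,
    abundance_weight: float | None = None,
) -> Proteoform:
    """Build a proteoform of a named chain with computed pI and Mw.

    When the record carries ``site_counts``, modification counts are
    validated against the number of annotatable sites.
    """
    chain = record.chain(chain_name)
    seq = chain.extract(record.sequence)
    mods = tuple(mods)
    if record.site_counts:
        per_kind: dict[str, int] = {}
        for m in mods:
            key = _SITE_KIND_KEYS[m.kind]
            per_kind[key] = per_kind.get(key, 0) + m.count
        for key, n in per_kind.items():
            if key in record.site_counts and n > record.site_counts[key]:
                raise ValueError(
                    f"{record.accession}/{chain_name}: {n} {key} modifications "
                    f"exceed {record.site_counts[key]} annotated sites"
                )
    return Proteoform(
        parent=record.accession,
        chain=chain,
        mods=mods,
        pI=isoelectric_point(seq, mods, pka_set),
        Mw=mass(seq, mods, "average"),
        abundance_weight=abundance_weight,
    )
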