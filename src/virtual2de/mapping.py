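"""Axis calibration, section geometry and 2DE pattern construction.

The first gel dimension is isoelectric focusing along an immobilized pH
gradient strip (possibly nonlinear, e.g. pH 3-11 NL); the second is
SDS-PAGE migration, log-linear in molecular weight.  A gel or strip is
cut into sections; per-section protein quantifications become
VirtualSpots, and the set of spots of one protein across sections is
its reconstructed 2DE pattern (the "spot train").

Two section geometries mirror the two experimental designs:

* ``grid96`` - a full gel cut into an 8 x 12 grid (96 sections), spots
  located in both pI and Mw;
* ``strip36`` - semi-virtual 2DE: an 18-cm IEF strip cut into 36 equal
  0.5-cm sections, with the Mw coordinate taken from theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OffGelError",
    "PiAxis",
    "MwAxis",
    "fit_pi_axis",
    "fit_mw_axis",
    "SectionScheme",
    "strip36_scheme",
    "grid96_scheme",
    "locate_section",
    "VirtualSpot",
    "Pattern2DE",
    "build_pattern",
    "spot_extent",
    "compare_patterns",
    "PatternComparison",
]


class OffGelError(ValueError):
    """A coordinate falls outside the calibrated range."""


@dataclass(frozen=True)
class PiAxis:
    """Monotone map between strip position (cm) and pH.

    Piecewise-linear through the anchor table; extrapolation beyond the
    anchors is forbidden (an off-strip coordinate is an error, not a
    number).
    """

    anchors: tuple[tuple[float, float], ...]  # (position_cm, pH)
    mode: str = "piecewise_linear"

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("need at least 2 anchors")
        pos = [p for p, _ in self.anchors]
        ph = [h for _, h in self.anchors]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("anchor positions must be strictly increasing")
        if any(b <= a for a, b in zip(ph, ph[1:])):
            raise ValueError("anchor pH values must be strictly increasing")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.anchors])

    @property
    def ph_values(self) -> np.ndarray:
        return np.array([h for _, h in self.anchors])

    def ph_at(self, position_cm: float) -> float:
        pos = self.positions
        if not pos[0] <= position_cm <= pos[-1]:
            raise OffGelError(
                f"position {position_cm} cm outside calibrated strip "
                f"[{pos[0]}, {pos[-1]}]"
            )
        return float(np.interp(position_cm, pos, self.ph_values))

    def position_at(self, ph: float) -> float:
        phv = self.ph_values
        if not phv[0] <= ph <= phv[-1]:
            raise OffGelError(
                f"pH {ph} outside calibrated gradient [{phv[0]}, {phv[-1]}]"
            )
        return float(np.interp(ph, phv, self.positions))


# A documented 5-point piecewise-linear approximation of a nonlinear
# 3-11 gradient on an 18-cm strip: the middle of the strip is
# flattened around pH 5-8 (where resolution is highest) and the ends
# are steep.  Users should supply the manufacturer's curve for
# accuracy; this shape is for realistic defaults and tests.
NL_3_11_ANCHORS_18CM = (
    (0.0, 3.0),
    (4.5, 5.0),
    (9.0, 6.5),
    (13.5, 8.0),
    (18.0, 11.0),
)


def fit_pi_axis(
    anchors: list[tuple[float, float]] | tuple[tuple[float, float], ...],
) -> PiAxis:
    return PiAxis(anchors=tuple((float(p), float(h)) for p, h in anchors))


@dataclass(frozen=True)
class MwAxis:
    """Least-squares log-linear SDS-PAGE calibration.

    log10(Mw) = intercept + slope * relative_migration; the slope is
    negative because larger proteins migrate less.
    """

    markers: tuple[tuple[float, float], ...]  # (relative_migration, Mw)
    slope: float
    intercept: float
    gel_percent: float | None = None

    def mw_at(self, migration: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * migration))

    def migration_at(self, mw: float) -> float:
        if mw <= 0:
            raise ValueError("Mw must be positive")
        return float((np.log10(mw) - self.intercept) / self.slope)


def fit_mw_axis(
    markers: list[tuple[float, float]] | tuple[tuple[float, float], ...],
    gel_percent: float | None = None,
) -> MwAxis:
    markers = tuple((float(m), float(w)) for m, w in markers)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    mig = np.array([m for m, _ in markers])
    if len(np.unique(mig)) != len(mig):
        raise ValueError("duplicate migration values in marker ladder")
    logmw = np.log10([w for _, w in markers])
    slope, intercept = np.polyfit(mig, logmw, 1)
    if slope >= 0:
        raise ValueError(
            "fitted slope is non-negative; check the marker ladder "
            "(larger proteins must migrate less)"
        )
    return MwAxis(markers=markers, slope=float(slope), intercept=float(intercept),
                  gel_percent=gel_percent)


@dataclass(frozen=True)
class SectionScheme:
    """A partition of the gel (or strip) into half-open sections.

    ``col_edges`` partitions the first (pI) dimension, ``row_edges`` the
    second (Mw) dimension; a strip scheme has a single row.  Interval
    convention: [low, high), with the final interval closed so that the
    edges form an exact partition of the calibrated range.
    """

    mode: str  # "grid96" | "strip36" | "custom"
    col_edges: tuple[float, ...]
    row_edges: tuple[float, ...] | None = None
    col_unit: str = "cm"  # "cm" (strip position) or "pH"
    row_unit: str | None = None  # "Da" or "migration"

    def __post_init__(self):
        if len(self.col_edges) < 2 or any(
            b <= a for a, b in zip(self.col_edges, self.col_edges[1:])
        ):
            raise ValueError("col_edges must be strictly increasing, length >= 2")
        if self.row_edges is not None and (
            len(self.row_edges) < 2
            or any(b <= a for a, b in zip(self.row_edges, self.row_edges[1:]))
        ):
            raise ValueError("row_edges must be strictly increasing, length >= 2")

    @property
    def n_cols(self) -> int:
        return len(self.col_edges) - 1

    @property
    def n_rows(self) -> int:
        return 1 if self.row_edges is None else len(self.row_edges) - 1

    @property
    def n_sections(self) -> int:
        return self.n_rows * self.n_cols

    def section_id(self, row: int, col: int) -> str:
        return str(col) if self.row_edges is None else f"{row}-{col}"

    def parse_section_id(self, section_id: str) -> tuple[int, int]:
        if self.row_edges is None:
            row, col = 0, int(section_id)
        else:
            r, c = section_id.split("-")
            row, col = int(r), int(c)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"section id {section_id!r} outside scheme")
        return row, col

    def col_window(self, col: int) -> tuple[float, float]:
        return self.col_edges[col], self.col_edges[col + 1]

    def row_window(self, row: int) -> tuple[float, float]:
        if self.row_edges is None:
            raise ValueError("strip scheme has no row windows")
        return self.row_edges[row], self.row_edges[row + 1]


def _locate_1d(x: float, edges: tuple[float, ...], what: str) -> int:
    if x < edges[0] or x > edges[-1]:
        raise OffGelError(f"{what} coordinate {x} is off-gel ({edges[0]}..{edges[-1]})")
    if x == edges[-1]:  # final interval is closed
        return len(edges) - 2
    return int(np.searchsorted(edges, x, side="right")) - 1


def locate_section(
    scheme: SectionScheme, col_coord: float, row_coord: float | None = None
) -> tuple[int, int]:
    """(row, col) of the section containing a point; half-open membership.

    Coordinates must be in the scheme's own units (``col_unit`` /
    ``row_unit``).  An out-of-range coordinate raises OffGelError.
    """
    col = _locate_1d(col_coord, scheme.col_edges, "first-dimension")
    if scheme.row_edges is None:
        return 0, col
    if row_coord is None:
        raise ValueError("row coordinate required for a grid scheme")
    row = _locate_1d(row_coord, scheme.row_edges, "second-dimension")
    return row, col


def strip36_scheme(length_cm: float = 18.0, n_sections: int = 36) -> SectionScheme:
    """Semi-virtual design: an IEF strip cut into equal sections."""
    edges = tuple(float(x) for x in np.linspace(0.0, length_cm, n_sections + 1))
    return SectionScheme(mode="strip36", col_edges=edges, col_unit="cm")


def grid96_scheme(
    pi_range: tuple[float, float],
    mw_range: tuple[float, float],
    n_rows: int = 8,
    n_cols: int = 12,
) -> SectionScheme:
    """Sectional design: a rectangular grid over the calibrated plane.

    Default 8 Mw-rows x 12 pI-columns (96 sections).  Column edges are
    equal in pH; row edges are equal in log10(Mw), matching SDS-PAGE
    geometry.  Fully overridable by constructing SectionScheme directly.
    """
    cols = tuple(float(x) for x in np.linspace(pi_range[0], pi_range[1], n_cols + 1))
    row_list = [
        float(x)
        for x in 10.0
        ** np.linspace(np.log10(mw_range[0]), np.log10(mw_range[1]), n_rows + 1)
    ]
    row_list[0], row_list[-1] = float(mw_range[0]), float(mw_range[1])
    rows = tuple(row_list)
    mode = "grid96" if n_rows * n_cols == 96 else "custom"
    return SectionScheme(
        mode=mode, col_edges=cols, row_edges=rows, col_unit="pH", row_unit="Da"
    )


@dataclass(frozen=True)
class VirtualSpot:
    accession: str
    section: tuple[int, int]  # (row, col)
    pi_window: tuple[float, float]  # [pH_low, pH_high)
    mw_value: float  # Da
    empai: float

    def __post_init__(self):
        if self.empai < 0:
            raise ValueError("emPAI must be >= 0")

    @property
    def pi_center(self) -> float:
        return 0.5 * (self.pi_window[0] + self.pi_window[1])


@dataclass
class Pattern2DE:
    spots: list[VirtualSpot]
    scheme: SectionScheme
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        keys = [(s.accession, s.section) for s in self.spots]
        if len(keys) != len(set(keys)):
            raise ValueError("more than one spot per (accession, section)")

    def accessions(self) -> list[str]:
        return sorted({s.accession for s in self.spots})

    def total_empai(self) -> float:
        return sum(s.empai for s in self.spots)

    def spots_for(self, accession: str) -> list[VirtualSpot]:
        return [s for s in self.spots if s.accession == accession]


def build_pattern(
    quants,
    scheme: SectionScheme,
    pi_axis: PiAxis | None = None,
    theoretical_mw: dict[str, float] | None = None,
    provenance: dict[str, str] | None = None,
) -> Pattern2DE:
    """Turn per-section quantifications into a 2DE pattern.

    In a strip scheme (semi-virtual 2DE) the Mw coordinate of every spot
    is the supplied theoretical chain Mw; in a grid scheme it is the
    section's Mw-window midpoint (geometric, matching the log-spaced
    rows).  Column windows in cm are converted to pH via ``pi_axis``.
    """
    spots = []
    for q in quants:
        row, col = scheme.parse_section_id(q.section_id)
        lo, hi = scheme.col_window(col)
        if scheme.col_unit == "cm":
            if pi_axis is None:
                raise ValueError("pi_axis required to convert cm windows to pH")
            pi_win = (pi_axis.ph_at(lo), pi_axis.ph_at(hi))
        else:
            pi_win = (lo, hi)
        if scheme.row_edges is None:
            if theoretical_mw is None or q.accession not in (theoretical_mw or {}):
                raise ValueError(
                    f"no theoretical Mw supplied for {q.accession} "
                    "(required in strip mode)"
                )
            mw = theoretical_mw[q.accession]
        else:
            rlo, rhi = scheme.row_window(row)
            mw = float(np.sqrt(rlo * rhi)) if scheme.row_unit == "Da" else 0.5 * (rlo + rhi)
        spots.append(
            VirtualSpot(
                accession=q.accession, section=(row, col), pi_window=pi_win,
                mw_value=mw, empai=q.empai,
            )
        )
    return Pattern2DE(spots=spots, scheme=scheme, provenance=dict(provenance or {}))


def spot_extent(pattern: Pattern2DE, accession: str) -> tuple[float, float, float, float]:
    """(pI_min, pI_max, Mw_min, Mw_max) bounding box of a protein's spots."""
    spots = pattern.spots_for(accession)
    if not spots:
        raise KeyError(f"no spots for accession {accession!r}")
    return (
        min(s.pi_window[0] for s in spots),
        max(s.pi_window[1] for s in spots),
        min(s.mw_value for s in spots),
        max(s.mw_value for s in spots),
    )


@dataclass
class PatternComparison:
    matched: list[tuple[VirtualSpot, VirtualSpot, float]]  # (a, b, log2 ratio)
    unmatched_a: list[VirtualSpot]
    unmatched_b: list[VirtualSpot]


def compare_patterns(
    a: Pattern2DE,
    b: Pattern2DE,
    pi_tol: float = 0.25,
    mw_tol_fraction: float = 0.1,
    pseudocount: float = 0.01,
) -> PatternComparison:
    """Greedy nearest-neighbour spot matching between two patterns.

    Spots of the same accession are matched when their pI centres are
    within ``pi_tol`` pH units and Mw within a relative
    ``mw_tol_fraction``; closest pairs are taken first.  Ratios are
    log2((emPAI_a + c) / (emPAI_b + c)) with pseudocount c so zero
    spots remain comparable.  Greedy matching is adequate because spot
    sets are small and tolerance windows rarely overlap.
    """
    matched = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    accs = sorted({s.accession for s in a.spots} | {s.accession for s in b.spots})
    for acc in accs:
        ia = [i for i, s in enumerate(a.spots) if s.accession == acc]
        ib = [j for j, s in enumerate(b.spots) if s.accession == acc]
        candidates = []
        for i in ia:
            for j in ib:
                sa, sb = a.spots[i], b.spots[j]
                dpi = abs(sa.pi_center - sb.pi_center)
                dmw = abs(sa.mw_value - sb.mw_value) / max(sa.mw_value, sb.mw_value)
                if dpi <= pi_tol and dmw <= mw_tol_fraction:
                    candidates.append((dpi + dmw, i, j))
        for _, i, j in sorted(candidates):
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            sa, sb = a.spots[i], b.spots[j]
            ratio = float(
                np.log2((sa.empai + pseudocount) / (sb.empai + pseudocount))
            )
            matched.append((sa, sb, ratio))
    return PatternComparison(
        matched=matched,
        unmatched_a=[s for i, s in enumerate(a.spots) if i not in used_a],
        unmatched_b=[s for j, s in enumerate(b.spots) if j not in used_b],
    )
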