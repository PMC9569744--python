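"""Deterministic SVG bubble maps of 2DE patterns.

One circle per virtual spot, positioned at (pI centre, Mw) with the Mw
axis logarithmic and inverted (large proteins at the top, as on a gel).
Circle AREA is proportional to emPAI by default, the perceptually
honest reading of "ball size proportional to abundance"; a
radius-proportional mode is available because the convention is
ambiguous in the field.

The writer is intentionally minimal and emits byte-identical output for
identical input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mapping import Pattern2DE

__all__ = ["RenderStyle", "render"]


@dataclass(frozen=True)
class RenderStyle:
    width: float = 640.0
    height: float = 480.0
    margin: float = 60.0
    max_radius: float = 18.0
    size_mode: str = "area"  # "area" | "radius"
    fill: str = "#2b6cb0"
    fill_opacity: float = 0.65
    n_ticks: int = 5

    def __post_init__(self):
        if self.size_mode not in ("area", "radius"):
            raise ValueError("size_mode must be area|radius")


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def render(pattern: Pattern2DE, style: RenderStyle = RenderStyle()) -> str:
    """Render a pattern to an SVG document string."""
    if not pattern.spots:
        raise ValueError("cannot render an empty pattern")
    s = style
    pis = [sp.pi_center for sp in pattern.spots]
    mws = [sp.mw_value for sp in pattern.spots]
    pi_lo = min(sp.pi_window[0] for sp in pattern.spots)
    pi_hi = max(sp.pi_window[1] for sp in pattern.spots)
    if pi_hi == pi_lo:
        pi_lo, pi_hi = pi_lo - 0.5, pi_hi + 0.5
    lmw_lo, lmw_hi = math.log10(min(mws)), math.log10(max(mws))
    if lmw_hi == lmw_lo:
        lmw_lo, lmw_hi = lmw_lo - 0.1, lmw_hi + 0.1
    emax = max(sp.empai for sp in pattern.spots)
    if emax <= 0:
        emax = 1.0

    x0, x1 = s.margin, s.width - s.margin
    y0, y1 = s.margin, s.height - s.margin

    def x_of(pi: float) -> float:
        return x0 + (pi - pi_lo) / (pi_hi - pi_lo) * (x1 - x0)

    def y_of(mw: float) -> float:
        # inverted: high Mw at top
        return y0 + (lmw_hi - math.log10(mw)) / (lmw_hi - lmw_lo) * (y1 - y0)

    def radius(empai: float) -> float:
        frac = empai / emax
        if s.size_mode == "area":
            return s.max_radius * math.sqrt(frac)
        return s.max_radius * frac

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(s.width)}" '
        f'height="{_fmt(s.height)}" viewBox="0 0 {_fmt(s.width)} {_fmt(s.height)}">',
        f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(x1 - x0)}" '
        f'height="{_fmt(y1 - y0)}" fill="none" stroke="#444" stroke-width="1"/>',
    ]
    # axis ticks
    for k in range(s.n_ticks):
        f = k / (s.n_ticks - 1)
        pi = pi_lo + f * (pi_hi - pi_lo)
        x = x_of(pi)
        parts.append(
            f'<line x1="{_fmt(x)}" y1="{_fmt(y1)}" x2="{_fmt(x)}" y2="{_fmt(y1 + 5)}" '
            'stroke="#444" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y1 + 20)}" font-size="11" '
            f'text-anchor="middle">{pi:.1f}</text>'
        )
        lmw = lmw_hi - f * (lmw_hi - lmw_lo)
        y = y0 + f * (y1 - y0)
        parts.append(
            f'<line x1="{_fmt(x0 - 5)}" y1="{_fmt(y)}" x2="{_fmt(x0)}" y2="{_fmt(y)}" '
            'stroke="#444" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_fmt(x0 - 8)}" y="{_fmt(y + 4)}" font-size="11" '
            f'text-anchor="end">{10.0 ** lmw:,.0f}</text>'
        )
    parts.append(
        f'<text x="{_fmt(0.5 * (x0 + x1))}" y="{_fmt(s.height - 12)}" font-size="13" '
        'text-anchor="middle">pI (pH units)</text>'
    )
    parts.append(
        f'<text x="14" y="{_fmt(0.5 * (y0 + y1))}" font-size="13" text-anchor="middle" '
        f'transform="rotate(-90 14 {_fmt(0.5 * (y0 + y1))})">Mw (Da)</text>'
    )
    for sp in sorted(pattern.spots, key=lambda t: (t.accession, t.section)):
        parts.append(
            f'<circle cx="{_fmt(x_of(sp.pi_center))}" cy="{_fmt(y_of(sp.mw_value))}" '
            f'r="{_fmt(radius(sp.empai))}" fill="{s.fill}" '
            f'fill-opacity="{s.fill_opacity}" data-accession="{sp.accession}" '
            f'data-empai="{sp.empai:.4f}"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
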