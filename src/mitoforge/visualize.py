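"""Circular mitogenome plot: gene features, GC content and depth tracks.

The renderer emits plain SVG markup composed deterministically (fixed
element order, fixed numeric formatting), so identical inputs produce
byte-identical files. Angle zero sits at 12 o'clock and coordinates run
clockwise, following genome-plot convention. Plus- and minus-strand
features are drawn on distinct rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import GeneAnnotation

DEFAULT_PALETTE = {
    "PCG": "#4daf4a",
    "tRNA": "#377eb8",
    "rRNA": "#e41a1c",
    "control_region": "#ff7f00",
}

DEFAULT_WINDOW = 100
DEFAULT_STEP = 100


@dataclass
class TrackData:
    kind: str                      # genes | gc | depth
    values: list = field(default_factory=list)
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP


def gc_windows(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    circular: bool = False,
) -> TrackData:
    """Per-window GC percentage over non-N bases.

    Windows start every ``step`` bp; in linear mode the final partial
    window is included, in circular mode windows wrap the origin.
    """
    L = len(sequence)
    if not 1 <= step <= window:
        raise ValueError("need 1 <= step <= window")
    if window > L and not circular:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    source = sequence + sequence[:window] if circular else sequence
    values = []
    for start in range(0, L, step):
        chunk = source[start:start + window]
        denom = len(chunk) - chunk.count("N")
        gc = 100.0 * (chunk.count("G") + chunk.count("C")) / denom if denom else 0.0
        values.append(gc)
    return TrackData(kind="gc", values=values, window=window, step=step)


def depth_windows(
    depths: Sequence[float],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> TrackData:
    """Wrap per-window depth values into a track."""
    if any(d < 0 for d in depths):
        raise ValueError("depth values must be non-negative")
    return TrackData(kind="depth", values=list(depths), window=window, step=step)


def _point(cx: float, cy: float, r: float, frac: float) -> tuple[float, float]:
    theta = 2.0 * math.pi * frac
    return cx + r * math.sin(theta), cy - r * math.cos(theta)


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _arc_path(cx, cy, r_in, r_out, f0, f1) -> str:
    """Donut-segment path from genome fraction f0 to f1 (clockwise)."""
    x0o, y0o = _point(cx, cy, r_out, f0)
    x1o, y1o = _point(cx, cy, r_out, f1)
    x1i, y1i = _point(cx, cy, r_in, f1)
    x0i, y0i = _point(cx, cy, r_in, f0)
    large = 1 if (f1 - f0) > 0.5 else 0
    return (
        f"M {_fmt(x0o)} {_fmt(y0o)} "
        f"A {_fmt(r_out)} {_fmt(r_out)} 0 {large} 1 {_fmt(x1o)} {_fmt(y1o)} "
        f"L {_fmt(x1i)} {_fmt(y1i)} "
        f"A {_fmt(r_in)} {_fmt(r_in)} 0 {large} 0 {_fmt(x0i)} {_fmt(y0i)} Z"
    )


def render_circular(
    annotations: Sequence[GeneAnnotation],
    seq_length: int,
    tracks: Sequence[TrackData] = (),
    style: Optional[dict[str, str]] = None,
    size: int = 640,
) -> str:
    """Render the circular map as an SVG string.

    Feature arcs span an angle proportional to their length; scalar
    tracks (gc, depth) are drawn as radial bar rings. Identical inputs
    yield identical bytes.
    """
    palette = dict(DEFAULT_PALETTE)
    if style:
        palette.update(style)
    L = seq_length
    for a in annotations:
        if a.start < 0 or a.end > L:
            raise ValueError(
                f"feature {a.gene} [{a.start},{a.end}) outside sequence "
                f"of length {L}"
            )
    cx = cy = size / 2.0
    r_backbone = size * 0.34
    parts: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
        f'height="{size}" viewBox="0 0 {size} {size}">',
        f'<rect width="{size}" height="{size}" fill="#ffffff"/>',
        f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r_backbone)}" '
        f'fill="none" stroke="#333333" stroke-width="1.0"/>',
    ]
    # feature rings: plus strand outside the backbone, minus inside
    for a in sorted(annotations, key=lambda a: (a.start, a.end, a.gene)):
        f0, f1 = a.start / L, a.end / L
        if a.strand == "-":
            r_in, r_out = r_backbone - 16, r_backbone - 4
        else:
            r_in, r_out = r_backbone + 4, r_backbone + 16
        colour = palette.get(a.kind, "#999999")
        parts.append(
            f'<path class="feature" d="{_arc_path(cx, cy, r_in, r_out, f0, f1)}" '
            f'fill="{colour}" stroke="none"><title>{a.gene}</title></path>'
        )
    # scalar rings
    ring_base = r_backbone - 30
    for t in tracks:
        if t.kind not in ("gc", "depth"):
            raise ValueError(f"unknown track kind {t.kind!r}")
        vmax = max(t.values) if t.values else 1.0
        vmax = vmax if vmax > 0 else 1.0
        height = 18.0
        r_out = ring_base
        colour = "#984ea3" if t.kind == "gc" else "#a65628"
        for i, v in enumerate(t.values):
            f0 = (i * t.step) / L
            f1 = min(((i * t.step) + t.step) / L, 1.0)
            h = height * (v / vmax)
            parts.append(
                f'<path class="track-{t.kind}" '
                f'd="{_arc_path(cx, cy, r_out - h, r_out, f0, f1)}" '
                f'fill="{colour}" stroke="none"/>'
            )
        ring_base -= height + 8
    # legend
    y = 18
    for kind in ("PCG", "tRNA", "rRNA", "control_region"):
        parts.append(
            f'<rect x="10" y="{y - 9}" width="12" height="10" '
            f'fill="{palette[kind]}"/>'
            f'<text x="26" y="{y}" font-size="11" '
            f'font-family="sans-serif">{kind}</text>'
        )
        y += 16
    for t in tracks:
        colour = "#984ea3" if t.kind == "gc" else "#a65628"
        parts.append(
            f'<rect x="10" y="{y - 9}" width="12" height="10" fill="{colour}"/>'
            f'<text x="26" y="{y}" font-size="11" '
            f'font-family="sans-serif">{t.kind}</text>'
        )
        y += 16
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
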