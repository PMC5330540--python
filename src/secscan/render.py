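"""Cloverleaf rendering of annotated candidates (text and SVG).

Arms are colored with the conventional scheme — acceptor red, D yellow,
anticodon green, variable blue, T purple; wobble GU/UG pairs are drawn
faint; the anticodon triplet and the discriminator base are circled.
Output is deterministic: byte-identical across runs for the same
candidate.
"""

from __future__ import annotations

from secscan.alphabet import is_wobble, pairs_canonically, to_rna
from secscan.annotate import TRNACandidate

ARM_COLORS = {
    "A": "#d62728",   # red
    "D": "#e6c229",   # yellow
    "C": "#2ca02c",   # green
    "V": "#1f77b4",   # blue
    "T": "#9467bd",   # purple
}


def _arm_strands(cand: TRNACandidate):
    """Per arm: (5' stem bases, loop bases, 3' stem bases) in RNA letters."""
    model = cand.hit.model
    cs = model.structure
    parse = cand.hit.parse
    seq = to_rna(cand.hit.matched_sequence)

    def base(col):
        pos = parse.col_to_pos.get(col)
        return None if pos is None else seq[pos]

    arms = {}
    for name in ("A", "D", "C", "V", "T"):
        stem = f"{name}-stem"
        pairs = [(base(i), base(j)) for i, j in cs.stem_pairs(stem)]
        pairs = [(a, b) for a, b in pairs if a is not None and b is not None]
        loop = [base(c) for c in cs.loop_columns(f"{name}-loop")]
        arms[name] = (pairs, [b for b in loop if b is not None])
    return arms


def render_text(cand: TRNACandidate) -> str:
    """Deterministic ASCII cloverleaf summary."""
    arms = _arm_strands(cand)
    lines = []
    iv = cand.hit.interval
    lines.append(f"tRNA-Sec candidate {iv.contig}:{iv.start + 1}-{iv.end}({iv.strand})"
                 f"  score={cand.bit_score:.1f} bits  model={cand.hit.domain_tag}")
    names = {"A": "Acceptor", "D": "D arm   ", "C": "Anticodon", "V": "Variable",
             "T": "T arm   "}
    for key in ("A", "D", "C", "V", "T"):
        pairs, loop = arms[key]
        five = "".join(a for a, _ in pairs)
        three = "".join(b for _, b in pairs)
        bars = "".join("." if is_wobble(a, b)
                       else "|" if pairs_canonically(a, b)
                       else " " for a, b in pairs)
        lines.append(f"{names[key]:<10} 5' {five}")
        lines.append(f"{'':<10}    {bars}  [{len(pairs)} bp]")
        lines.append(f"{'':<10} 3' {three}" + (f"   loop {''.join(loop)}" if loop else ""))
    ac = f"({cand.anticodon})" if cand.anticodon else "undefined"
    lines.append(f"anticodon {ac}  fold {cand.fold_label}"
                 f"  AT-stem {cand.arm_annotation.at_stem_total} bp")
    if cand.discriminator is not None:
        lines.append(f"discriminator ({cand.discriminator[0]}) at {cand.discriminator[1] + 1}"
                     f"  CCA tail: {'yes' if cand.cca_tail else 'no'}")
    else:
        lines.append("discriminator undefined")
    if cand.intron is not None:
        lines.append(f"intron {cand.intron.start + 1}-{cand.intron.end}"
                     f" ({cand.intron.length} nt)")
    return "\n".join(lines) + "\n"


def _svg_circle(x, y, r, stroke, fill="none", width=1.5, dash=""):
    d = f' stroke-dasharray="{dash}"' if dash else ""
    return (f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{r}" stroke="{stroke}" '
            f'stroke-width="{width}" fill="{fill}"{d}/>')


def _svg_text(x, y, s, size=11):
    return (f'<text x="{x:.1f}" y="{y + 4:.1f}" text-anchor="middle" '
            f'font-family="monospace" font-size="{size}">{s}</text>')


def render_svg(cand: TRNACandidate) -> str:
    """Schematic cloverleaf SVG: one group per arm, circled motifs."""
    arms = _arm_strands(cand)
    cx, cy, step, r = 330.0, 300.0, 24.0, 9.0
    parts = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<svg xmlns="http://www.w3.org/2000/svg" width="660" height="640" '
             'viewBox="0 0 660 640">',
             f'<title>tRNA-Sec cloverleaf {cand.hit.interval.contig}</title>']

    # ladder directions per arm: acceptor up, D left, anticodon down,
    # V down-right diagonal, T right
    geom = {
        "A": ((0, -1), (-14, 0), (14, 0)),
        "D": ((-1, 0), (0, -14), (0, 14)),
        "C": ((0, 1), (-14, 0), (14, 0)),
        "V": ((0.8, 0.8), (-11, 11), (11, -11)),
        "T": ((1, 0), (0, -14), (0, 14)),
    }
    anchor = {
        "A": (cx, cy - 40), "D": (cx - 60, cy), "C": (cx, cy + 40),
        "V": (cx + 45, cy + 45), "T": (cx + 60, cy),
    }

    for key in ("A", "D", "C", "V", "T"):
        pairs, loop = arms[key]
        color = ARM_COLORS[key]
        (dx, dy), (ox5, oy5), (ox3, oy3) = geom[key]
        ax, ay = anchor[key]
        parts.append(f'<g id="arm-{key}" stroke="none" fill="{color}">')
        ends = []
        for k, (a, b) in enumerate(pairs):
            x, y = ax + dx * step * k, ay + dy * step * k
            x5, y5, x3, y3 = x + ox5, y + oy5, x + ox3, y + oy3
            faint = ' opacity="0.35"' if is_wobble(a, b) else ""
            parts.append(f'<g{faint}>')
            parts.append(f'<line x1="{x5:.1f}" y1="{y5:.1f}" x2="{x3:.1f}" '
                         f'y2="{y3:.1f}" stroke="{color}" stroke-width="2"/>')
            parts.append(_svg_circle(x5, y5, r, color, "#ffffff"))
            parts.append(_svg_text(x5, y5, a))
            parts.append(_svg_circle(x3, y3, r, color, "#ffffff"))
            parts.append(_svg_text(x3, y3, b))
            parts.append("</g>")
            ends = [x + dx * step, y + dy * step]
        # loop residues fan out past the last pair
        if loop and ends:
            import math
            n = len(loop)
            base_ang = math.atan2(dy, dx)
            for k, b in enumerate(loop):
                ang = base_ang + (k - (n - 1) / 2) * (math.pi / max(n, 3))
                lx = ends[0] + 26 * math.cos(ang)
                ly = ends[1] + 26 * math.sin(ang)
                parts.append(_svg_circle(lx, ly, r, color, "#ffffff"))
                parts.append(_svg_text(lx, ly, b))
        parts.append("</g>")

    # circled motifs: anticodon triplet under the C arm, discriminator top right
    ncirc = 0
    if cand.anticodon:
        pairs_c, _ = arms["C"]
        yy = anchor["C"][1] + step * len(pairs_c) + 40
        parts.append('<g id="anticodon-circle">')
        for k, b in enumerate(cand.anticodon):
            x = cx + (k - 1) * 26
            parts.append(_svg_circle(x, yy, r + 3.5, "#000000", "none", 1.8))
            parts.append(_svg_text(x, yy, b))
        parts.append("</g>")
        ncirc += 1
    if cand.discriminator is not None:
        pairs_a, _ = arms["A"]
        yy = anchor["A"][1] - step * len(pairs_a) - 20
        parts.append('<g id="discriminator-circle">')
        parts.append(_svg_circle(cx + 60, yy, r + 3.5, "#000000", "none", 1.8))
        parts.append(_svg_text(cx + 60, yy, cand.discriminator[0]))
        parts.append("</g>")
        ncirc += 1
    parts.append(f"<!-- circled motifs: {ncirc} -->")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_cloverleaf(cand: TRNACandidate) -> tuple[str, str]:
    """(text diagram, SVG document) for an annotated candidate."""
    return render_text(cand), render_svg(cand)
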