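"""Published-style report rendering: support tables, mating matrices,
spore tables, ellipse layers and partition-diff summaries.

Display rounding is centralized here (supports as printed integers when
integral, percentages to one decimal, micrometre values to one decimal, Q
to two); all upstream computation keeps full precision.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .concordance import IELCall, iel_resolution_table
from .mating import MatingMatrix, pair_table
from .morphometry import EllipseSpec, SporeSampleSummary
from .phylo_io import SupportRecord
from .ranking import PartitionDiff, SpeciesPartition

__all__ = [
    "format_support",
    "iel_cell",
    "ps_cell",
    "support_table_frame",
    "mating_table_frame",
    "spore_table_frame",
    "ellipse_frame",
    "ellipse_svg",
    "diff_summary",
    "partition_frame",
]


def format_support(v: Optional[float]) -> str:
    if v is None:
        return "-"
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def iel_cell(mpbp: Optional[float], bpp: Optional[float],
             is_iel: bool = True) -> str:
    """Render one per-locus cell: "IEL (MPBP/BPP)", or "(MPBP/BPP)" for a
    present-but-not-IEL clade, or "" when absent."""
    if mpbp is None and bpp is None:
        return ""
    body = f"({format_support(mpbp)}/{format_support(bpp)})"
    return f"IEL {body}" if is_iel else body


def ps_cell(rec: SupportRecord) -> str:
    """Concatenated-tree cell: "PS (MPBP/MLBS/BPP)"."""
    return (f"PS ({format_support(rec.mpbp)}/{format_support(rec.mlbs)}"
            f"/{format_support(rec.bpp)})")


def support_table_frame(calls: Iterable[IELCall],
                        loci: Sequence[str],
                        ps_supports: Optional[Mapping[str, SupportRecord]]
                        = None,
                        species_count: Optional[int] = None) -> pd.DataFrame:
    """Per-species x per-locus IEL table with a resolution row.

    Rows are species (call ``species`` labels, falling back to a clade
    digest), columns the loci plus optionally a concatenated-tree column,
    with a final "IEL resolution" row of "x/n" counts.
    """
    calls = list(calls)
    by_species: Dict[str, Dict[str, IELCall]] = {}
    for c in calls:
        label = c.species or ",".join(sorted(c.clade.clade_side)[:2]) + ",..."
        by_species.setdefault(label, {})[c.locus] = c
    n = species_count if species_count is not None else len(by_species)
    rows = []
    for label in sorted(by_species):
        row: Dict[str, str] = {"species": label}
        for locus in loci:
            c = by_species[label].get(locus)
            row[locus] = iel_cell(c.mpbp, c.bpp, c.is_iel) if c else ""
        if ps_supports is not None:
            rec = ps_supports.get(label)
            row["concatenated"] = ps_cell(rec) if rec else ""
        rows.append(row)
    resolution = iel_resolution_table(calls, n, loci)
    res_row = {"species": "IEL resolution"}
    res_row.update({locus: resolution[locus] for locus in loci})
    if ps_supports is not None:
        res_row["concatenated"] = ""
    rows.append(res_row)
    return pd.DataFrame(rows)


def mating_table_frame(matrix: MatingMatrix) -> pd.DataFrame:
    """Group-pair IF/IS/N matrix with one-decimal display rounding."""
    t = pair_table(matrix)
    t["if_pct"] = t["if_pct"].round(1)
    t["is_pct"] = t["is_pct"].round(1)
    return t


def spore_table_frame(summaries: Sequence[SporeSampleSummary]) -> pd.DataFrame:
    """Per-species "mean ± EL" table for length and Q, plus n."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.species):
        rows.append({
            "species": s.species,
            "length": f"{s.l_m:.2f} ± {s.el_l:.2f}",
            "q_value": f"{s.q_m:.2f} ± {s.el_q:.2f}",
            "n": s.n_spores,
        })
    return pd.DataFrame(rows)


def ellipse_frame(specs: Sequence[EllipseSpec]) -> pd.DataFrame:
    rows = [{"species": e.species, "cx": e.center[0], "cy": e.center[1],
             "rx": e.radii[0], "ry": e.radii[1]}
            for e in sorted(specs, key=lambda x: x.species)]
    return pd.DataFrame(rows)


def ellipse_svg(specs: Sequence[EllipseSpec], width: int = 640,
                height: int = 480, pad: float = 0.08) -> str:
    """Minimal standalone SVG of the per-species confidence ellipses in
    (mean length, mean Q) space."""
    specs = sorted(specs, key=lambda x: x.species)
    if not specs:
        return (f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
                f'height="{height}"/>')
    xs = [e.center[0] for e in specs]
    ys = [e.center[1] for e in specs]
    rx = max(max(e.radii[0] for e in specs), 1e-9)
    ry = max(max(e.radii[1] for e in specs), 1e-9)
    x0, x1 = min(xs) - 3 * rx, max(xs) + 3 * rx
    y0, y1 = min(ys) - 3 * ry, max(ys) + 3 * ry
    if x1 == x0:
        x1 = x0 + 1.0
    if y1 == y0:
        y1 = y0 + 1.0

    def sx(x):
        return pad * width + (x - x0) / (x1 - x0) * (1 - 2 * pad) * width

    def sy(y):  # SVG y grows downward
        return height - (pad * height
                         + (y - y0) / (y1 - y0) * (1 - 2 * pad) * height)

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}">']
    for e in specs:
        cx, cy = sx(e.center[0]), sy(e.center[1])
        erx = max(e.radii[0] / (x1 - x0) * (1 - 2 * pad) * width, 1.0)
        ery = max(e.radii[1] / (y1 - y0) * (1 - 2 * pad) * height, 1.0)
        parts.append(
            f'<ellipse cx="{cx:.1f}" cy="{cy:.1f}" rx="{erx:.1f}" '
            f'ry="{ery:.1f}" fill="none" stroke="black"/>')
        parts.append(f'<text x="{cx + erx + 2:.1f}" y="{cy:.1f}" '
                     f'font-size="10">{e.species}</text>')
    parts.append("</svg>")
    return "\n".join(parts)


def partition_frame(partition: SpeciesPartition) -> pd.DataFrame:
    """Two-column (taxon, species) export, sorted by taxon."""
    rows = sorted(partition.assignment.items())
    return pd.DataFrame(rows, columns=["taxon", "species"])


def diff_summary(diff: PartitionDiff, label_a: str = "A",
                 label_b: str = "B") -> Dict:
    """Machine-readable + prose summary of a partition diff."""
    n_a = diff.identical_pairs + sum(len(m[0]) for m in diff.mergers) \
        + len(diff.splits) + sum(len(c[0]) for c in diff.complex)
    n_b = diff.identical_pairs + len(diff.mergers) \
        + sum(len(s[1]) for s in diff.splits) \
        + sum(len(c[1]) for c in diff.complex)
    prose = (f"{n_a} {label_a} group(s) -> {n_b} {label_b} group(s); "
             f"{diff.identical_pairs} identical, {len(diff.mergers)} "
             f"merger(s), {len(diff.splits)} split(s)")
    if diff.complex:
        prose += f", {len(diff.complex)} complex overlap(s)"
    return {
        "groups_a": n_a,
        "groups_b": n_b,
        "identical_pairs": diff.identical_pairs,
        "mergers": [[list(src), dst] for src, dst in diff.mergers],
        "splits": [[src, list(dst)] for src, dst in diff.splits],
        "complex": [[list(a), list(b)] for a, b in diff.complex],
        "summary": prose,
    }
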