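"""Diagnostic plots: parallel-coordinates and scatter chromosome views."""

from __future__ import annotations

import logging
import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .genome_build import GenomeBuild
from .map_model import MapCollection

logger = logging.getLogger(__name__)

__all__ = ["plot_chromosome"]


def _lifted_points(
    build: GenomeBuild, collection: MapCollection, chromosome_id: str
) -> dict[tuple[str, str], list[tuple[int, float]]]:
    """(map, linkage group) -> [(chromosome position, map position)] for
    markers placed on the chromosome."""
    points: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for marker in collection:
        placement = build.placements.get(marker.scaffold_id)
        if placement is None or placement.chrom != chromosome_id:
            continue
        _, pos, _ = build.lift(marker.scaffold_id, marker.pos)
        points.setdefault(marker.track, []).append((pos, marker.map_pos))
    return points


def plot_chromosome(
    build: GenomeBuild,
    collection: MapCollection,
    chromosome_id: str,
    style: str = "scatter",
    out_path: str | os.PathLike = "chromosome.png",
) -> Path:
    """Render one reconstructed chromosome against its maps.

    ``style='parallel'`` draws the chromosome track with one track per
    linkage group and a connecting line per marker; ``style='scatter'``
    draws physical vs map position per map, with alternating shaded boxes
    at scaffold boundaries and the Pearson correlation annotated.
    """
    if style not in ("parallel", "scatter"):
        raise ValueError(f"unknown style {style!r}")
    out_path = Path(out_path)
    points = _lifted_points(build, collection, chromosome_id)
    chrom_len = build.chrom_lengths[chromosome_id]
    if not points:
        logger.warning("%s: no markers to plot", chromosome_id)
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.set_title(f"{chromosome_id} (no markers)")
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return out_path

    tracks = sorted(points)
    if style == "parallel":
        fig, ax = plt.subplots(figsize=(8, 1.2 + len(tracks)))
        ax.hlines(0, 0, chrom_len, lw=6, color="0.3")
        ax.text(chrom_len / 2, 0.25, chromosome_id, ha="center")
        for level, track in enumerate(tracks, start=1):
            pts = points[track]
            ys = [y for _, y in pts]
            lo, hi = min(ys), max(ys)
            span = (hi - lo) or 1.0
            y_level = -level
            ax.hlines(y_level, 0, chrom_len, lw=6, color="0.6")
            ax.text(chrom_len / 2, y_level + 0.25, "-".join(track), ha="center")
            for x, y in pts:
                ax.plot(
                    [x, (y - lo) / span * chrom_len],
                    [-0.05, y_level + 0.05],
                    lw=0.3,
                    color="steelblue",
                    alpha=0.6,
                )
        ax.set_xlim(0, chrom_len)
        ax.axis("off")
    else:
        fig, axes = plt.subplots(
            1, len(tracks), figsize=(4 * len(tracks), 3.5), squeeze=False
        )
        # scaffold boundary boxes from AGP component rows
        spans = [
            (row.object_beg - 1, row.object_end)
            for row in build.agp_rows
            if row.object == chromosome_id and row.component_type == "W"
        ]
        for ax, track in zip(axes[0], tracks):
            pts = points[track]
            xs = np.array([x for x, _ in pts], dtype=float)
            ys = np.array([y for _, y in pts], dtype=float)
            for i, (beg, end) in enumerate(spans):
                if i % 2 == 0:
                    ax.axvspan(beg, end, color="0.9", zorder=0)
            ax.plot(xs, ys, ".", ms=3, color="steelblue")
            if len(xs) > 1 and xs.std() > 0 and ys.std() > 0:
                rho = float(np.corrcoef(xs, ys)[0, 1])
            else:
                rho = 1.0
            ax.set_title("-".join(track))
            ax.text(
                0.05, 0.92, rf"$\rho$ = {rho:.3f}", transform=ax.transAxes, fontsize=9
            )
            ax.set_xlim(0, chrom_len)
            ax.set_xlabel("chromosome position (bp)")
            ax.set_ylabel("map position")
        fig.suptitle(chromosome_id)
        fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
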