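"""Unsupervised (template-free) analysis of read boundaries.

Every read is embedded in a conceptual length x length matrix at the cell
given by its alignment (start, end) pair.  Cells with many reads form
intensity "hubs" that mark abundant RNA species whose ends coincide with
processing sites; one-nucleotide-at-a-time exoribonucleolytic trimming shows
up as horizontal (5'->3') or vertical (3'->5') trails of occupied cells, and
positions where the exonuclease pauses appear as brighter dots on a trail.

The matrix is stored sparsely: for a ~13 kb reference a dense matrix would
hold ~1.8e8 cells while reads occupy only a tiny fraction of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ingest import ReadSet
from .refmodel import ProcessingSite

__all__ = [
    "IntensityMatrix",
    "Hub",
    "HubSet",
    "build_matrix",
    "detect_hubs",
    "normalize_intensities",
    "render_matrix",
    "overlay",
    "extract_trails",
]


@dataclass
class IntensityMatrix:
    """Sparse 2D histogram of reads keyed by (start, end) cell.

    Cells use the read convention: 0-based start, exclusive end, so
    start < end for every occupied cell.  ``read_ids`` optionally tracks the
    identifiers contributing to each cell (the CSV export contract).
    """

    cells: dict[tuple[int, int], int]
    dim: int
    read_ids: Optional[dict[tuple[int, int], list[str]]] = None

    def __post_init__(self) -> None:
        for (s, e), c in self.cells.items():
            if not (0 <= s < e <= self.dim):
                raise ValueError(f"invalid cell ({s}, {e}) for dim {self.dim}")
            if c < 1:
                raise ValueError(f"cell ({s}, {e}) has non-positive count {c}")

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def to_csv(self, path: str | Path) -> None:
        """CSV export: 1-based inclusive start/end, read count, read-ID list."""
        rows = []
        for (s, e) in sorted(self.cells):
            ids = ";".join(self.read_ids.get((s, e), [])) if self.read_ids else ""
            rows.append({"start": s + 1, "end": e, "read_count": self.cells[(s, e)], "read_ids": ids})
        pd.DataFrame(rows, columns=["start", "end", "read_count", "read_ids"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, dim: int) -> "IntensityMatrix":
        df = pd.read_csv(path, keep_default_na=False)
        cells: dict[tuple[int, int], int] = {}
        ids: dict[tuple[int, int], list[str]] = {}
        for row in df.itertuples(index=False):
            cell = (int(row.start) - 1, int(row.end))
            cells[cell] = int(row.read_count)
            if row.read_ids:
                ids[cell] = str(row.read_ids).split(";")
        return cls(cells=cells, dim=dim, read_ids=ids or None)


@dataclass
class Hub:
    """A merged cluster of nearby occupied cells."""

    apex: tuple[int, int]
    total_reads: int
    member_cells: list[tuple[int, int]]
    nearest_site: Optional[dict[str, tuple[str, int]]] = None  # axis -> (site name, distance)

    def __post_init__(self) -> None:
        if self.apex not in self.member_cells:
            raise ValueError("hub apex must be one of its member cells")


@dataclass
class HubSet:
    hubs: list[Hub] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hubs)

    def __iter__(self) -> Iterator[Hub]:
        return iter(self.hubs)

    def __getitem__(self, i: int) -> Hub:
        return self.hubs[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hubs:
            row = {
                "start": h.apex[0] + 1,
                "end": h.apex[1],
                "total_reads": h.total_reads,
                "n_cells": len(h.member_cells),
            }
            if h.nearest_site:
                for axis in ("start", "end"):
                    if axis in h.nearest_site:
                        name, dist = h.nearest_site[axis]
                        row[f"nearest_{axis}_site"] = name
                        row[f"nearest_{axis}_distance"] = dist
            rows.append(row)
        return pd.DataFrame(rows)


def build_matrix(rs: ReadSet, track_ids: bool = True) -> IntensityMatrix:
    """One increment per read at its (start, end) cell."""
    cells: dict[tuple[int, int], int] = {}
    ids: dict[tuple[int, int], list[str]] = {} if track_ids else None
    for r in rs.records:
        cell = (r.start, r.end)
        cells[cell] = cells.get(cell, 0) + 1
        if track_ids:
            ids.setdefault(cell, []).append(r.read_id)
    return IntensityMatrix(cells=cells, dim=rs.ref_length, read_ids=ids)


def _cluster_cells(
    cells: Sequence[tuple[int, int]], merge_radius: int
) -> list[list[tuple[int, int]]]:
    """Connected components under Chebyshev distance <= merge_radius."""
    occupied = set(cells)
    seen: set[tuple[int, int]] = set()
    components = []
    offsets = [
        (dx, dy)
        for dx in range(-merge_radius, merge_radius + 1)
        for dy in range(-merge_radius, merge_radius + 1)
        if (dx, dy) != (0, 0)
    ]
    for cell in sorted(occupied):
        if cell in seen:
            continue
        comp = []
        stack = [cell]
        seen.add(cell)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for dx, dy in offsets:
                nb = (cur[0] + dx, cur[1] + dy)
                if nb in occupied and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        components.append(sorted(comp))
    return components


def _annotate_nearest(
    apex: tuple[int, int], sites: Sequence[ProcessingSite]
) -> dict[str, tuple[str, int]]:
    out = {}
    start1, end1 = apex[0] + 1, apex[1]  # 1-based coordinates of the boundary pair
    for axis, pos in (("start", start1), ("end", end1)):
        name, dist = min(
            ((s.name, abs(s.position - pos)) for s in sites),
            key=lambda t: (t[1], t[0]),
        )
        out[axis] = (name, dist)
    return out


def detect_hubs(
    m: IntensityMatrix,
    min_reads: int = 10,
    merge_radius: int = 3,
    sites: Optional[Sequence[ProcessingSite]] = None,
) -> HubSet:
    """Cluster occupied cells and retain clusters with >= min_reads reads.

    Cells are merged by Chebyshev distance <= ``merge_radius`` (the boundary
    coordinates of minor species are estimates, so nearby cells belong to the
    same species).  The apex is the modal cell, ties resolved to the smallest
    (start, end) lexicographically.  Hubs are sorted by total reads, then
    apex.  When ``sites`` is given each hub is annotated with the nearest
    processing site on each axis and its distance (no cutoff is imposed).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    hubs = []
    for comp in _cluster_cells(list(m.cells), merge_radius):
        total = sum(m.cells[c] for c in comp)
        if total < min_reads:
            continue
        top = max(m.cells[c] for c in comp)
        apex = min(c for c in comp if m.cells[c] == top)
        hubs.append(
            Hub(
                apex=apex,
                total_reads=total,
                member_cells=comp,
                nearest_site=_annotate_nearest(apex, sites) if sites else None,
            )
        )
    hubs.sort(key=lambda h: (-h.total_reads, h.apex))
    return HubSet(hubs)


def normalize_intensities(
    m: IntensityMatrix, contrast_pct: float = 2.0
) -> dict[tuple[int, int], float]:
    """Min-max normalise occupied-cell counts with percentile contrast clipping.

    Counts are scaled to [0, 1]; with ``contrast_pct`` = c > 0 the values are
    then clipped at the c-th and (100-c)-th percentiles of the occupied-cell
    values and rescaled, saturating the brightest tail so faint trails remain
    visible.  c = 0 reduces to plain min-max.  A constant (or empty/all-zero)
    matrix maps to all zeros.
    """
    if not (0 <= contrast_pct < 50):
        raise ValueError("contrast_pct must lie in [0, 50)")
    if not m.cells:
        warnings.warn("empty intensity matrix: nothing to render", stacklevel=2)
        return {}
    cells = sorted(m.cells)
    counts = np.array([m.cells[c] for c in cells], dtype=np.float64)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return {c: 0.0 for c in cells}
    vals = (counts - lo) / (hi - lo)
    if contrast_pct > 0:
        plo, phi = np.percentile(vals, [contrast_pct, 100 - contrast_pct])
        if phi > plo:
            vals = np.clip((vals - plo) / (phi - plo), 0.0, 1.0)
    return dict(zip(cells, vals))


def render_matrix(
    m: IntensityMatrix, contrast_pct: float = 2.0, bins: int = 1000
) -> np.ma.MaskedArray:
    """Normalised image array (end on rows, start on columns), empty cells masked.

    The matrix is binned down to at most ``bins`` x ``bins`` pixels taking the
    maximum normalised value per pixel.
    """
    vals = normalize_intensities(m, contrast_pct)
    n = min(bins, m.dim)
    img = np.full((n, n), np.nan)
    scale = n / m.dim
    for (s, e), v in vals.items():
        x = min(int(s * scale), n - 1)
        y = min(int((e - 1) * scale), n - 1)
        if np.isnan(img[y, x]) or v > img[y, x]:
            img[y, x] = v
    return np.ma.masked_invalid(img)


_COLORS = {
    "blue": (0.12, 0.35, 0.85),
    "red": (0.85, 0.15, 0.15),
    "yellow": (0.90, 0.80, 0.10),
    "green": (0.10, 0.65, 0.25),
    "purple": (0.55, 0.20, 0.70),
    "orange": (0.95, 0.55, 0.10),
}


def overlay(
    matrices: Sequence[tuple[IntensityMatrix, str]],
    contrast_pct: float = 2.0,
    bins: int = 1000,
    labels: Optional[Sequence[str]] = None,
    path: Optional[str | Path] = None,
):
    """Composite several conditions' matrices in different colours.

    Each matrix is rendered independently (min-max + contrast clipping) and
    additively blended into an RGB image; a region occupied by only one
    condition keeps that condition's pure colour.  All matrices must share
    the reference dimension.
    """
    from matplotlib.figure import Figure
    from matplotlib.patches import Patch

    if not matrices:
        raise ValueError("no matrices to overlay")
    dims = {m.dim for m, _ in matrices}
    if len(dims) != 1:
        raise ValueError(f"matrices have mismatching dimensions: {sorted(dims)}")
    dim = dims.pop()
    n = min(bins, dim)
    rgb = np.zeros((n, n, 3))
    legend = []
    for i, (m, color) in enumerate(matrices):
        c = np.array(_COLORS.get(color, _COLORS["blue"]) if isinstance(color, str) else color)
        img = render_matrix(m, contrast_pct, bins=n).filled(0.0)
        rgb += img[:, :, None] * c[None, None, :]
        legend.append(
            Patch(color=c, label=labels[i] if labels else str(color))
        )
    rgb = np.clip(rgb, 0, 1)
    fig = Figure(figsize=(7, 7))
    ax = fig.add_subplot(111)
    ax.imshow(rgb, origin="lower", extent=(0, dim, 0, dim), interpolation="nearest")
    ax.set_xlabel("alignment start (nt)")
    ax.set_ylabel("alignment end (nt)")
    ax.legend(handles=legend, loc="lower right")
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def extract_trails(
    m: IntensityMatrix,
    axis: str,
    anchor: int,
    span: int,
    prominence: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Extract a 1D exonucleolytic trail profile and its pause positions.

    ``axis='fixed_end'`` walks the horizontal line of cells sharing the end
    coordinate ``anchor`` (5'->3' trimming of the start), over starts in
    ``[anchor - span, anchor)``; ``axis='fixed_start'`` walks the vertical
    line of cells sharing start ``anchor`` over ends in
    ``(anchor, anchor + span]``.  Pauses are interior local maxima of the
    profile with prominence above ``prominence`` (default: half the profile
    maximum).  Returns (positions, counts, pause positions).
    """
    if axis not in {"fixed_end", "fixed_start"}:
        raise ValueError("axis must be 'fixed_end' or 'fixed_start'")
    if not (0 <= anchor <= m.dim):
        raise ValueError("anchor outside the reference")
    if axis == "fixed_end":
        positions = np.arange(max(0, anchor - span), anchor)
        counts = np.array([m.cells.get((int(p), anchor), 0) for p in positions], dtype=np.int64)
    else:
        positions = np.arange(anchor + 1, min(m.dim, anchor + span) + 1)
        counts = np.array([m.cells.get((anchor, int(p)), 0) for p in positions], dtype=np.int64)
    if counts.size == 0 or counts.max() == 0:
        return positions, counts, []
    if prominence is None:
        prominence = counts.max() / 2.0
    peaks, _ = find_peaks(counts, prominence=prominence)
    return positions, counts, [int(positions[p]) for p in peaks]
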