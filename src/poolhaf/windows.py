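"""Haplotype window construction.

Non-overlapping genomic windows are anchored on genes, chip markers, or a
fixed contig grid. Gene/marker anchors are grown into their flanking
intergenic regions: for a gap of g bp between two consecutive anchors, 10%
of g is left unannotated and the remainder is split evenly, so each side
gains floor(0.45 * g) bp. A window therefore captures nearby SNPs whose
reads would otherwise be lost to the frequency estimate.

Worked example: genes at 200-560 and 800-850 leave a 240 bp intergenic
region; 10% (24 bp) stays unannotated, each gene gains 108 bp, and the new
boundaries are 668 and 692.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ChromosomeTable, GeneAnnotation, MarkerRecord

__all__ = [
    "AnchorInterval",
    "HaplotypeWindow",
    "anchors_from_genes",
    "anchors_from_markers",
    "extend_anchors",
    "contig_windows",
    "filter_windows",
    "assign_snps",
]


@dataclass(frozen=True, slots=True)
class AnchorInterval:
    """An unextended anchor: a gene span, a 1-bp marker, or a grid cell."""

    anchor_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    anchor_type: str  # gene|marker|contig

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"anchor {self.anchor_id}: start > end")
        if self.start < 1:
            raise ValueError(f"anchor {self.anchor_id}: start must be >= 1")


@dataclass(frozen=True, slots=True)
class HaplotypeWindow:
    """An extended window; ``core_*`` is the unextended anchor span."""

    anchor_id: str
    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int
    anchor_type: str

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start <= self.core_end <= self.end):
            raise ValueError(
                f"window {self.anchor_id}: must contain its core anchor span"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def anchors_from_genes(genes: Iterable[GeneAnnotation]) -> list[AnchorInterval]:
    return [AnchorInterval(g.gene_id, g.chrom, g.start, g.end, "gene")
            for g in genes]


def anchors_from_markers(markers: Iterable[MarkerRecord]) -> list[AnchorInterval]:
    # a marker is a 1-bp anchor: start == end == pos_bp
    return [AnchorInterval(m.marker_id, m.chrom, m.pos_bp, m.pos_bp, "marker")
            for m in markers]


def extend_anchors(
    anchors: Sequence[AnchorInterval],
    chrom_table: ChromosomeTable,
    extension_fraction: float = 0.45,
    gap_fraction: float = 0.10,
) -> list[HaplotypeWindow]:
    """Grow anchors into their intergenic flanks.

    For consecutive anchors with gap ``g = next.start - prev.end > 0`` each
    facing flank is extended by ``floor(extension_fraction * g)``;
    ``gap_fraction`` of the gap stays unannotated between the two windows.
    Anchors that touch or overlap receive no extension in that direction.
    Chromosome termini are treated as neighbour edges: the flank toward the
    chromosome boundary is the distance to position 1 (or to the chromosome
    length) and is extended with the same rule.

    Input must be sorted by start within each chromosome. The extension step
    never introduces overlap between windows; overlap can only persist where
    the input anchors themselves overlap.
    """
    if not (0.0 <= extension_fraction <= 1.0 and 0.0 <= gap_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if 2 * extension_fraction + gap_fraction > 1.0 + 1e-9:
        raise ValueError("2*extension_fraction + gap_fraction must not exceed 1")

    by_chrom: dict[str, list[AnchorInterval]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)

    out: list[HaplotypeWindow] = []
    for chrom, group in by_chrom.items():
        if chrom not in chrom_table:
            raise ValueError(f"anchor chromosome {chrom!r} not in chromosome table")
        length = chrom_table.length(chrom)
        starts = [a.start for a in group]
        if starts != sorted(starts):
            raise ValueError(f"anchors on {chrom} are not sorted by start")
        for a in group:
            if a.end > length:
                raise ValueError(
                    f"anchor {a.anchor_id} exceeds chromosome {chrom} length"
                )
        n = len(group)
        for i, a in enumerate(group):
            # left flank
            if i == 0:
                gap_l = a.start - 1
                ext_l = int(np.floor(extension_fraction * gap_l))
            else:
                gap_l = a.start - group[i - 1].end
                ext_l = _flank_extension(gap_l, extension_fraction, yielding=True)
            # right flank
            if i == n - 1:
                gap_r = length - a.end
                ext_r = int(np.floor(extension_fraction * gap_r))
            else:
                gap_r = group[i + 1].start - a.end
                ext_r = _flank_extension(gap_r, extension_fraction, yielding=False)
            start = max(1, a.start - ext_l)
            end = min(length, a.end + ext_r)
            out.append(HaplotypeWindow(a.anchor_id, chrom, start, end,
                                       a.start, a.end, a.anchor_type))
    out.sort(key=lambda w: (w.chrom, w.start, w.end))
    return out


def _flank_extension(gap: int, fraction: float, yielding: bool) -> int:
    """Extension into an inter-anchor gap; 0 for touching/overlapping anchors.

    The downstream window's left flank is the ``yielding`` side: in the
    degenerate fraction=0.5 case it backs off one base so the two extensions
    never meet or cross.
    """
    if gap <= 0:
        return 0
    ext = int(np.floor(fraction * gap))
    if yielding and 2 * ext >= gap:
        ext = max(0, gap - ext - 1)
    return ext


def contig_windows(chrom_table: ChromosomeTable,
                   window_size: int = 100_000) -> list[HaplotypeWindow]:
    """Fixed tiling of each chromosome into ``window_size`` bp windows.

    The final window is truncated at the chromosome end. Window ids are
    ``chrom:index`` with a 1-based index.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    out = []
    for chrom, length in chrom_table.items():
        n = int(np.ceil(length / window_size))
        for i in range(n):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            out.append(HaplotypeWindow(f"{chrom}:{i + 1}", chrom, start, end,
                                       start, end, "contig"))
    return out


def filter_windows(windows: Iterable[HaplotypeWindow], min_size: int = 500,
                   max_size: int = 1_000_000) -> list[HaplotypeWindow]:
    """Retain windows whose span lies in [min_size, max_size] (inclusive)."""
    return [w for w in windows if min_size <= w.span <= max_size]


def assign_snps(
    sites: Sequence,
    windows: Sequence[HaplotypeWindow],
) -> tuple[dict[HaplotypeWindow, list], list]:
    """Map each site to the window containing it (closed interval).

    ``sites`` may be any records with ``chrom`` and ``pos`` attributes,
    sorted by (chrom, pos). Windows must be sorted and pairwise
    non-overlapping per chromosome; a site on a window boundary is included.
    Returns (window -> member sites, unassigned sites).
    """
    win_by_chrom: dict[str, list[HaplotypeWindow]] = {}
    for w in windows:
        win_by_chrom.setdefault(w.chrom, []).append(w)
    arrays = {}
    for chrom, group in win_by_chrom.items():
        starts = np.array([w.start for w in group])
        ends = np.array([w.end for w in group])
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"windows on {chrom} are not sorted by start")
        if np.any(ends[:-1] >= starts[1:]):
            raise ValueError(f"windows on {chrom} overlap")
        arrays[chrom] = (starts, ends, group)

    assigned: dict[HaplotypeWindow, list] = {w: [] for w in windows}
    unassigned: list = []
    sites_by_chrom: dict[str, list] = {}
    for s in sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in sites_by_chrom.items():
        if chrom not in arrays:
            unassigned.extend(group)
            continue
        starts, ends, wins = arrays[chrom]
        pos = np.array([s.pos for s in group])
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        for s, i, ok in zip(group, idx, inside):
            if ok:
                assigned[wins[i]].append(s)
            else:
                unassigned.append(s)
    return assigned, unassigned
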