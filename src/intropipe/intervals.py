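"""Interval algebra shared by the detectors.

Coverage is counted as *distinct supporting reads* overlapping a bin, not
per-base depth: the detection procedure intersects read-name sets between
references, so every bin carries the set of read names that touch it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import AlignmentRecord, GeneFeature, GenomicInterval

__all__ = [
    "CoverageBin",
    "MergedBlock",
    "bin_coverage",
    "merge_blocks",
    "combined_length",
    "intersect_genes",
]


@dataclass
class CoverageBin:
    """A fixed-width bin carrying the names of reads overlapping it."""

    seqid: str
    start: int
    end: int
    read_names: set[str] = field(default_factory=set)

    @property
    def count(self) -> int:
        return len(self.read_names)


@dataclass
class MergedBlock:
    """Maximal run of adjacent qualifying bins, with the union read set."""

    seqid: str
    start: int
    end: int
    read_names: set[str]
    n_bins: int

    @property
    def count(self) -> int:
        return len(self.read_names)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mean_coverage(self) -> float:
        return len(self.read_names) / self.n_bins if self.n_bins else 0.0

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.start, self.end, self.read_names)


def bin_coverage(
    records: Iterable[AlignmentRecord],
    bin_size: int = 1000,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[CoverageBin]:
    """Tile each scaffold with ``bin_size`` bins and collect overlapping reads.

    A read belongs to every bin its target interval overlaps by >= 1 bp. Bins
    tile from 0; when ``scaffold_lengths`` is given bins extend to the
    scaffold end (final bin possibly short), otherwise to the last covered
    bin. Bins with zero reads are included within the tiled range.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    per_bin: dict[str, dict[int, set[str]]] = defaultdict(lambda: defaultdict(set))
    max_end: dict[str, int] = defaultdict(int)
    for rec in records:
        first = rec.target_start // bin_size
        last = (rec.target_end - 1) // bin_size
        for b in range(first, last + 1):
            per_bin[rec.target][b].add(rec.read_id)
        max_end[rec.target] = max(max_end[rec.target], rec.target_end)
    bins: list[CoverageBin] = []
    seqids = (
        sorted(scaffold_lengths) if scaffold_lengths is not None else sorted(per_bin)
    )
    for seqid in seqids:
        if scaffold_lengths is not None:
            length = scaffold_lengths[seqid]
        else:
            length = max_end[seqid]
        n_bins = (length + bin_size - 1) // bin_size
        for b in range(n_bins):
            start = b * bin_size
            end = min(start + bin_size, length)
            bins.append(CoverageBin(seqid, start, end, per_bin[seqid].get(b, set())))
    return bins


def merge_blocks(bins: Sequence[CoverageBin], min_count: int = 30) -> list[MergedBlock]:
    """Merge maximal runs of adjacent bins with ``count >= min_count``.

    Bins must be sorted by (seqid, start), as :func:`bin_coverage` emits them.
    Adjacency means abutting coordinates on the same seqid.
    """
    blocks: list[MergedBlock] = []
    current: MergedBlock | None = None
    for b in bins:
        if b.count >= min_count:
            if (
                current is not None
                and current.seqid == b.seqid
                and current.end == b.start
            ):
                current.end = b.end
                current.read_names |= b.read_names
                current.n_bins += 1
            else:
                if current is not None:
                    blocks.append(current)
                current = MergedBlock(b.seqid, b.start, b.end, set(b.read_names), 1)
        else:
            if current is not None:
                blocks.append(current)
                current = None
    if current is not None:
        blocks.append(current)
    return blocks


def combined_length(
    blocks: Iterable[MergedBlock | GenomicInterval], group_by: str = "seqid"
) -> pd.DataFrame:
    """Per-seqid total block length, sorted descending (then by name)."""
    totals: dict[str, int] = defaultdict(int)
    for b in blocks:
        totals[getattr(b, group_by)] += b.end - b.start
    table = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=[group_by, "total_bp"],
    )
    return table


def intersect_genes(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneFeature]
) -> list[tuple[GenomicInterval, str]]:
    """All (region, gene_id) pairs overlapping by >= 1 bp (bedtools-style).

    A gene overlapping two regions is reported once per region. Inputs must
    be sorted by (seqid, start); a linear sweep per seqid is used.
    """
    by_seq: dict[str, list[GeneFeature]] = defaultdict(list)
    for g in genes:
        by_seq[g.seqid].append(g)
    for gl in by_seq.values():
        gl.sort(key=lambda g: g.start)
    pairs: list[tuple[GenomicInterval, str]] = []
    for region in sorted(regions, key=lambda r: (r.seqid, r.start)):
        for g in by_seq.get(region.seqid, ()):
            if g.start >= region.end:
                break
            if g.end > region.start:
                pairs.append((region, g.gene_id))
    return pairs


def unique_genes(pairs: Iterable[tuple[GenomicInterval, str]]) -> list[str]:
    """Deduplicated gene-id list, preserving first-seen order."""
    seen: dict[str, None] = {}
    for _, gid in pairs:
        seen.setdefault(gid, None)
    return list(seen)
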