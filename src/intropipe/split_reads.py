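"""Detect putatively introgressed regions from split long-read alignments.

A read is evidence of introgression when it aligns fully to the focal
assembly but splits, without overlap on the read, between the two donor
references: the split point marks an ancestry switch, expected at the
boundary of an introgressed block. The same signal can also arise from
incomplete lineage sorting or mapping artifacts; this module only reports
the intervals, it does not adjudicate their cause.

The procedure: trim alignments near scaffold ends (false-positive guard),
classify split reads, bin the focal coverage of those reads over 1 kb
intervals, merge contiguous covered bins, and report intervals with enough
supporting reads outside the unplaced-scaffold pool (LG0), pairing each
focal interval with the donor intervals sharing the most read names.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .intervals import MergedBlock, bin_coverage, merge_blocks
from .io_formats import AlignmentRecord

__all__ = [
    "SplitReadCall",
    "trim_scaffold_ends",
    "classify_split_reads",
    "call_intervals",
    "rank_groups",
]


@dataclass
class SplitReadCall:
    """A focal interval supported by split reads, with its donor partners."""

    focal_interval: MergedBlock
    partner_intervals: dict[str, tuple[MergedBlock, int]] = field(default_factory=dict)

    @property
    def n_support_reads(self) -> int:
        return self.focal_interval.count

    @property
    def linkage_group(self) -> str:
        return self.focal_interval.seqid


def trim_scaffold_ends(
    records: list[AlignmentRecord],
    scaffold_lengths: dict[str, int],
    trim_bp: int = 10_000,
) -> list[AlignmentRecord]:
    """Drop records not fully inside [trim_bp, scaffold_length - trim_bp).

    Scaffolds shorter than 2 x trim_bp contribute nothing. Records naming a
    scaffold absent from ``scaffold_lengths`` are an error.
    """
    kept = []
    for rec in records:
        if rec.target not in scaffold_lengths:
            raise ValueError(f"record names unknown scaffold {rec.target!r}")
        hi = scaffold_lengths[rec.target] - trim_bp
        if rec.target_start >= trim_bp and rec.target_end <= hi:
            kept.append(rec)
    return kept


def classify_split_reads(
    focal_recs: list[AlignmentRecord],
    donorA_recs: list[AlignmentRecord],
    donorB_recs: list[AlignmentRecord],
    min_focal_fraction: float = 0.95,
    min_donor_len: int = 200,
) -> set[str]:
    """Reads fully aligned to the focal assembly but split between donors.

    A read qualifies when (i) its focal records cover >= ``min_focal_fraction``
    of its length, (ii) it has at least one donorA and one donorB record of
    aligned length >= ``min_donor_len``, and (iii) no base of the read aligns
    to both donors (the read-coordinate spans of the two donors' records are
    pairwise disjoint). Output is independent of record order.
    """
    focal_cov: dict[str, list[tuple[int, int]]] = defaultdict(list)
    read_len: dict[str, int] = {}
    for rec in focal_recs:
        focal_cov[rec.read_id].append((rec.read_start, rec.read_end))
        read_len[rec.read_id] = rec.read_len
    donor_spans: dict[str, dict[str, list[tuple[int, int]]]] = {
        "donorA": defaultdict(list),
        "donorB": defaultdict(list),
    }
    for recs, label in ((donorA_recs, "donorA"), (donorB_recs, "donorB")):
        for rec in recs:
            if rec.read_end - rec.read_start >= min_donor_len:
                donor_spans[label][rec.read_id].append((rec.read_start, rec.read_end))
    out: set[str] = set()
    for read_id, spans in focal_cov.items():
        covered = _union_length(spans)
        if covered < min_focal_fraction * read_len[read_id]:
            continue
        a_spans = donor_spans["donorA"].get(read_id)
        b_spans = donor_spans["donorB"].get(read_id)
        if not a_spans or not b_spans:
            continue
        if any(
            a0 < b1 and b0 < a1 for a0, a1 in a_spans for b0, b1 in b_spans
        ):
            continue
        out.add(read_id)
    return out


def _union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(spans):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def call_intervals(
    split_reads: set[str],
    focal_recs: list[AlignmentRecord],
    donorA_recs: list[AlignmentRecord] | None = None,
    donorB_recs: list[AlignmentRecord] | None = None,
    bin_size: int = 1000,
    min_count: int = 30,
    min_reads_per_interval: int = 10,
    exclude: set[str] = frozenset({"LG0"}),
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[list[SplitReadCall], list[SplitReadCall]]:
    """(candidates, reported): merged focal intervals covered by split reads.

    Candidates are maximal runs of adjacent ``bin_size`` bins holding at
    least one split read; those whose union read set reaches
    ``min_reads_per_interval`` and whose seqid is not excluded form the
    reported list. ``min_count`` additionally marks blocks meeting the
    high-coverage merge threshold (``MergedBlock.count >= min_count``); it
    does not gate candidacy. When donor records are given, each call is
    paired with the donor interval sharing the highest read-name
    intersection (ties broken by coordinate, first wins).
    """
    focal_split = [r for r in focal_recs if r.read_id in split_reads]
    bins = bin_coverage(focal_split, bin_size, scaffold_lengths)
    candidates_blocks = merge_blocks(bins, min_count=1)
    donor_blocks: dict[str, list[MergedBlock]] = {}
    for label, recs in (("donorA", donorA_recs), ("donorB", donorB_recs)):
        if recs is not None:
            d_split = [r for r in recs if r.read_id in split_reads]
            donor_blocks[label] = merge_blocks(
                bin_coverage(d_split, bin_size), min_count=1
            )
    candidates = []
    for blk in candidates_blocks:
        call = SplitReadCall(blk)
        for label, blocks in donor_blocks.items():
            best = None
            best_n = 0
            for db in sorted(blocks, key=lambda b: (b.seqid, b.start)):
                n = len(blk.read_names & db.read_names)
                if n > best_n:
                    best, best_n = db, n
            if best is not None:
                call.partner_intervals[label] = (best, best_n)
        candidates.append(call)
    reported = [
        c
        for c in candidates
        if c.n_support_reads >= min_reads_per_interval
        and c.linkage_group not in exclude
    ]
    return candidates, reported


def rank_groups(calls: list[SplitReadCall]) -> pd.DataFrame:
    """Rank linkage groups by interval count, then combined length.

    Columns: lg, n_intervals, n_reads (distinct supporting reads), and
    combined_bp; sorted by n_intervals desc, combined_bp desc, lg name.
    """
    per_lg: dict[str, dict] = defaultdict(
        lambda: {"n_intervals": 0, "reads": set(), "combined_bp": 0}
    )
    for c in calls:
        d = per_lg[c.linkage_group]
        d["n_intervals"] += 1
        d["reads"] |= c.focal_interval.read_names
        d["combined_bp"] += c.focal_interval.length
    rows = [
        (lg, d["n_intervals"], len(d["reads"]), d["combined_bp"])
        for lg, d in per_lg.items()
    ]
    rows.sort(key=lambda r: (-r[1], -r[3], r[0]))
    return pd.DataFrame(rows, columns=["lg", "n_intervals", "n_reads", "combined_bp"])
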