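"""Anchor assembly scaffolds into linkage groups from a genetic map.

Array probes with known genetic positions (LG, cM) are aligned to the
scaffolds; each scaffold inherits the LG of its probes. Scaffolds carrying
probes from two or more LGs in disjoint bp blocks are chimeric joins and are
broken between the most distal probes of adjacent blocks. Within an LG,
scaffolds are ordered by median probe cM and oriented by the sign of the
Spearman rank correlation between bp and cM, then concatenated with 100-N
gaps. A Marey table (physical vs genetic position on the built LG) provides
the monotonicity QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_formats import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldAssignment",
    "best_hits",
    "assign_scaffolds",
    "break_chimeras",
    "order_and_orient",
    "build_lg_sequences",
    "marey_table",
]

UNPLACED = "LG0"
GAP = 100


@dataclass
class ScaffoldAssignment:
    """A scaffold's LG assignment with its per-LG probe support."""

    scaffold: str
    lg: str  # LG0 when no probes mapped
    lg_counts: dict[str, int] = field(default_factory=dict)
    n_probes: int = 0

    @property
    def is_chimera_candidate(self) -> bool:
        return len(self.lg_counts) > 1


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per probe: highest score; cross-scaffold ties dropped."""
    hits = hits.sort_values(["probe_id", "score"], ascending=[True, False])
    dropped = 0
    keep_rows = []
    for pid, sub in hits.groupby("probe_id", sort=False):
        top = sub[sub["score"] == sub["score"].iloc[0]]
        if top["scaffold"].nunique() > 1:
            dropped += 1
            continue
        keep_rows.append(top.iloc[0])
    if dropped:
        logger.info("dropped %d probes with tied multi-scaffold best hits", dropped)
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def _merged(hits: pd.DataFrame, gmap: pd.DataFrame) -> pd.DataFrame:
    return hits.merge(gmap, on="probe_id", how="inner")


def assign_scaffolds(
    hits: pd.DataFrame,
    gmap: pd.DataFrame,
    scaffolds: SequenceSet | list[str] | None = None,
) -> list[ScaffoldAssignment]:
    """Assign each scaffold the LG of its probes; flag multi-LG scaffolds.

    ``hits`` must already be deduplicated to one best hit per probe.
    Scaffolds listed in ``scaffolds`` but carrying no probe go to LG0.
    """
    m = _merged(hits, gmap)
    out: list[ScaffoldAssignment] = []
    seen = set()
    for scaffold, sub in m.groupby("scaffold", sort=True):
        counts = sub["lg"].value_counts().to_dict()
        major = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out.append(ScaffoldAssignment(scaffold, major, counts, len(sub)))
        seen.add(scaffold)
    if scaffolds is not None:
        names = scaffolds.names() if isinstance(scaffolds, SequenceSet) else scaffolds
        for name in names:
            if name not in seen:
                out.append(ScaffoldAssignment(name, UNPLACED, {}, 0))
    return out


def break_chimeras(
    assignments: list[ScaffoldAssignment],
    hits: pd.DataFrame,
    gmap: pd.DataFrame,
    scaffold_lengths: dict[str, int],
) -> tuple[pd.DataFrame, list[dict], pd.DataFrame]:
    """Cut chimera-candidate scaffolds between their per-LG probe blocks.

    For each flagged scaffold the probes of each LG must occupy disjoint bp
    ranges; the cut between adjacent blocks is the midpoint between the last
    probe of one block and the first probe of the next (the most distally
    mapped probes). Pieces are renamed ``scaffold.1``, ``scaffold.2``, ... in
    bp order and probes are re-addressed onto them. Scaffolds whose LG
    blocks overlap are left unbroken and reported as unresolvable.

    Returns (pieces, break_records, new_hits): ``pieces`` maps every output
    scaffold to its source interval; ``new_hits`` is the hit table on the
    output scaffolds.
    """
    m = _merged(hits, gmap)
    pieces_rows: list[dict] = []
    breaks: list[dict] = []
    new_hit_rows: list[pd.DataFrame] = []
    flagged = {a.scaffold for a in assignments if a.is_chimera_candidate}
    for scaffold, sub in m.groupby("scaffold", sort=True):
        length = scaffold_lengths[scaffold]
        if scaffold not in flagged:
            pieces_rows.append(
                {"piece": scaffold, "source": scaffold, "start": 0, "end": length}
            )
            new_hit_rows.append(sub)
            continue
        ranges = (
            sub.groupby("lg")["bp"]
            .agg(["min", "max"])
            .sort_values("min")
            .reset_index()
        )
        overlapping = any(
            ranges.loc[i + 1, "min"] <= ranges.loc[i, "max"]
            for i in range(len(ranges) - 1)
        )
        if overlapping:
            logger.warning(
                "scaffold %s: overlapping LG probe blocks; left unbroken", scaffold
            )
            breaks.append(
                {"scaffold": scaffold, "resolved": False, "cuts": []}
            )
            pieces_rows.append(
                {"piece": scaffold, "source": scaffold, "start": 0, "end": length}
            )
            new_hit_rows.append(sub)
            continue
        cuts = [
            int((ranges.loc[i, "max"] + ranges.loc[i + 1, "min"]) // 2)
            for i in range(len(ranges) - 1)
        ]
        bounds = [0] + cuts + [length]
        breaks.append({"scaffold": scaffold, "resolved": True, "cuts": cuts})
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            piece = f"{scaffold}.{i + 1}"
            pieces_rows.append(
                {"piece": piece, "source": scaffold, "start": start, "end": end}
            )
            in_piece = sub[(sub["bp"] >= start) & (sub["bp"] < end)].copy()
            in_piece["scaffold"] = piece
            in_piece["bp"] = in_piece["bp"] - start
            new_hit_rows.append(in_piece)
    # scaffolds with no probes at all pass through untouched
    for a in assignments:
        if a.n_probes == 0 and a.scaffold in scaffold_lengths:
            pieces_rows.append(
                {
                    "piece": a.scaffold,
                    "source": a.scaffold,
                    "start": 0,
                    "end": scaffold_lengths[a.scaffold],
                }
            )
    pieces = pd.DataFrame(pieces_rows)
    new_hits = (
        pd.concat(new_hit_rows, ignore_index=True)
        if new_hit_rows
        else m.iloc[0:0]
    )
    return pieces, breaks, new_hits


def order_and_orient(merged_hits: pd.DataFrame) -> pd.DataFrame:
    """Order scaffolds within each LG by median probe cM and orient them.

    Orientation is '+' when the Spearman rank correlation between bp and cM
    is >= 0, '-' when negative; scaffolds with fewer than two distinct probe
    positions are oriented '+' and flagged orientation-unknown. Ties in
    median cM break by scaffold name. Columns: lg, scaffold, orientation,
    orientation_known, median_cm, n_probes.
    """
    rows = []
    for (lg, scaffold), sub in merged_hits.groupby(["lg", "scaffold"], sort=True):
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        known = len(np.unique(bp)) >= 2 and len(np.unique(cm)) >= 2
        if known:
            rho = spearmanr(bp, cm).statistic
            if np.isnan(rho):
                known, orient = False, "+"
            else:
                orient = "+" if rho >= 0 else "-"
        else:
            orient = "+"
        rows.append(
            {
                "lg": lg,
                "scaffold": scaffold,
                "orientation": orient,
                "orientation_known": known,
                "median_cm": float(np.median(cm)),
                "n_probes": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["lg", "median_cm", "scaffold"], ignore_index=True
    )


def build_lg_sequences(
    order: pd.DataFrame, scaffolds: SequenceSet, gap: int = GAP
) -> tuple[SequenceSet, pd.DataFrame]:
    """Concatenate ordered, oriented scaffolds into LG sequences (AGP 2.1).

    '-' scaffolds are reverse-complemented; neighbours are separated by
    exactly ``gap`` N characters. Emitted LG length is the sum of scaffold
    lengths plus gap * (n - 1). AGP rows use W components and U gap rows.
    """
    lg_seqs: dict[str, str] = {}
    agp_rows = []
    for lg, sub in order.groupby("lg", sort=True):
        parts = []
        pos = 0
        part_no = 0
        for row in sub.itertuples():
            if row.scaffold not in scaffolds:
                raise KeyError(f"scaffold {row.scaffold!r} absent from sequence set")
            seq = scaffolds[row.scaffold]
            if row.orientation == "-":
                seq = _revcomp(seq)
            if parts:
                part_no += 1
                agp_rows.append(
                    (lg, pos + 1, pos + gap, part_no, "U", gap,
                     "scaffold", "yes", "map")
                )
                parts.append("N" * gap)
                pos += gap
            part_no += 1
            agp_rows.append(
                (lg, pos + 1, pos + len(seq), part_no, "W", row.scaffold,
                 1, len(seq), row.orientation)
            )
            parts.append(seq)
            pos += len(seq)
        lg_seqs[lg] = "".join(parts)
    agp = pd.DataFrame(
        agp_rows,
        columns=[
            "object", "object_beg", "object_end", "part_number",
            "component_type", "component_id", "component_beg",
            "component_end", "orientation",
        ],
    )
    return SequenceSet(lg_seqs), agp


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def marey_table(
    order: pd.DataFrame,
    merged_hits: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    gap: int = GAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe positions on the built LGs versus genetic position.

    Returns (table, scores): ``table`` has lg, probe_id, bp_on_lg, cm sorted
    by bp within LG; ``scores`` holds one monotonicity score per LG, the
    fraction of adjacent probe pairs whose cM does not decrease along the
    built sequence. LGs without probes are absent.
    """
    offsets: dict[str, tuple[str, int, str]] = {}
    for lg, sub in order.groupby("lg", sort=True):
        pos = 0
        for i, row in enumerate(sub.itertuples()):
            if i > 0:
                pos += gap
            offsets[row.scaffold] = (lg, pos, row.orientation)
            pos += scaffold_lengths[row.scaffold]
    rows = []
    for row in merged_hits.itertuples():
        if row.scaffold not in offsets:
            continue
        lg, off, orient = offsets[row.scaffold]
        length = scaffold_lengths[row.scaffold]
        bp = row.bp if orient == "+" else length - 1 - row.bp
        rows.append({"lg": lg, "probe_id": row.probe_id,
                     "bp_on_lg": off + bp, "cm": row.cm})
    table = pd.DataFrame(rows).sort_values(["lg", "bp_on_lg"], ignore_index=True)
    scores = []
    for lg, sub in table.groupby("lg", sort=True):
        cm = sub["cm"].to_numpy()
        if len(cm) < 2:
            scores.append({"lg": lg, "monotonicity": 1.0})
            continue
        diffs = np.diff(cm)
        scores.append(
            {"lg": lg, "monotonicity": float((diffs >= 0).mean())}
        )
    return table, pd.DataFrame(scores)
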