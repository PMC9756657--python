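#!/usr/bin/env python
"""Anchor scaffolds into linkage groups and QC the build with Marey tables.

Reads the probe hits, genetic map and scaffolds from 01, deduplicates hits,
assigns scaffolds to LGs, breaks chimeric scaffolds between their per-LG
probe blocks, orders and orients scaffolds by genetic position, builds LG
sequences joined by 100-N gaps (with AGP), and writes per-LG Marey tables
with monotonicity scores plus a QC plot.
"""

from pathlib import Path

import pandas as pd

from intropipe.io_formats import SequenceSet, read_fasta, write_fasta
from intropipe.linkage_anchoring import (
    assign_scaffolds,
    best_hits,
    break_chimeras,
    build_lg_sequences,
    marey_table,
    order_and_orient,
)

SCRATCH = Path("scratch/synthetic")
RESULTS = Path("results")


def main() -> None:
    if not (SCRATCH / "probe_hits.tsv").exists():
        raise SystemExit("run analysis/01_simulate_data.py first")
    hits = best_hits(pd.read_csv(SCRATCH / "probe_hits.tsv", sep="\t"))
    gmap = pd.read_csv(SCRATCH / "genetic_map.tsv", sep="\t")
    scaffolds = read_fasta(SCRATCH / "map_scaffolds.fa")

    assigns = assign_scaffolds(hits, gmap, scaffolds)
    flagged = [a.scaffold for a in assigns if a.is_chimera_candidate]
    print(f"{len(assigns)} scaffolds; {len(flagged)} flagged as chimera candidates")

    pieces, breaks, new_hits = break_chimeras(
        assigns, hits, gmap, scaffolds.lengths()
    )
    resolved = sum(b["resolved"] for b in breaks)
    print(f"{resolved}/{len(breaks)} chimeras broken at inter-block midpoints")
    pd.DataFrame(breaks).to_csv(RESULTS / "chimera_breaks.tsv", sep="\t", index=False)

    piece_seqs = SequenceSet(
        {r.piece: scaffolds[r.source][r.start : r.end] for r in pieces.itertuples()}
    )
    order = order_and_orient(new_hits)
    order.to_csv(RESULTS / "lg_scaffold_order.tsv", sep="\t", index=False)
    built, agp = build_lg_sequences(order, piece_seqs)
    write_fasta(built, SCRATCH / "linkage_groups.fa")
    agp.to_csv(RESULTS / "linkage_groups.agp", sep="\t", index=False)

    placed = set(order.scaffold)
    lg0 = [n for n in piece_seqs.names() if n not in placed]
    anchored_bp = sum(len(piece_seqs[s]) for s in placed)
    total_bp = scaffolds.total_length()
    print(f"anchored {len(placed)} scaffold pieces "
          f"({anchored_bp / total_bp:.1%} of assembly bases) into "
          f"{built.names().__len__()} LGs; {len(lg0)} pieces in the LG0 pool")

    table, scores = marey_table(order, new_hits, piece_seqs.lengths())
    table.to_csv(RESULTS / "marey_table.tsv", sep="\t", index=False)
    scores.to_csv(RESULTS / "marey_monotonicity.tsv", sep="\t", index=False)
    print(f"Marey monotonicity: min {scores.monotonicity.min():.3f}, "
          f"mean {scores.monotonicity.mean():.3f} over {len(scores)} LGs")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        lgs = sorted(table.lg.unique(), key=lambda s: int(s.lstrip("LG")))[:6]
        fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharey=False)
        for ax, lg in zip(axes.ravel(), lgs):
            sub = table[table.lg == lg]
            ax.plot(sub.bp_on_lg / 1e6, sub.cm, ".", ms=4)
            ax.set_title(lg)
            ax.set_xlabel("Mb on LG")
            ax.set_ylabel("cM")
        fig.tight_layout()
        fig.savefig(SCRATCH / "marey_plots.png", dpi=120)
        print(f"Marey plots for {len(lgs)} LGs -> {SCRATCH / 'marey_plots.png'}")
    except Exception as exc:  # plotting is QC sugar, never fatal
        print(f"plotting skipped: {exc}")


if __name__ == "__main__":
    main()
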