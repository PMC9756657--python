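"""Ground-truthed synthetic fixtures for every pipeline stage.

The generator emulates the three-reference introgression setting: a focal
genome derived from a "niloticus-like" donor (donorA) except for planted
blocks of "mossambicus-like" (donorB) ancestry, HiFi-like reads spanning the
block boundaries, exact alignments of those reads to all three references,
coalescent-based genotypes for five populations plus an outgroup role, and a
22-linkage-group genetic map with injected chimeric scaffolds.

Everything is deterministic given (params, seed): the same inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _coalescent
from .io_formats import (
    AlignmentRecord,
    GenomicInterval,
    GenotypeMatrix,
    SequenceSet,
)

__all__ = [
    "SimulationParams",
    "TruthSet",
    "simulate_genomes",
    "simulate_reads",
    "simulate_alignments",
    "simulate_genotypes",
    "simulate_probe_map",
    "POPULATIONS",
]

POPULATIONS = ("focal", "niloticus", "aureus", "mossambicus", "urolepis")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationParams:
    """Tunable knobs of the generator; defaults are the study conditions.

    ``donor_divergence`` is the per-lineage substitution rate separating each
    donor from their common ancestor (so donors differ at ~2x this rate).
    ``admixture_proportion`` (f) is the fraction of the focal genome replaced
    by donorB ancestry. ``block_margin`` keeps planted blocks away from
    scaffold ends so every planted boundary is in principle detectable by the
    read-based detector; when None it defaults to read_length + 10 kb.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_scaffolds: int = 2
    donor_divergence: float = 0.02
    focal_divergence: float = 0.0
    admixture_proportion: float = 0.1
    introgressed_block_length: int = 50_000
    block_margin: int | None = None
    ils_rate: float = 0.1
    read_length: int = 15_000
    read_depth: float = 30.0
    n_sites: int = 20_000
    samples_per_pop: int = 2
    mean_site_depth: int = 300
    window_size: int = 200
    window_overlap: int = 40
    n_lgs: int = 22
    scaffolds_per_lg: int = 4
    probes_per_scaffold: int = 8
    chimera_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_proportion <= 1.0:
            raise ValueError("admixture_proportion must be in [0, 1]")
        if not 0.0 <= self.ils_rate <= 1.0:
            raise ValueError("ils_rate must be in [0, 1]")
        for name in ("genome_length", "read_length", "introgressed_block_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def margin(self) -> int:
        if self.block_margin is not None:
            return self.block_margin
        return self.read_length + 10_000


@dataclass
class TruthSet:
    """Ground truth emitted alongside fixtures, used as the test oracle."""

    introgressed_blocks: list[GenomicInterval] = field(default_factory=list)
    site_labels: np.ndarray | None = None  # per-site genealogy class codes
    scaffold_order: dict[str, list[tuple[str, str]]] | None = None
    chimera_joins: list[dict] | None = None

    def blocks_on(self, seqid: str) -> list[GenomicInterval]:
        return sorted(
            (b for b in self.introgressed_blocks if b.seqid == seqid),
            key=lambda b: b.start,
        )

    def block_boundaries(self) -> list[tuple[str, int]]:
        out = []
        for b in self.introgressed_blocks:
            out.append((b.seqid, b.start))
            out.append((b.seqid, b.end))
        return out


# ---------------------------------------------------------------------------
# helpers


def _scaffold_layout(params: SimulationParams) -> dict[str, int]:
    base = params.genome_length // params.n_scaffolds
    lengths = {
        f"LG{i + 1}": base for i in range(params.n_scaffolds)
    }
    lengths[f"LG{params.n_scaffolds}"] += params.genome_length - base * params.n_scaffolds
    return lengths

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-like substitutions: each base mutates to a different one."""
    out = seq.copy()
    if rate <= 0:
        return out
    mask = rng.random(seq.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shift) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _draw_blocks(
    rng: np.random.Generator,
    scaffold_lengths: dict[str, int],
    f: float,
    mean_block: int,
    margin: int,
) -> list[GenomicInterval]:
    """Exponential block lengths placed uniformly without overlap.

    Lengths are drawn stick-breaking style until the total reaches
    f * genome_length exactly (the last block is truncated).
    """
    total_len = sum(scaffold_lengths.values())
    target = int(round(f * total_len))
    if target <= 0:
        return []
    if f >= 1.0:
        return [
            GenomicInterval(s, 0, ln, "donorB") for s, ln in scaffold_lengths.items()
        ]
    lengths: list[int] = []
    remaining = target
    while remaining > 0:
        ln = int(round(rng.exponential(mean_block)))
        ln = max(ln, 1)
        if ln >= remaining:
            ln = remaining
        lengths.append(ln)
        remaining -= ln
    if target < mean_block:
        warnings.warn(
            "requested total introgression is below one mean block length; "
            "emitting a single truncated block"
        )
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffold_lengths}
    out: list[GenomicInterval] = []
    scaffolds = list(scaffold_lengths)
    for ln in sorted(lengths, reverse=True):
        done = False
        for _ in range(500):
            s = scaffolds[rng.integers(0, len(scaffolds))]
            lo, hi = margin, scaffold_lengths[s] - margin - ln
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            if all(
                start + ln <= a or start >= b for a, b in placed[s]
            ):
                placed[s].append((start, start + ln))
                out.append(GenomicInterval(s, start, start + ln, "donorB"))
                done = True
                break
        if not done:
            warnings.warn(f"could not place a block of length {ln}; dropped")
    out.sort(key=lambda b: (b.seqid, b.start))
    return out


# ---------------------------------------------------------------------------
# genomes


def simulate_genomes(
    params: SimulationParams,
) -> tuple[SequenceSet, SequenceSet, SequenceSet, TruthSet]:
    """(focal, donorA, donorB, truth): donors diverge independently from a
    common ancestor; the focal genome copies donorA except inside planted
    blocks, which carry the homologous donorB sequence."""
    rng = np.random.default_rng([params.seed, 0])
    layout = _scaffold_layout(params)
    blocks = _draw_blocks(
        rng,
        layout,
        params.admixture_proportion,
        params.introgressed_block_length,
        params.margin,
    )
    focal_d, donora_d, donorb_d = {}, {}, {}
    for seqid, length in layout.items():
        anc = rng.integers(0, 4, size=length, dtype=np.uint8)
        a = _mutate(anc, params.donor_divergence, rng)
        b = _mutate(anc, params.donor_divergence, rng)
        fo = _mutate(a, params.focal_divergence, rng)
        for blk in blocks:
            if blk.seqid == seqid:
                fo[blk.start : blk.end] = b[blk.start : blk.end]
        focal_d[seqid] = _codes_to_str(fo)
        donora_d[seqid] = _codes_to_str(a)
        donorb_d[seqid] = _codes_to_str(b)
    truth = TruthSet(introgressed_blocks=blocks)
    return (
        SequenceSet(focal_d),
        SequenceSet(donora_d),
        SequenceSet(donorb_d),
        truth,
    )


# ---------------------------------------------------------------------------
# reads


_READ_NAME = re.compile(r"^(?P<rid>[^|]+)\|(?P<scaf>[^|]+)\|(?P<start>\d+)\|(?P<end>\d+)$")


def simulate_reads(focal: SequenceSet, params: SimulationParams) -> SequenceSet:
    """Error-free HiFi-like reads at ``read_depth`` fold coverage.

    Lengths are normal around ``read_length`` (sd 10%, truncated to the
    scaffold); starts are uniform. Read names encode the true origin interval
    (``readNNNNNN|scaffold|start|end``) for oracle checks.
    """
    rng = np.random.default_rng([params.seed, 1])
    reads: dict[str, str] = {}
    i = 0
    for seqid, seq in focal.items():
        scaf_len = len(seq)
        n_reads = int(round(params.read_depth * scaf_len / params.read_length))
        if n_reads <= 0:
            continue
        lengths = rng.normal(params.read_length, 0.1 * params.read_length, n_reads)
        lengths = np.clip(lengths, params.read_length * 0.5, params.read_length * 1.5)
        lengths = lengths.astype(np.int64)
        if params.read_length > scaf_len:
            warnings.warn(
                f"read_length exceeds scaffold {seqid} length; reads truncated"
            )
        lengths = np.minimum(lengths, scaf_len)
        for ln in lengths:
            start = int(rng.integers(0, scaf_len - ln + 1))
            name = f"read{i:06d}|{seqid}|{start}|{start + ln}"
            reads[name] = seq[start : start + ln]
            i += 1
    return SequenceSet(reads)


def read_origin(read_name: str) -> tuple[str, int, int]:
    """Decode the true origin interval from a simulated read name."""
    m = _READ_NAME.match(read_name)
    if m is None:
        raise ValueError(f"read {read_name!r} does not encode a known origin")
    return m.group("scaf"), int(m.group("start")), int(m.group("end"))


# ---------------------------------------------------------------------------
# alignments


def simulate_alignments(
    reads: SequenceSet,
    focal: SequenceSet,
    donorA: SequenceSet,
    donorB: SequenceSet,
    truth: TruthSet,
) -> list[AlignmentRecord]:
    """Exact alignments emulating a long-read mapper's output.

    Each read maps full-length to the focal genome at its true origin. Donor
    records follow the planted ancestry: read portions of donorA ancestry
    align to donorA, portions inside introgressed blocks align to donorB, at
    the homologous coordinates (the simulation plants no indels, so
    homologous coordinates coincide). Reads spanning a block boundary are
    therefore emitted as split, non-overlapping donor records.
    """
    blocks_by_seq: dict[str, list[GenomicInterval]] = {}
    for seqid in focal.names():
        blocks_by_seq[seqid] = truth.blocks_on(seqid)
    records: list[AlignmentRecord] = []
    for name in reads.names():
        seqid, start, end = read_origin(name)
        if seqid not in focal:
            raise ValueError(f"read {name!r} names unknown scaffold {seqid!r}")
        read_len = end - start
        records.append(
            AlignmentRecord(name, read_len, 0, read_len, "focal", seqid, start, end)
        )
        for seg_start, seg_end, label in _ancestry_segments(
            start, end, blocks_by_seq[seqid]
        ):
            records.append(
                AlignmentRecord(
                    name,
                    read_len,
                    seg_start - start,
                    seg_end - start,
                    label,
                    seqid,
                    seg_start,
                    seg_end,
                )
            )
    return records


def _ancestry_segments(
    start: int, end: int, blocks: Sequence[GenomicInterval]
) -> list[tuple[int, int, str]]:
    """Partition [start, end) into maximal donorA/donorB ancestry segments."""
    cuts = [start]
    for b in blocks:
        if b.start < end and b.end > start:
            cuts.extend([max(b.start, start), min(b.end, end)])
    cuts.append(end)
    cuts = sorted(set(cuts))
    segs: list[tuple[int, int, str]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = (a + b) // 2
        label = "donorA"
        for blk in blocks:
            if blk.start <= mid < blk.end:
                label = "donorB"
                break
        if segs and segs[-1][2] == label and segs[-1][1] == a:
            segs[-1] = (segs[-1][0], b, label)
        else:
            segs.append((a, b, label))
    return segs


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(params: SimulationParams) -> tuple[GenotypeMatrix, TruthSet]:
    """Coalescent genotypes for the five populations with planted admixture.

    Site coordinates live on the same scaffold layout as the simulated
    genomes; sites falling inside planted donorB blocks have the focal
    lineages trace into the mossambicus population at a recent time. One
    derived mutation per site is placed proportional to branch length, so
    the outgroup is ancestral except under draws on its own subtree.
    """
    if params.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng([params.seed, 2])
    layout = _scaffold_layout(params)
    blocks = _draw_blocks(
        rng,
        layout,
        params.admixture_proportion,
        params.introgressed_block_length,
        margin=0,
    )
    # positions across the concatenated layout, then mapped to scaffolds
    total = sum(layout.values())
    offs = np.cumsum([0] + [layout[s] for s in layout])
    flat = np.sort(
        rng.choice(total, size=min(params.n_sites, total), replace=False)
    )
    seqids = np.empty(flat.size, dtype=object)
    pos0 = np.empty(flat.size, dtype=np.int64)
    names = list(layout)
    for i, s in enumerate(names):
        mask = (flat >= offs[i]) & (flat < offs[i + 1])
        seqids[mask] = s
        pos0[mask] = flat[mask] - offs[i]
    admixed = np.zeros(flat.size, dtype=bool)
    for b in blocks:
        admixed |= (seqids == b.seqid) & (pos0 >= b.start) & (pos0 < b.end)
    derived, labels = _coalescent.simulate_site_patterns(
        flat.size,
        admixed,
        n_dip_per_pop=params.samples_per_pop,
        ils_rate=params.ils_rate,
        seed=int(rng.integers(0, 2**31)),
    )
    n_dip = params.samples_per_pop
    genotypes = derived.reshape(flat.size, 5 * n_dip, 2).sum(axis=2).astype(np.int8)
    samples = [f"{pop}_{i + 1}" for pop in POPULATIONS for i in range(n_dip)]
    populations = {s: s.rsplit("_", 1)[0] for s in samples}
    ref_codes = rng.integers(0, 4, size=flat.size)
    alt_codes = (ref_codes + rng.integers(1, 4, size=flat.size)) % 4
    sites = pd.DataFrame(
        {
            "seqid": seqids,
            "pos": pos0 + 1,
            "ref": [chr(_BASES[c]) for c in ref_codes],
            "alt": [chr(_BASES[c]) for c in alt_codes],
            "total_depth": rng.poisson(params.mean_site_depth, size=flat.size),
            "is_indel": False,
            "is_biallelic": True,
            "dist_to_indel": GenotypeMatrix.NO_INDEL,
        }
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["seqid"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    matrix = GenotypeMatrix(
        sites=sites,
        genotypes=genotypes[order],
        samples=samples,
        populations=populations,
    )
    truth = TruthSet(introgressed_blocks=blocks, site_labels=labels[order])
    return matrix, truth


# ---------------------------------------------------------------------------
# probe map / linkage-map fixture


def simulate_probe_map(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SequenceSet, TruthSet]:
    """(probe hits, genetic map, scaffolds, truth) for the anchoring stage.

    Scaffolds are assigned a true LG, order and orientation; probe cM
    positions increase with bp on '+' scaffolds and decrease on '-' ones.
    ``chimera_fraction`` of scaffolds are built by concatenating pieces from
    two different LGs, with the join point recorded in the truth set.
    """
    if params.n_lgs < 1:
        raise ValueError("n_lgs must be >= 1")
    if params.probes_per_scaffold < 2:
        warnings.warn(
            "probes_per_scaffold < 2: scaffold orientation is undefined; "
            "probes are still emitted"
        )
    rng = np.random.default_rng([params.seed, 3])
    cm_per_bp = 5.0e-5  # ~1 cM / 20 kb
    hits_rows, map_rows = [], []
    seqs: dict[str, str] = {}
    order: dict[str, list[tuple[str, str]]] = {}
    scaffold_meta: list[dict] = []  # per scaffold, for chimera injection
    probe_i = 0
    for lg_i in range(1, params.n_lgs + 1):
        lg = f"LG{lg_i}"
        order[lg] = []
        cm0 = 0.0
        for sc_i in range(params.scaffolds_per_lg):
            name = f"scf{lg_i:02d}_{sc_i + 1}"
            length = int(rng.integers(50_000, 150_001))
            orient = "+" if rng.random() < 0.5 else "-"
            seqs[name] = _codes_to_str(
                rng.integers(0, 4, size=length, dtype=np.uint8)
            )
            order[lg].append((name, orient))
            n_probes = max(params.probes_per_scaffold, 1)
            bps = np.sort(
                rng.choice(length, size=min(n_probes, length), replace=False)
            )
            probes = []
            for bp in bps:
                within = bp if orient == "+" else length - 1 - bp
                cm = cm0 + within * cm_per_bp
                pid = f"probe{probe_i:05d}"
                probes.append((pid, int(bp), float(cm)))
                probe_i += 1
            scaffold_meta.append(
                {"name": name, "lg": lg, "orient": orient, "length": length,
                 "probes": probes}
            )
            cm0 += length * cm_per_bp
    n_chim = int(round(params.chimera_fraction * len(scaffold_meta)))
    chimera_joins: list[dict] = []
    consumed: set[str] = set()
    # pair scaffolds from different LGs into chimeras
    perm = rng.permutation(len(scaffold_meta))
    candidates = [scaffold_meta[i] for i in perm]
    ci = 0
    while ci < n_chim and len(candidates) >= 2:
        a = candidates.pop()
        b = next((m for m in candidates if m["lg"] != a["lg"]), None)
        if b is None:
            break
        candidates.remove(b)
        cname = f"chim{ci + 1}_{a['name']}_{b['name']}"
        seqs[cname] = seqs.pop(a["name"]) + seqs.pop(b["name"])
        consumed |= {a["name"], b["name"]}
        join = a["length"]
        for pid, bp, cm in a["probes"]:
            hits_rows.append((pid, cname, bp, "+", 100))
            map_rows.append((pid, a["lg"], cm))
        for pid, bp, cm in b["probes"]:
            hits_rows.append((pid, cname, bp + join, "+", 100))
            map_rows.append((pid, b["lg"], cm))
        chimera_joins.append(
            {
                "name": cname,
                "join": join,
                "components": [
                    {"name": a["name"], "lg": a["lg"], "orient": a["orient"]},
                    {"name": b["name"], "lg": b["lg"], "orient": b["orient"]},
                ],
            }
        )
        ci += 1
    for m in scaffold_meta:
        if m["name"] in consumed:
            continue
        for pid, bp, cm in m["probes"]:
            hits_rows.append((pid, m["name"], bp, "+", 100))
            map_rows.append((pid, m["lg"], cm))
    hits = pd.DataFrame(
        hits_rows, columns=["probe_id", "scaffold", "bp", "strand", "score"]
    )
    gmap = pd.DataFrame(map_rows, columns=["probe_id", "lg", "cm"])
    truth = TruthSet(scaffold_order=order, chimera_joins=chimera_joins)
    return hits, gmap, SequenceSet(seqs), truth
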