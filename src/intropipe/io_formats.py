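"""Readers and writers for the standard formats the pipeline touches.

Internal coordinate convention is uniform: 0-based, half-open. GFF3 and VCF
use 1-based conventions on disk and are converted here, at the I/O boundary,
and nowhere else. BED and PAF are already 0-based half-open and pass through
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceSet",
    "AlignmentRecord",
    "GenomicInterval",
    "GenotypeMatrix",
    "GeneFeature",
    "WindowTree",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "read_bed",
    "write_bed",
    "read_window_trees",
    "write_window_trees",
]

VALID_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file violated the expected on-disk format or a type invariant."""


@dataclass
class SequenceSet:
    """Ordered collection of named uppercase A/C/G/T/N sequences."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            if set(seq) - VALID_ALPHABET:
                bad = sorted(set(seq) - VALID_ALPHABET)
                raise FormatError(f"sequence {name!r} contains invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment segment (PAF-style coordinates)."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    ref_label: str  # focal / donorA / donorB
    target: str
    target_start: int
    target_end: int
    strand: str = "+"
    mapq: int = 60

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise FormatError(
                f"read {self.read_id}: invalid read span "
                f"[{self.read_start},{self.read_end}) for length {self.read_len}"
            )
        if not (0 <= self.target_start < self.target_end):
            raise FormatError(
                f"read {self.read_id}: invalid target span "
                f"[{self.target_start},{self.target_end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"read {self.read_id}: invalid strand {self.strand!r}")
        if not (0 <= self.mapq <= 255):
            raise FormatError(f"read {self.read_id}: mapq {self.mapq} out of range")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span with an optional payload (label, weight, reads)."""

    seqid: str
    start: int
    end: int
    payload: object = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.seqid}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneFeature:
    """An annotation feature, stored 0-based half-open."""

    seqid: str
    start: int
    end: int
    strand: str
    feature_type: str
    gene_id: str
    confidence: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"feature {self.gene_id or '?'} {self.seqid}:{self.start}-{self.end} "
                "has start >= end"
            )
        if self.feature_type == "gene" and not self.gene_id:
            raise FormatError(
                f"gene feature at {self.seqid}:{self.start}-{self.end} lacks a gene id"
            )


@dataclass
class WindowTree:
    """A genomic window together with the tree inferred from it."""

    window: GenomicInterval
    tree: "dendropy.Tree"  # noqa: F821 - imported lazily
    newick: str = ""


MISSING = -1  # genotype code for a missing call


@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples genotype matrix with population labels.

    ``sites`` columns: seqid, pos (1-based), ref, alt, total_depth,
    is_indel, is_biallelic, dist_to_indel (bp to the nearest indel on the
    same seqid; large sentinel when none). ``genotypes`` holds diploid codes
    {0,1,2} with -1 for missing, shape (n_sites, n_samples).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str]

    NO_INDEL = 10**9

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype array shape does not match sites x samples")
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ValueError(f"samples without a population label: {missing}")
        order = self.sites[["seqid", "pos"]]
        if not order.equals(order.sort_values(["seqid", "pos"]).reset_index(drop=True)):
            raise ValueError("sites must be sorted by (seqid, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def samples_of(self, population: str) -> list[int]:
        return [
            i for i, s in enumerate(self.samples) if self.populations[s] == population
        ]

    def alt_freqs(self, population: str) -> np.ndarray:
        """Per-site ALT allele frequency within one population (NaN if no calls)."""
        cols = self.samples_of(population)
        if not cols:
            raise ValueError(f"no samples belong to population {population!r}")
        g = self.genotypes[:, cols].astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nansum(g, axis=1) / (2.0 * np.sum(~np.isnan(g), axis=1))

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            genotypes=self.genotypes[np.asarray(mask)],
            samples=list(self.samples),
            populations=dict(self.populations),
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (uppercased, validated)."""
    entries: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        name = rec.id
        if name in entries:
            raise FormatError(f"{path}: duplicate sequence name {name!r} (record {i})")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {name!r} (record {i}) has no sequence")
        entries[name] = seq
    return SequenceSet(entries)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path, ref_label: str) -> list[AlignmentRecord]:
    """Read minimap2-dialect PAF (columns 1-12), tagging records ``ref_label``."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF line has {len(cols)} columns (< 12)"
                )
            try:
                read_len, read_start, read_end = map(int, cols[1:4])
                target_start, target_end = int(cols[7]), int(cols[8])
                mapq = int(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                records.append(
                    AlignmentRecord(
                        read_id=cols[0],
                        read_len=read_len,
                        read_start=read_start,
                        read_end=read_end,
                        ref_label=ref_label,
                        target=cols[5],
                        target_start=target_start,
                        target_end=target_end,
                        strand=cols[4],
                        mapq=mapq,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_paf(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Write records as 12-column PAF (residue matches = block length)."""
    with open(path, "w") as fh:
        for r in records:
            block = r.target_end - r.target_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id,
                        r.read_len,
                        r.read_start,
                        r.read_end,
                        r.strand,
                        r.target,
                        0,
                        r.target_start,
                        r.target_end,
                        block,
                        block,
                        r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, sample_populations: Mapping[str, str]) -> GenotypeMatrix:
    """Load a VCF 4.x into a :class:`GenotypeMatrix`.

    Loads SNPs and indels; multiallelic records are retained but flagged
    non-biallelic (downstream filtering drops them). ``dist_to_indel`` is the
    distance (bp) from each site to the nearest base of any indel's REF span
    on the same seqid, 0 when overlapping.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in sample_populations]
    if unlabeled:
        raise ValueError(
            f"{path}: samples without a population label: {unlabeled}"
        )
    rows = []
    geno = []
    for var in vcf:
        codes = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                codes.append(MISSING)
            else:
                codes.append(sum(1 for a in alleles if a > 0))
        dp = var.INFO.get("DP")
        rows.append(
            {
                "seqid": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": ",".join(var.ALT) if var.ALT else ".",
                "total_depth": int(dp) if dp is not None else 0,
                "is_indel": bool(var.is_indel),
                "is_biallelic": len(var.ALT) == 1,
                "ref_len": len(var.REF),
            }
        )
        geno.append(codes)
    sites = pd.DataFrame(
        rows,
        columns=[
            "seqid", "pos", "ref", "alt", "total_depth",
            "is_indel", "is_biallelic", "ref_len",
        ],
    )
    genotypes = (
        np.array(geno, dtype=np.int8)
        if geno
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["seqid"].to_numpy())) if len(sites) else []
    sites = sites.iloc[order].reset_index(drop=True) if len(sites) else sites
    genotypes = genotypes[order] if len(sites) else genotypes
    sites["dist_to_indel"] = _distance_to_nearest_indel(sites)
    sites = sites.drop(columns=["ref_len"])
    return GenotypeMatrix(
        sites=sites,
        genotypes=genotypes,
        samples=samples,
        populations={s: sample_populations[s] for s in samples},
    )


def _distance_to_nearest_indel(sites: pd.DataFrame) -> np.ndarray:
    """Exhaustive per-seqid scan: bp distance from each site to any indel span."""
    dist = np.full(len(sites), GenotypeMatrix.NO_INDEL, dtype=np.int64)
    for seqid, idx in sites.groupby("seqid").groups.items():
        idx = np.asarray(idx)
        sub = sites.loc[idx]
        indels = sub[sub["is_indel"]]
        if indels.empty:
            continue
        starts = indels["pos"].to_numpy()
        ends = starts + indels["ref_len"].to_numpy() - 1  # inclusive REF span
        for i in idx:
            p = sites.at[i, "pos"]
            d = np.where(
                (p >= starts) & (p <= ends),
                0,
                np.minimum(np.abs(p - starts), np.abs(p - ends)),
            )
            dist[i] = int(d.min())
    return dist


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal diploid VCF 4.2 with INFO/DP and GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for seqid in matrix.sites["seqid"].unique():
            fh.write(f"##contig=<ID={seqid}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i, row in matrix.sites.iterrows():
            gts = "\t".join(gt_map[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{row.seqid}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"DP={row.total_depth}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read GFF3 into features with 0-based half-open coordinates."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    features: list[GeneFeature] = []
    for row in df.itertuples():
        start, end = int(row.Start), int(row.End)
        if start >= end:
            raise FormatError(
                f"{path}: feature at {row.Chromosome}:{start}-{end} "
                "has non-positive length after coordinate conversion"
            )
        gene_id = getattr(row, "ID", "") or getattr(row, "gene_id", "") or ""
        features.append(
            GeneFeature(
                seqid=str(row.Chromosome),
                start=start,
                end=end,
                strand=str(getattr(row, "Strand", ".")),
                feature_type=str(row.Feature),
                gene_id=str(gene_id),
                confidence=str(getattr(row, "biotype", "") or ""),
            )
        )
    return features


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            payload = cols[3] if len(cols) > 3 else None
            try:
                intervals.append(GenomicInterval(cols[0], start, end, payload))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.payload is not None and isinstance(iv.payload, str):
                fh.write(f"{iv.seqid}\t{iv.start}\t{iv.end}\t{iv.payload}\n")
            else:
                fh.write(f"{iv.seqid}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Window trees


def read_window_trees(
    path: str | Path, groups: Mapping[str, Sequence[str]] | None = None
) -> list[WindowTree]:
    """Read a TSV of (seqid, start, end, newick) windows.

    When ``groups`` is given, every tip label must belong to some group.
    Windows are returned sorted by (seqid, start).
    """
    import dendropy

    known_tips = None
    if groups is not None:
        known_tips = {tip for tips in groups.values() for tip in tips}
    windows: list[WindowTree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seqid\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            seqid, start, end, newick = cols[0], int(cols[1]), int(cols[2]), cols[3]
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: window {seqid}:{start}-{end} has start >= end"
                )
            try:
                tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
            except Exception as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable newick for window "
                    f"{seqid}:{start}-{end}: {exc}"
                ) from exc
            if known_tips is not None:
                for leaf in tree.leaf_node_iter():
                    if leaf.taxon.label not in known_tips:
                        raise FormatError(
                            f"{path}:{lineno}: tip {leaf.taxon.label!r} not in any group"
                        )
            windows.append(
                WindowTree(GenomicInterval(seqid, start, end), tree, newick)
            )
    windows.sort(key=lambda w: (w.window.seqid, w.window.start))
    return windows


def write_window_trees(windows: Sequence[WindowTree], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seqid\tstart\tend\tnewick\n")
        for w in windows:
            nwk = w.newick or w.tree.as_string(schema="newick", preserve_underscores=True).strip()
            fh.write(f"{w.window.seqid}\t{w.window.start}\t{w.window.end}\t{nwk}\n")


def write_truth_json(truth: object, path: str | Path) -> None:
    """Serialize a TruthSet-like object (dataclass dict) to JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    if isinstance(obj, GenomicInterval):
        return {"seqid": obj.seqid, "start": obj.start, "end": obj.end,
                "payload": obj.payload}
    raise TypeError(f"not JSON serializable: {type(obj)}")
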