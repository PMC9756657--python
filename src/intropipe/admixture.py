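"""Site filtering, LD pruning, and frequency-based admixture statistics.

The D (ABBA-BABA) statistic measures the asymmetry of derived-allele sharing
between a recipient/sister pair (P2/P1) and a candidate donor (P3), relative
to an outgroup O used to polarize alleles:

    ABBA_i = (1 - p1) * p2 * p3 * (1 - pO)
    BABA_i = p1 * (1 - p2) * p3 * (1 - pO)
    D = sum(ABBA - BABA) / sum(ABBA + BABA)

with per-population derived-allele frequencies p. Under incomplete lineage
sorting alone D is 0 in expectation; gene flow P3 -> P2 drives it positive.
Significance comes from a delete-one block jackknife over contiguous
equal-site blocks.

The f4-admixture ratio estimates the admixture fraction using the donor
population in both numerator and denominator slots (the within-P3 "f_hom"
form, appropriate for the few-samples-per-population setting):

    f_G = sum[(p2 - p1) * p3 * (1 - pO)] / sum[(p3 - p1) * p3 * (1 - pO)]

f-branch summarizes correlated f4 ratios over a rooted species tree to
assign gene-flow evidence to specific branches: for branch b and taxon C
(neither below b nor below b's parent),

    f_b(C) = median over A in desc(sister(b)) of
             [ min over B in desc(b) of f_G(A, B, C) ]

with negative entries clipped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "SiteFilterParams",
    "TrioResult",
    "FBranchMatrix",
    "filter_sites",
    "ld_prune",
    "d_statistic",
    "f4_ratio",
    "f_branch",
    "SPECIES_TREE_NEWICK",
]

SPECIES_TREE_NEWICK = "((((focal,niloticus),aureus),mossambicus),urolepis);"


@dataclass
class SiteFilterParams:
    """Exclusion rules applied to called SNPs before statistics."""

    min_total_depth: int = 90
    max_total_depth: int = 900
    min_minor_allele_count: int = 3
    max_missing_individuals: int = 1
    indel_exclusion_distance: int = 3
    exclude_seqids: frozenset[str] = frozenset({"LG3"})

    def __post_init__(self) -> None:
        if not 0 < self.min_total_depth < self.max_total_depth:
            raise ValueError("need 0 < min_total_depth < max_total_depth")
        if self.min_minor_allele_count < 0 or self.max_missing_individuals < 0:
            raise ValueError("counts must be non-negative")


def filter_sites(
    matrix: GenotypeMatrix, params: SiteFilterParams | None = None
) -> GenotypeMatrix:
    """Biallelic SNPs surviving every exclusion rule.

    Removes: non-biallelic records and indels; total depth < min or > max;
    minor allele count < min; more than ``max_missing_individuals`` missing
    calls; SNPs overlapping or within ``indel_exclusion_distance`` bp of an
    indel; excluded seqids. Per-criterion removal counts are logged.
    """
    params = params or SiteFilterParams()
    s = matrix.sites
    g = matrix.genotypes
    n_called = (g != MISSING).sum(axis=1)
    ac = np.where(g == MISSING, 0, g).sum(axis=1)
    total_alleles = 2 * n_called
    mac = np.minimum(ac, total_alleles - ac)
    n_missing = (g == MISSING).sum(axis=1)

    is_snp = s["is_biallelic"].to_numpy() & ~s["is_indel"].to_numpy()
    depth_ok = (s["total_depth"].to_numpy() >= params.min_total_depth) & (
        s["total_depth"].to_numpy() <= params.max_total_depth
    )
    mac_ok = mac >= params.min_minor_allele_count
    missing_ok = n_missing <= params.max_missing_individuals
    indel_ok = s["dist_to_indel"].to_numpy() > params.indel_exclusion_distance
    seqid_ok = ~s["seqid"].isin(params.exclude_seqids).to_numpy()

    for name, ok in (
        ("non_biallelic_or_indel", is_snp),
        ("total_depth", depth_ok),
        ("minor_allele_count", mac_ok),
        ("missing_individuals", missing_ok),
        ("near_indel", indel_ok),
        ("excluded_seqid", seqid_ok),
    ):
        logger.info("filter %s removed %d sites", name, int((~ok).sum()))
    keep = is_snp & depth_ok & mac_ok & missing_ok & indel_ok & seqid_ok
    return matrix.subset(keep)


def ld_prune(
    matrix: GenotypeMatrix, r2_max: float = 0.6, window: int = 20_000
) -> GenotypeMatrix:
    """Greedy left-to-right linkage pruning.

    Scanning sites in position order per seqid, a site is dropped when its
    genotype r^2 with any *retained* site within ``window`` bp upstream
    exceeds ``r2_max``.
    """
    s = matrix.sites
    g = matrix.genotypes.astype(float)
    g[g == MISSING] = np.nan
    keep = np.zeros(len(s), dtype=bool)
    for _, idx in s.groupby("seqid").groups.items():
        idx = np.asarray(idx)
        retained: list[int] = []
        pos = s.loc[idx, "pos"].to_numpy()
        for j, i in enumerate(idx):
            ok = True
            for rj in reversed(retained):
                if pos[j] - pos[rj] > window:
                    break
                if _genotype_r2(g[i], g[idx[rj]]) > r2_max:
                    ok = False
                    break
            if ok:
                keep[i] = True
                retained.append(j)
    return matrix.subset(keep)


def _genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    both = ~(np.isnan(a) | np.isnan(b))
    if both.sum() < 2:
        return 0.0
    x, y = a[both], b[both]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# D / f4 / f-branch


@dataclass
class TrioResult:
    P1: str
    P2: str
    P3: str
    O: str
    n_sites_used: int
    ABBA_sum: float
    BABA_sum: float
    D: float
    jackknife_SE: float
    Z: float
    f_G: float


@dataclass
class FBranchMatrix:
    """f-branch entries as a branches x taxa frame (NaN where undefined)."""

    table: pd.DataFrame  # index: branch labels, columns: taxa

    def max_entry(self) -> tuple[str, str, float]:
        stacked = self.table.stack()
        idx = stacked.idxmax()
        return idx[0], idx[1], float(stacked.loc[idx])


def _polarized_freqs(
    matrix: GenotypeMatrix, pops: list[str]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-population derived-allele frequencies, ancestral = outgroup major.

    The last population in ``pops`` is the outgroup. Sites where the
    outgroup's two alleles tie at 0.5 cannot be polarized and are masked;
    their count is logged.
    """
    freqs = {p: matrix.alt_freqs(p) for p in pops}
    pO = freqs[pops[-1]]
    usable = ~np.isnan(pO)
    for p in pops:
        usable &= ~np.isnan(freqs[p])
    tied = usable & (pO == 0.5)
    if tied.any():
        logger.info("dropped %d sites with unpolarizable outgroup", int(tied.sum()))
    usable &= pO != 0.5
    flip = pO > 0.5
    out = {}
    for p in pops:
        f = freqs[p].copy()
        f[flip] = 1.0 - f[flip]
        out[p] = f
    return out, usable


def d_statistic(
    matrix: GenotypeMatrix,
    P1: str,
    P2: str,
    P3: str,
    O: str,
    n_jackknife_blocks: int = 20,
) -> TrioResult:
    """Patterson's D with delete-one block-jackknife SE and Z score."""
    f, usable = _polarized_freqs(matrix, [P1, P2, P3, O])
    p1, p2, p3, pO = (f[p][usable] for p in (P1, P2, P3, O))
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        return TrioResult(
            P1, P2, P3, O, int(usable.sum()), 0.0, 0.0,
            float("nan"), float("nan"), float("nan"), float("nan"),
        )
    D = num.sum() / den.sum()
    blocks = np.array_split(np.arange(num.size), n_jackknife_blocks)
    blocks = [b for b in blocks if b.size]
    nb = len(blocks)
    d_del = np.empty(nb)
    for i, b in enumerate(blocks):
        mask = np.ones(num.size, dtype=bool)
        mask[b] = False
        d_del[i] = num[mask].sum() / den[mask].sum() if den[mask].sum() else np.nan
    se = float(np.sqrt((nb - 1) / nb * np.nansum((d_del - np.nanmean(d_del)) ** 2)))
    z = D / se if se > 0 else float("inf") if D != 0 else 0.0
    fg = f4_ratio(matrix, P1, P2, P3, O)
    return TrioResult(
        P1, P2, P3, O, int(usable.sum()),
        float(abba.sum()), float(baba.sum()), float(D), se, float(z), fg,
    )


def f4_ratio(
    matrix: GenotypeMatrix,
    P1: str,
    P2: str,
    P3: str,
    O: str,
    clip: bool = True,
) -> float:
    """Admixture-fraction estimate f_G (within-P3 denominator form)."""
    f, usable = _polarized_freqs(matrix, [P1, P2, P3, O])
    p1, p2, p3, pO = (f[p][usable] for p in (P1, P2, P3, O))
    num = ((p2 - p1) * p3 * (1 - pO)).sum()
    den = ((p3 - p1) * p3 * (1 - pO)).sum()
    if den == 0:
        logger.warning("f4_ratio undefined: zero denominator")
        return float("nan")
    raw = float(num / den)
    if clip and not (0.0 <= raw <= 1.0):
        logger.info("f4_ratio %.4f clipped into [0, 1]", raw)
        return float(min(1.0, max(0.0, raw)))
    return raw


def f_branch(
    matrix: GenotypeMatrix,
    tree_newick: str = SPECIES_TREE_NEWICK,
    outgroup: str = "urolepis",
) -> FBranchMatrix:
    """Branch-resolved admixture signal from correlated f4 ratios.

    Branches are labelled by their descendant leaf set (comma-joined).
    Entries are clipped at zero; (branch, taxon) pairs with no valid trio
    are NaN.
    """
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick", preserve_underscores=True)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    ingroup = [t for t in taxa if t != outgroup]
    cache: dict[tuple[str, str, str], float] = {}

    def fg(A: str, B: str, C: str) -> float:
        key = (A, B, C)
        if key not in cache:
            cache[key] = f4_ratio(matrix, A, B, C, outgroup, clip=False)
        return cache[key]

    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        desc = [l.taxon.label for l in node.leaf_iter()]
        if outgroup in desc:
            continue
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        sister_desc = [
            l.taxon.label for s in siblings for l in s.leaf_iter()
        ]
        if outgroup in sister_desc:
            continue
        parent_desc = set(desc) | set(sister_desc)
        branch_label = ",".join(sorted(desc))
        row = {}
        for C in ingroup:
            if C in parent_desc:
                continue
            vals = []
            for A in sister_desc:
                mins = [fg(A, B, C) for B in desc]
                mins = [m for m in mins if not np.isnan(m)]
                if mins:
                    vals.append(min(mins))
            row[C] = max(0.0, float(np.median(vals))) if vals else np.nan
        rows[branch_label] = row
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    table = table.reindex(columns=[t for t in ingroup])
    return FBranchMatrix(table)
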