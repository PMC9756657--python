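"""Topology weighting over taxon groups by exhaustive enumeration.

For a window tree with several tips per taxon group, the weighting of a
candidate group topology is the fraction of one-tip-per-group subtrees whose
induced unrooted topology matches it (the "complete" method: every
combination is enumerated, nothing is sampled). With five groups there are
(2*5-5)!! = 15 possible unrooted bifurcating topologies; one matches the
species tree and the other 14 are discordant.

Combinations whose induced topology is unresolved (a polytomy survives the
pruning) have their unit of weight split equally among the compatible
topologies; a "discard" policy is available instead.

Weights are accumulated as exact rationals and exposed as floats.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, GenotypeMatrix, WindowTree

__all__ = [
    "TaxonGroups",
    "Topology",
    "TopologySet",
    "WeightVector",
    "enumerate_topologies",
    "weight_window",
    "weight_series",
    "smooth_weights",
    "extract_regions",
    "infer_window_trees",
    "SPECIES_TOPOLOGY",
    "DONOR_SISTER_TOPOLOGY",
]

# rooted display forms; matching is always on the unrooted topology
SPECIES_TOPOLOGY = "((((focal,niloticus),aureus),mossambicus),urolepis);"
# focal grouping with the mossambicus-like donor, the rest per species tree
DONOR_SISTER_TOPOLOGY = "(((focal,mossambicus),(niloticus,aureus)),urolepis);"


@dataclass
class TaxonGroups:
    """Ordered mapping of group name -> tip labels (tips disjoint)."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two taxon groups")
        seen: set[str] = set()
        for name, tips in self.groups.items():
            if not tips:
                raise ValueError(f"group {name!r} is empty")
            overlap = seen & set(tips)
            if overlap:
                raise ValueError(f"tips in multiple groups: {sorted(overlap)}")
            seen |= set(tips)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def group_of(self) -> dict[str, str]:
        return {t: g for g, tips in self.groups.items() for t in tips}

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class Topology:
    """An unrooted bifurcating topology on group names, as its split set."""

    splits: frozenset[frozenset[str]]
    newick: str


@dataclass
class TopologySet:
    """All canonical unrooted bifurcating topologies on a set of group names."""

    group_names: list[str]
    topologies: list[Topology]
    _index: dict[frozenset, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t.splits: i for i, t in enumerate(self.topologies)}

    def __len__(self) -> int:
        return len(self.topologies)

    def index_of_splits(self, splits: frozenset) -> int | None:
        return self._index.get(splits)

    def index_of(self, newick: str) -> int:
        """Index of the topology given as a newick string over group names."""
        splits = _newick_splits(newick, self.group_names)
        idx = self.index_of_splits(splits)
        if idx is None:
            raise ValueError(f"topology {newick!r} not found in the set")
        return idx

    def compatible_with(self, splits: Iterable[frozenset[str]]) -> list[int]:
        s = set(splits)
        return [i for i, t in enumerate(self.topologies) if s <= t.splits]


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def enumerate_topologies(groups: TaxonGroups | Sequence[str]) -> TopologySet:
    """All (2k-5)!! distinct unrooted bifurcating topologies on k group names.

    Built by recursive edge insertion; each topology is canonicalized by its
    set of non-trivial splits and given a deterministic rooted newick for
    display (rooted at the last group name).
    """
    names = groups.names if isinstance(groups, TaxonGroups) else list(groups)
    k = len(names)
    if k < 4:
        raise ValueError("topology weighting needs at least 4 groups")
    # tree as dict node -> set of neighbours; leaves are group names,
    # internal nodes ints
    trees: list[dict] = []
    base: dict = {0: {names[0], names[1], names[2]}}
    for n in names[:3]:
        base[n] = {0}
    trees.append(base)
    for taxon in names[3:]:
        new_trees = []
        for tree in trees:
            for u, v in _edges(tree):
                t2 = {n: set(nb) for n, nb in tree.items()}
                w = max((n for n in t2 if isinstance(n, int)), default=-1) + 1
                t2[u].discard(v)
                t2[v].discard(u)
                t2[u].add(w)
                t2[v].add(w)
                t2[w] = {u, v, taxon}
                t2[taxon] = {w}
                new_trees.append(t2)
        trees = new_trees
    assert len(trees) == _double_factorial(2 * k - 5)
    ref = names[0]
    topologies = []
    seen = set()
    for tree in trees:
        splits = _tree_splits(tree, names, ref)
        if splits in seen:
            continue
        seen.add(splits)
        topologies.append(Topology(splits, _tree_newick(tree, names)))
    return TopologySet(list(names), topologies)


def _edges(tree: dict) -> list[tuple]:
    out = []
    for u, nbs in tree.items():
        for v in nbs:
            if repr(u) < repr(v):
                out.append((u, v))
    return out


def _leafset_below(tree: dict, child, parent) -> frozenset:
    if not isinstance(child, int):
        return frozenset([child])
    out: set = set()
    for nb in tree[child]:
        if nb != parent:
            out |= _leafset_below(tree, nb, child)
    return frozenset(out)


def _normalize_split(side: frozenset, names: Sequence[str], ref: str) -> frozenset:
    if ref in side:
        return frozenset(names) - side
    return side


def _tree_splits(tree: dict, names: Sequence[str], ref: str) -> frozenset:
    k = len(names)
    splits = set()
    for u, v in _edges(tree):
        if isinstance(u, int) and isinstance(v, int):
            side = _leafset_below(tree, u, v)
            if 2 <= len(side) <= k - 2:
                splits.add(_normalize_split(side, names, ref))
    return frozenset(splits)


def _tree_newick(tree: dict, names: Sequence[str]) -> str:
    """Deterministic rooted display newick, rooted at the last group name."""
    root_leaf = names[-1]
    (anchor,) = tree[root_leaf]

    def render(node, parent) -> str:
        if not isinstance(node, int):
            return node
        kids = sorted(
            (render(nb, node) for nb in tree[node] if nb != parent),
        )
        return "(" + ",".join(kids) + ")"

    return f"({render(anchor, root_leaf)},{root_leaf});"


def _newick_splits(newick: str, names: Sequence[str]) -> frozenset:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    full = frozenset(names)
    ref = names[0]
    k = len(names)
    splits = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if leaves - full:
            raise ValueError(f"unknown taxa in newick: {sorted(leaves - full)}")
        if 2 <= len(leaves) <= k - 2:
            splits.add(_normalize_split(leaves, names, ref))
    return frozenset(splits)


# ---------------------------------------------------------------------------
# weighting


@dataclass
class WeightVector:
    """Normalized topology weights of one window (exact counts kept)."""

    window: GenomicInterval | None
    counts: list[Fraction]
    total: int

    @property
    def weights(self) -> np.ndarray:
        return np.array([float(c) / self.total for c in self.counts])


def tree_splits_by_label(tree) -> list[frozenset]:
    """Leaf-label sets below each edge of a dendropy tree (one side each)."""
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def weight_window(
    tree,
    groups: TaxonGroups,
    topologies: TopologySet,
    polytomy: str = "distribute",
    window: GenomicInterval | None = None,
) -> WeightVector:
    """TWISST "complete" weighting of one window tree.

    Iterates over every combination of one tip per group, restricts the
    tree's splits to the chosen tips, and matches the induced unrooted
    topology against the topology set. ``polytomy`` is "distribute" (split
    the combination's weight equally over compatible topologies) or
    "discard" (drop the combination from the total).
    """
    if polytomy not in ("distribute", "discard"):
        raise ValueError("polytomy must be 'distribute' or 'discard'")
    k = len(groups)
    names = groups.names
    ref_group = names[0]
    group_of = groups.group_of()
    tip_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    for g, tips in groups.groups.items():
        for t in tips:
            if t not in tip_labels:
                raise ValueError(f"tip {t!r} (group {g!r}) absent from tree")
    full_splits = [s for s in tree_splits_by_label(tree) if len(s) >= 2]
    counts = [Fraction(0) for _ in range(len(topologies))]
    total = 0
    group_set = frozenset(names)
    for combo in itertools.product(*(groups.groups[g] for g in names)):
        chosen = set(combo)
        induced: set[frozenset] = set()
        for s in full_splits:
            x = s & chosen
            if 2 <= len(x) <= k - 2:
                side = frozenset(group_of[t] for t in x)
                if ref_group in side:
                    side = group_set - side
                induced.add(side)
        idx = topologies.index_of_splits(frozenset(induced))
        if idx is not None and len(induced) == k - 3:
            counts[idx] += 1
            total += 1
        else:
            compat = topologies.compatible_with(induced)
            if polytomy == "distribute":
                share = Fraction(1, len(compat))
                for i in compat:
                    counts[i] += share
                total += 1
            # 'discard': combination dropped from the total
    if total == 0:
        raise ValueError("no combination produced a scorable topology")
    return WeightVector(window, counts, total)


def weight_series(
    windows: Sequence[WindowTree],
    groups: TaxonGroups,
    topologies: TopologySet,
    polytomy: str = "distribute",
) -> pd.DataFrame:
    """Per-window weights as a tidy frame: seqid, start, end, w_0..w_{T-1}."""
    rows = []
    for wt in windows:
        wv = weight_window(wt.tree, groups, topologies, polytomy, wt.window)
        rows.append(
            [wt.window.seqid, wt.window.start, wt.window.end, *wv.weights]
        )
    cols = ["seqid", "start", "end"] + [f"w_{i}" for i in range(len(topologies))]
    return pd.DataFrame(rows, columns=cols)


def smooth_weights(series: pd.DataFrame, span: float = 0.05) -> pd.DataFrame:
    """Loess-smooth each topology weight along the genome (reporting only).

    Local linear regression with tricube weights (lowess) over ``span`` as a
    fraction of the windows of each seqid, evaluated at window midpoints.
    The raw series should be kept alongside: region extraction operates on
    raw weights. A single-window seqid is returned unchanged with a warning.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = series.copy()
    wcols = [c for c in series.columns if c.startswith("w_")]
    for seqid, idx in series.groupby("seqid").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            warnings.warn(f"seqid {seqid!r} has a single window; not smoothed")
            continue
        x = (
            series.loc[idx, "start"].to_numpy() + series.loc[idx, "end"].to_numpy()
        ) / 2.0
        for c in wcols:
            y = series.loc[idx, c].to_numpy(dtype=float)
            out.loc[idx, c] = lowess(
                y, x, frac=span, it=0, return_sorted=False
            )
    return out


def extract_regions(
    series: pd.DataFrame,
    target_topology: int | str,
    threshold: float = 1.0,
    tol: float = 1e-9,
) -> list[GenomicInterval]:
    """Maximal runs of consecutive windows with target weight >= threshold.

    Runs are merged into intervals spanning the first window's start to the
    last window's end. Applies to raw weights (a threshold of 1.0 is only
    attainable before smoothing).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    col = (
        target_topology
        if isinstance(target_topology, str)
        else f"w_{target_topology}"
    )
    regions: list[GenomicInterval] = []
    for seqid, sub in series.groupby("seqid", sort=True):
        sub = sub.sort_values("start")
        run_start = None
        run_end = None
        for row in sub.itertuples():
            if getattr(row, col) >= threshold - tol:
                if run_start is None:
                    run_start = row.start
                run_end = row.end
            else:
                if run_start is not None:
                    regions.append(GenomicInterval(seqid, run_start, run_end))
                    run_start = None
        if run_start is not None:
            regions.append(GenomicInterval(seqid, run_start, run_end))
    return regions


# ---------------------------------------------------------------------------
# window trees from genotypes (neighbor joining on Hamming distances)


def infer_window_trees(
    matrix: GenotypeMatrix,
    window: int = 200,
    overlap: int = 40,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[WindowTree]:
    """Sliding-window neighbor-joining trees over genotype codes.

    Windows of ``window`` bp advance by ``window - overlap`` bp. Pairwise
    distances are mean absolute genotype-code differences over sites where
    both samples are called; windows with no variant site are skipped, and a
    sample with no called site in a window is dropped for that window.
    """
    import dendropy
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if overlap >= window:
        raise ValueError("overlap must be smaller than window")
    step = window - overlap
    out: list[WindowTree] = []
    for seqid, sub in matrix.sites.groupby("seqid", sort=True):
        pos0 = sub["pos"].to_numpy() - 1  # back to 0-based
        geno = matrix.genotypes[np.asarray(sub.index)]
        length = (
            seq_lengths[seqid] if seq_lengths is not None else int(pos0.max()) + 1
        )
        for start in range(0, max(length - overlap, 1), step):
            end = min(start + window, length)
            mask = (pos0 >= start) & (pos0 < end)
            if not mask.any():
                continue
            g = geno[mask].astype(float)
            g[g < 0] = np.nan
            called = ~np.isnan(g)
            keep = [i for i in range(g.shape[1]) if called[:, i].any()]
            if len(keep) < 4:
                continue
            labels = [matrix.samples[i] for i in keep]
            n = len(keep)
            dm = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    both = called[:, keep[a]] & called[:, keep[b]]
                    if both.any():
                        d = np.abs(g[both, keep[a]] - g[both, keep[b]]).mean()
                    else:
                        d = 0.0
                    dm[a, b] = dm[b, a] = d
            tree_sk = nj(DistanceMatrix(dm, labels))
            newick = str(tree_sk)
            tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
            out.append(
                WindowTree(GenomicInterval(seqid, start, end), tree, newick.strip())
            )
    return out
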