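import itertools
from fractions import Fraction

import dendropy
import numpy as np
import pandas as pd
import pytest

from intropipe.synthetic_data import SimulationParams, simulate_genotypes
from intropipe.topology_weighting import (
    DONOR_SISTER_TOPOLOGY,
    SPECIES_TOPOLOGY,
    TaxonGroups,
    enumerate_topologies,
    extract_regions,
    infer_window_trees,
    smooth_weights,
    weight_series,
    weight_window,
)
from conftest import random_binary_newick


def oracle_weights(newick, groups, topologies):
    """Independent re-enumeration: dendropy subtree extraction per combo.

    For every one-tip-per-group combination the induced tree is obtained via
    dendropy's taxon retention; its splits (leafsets under each node, mapped
    to group names) are compared with each candidate topology's split set.
    """
    names = groups.names
    ref = names[0]
    full = frozenset(names)
    g_of = groups.group_of()
    counts = [Fraction(0) for _ in topologies.topologies]
    k = len(names)
    for combo in itertools.product(*(groups.groups[g] for g in names)):
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        sub = tree.extract_tree_with_taxa_labels(combo)
        splits = set()
        for node in sub.preorder_node_iter():
            leaves = frozenset(
                g_of[l.taxon.label] for l in node.leaf_iter()
            )
            if 2 <= len(leaves) <= k - 2:
                side = full - leaves if ref in leaves else leaves
                splits.add(side)
        matches = [
            i
            for i, t in enumerate(topologies.topologies)
            if splits <= t.splits
        ]
        if len(splits) == k - 3:
            matches = [
                i for i, t in enumerate(topologies.topologies) if splits == t.splits
            ]
        share = Fraction(1, len(matches))
        for i in matches:
            counts[i] += share
    return counts


class TestEnumeration:
    @pytest.mark.parametrize(
        "k,expected", [(4, 3), (5, 15), (6, 105)]
    )
    def test_double_factorial_counts(self, k, expected):
        ts = enumerate_topologies([f"g{i}" for i in range(k)])
        assert len(ts) == expected
        assert len({t.splits for t in ts.topologies}) == expected

    def test_rejects_too_few_groups(self):
        with pytest.raises(ValueError):
            enumerate_topologies(["a", "b", "c"])

    def test_species_and_donor_topologies_present(self, five_topologies):
        si = five_topologies.index_of(SPECIES_TOPOLOGY)
        di = five_topologies.index_of(DONOR_SISTER_TOPOLOGY)
        assert si != di
        assert 0 <= si < 15 and 0 <= di < 15


class TestWeightWindow:
    def test_single_combination_unit_vector(self, five_groups, five_topologies):
        # one tip per group: the window tree IS one of the topologies
        tree = dendropy.Tree.get(
            data="((((focal_1,niloticus_1),aureus_1),mossambicus_1),urolepis_1);",
            schema="newick",
            preserve_underscores=True,
        )
        g = TaxonGroups({p: [f"{p}_1"] for p in five_groups.names})
        wv = weight_window(tree, g, five_topologies)
        si = five_topologies.index_of(SPECIES_TOPOLOGY)
        assert wv.total == 1
        assert wv.counts[si] == 1
        assert wv.weights.sum() == pytest.approx(1.0)

    def test_two_focal_tips_on_opposite_sides_split_half(self, five_topologies):
        # focal_1 groups with niloticus, focal_2 with mossambicus
        tree = dendropy.Tree.get(
            data="((((focal_1,niloticus_1),aureus_1),(focal_2,mossambicus_1)),urolepis_1);",
            schema="newick",
            preserve_underscores=True,
        )
        g = TaxonGroups(
            {
                "focal": ["focal_1", "focal_2"],
                "niloticus": ["niloticus_1"],
                "aureus": ["aureus_1"],
                "mossambicus": ["mossambicus_1"],
                "urolepis": ["urolepis_1"],
            }
        )
        wv = weight_window(tree, g, five_topologies)
        assert wv.total == 2
        nonzero = {i: c for i, c in enumerate(wv.counts) if c}
        assert set(nonzero.values()) == {Fraction(1)}
        assert len(nonzero) == 2

    def test_polytomy_weight_distributed_equally(self, five_topologies):
        tree = dendropy.Tree.get(
            data="(focal_1,niloticus_1,aureus_1,(mossambicus_1,urolepis_1));",
            schema="newick",
            preserve_underscores=True,
        )
        g = TaxonGroups({p: [f"{p}_1"] for p in
                         ["focal", "niloticus", "aureus", "mossambicus", "urolepis"]})
        wv = weight_window(tree, g, five_topologies)
        nonzero = [c for c in wv.counts if c]
        assert nonzero == [Fraction(1, 3)] * 3
        # discard policy: the only combination is unresolved -> nothing scorable
        with pytest.raises(ValueError, match="scorable"):
            weight_window(tree, g, five_topologies, polytomy="discard")

    def test_missing_tip_rejected(self, five_groups, five_topologies):
        tree = dendropy.Tree.get(data="(focal_1,(niloticus_1,aureus_1));", schema="newick", preserve_underscores=True)
        with pytest.raises(ValueError, match="absent"):
            weight_window(tree, five_groups, five_topologies)

    def test_matches_independent_oracle_on_random_trees(
        self, five_groups, five_topologies
    ):
        rng = np.random.default_rng(7)
        tips = [t for tips in five_groups.groups.values() for t in tips]
        for _ in range(10):
            nwk = random_binary_newick(rng, tips)
            tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
            wv = weight_window(tree, five_groups, five_topologies)
            assert wv.counts == oracle_weights(nwk, five_groups, five_topologies)
            assert wv.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestSmoothing:
    @staticmethod
    def series(values):
        n = len(values)
        df = pd.DataFrame(
            {
                "seqid": "LG1",
                "start": np.arange(n) * 160,
                "end": np.arange(n) * 160 + 200,
                "w_0": values,
            }
        )
        df["w_1"] = 1.0 - df["w_0"]
        return df

    def test_constant_series_unchanged(self):
        df = self.series([0.4] * 30)
        out = smooth_weights(df, span=0.2)
        assert np.allclose(out["w_0"], 0.4)

    def test_step_series_bounded_by_input_range(self):
        df = self.series([0.0] * 20 + [1.0] * 20)
        out = smooth_weights(df, span=0.3)
        assert out["w_0"].min() >= -1e-9 and out["w_0"].max() <= 1 + 1e-9

    def test_single_window_returned_with_warning(self):
        df = self.series([0.5])
        with pytest.warns(UserWarning, match="single window"):
            out = smooth_weights(df)
        assert out["w_0"].iloc[0] == 0.5


class TestExtractRegions:
    def test_no_window_at_threshold(self):
        df = TestSmoothing.series([0.5, 0.9, 0.99])
        assert extract_regions(df, 0, threshold=1.0) == []

    def test_three_consecutive_windows_span(self):
        # 200 bp windows with 40 bp overlap step 160: region = 200 + 2*160
        df = TestSmoothing.series([1.0, 1.0, 1.0, 0.2])
        (region,) = extract_regions(df, 0, threshold=1.0)
        assert (region.start, region.end) == (0, 520)

    def test_threshold_out_of_range_rejected(self):
        df = TestSmoothing.series([0.5])
        with pytest.raises(ValueError):
            extract_regions(df, 0, threshold=1.5)

    def test_synthetic_recovery_jaccard(self, five_groups, five_topologies):
        p = SimulationParams(
            seed=3, admixture_proportion=0.2, genome_length=50_000, n_scaffolds=1,
            n_sites=4_000, introgressed_block_length=10_000, ils_rate=0.1,
        )
        matrix, truth = simulate_genotypes(p)
        windows = infer_window_trees(matrix, 200, 40, seq_lengths={"LG1": 50_000})
        series = weight_series(windows, five_groups, five_topologies)
        di = five_topologies.index_of(DONOR_SISTER_TOPOLOGY)
        regions = extract_regions(series, di, threshold=1.0)

        def covered(ivs):
            s = set()
            for iv in ivs:
                s.update(range(iv.start, iv.end))
            return s

        a, b = covered(regions), covered(truth.introgressed_blocks)
        assert len(a & b) / len(a | b) >= 0.5
        # donor-sister weight is higher inside the true blocks
        mid = (series.start + series.end) / 2
        inside = np.zeros(len(series), bool)
        for blk in truth.introgressed_blocks:
            inside |= (mid >= blk.start) & (mid < blk.end)
        col = series[f"w_{di}"]
        assert col[inside].mean() > col[~inside].mean()


class TestInferWindowTrees:
    def test_identical_samples_are_adjacent_tips(self):
        # construct 6 samples; two identical at every site
        from conftest import make_matrix

        patterns = [
            (1, 1, 0, 0, 0),
            (1, 1, 1, 0, 0),
            (0, 0, 1, 1, 0),
            (1, 1, 0, 1, 0),
        ]
        m = make_matrix(patterns)
        windows = infer_window_trees(m, window=200, overlap=40)
        tree = windows[0].tree
        # focal_1 and niloticus_1 are identical at all sites: distance 0
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        d = pdm.patristic_distance(taxa["focal_1"], taxa["niloticus_1"])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_nj_recovers_additive_topology(self):
        import numpy as np

        from intropipe.io_formats import GenotypeMatrix

        # 4 samples with block-structured genotypes -> additive distances
        # pair (s1,s2) and (s3,s4) each share private variants
        geno = []
        for _ in range(20):
            geno.append([2, 2, 0, 0, 0])
        for _ in range(20):
            geno.append([0, 0, 2, 2, 0])
        patterns = geno
        from conftest import make_matrix

        m = make_matrix(patterns)
        windows = infer_window_trees(m, window=500, overlap=0)
        tree = windows[0].tree
        splits = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in tree.preorder_node_iter()
        }
        assert frozenset({"focal_1", "niloticus_1"}) in splits or frozenset(
            {"aureus_1", "mossambicus_1", "urolepis_1"}
        ) in splits

    def test_deterministic(self):
        p = SimulationParams(seed=5, n_sites=500, genome_length=20_000, n_scaffolds=1)
        m, _ = simulate_genotypes(p)
        w1 = infer_window_trees(m)
        w2 = infer_window_trees(m)
        assert [w.newick for w in w1] == [w.newick for w in w2]
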