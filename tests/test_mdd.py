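import json

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from mddpalm.mdd import (
    DEFAULT_GROUPS,
    DEFAULT_SCHEME,
    AAGroupScheme,
    ContingencyTable,
    MDDConfig,
    assign_subgroup,
    build_contingency,
    chi_square,
    composition_enrichment,
    mdd_cluster,
    position_frequency_matrix,
    select_split,
    tree_from_dict,
    tree_to_dict,
)
from mddpalm.sequence_io import AA20, Fragment
from mddpalm.synthetic import (
    MotifRule,
    SyntheticConfig,
    default_palm_config,
    generate,
    planted_offsets,
    single_motif_config,
)

from conftest import make_fragment, random_fragment


def brute_force_chi2(counts):
    """Direct evaluation of the chi-square formula with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    row = [counts[m, :].sum() for m in range(5)]
    col = [counts[:, n].sum() for n in range(5)]
    stat = 0.0
    for m in range(5):
        for n in range(5):
            expected = row[m] * col[n] / total
            if expected > 0:
                stat += (counts[m, n] - expected) ** 2 / expected
    return stat


class TestGroupScheme:
    def test_every_residue_mapped_once(self):
        assert set(DEFAULT_GROUPS) == set(AA20)

    def test_group_contents(self):
        assert DEFAULT_SCHEME.residues_of("basic") == frozenset("KRH")
        assert DEFAULT_SCHEME.residues_of("polar") == frozenset("GSTCQN")
        assert DEFAULT_SCHEME.residues_of("acidic") == frozenset("DE")
        assert DEFAULT_SCHEME.residues_of("aromatic") == frozenset("FWY")
        assert DEFAULT_SCHEME.residues_of("hydrophobic") == frozenset("AVLIMP")

    def test_x_maps_to_none(self):
        assert DEFAULT_SCHEME.group_index("X") is None

    def test_incomplete_mapping_rejected(self):
        bad = {aa: "polar" for aa in AA20[:-1]}
        with pytest.raises(ValueError, match="not mapped"):
            AAGroupScheme(mapping=bad)


class TestContingency:
    def test_single_cell(self):
        frags = [
            make_fragment("A" * 9 + "G" + "C" + "A" * 3 + "K" + "A" * 6, pid=f"p{i}")
            for i in range(10)
        ]
        table = build_contingency(frags, 4, -1)
        basic = DEFAULT_SCHEME.group_names.index("basic")
        polar = DEFAULT_SCHEME.group_names.index("polar")
        assert table.counts[basic, polar] == 10
        assert table.total == 10

    def test_total_conservation(self, rng):
        frags = [random_fragment(rng, pid=f"p{i}") for i in range(50)]
        assert build_contingency(frags, -3, 7).total == 50

    def test_x_at_offset_skipped(self):
        with_x = make_fragment("A" * 10 + "C" + "A" * 3 + "X" + "A" * 6, pid="x")
        plain = make_fragment("A" * 10 + "C" + "A" * 10, pid="a")
        assert build_contingency([with_x, plain], 4, 1).total == 1
        assert build_contingency([with_x, plain], 1, 2).total == 2

    def test_center_offset_rejected(self):
        frags = [make_fragment("A" * 10 + "C" + "A" * 10)]
        with pytest.raises(ValueError):
            build_contingency(frags, 0, 1)

    def test_identical_offsets_rejected(self):
        frags = [make_fragment("A" * 10 + "C" + "A" * 10)]
        with pytest.raises(ValueError):
            build_contingency(frags, 3, 3)


class TestChiSquare:
    def test_independence_gives_zero(self):
        row = np.array([10, 20, 5, 40, 25], dtype=float)
        col = np.array([8, 2, 30, 40, 20], dtype=float)
        counts = np.outer(row, col) / 100.0
        table = ContingencyTable(counts, 1, 2)
        assert chi_square(table) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_diagonal_table(self):
        counts = np.zeros((5, 5))
        counts[0, 0] = 10
        counts[1, 1] = 10
        table = ContingencyTable(counts, 1, 2)
        assert chi_square(table) == pytest.approx(20.0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            counts = rng.integers(0, 30, size=(5, 5)).astype(float)
            if counts.sum() == 0:
                continue
            table = ContingencyTable(counts, 1, 2)
            assert chi_square(table) == pytest.approx(
                brute_force_chi2(counts), abs=1e-9
            )

    def test_against_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.integers(1, 30, size=(5, 5)).astype(float)
            table = ContingencyTable(counts, 1, 2)
            stat = chi2_contingency(counts, correction=False).statistic
            assert chi_square(table) == pytest.approx(stat, abs=1e-9)

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 30, size=(5, 5)).astype(float)
        perm = rng.permutation(5)
        base = chi_square(ContingencyTable(counts, 1, 2))
        shuffled = chi_square(ContingencyTable(counts[perm][:, perm], 1, 2))
        assert shuffled == pytest.approx(base, abs=1e-9)

    def test_empty_table_errors(self):
        table = ContingencyTable(np.zeros((5, 5)), 1, 2)
        with pytest.raises(ValueError):
            chi_square(table)


class TestSelectSplit:
    def test_recovers_planted_motif(self):
        ds = generate(single_motif_config(seed=11))
        assert select_split(ds.positives) == (4, "basic")

    def test_agrees_with_exhaustive_dependence_scores(self):
        ds = generate(single_motif_config(seed=5))
        frags = ds.positives
        config = MDDConfig(n=10)
        offsets = [o for o in range(-10, 11) if o != 0]
        chis = {}
        for i in offsets:
            for j in offsets:
                if i < j:
                    t = build_contingency(frags, i, j)
                    chis[(i, j)] = chis[(j, i)] = chi_square(t)
        d = {
            i: sum(chis[(i, j)] for j in offsets if j != i)
            for i in offsets
            if max(chis[(i, j)] for j in offsets if j != i) > config.chi2_threshold
        }
        expected_offset = min(d, key=lambda i: (-d[i], abs(i), 0 if i < 0 else 1))
        offset, _ = select_split(frags, config=config)
        assert offset == expected_offset

    def test_uniform_fragments_give_none_at_strict_threshold(self):
        # With ~190 candidate position pairs, the default 34.3 cutoff
        # (per-pair p ~ 0.005) is crossed somewhere by chance in most
        # uniform datasets; a strict cutoff must never fire without signal.
        config = MDDConfig(chi2_threshold=60.0, n=10)
        for seed in range(8):
            cfg = SyntheticConfig(n=10, n_pos=400, n_neg=0, seed=seed)
            assert select_split(generate(cfg).positives, config=config) is None

    def test_single_fragment_gives_none(self, rng):
        assert select_split([random_fragment(rng)]) is None


class TestMDDCluster:
    def test_small_set_single_leaf(self, rng):
        frags = [random_fragment(rng, pid=f"p{i}") for i in range(50)]
        tree = mdd_cluster(frags, config=MDDConfig(max_cluster_size=100, n=10))
        assert len(tree.leaves()) == 1
        assert tree.leaves()[0].subgroup_id == "Palm1"

    def test_two_motif_first_split_has_larger_dependence(self):
        cfg = default_palm_config(seed=21)
        cfg.n_neg = 0
        frags = generate(cfg).positives
        tree = mdd_cluster(frags)
        assert len(tree.leaves()) >= 3
        first = tree.splits()[0]
        assert first == select_split(frags, config=tree.config)

    def test_leaves_partition_input(self):
        cfg = default_palm_config(seed=3)
        cfg.n_neg = 0
        frags = generate(cfg).positives
        tree = mdd_cluster(frags)
        seen = [f.key for leaf in tree.leaves() for f in leaf.members]
        assert len(seen) == len(frags)
        assert set(seen) == {f.key for f in frags}

    def test_leaf_ids_depth_first(self):
        cfg = default_palm_config(seed=3)
        cfg.n_neg = 0
        tree = mdd_cluster(generate(cfg).positives)
        ids = [leaf.subgroup_id for leaf in tree.leaves()]
        assert ids == [f"Palm{i}" for i in range(1, len(ids) + 1)]

    def test_match_children_carry_split_group(self):
        cfg = default_palm_config(seed=3)
        cfg.n_neg = 0
        tree = mdd_cluster(generate(cfg).positives)

        def check(node):
            if node.split_offset is None:
                return
            residues = tree.scheme.residues_of(node.split_group)
            stack = [node.match_child]
            while stack:
                child = stack.pop()
                if child.split_offset is None:
                    for f in child.members:
                        assert f.residue_at(node.split_offset) in residues
                else:
                    stack.extend([child.match_child, child.rest_child])
            check(node.match_child)
            check(node.rest_child)

        check(tree.root)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mdd_cluster([])


class TestAssignSubgroup:
    def test_single_leaf_tree(self, rng):
        frags = [random_fragment(rng, pid=f"p{i}") for i in range(10)]
        tree = mdd_cluster(frags, config=MDDConfig(max_cluster_size=100, n=10))
        assert assign_subgroup(random_fragment(rng), tree) == "Palm1"

    def test_routing_reproduces_training_leaf(self):
        cfg = default_palm_config(seed=13)
        cfg.n_neg = 0
        frags = generate(cfg).positives
        tree = mdd_cluster(frags)
        for leaf in tree.leaves():
            for f in leaf.members:
                assert assign_subgroup(f, tree) == leaf.subgroup_id

    def test_x_routes_to_rest(self):
        cfg = default_palm_config(seed=13)
        cfg.n_neg = 0
        tree = mdd_cluster(generate(cfg).positives)
        offset = tree.root.split_offset
        res = list("A" * 10 + "C" + "A" * 10)
        res[10 + offset] = "X"
        frag = Fragment("q", 1, "".join(res), "positive")
        node = tree.root
        expected = node.rest_child
        # walk manually: first hop must go to rest
        residues = tree.scheme.residues_of(node.split_group)
        assert frag.residue_at(offset) == "X"
        sid = assign_subgroup(frag, tree)
        rest_ids = {l.subgroup_id for l in _leaves_of(expected)}
        assert sid in rest_ids


def _leaves_of(node):
    if node.split_offset is None:
        return [node]
    return _leaves_of(node.match_child) + _leaves_of(node.rest_child)


class TestTreeSerialization:
    def test_json_round_trip_routing(self):
        cfg = default_palm_config(seed=2)
        cfg.n_neg = 0
        ds = generate(cfg)
        tree = mdd_cluster(ds.positives)
        clone = tree_from_dict(json.loads(json.dumps(tree_to_dict(tree))))
        for f in ds.positives[:100]:
            assert assign_subgroup(f, clone) == assign_subgroup(f, tree)


class TestCompositionEnrichment:
    @staticmethod
    def _ztest_oracle(k1, n1, k2, n2):
        from statsmodels.stats.proportion import proportions_ztest

        stat, p = proportions_ztest([k1, k2], [n1, n2])
        return stat, p

    def test_identical_sets_nothing_significant(self, rng):
        frags = [random_fragment(rng, pid=f"p{i}") for i in range(50)]
        report = composition_enrichment(frags, list(frags), alpha=0.01)
        assert (report.direction == "ns").all()

    def test_planted_lysine_enriched(self):
        rules = [([MotifRule(4, frozenset("K"), 0.8)], 1.0)]
        pos = generate(
            SyntheticConfig(n=10, n_pos=500, n_neg=0, rules=rules, seed=1)
        ).positives
        neg_cfg = SyntheticConfig(n=10, n_pos=0, n_neg=500, seed=2)
        neg = generate(neg_cfg).negatives
        report = composition_enrichment(pos, neg, alpha=0.01)
        row = report[(report.offset == 4) & (report.residue == "K")].iloc[0]
        assert row.direction == "enriched"
        assert row.pvalue < 0.01
        # cross-check the z statistic against statsmodels
        k1 = sum(f.residue_at(4) == "K" for f in pos)
        k2 = sum(f.residue_at(4) == "K" for f in neg)
        stat, p = self._ztest_oracle(k1, 500, k2, 500)
        assert row.z == pytest.approx(stat, abs=1e-9)
        assert row.pvalue == pytest.approx(p, abs=1e-12)

    def test_swapping_sets_flips_direction(self, rng):
        rules = [([MotifRule(4, frozenset("K"), 0.8)], 1.0)]
        pos = generate(
            SyntheticConfig(n=10, n_pos=300, n_neg=0, rules=rules, seed=3)
        ).positives
        neg = generate(SyntheticConfig(n=10, n_pos=0, n_neg=300, seed=4)).negatives
        fwd = composition_enrichment(pos, neg, alpha=0.01)
        rev = composition_enrichment(neg, pos, alpha=0.01)
        sig = fwd[fwd.direction != "ns"]
        assert len(sig) > 0
        for _, row in sig.iterrows():
            mirror = rev[(rev.offset == row.offset) & (rev.residue == row.residue)].iloc[0]
            assert {row.direction, mirror.direction} == {"enriched", "depleted"}

    def test_pfm_shared_with_pwm(self, rng):
        frags = [random_fragment(rng, pid=f"p{i}") for i in range(20)]
        pfm = position_frequency_matrix(frags)
        assert np.allclose(pfm.entries.sum(axis=0), 1.0)


class TestTermination:
    def test_terminates_on_random_inputs(self):
        for seed in range(5):
            cfg = SyntheticConfig(n=6, n_pos=80, n_neg=0, seed=seed)
            frags = generate(cfg).positives
            tree = mdd_cluster(
                frags, config=MDDConfig(max_cluster_size=10, min_subgroup_size=2, n=6)
            )
            seen = [f.key for leaf in tree.leaves() for f in leaf.members]
            assert sorted(seen) == sorted(f.key for f in frags)
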