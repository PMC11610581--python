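import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tandemdup.grouping import (
    DistanceMatrix,
    GroupingParams,
    build_nj_tree,
    decompose_groups,
    snv_distance_matrix,
    windowed_diversity,
)
from tandemdup.simulate import ClusterSpec, SimConfig, simulate_haplotype_pool

from conftest import mutated, random_seq, substituted
from _oracles import brute_force_pi


class TestSnvDistance:
    def test_identical_copies_have_zero_distance(self):
        dm = snv_distance_matrix({"a": "ACGT" * 2500, "b": "ACGT" * 2500})
        assert dm.value("a", "b") == 0.0

    def test_engineered_substitution_count(self, rng):
        a = random_seq(rng, 10_000)
        b = substituted(a, rng.choice(10_000, 23, replace=False), rng)
        dm = snv_distance_matrix({"a": a, "b": b})
        assert dm.value("a", "b") == pytest.approx(23.0)

    def test_symmetry_and_gap_handling(self, rng):
        a = random_seq(rng, 1_000)
        b = "-" * 100 + a[100:]
        c = mutated(a, 0.01, rng)
        dm = snv_distance_matrix({"a": a, "b": b, "c": c})
        assert np.allclose(dm.d, dm.d.T)
        assert dm.value("a", "b") == 0.0  # gaps excluded from comparison

    def test_zero_overlap_pair_rejected(self):
        with pytest.raises(ValueError, match="no comparable"):
            snv_distance_matrix({"a": "AC--", "b": "--GT"})


class TestNjTree:
    def test_four_taxon_additive_topology(self):
        # additive distances on tree ((a,b),(c,d)) with internal edge 10
        labels = ("a", "b", "c", "d")
        d = np.array(
            [
                [0, 4, 14, 16],
                [4, 0, 14, 16],
                [14, 14, 0, 8],
                [16, 16, 8, 0],
            ],
            dtype=float,
        )
        tree = build_nj_tree(DistanceMatrix(labels, d), outgroup="d")
        # a and b must be sisters
        a = tree.find("a")
        sisters = {t.name for t in a.parent.tips()}
        assert sisters == {"a", "b"}

    def test_three_taxon_tip_distances_recovered(self):
        labels = ("a", "b", "c")
        d = np.array([[0, 6, 8], [6, 0, 10], [8, 10, 0]], dtype=float)
        tree = build_nj_tree(DistanceMatrix(labels, d), outgroup="c")
        for x, y in itertools.combinations(labels, 2):
            got = tree.find(x).distance(tree.find(y))
            assert got == pytest.approx(d[labels.index(x), labels.index(y)])

    def test_simulated_truth_groups_are_monophyletic(self):
        cfg = SimConfig(
            seed=5, n_samples=3, n_truth_groups=3,
            cluster_specs=(ClusterSpec("c1", (3, 3), 5_000, 200),),
            flank_len=2_000, allelic_rate=10.0, paralog_divergence=80.0,
        )
        _, truth = simulate_haplotype_pool(cfg)
        seqs = {c.copy_id: c.sequence for c in truth.copies}
        rng = np.random.default_rng(0)
        seqs["outgroup"] = random_seq(rng, 5_000)
        dm = snv_distance_matrix(seqs)
        tree = build_nj_tree(dm, "outgroup")
        groups = {}
        for c in truth.copies:
            groups.setdefault(c.truth_group, set()).add(c.copy_id)
        for members in groups.values():
            mrca = tree.lca([tree.find(m) for m in members])
            clade = {t.name for t in mrca.tips()}
            assert clade == members

    def test_nonfinite_distances_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(("a", "b", "c"), d), outgroup="c")


def block_matrix(sizes, within, between, rng):
    """Distance matrix with block structure plus jitter."""
    labels = []
    group = []
    for gi, n in enumerate(sizes):
        for i in range(n):
            labels.append(f"g{gi}_m{i:02d}")
            group.append(gi)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if group[i] == group[j] else between
            d[i, j] = d[j, i] = base + rng.uniform(-0.1, 0.1) * base
    return DistanceMatrix(tuple(labels), d), group


class TestDecomposeGroups:
    def test_everything_within_cutoff_is_one_group(self, rng):
        dm, _ = block_matrix([12], within=10.0, between=10.0, rng=rng)
        labels = list(dm.labels) + ["out"]
        n = len(labels)
        d = np.zeros((n, n))
        d[:-1, :-1] = dm.d
        d[-1, :-1] = d[:-1, -1] = 300.0
        dm2 = DistanceMatrix(tuple(labels), d)
        tree = build_nj_tree(dm2, "out")
        part = decompose_groups(tree, dm2, GroupingParams(), outgroup="out")
        assert len(part.groups) == 1
        assert len(next(iter(part.groups.values()))) == 12

    def test_small_tight_clade_goes_unassigned(self, rng):
        dm, group = block_matrix([12, 8], within=10.0, between=90.0, rng=rng)
        labels = list(dm.labels) + ["out"]
        n = len(labels)
        d = np.zeros((n, n))
        d[:-1, :-1] = dm.d
        d[-1, :-1] = d[:-1, -1] = 400.0
        dm2 = DistanceMatrix(tuple(labels), d)
        tree = build_nj_tree(dm2, "out")
        part = decompose_groups(tree, dm2, GroupingParams(), outgroup="out")
        assert len(part.groups) == 1
        assert len(part.unassigned) == 8
        assert all(m.startswith("g1_") for m in part.unassigned)

    def test_partition_invariants_on_random_block_matrices(self, rng):
        params = GroupingParams()
        for _ in range(10):
            sizes = rng.integers(3, 15, size=int(rng.integers(2, 5)))
            dm, _ = block_matrix(list(sizes), within=12.0, between=120.0, rng=rng)
            labels = list(dm.labels) + ["out"]
            n = len(labels)
            d = np.zeros((n, n))
            d[:-1, :-1] = dm.d
            d[-1, :-1] = d[:-1, -1] = 500.0
            dm2 = DistanceMatrix(tuple(labels), d)
            tree = build_nj_tree(dm2, "out")
            part = decompose_groups(tree, dm2, params, outgroup="out")
            members = [m for ms in part.groups.values() for m in ms]
            assert sorted(members + list(part.unassigned)) == sorted(dm.labels)
            for ms in part.groups.values():
                assert len(ms) >= params.min_members
                idx = [dm2.labels.index(m) for m in ms]
                sub = dm2.d[np.ix_(idx, idx)]
                n = len(idx)
                assert sub.sum() / (n * (n - 1)) <= params.cutoff  # mean pairwise

    def test_monotonicity_in_cutoff_and_min_members(self, rng):
        dm, _ = block_matrix([12, 12, 12], within=10.0, between=60.0, rng=rng)
        labels = list(dm.labels) + ["out"]
        n = len(labels)
        d = np.zeros((n, n))
        d[:-1, :-1] = dm.d
        d[-1, :-1] = d[:-1, -1] = 300.0
        dm2 = DistanceMatrix(tuple(labels), d)
        tree = build_nj_tree(dm2, "out")
        counts = [
            len(decompose_groups(tree, dm2, GroupingParams(15.3, m, 10), outgroup="out").groups)
            for m in (1.5, 3.0, 5.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts_mm = [
            len(decompose_groups(tree, dm2, GroupingParams(15.3, 1.5, mm), outgroup="out").groups)
            for mm in (5, 10, 13)
        ]
        assert counts_mm == sorted(counts_mm, reverse=True)

    def test_max_statistic_is_stricter_than_mean(self, rng):
        """A single outlier copy splits its clade under the max reading but
        not under the default mean reading."""
        dm, _ = block_matrix([12], within=10.0, between=10.0, rng=rng)
        d = dm.d.copy()
        d[0, 1:12] = d[1:12, 0] = 30.0  # one hypermutated copy
        labels = list(dm.labels) + ["out"]
        full = np.zeros((13, 13))
        full[:-1, :-1] = d
        full[-1, :-1] = full[:-1, -1] = 300.0
        dm2 = DistanceMatrix(tuple(labels), full)
        tree = build_nj_tree(dm2, "out")
        mean_part = decompose_groups(tree, dm2, GroupingParams(), outgroup="out")
        max_part = decompose_groups(
            tree, dm2, GroupingParams(statistic="max"), outgroup="out"
        )
        assert len(next(iter(mean_part.groups.values()))) == 12
        assert all(len(ms) < 12 for ms in max_part.groups.values())

    def test_group_recovery_from_simulated_copies(self):
        """Three truth groups of 12 copies at ~10 within / ~60 between
        SNVs per 10 kbp are recovered exactly at the 22.95 cutoff."""
        cfg = SimConfig(
            seed=31, n_samples=3, n_truth_groups=3,
            cluster_specs=(ClusterSpec("c1", (6, 6), 11_000, 500),),
            flank_len=2_000, allelic_rate=10.0, paralog_divergence=60.0,
        )
        _, truth = simulate_haplotype_pool(cfg)
        seqs = {c.copy_id: c.sequence for c in truth.copies}
        rng = np.random.default_rng(1)
        seqs["outgroup"] = random_seq(rng, 11_000)  # distant, unbiased outgroup
        dm = snv_distance_matrix(seqs)
        tree = build_nj_tree(dm, "outgroup")
        part = decompose_groups(tree, dm, GroupingParams(15.3, 1.5, 10), outgroup="outgroup")
        got = part.group_of()
        labels = sorted(l for l in dm.labels if l != "outgroup")
        truth_map = {c.copy_id: c.truth_group for c in truth.copies}
        ari = adjusted_rand_score(
            [truth_map[l] for l in labels], [str(got[l]) for l in labels]
        )
        assert ari == 1.0


class TestWindowedDiversity:
    def test_identical_sequences_have_zero_pi(self, rng):
        s = random_seq(rng, 10_000)
        windows = windowed_diversity([s, s, s], window=1_000)
        assert all(w.pi == 0.0 for w in windows)

    def test_two_sequences_k_over_l(self, rng):
        a = random_seq(rng, 2_000)
        b = substituted(a, [10, 20, 30, 500], rng)  # 4 diffs in first window
        windows = windowed_diversity([a, b], window=1_000)
        assert windows[0].pi == pytest.approx(4 / 1_000)

    def test_minimum_window_has_low_percentile(self, rng):
        base = random_seq(rng, 100 * 500)
        noisy = mutated(base, 0.02, rng)
        # engineer window 37 to be identical (minimum pi)
        noisy = noisy[: 37 * 500] + base[37 * 500 : 38 * 500] + noisy[38 * 500 :]
        windows = windowed_diversity([base, noisy], window=500)
        lowest = min(windows, key=lambda w: w.pi)
        assert lowest.interval.start == 37 * 500
        assert lowest.percentile <= 5.0

    def test_zero_comparable_window_is_flagged(self):
        a = "ACGT" * 250 + "-" * 1_000
        b = "ACGT" * 250 + "A" * 1_000
        windows = windowed_diversity([a, b], window=1_000)
        assert not windows[0].flagged
        assert windows[1].flagged and windows[1].pi is None

    def test_matches_brute_force(self, rng):
        seqs = [random_seq(rng, 3_000)]
        for _ in range(4):
            s = mutated(seqs[0], 0.01, rng)
            if rng.random() < 0.5:  # sprinkle gaps
                pos = rng.integers(0, 2_900)
                s = s[:pos] + "-" * 50 + s[pos + 50 :]
            seqs.append(s)
        got = [w.pi for w in windowed_diversity(seqs, window=500, step=250)]
        want = brute_force_pi(seqs, window=500, step=250)
        for g, w in zip(got, want):
            assert g == pytest.approx(w)
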