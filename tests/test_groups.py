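"""Pooling, frequency matrices, ARI, row clustering, stability scan, groups."""

import itertools

import numpy as np
import pytest

from mapperms import (
    ConsistencyTable,
    Partition,
    adjusted_rand_index,
    bootstrap_ari,
    cluster_rows,
    consistency_scan,
    extract_representative_groups,
    frequency_matrix,
    pool_rums,
)
from mapperms.datasets import wine_consistency_scores, wine_marker_counts
from mapperms.groups import ViewResult
from mapperms.unique import RuMSSet


def make_rums(sample_id, vectors):
    vectors = np.asarray(vectors, float).reshape(-1, 2) if np.size(vectors) else \
        np.empty((0, 2))
    n = vectors.shape[0]
    if n:
        vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return RuMSSet(
        sample_id=sample_id,
        indices=np.arange(n),
        vectors=vectors,
        retention_index=np.arange(n),
        nearest_foreign=np.full(n, np.inf),
        three_delta=0.072,
    )


def view_from_freq(freq, shuffle_id=1):
    freq = np.asarray(freq, float)
    from mapperms.ballmapper import BallCover

    cover = BallCover(
        epsilon=0.24,
        landmark_indices=np.arange(freq.shape[1]),
        membership=[np.array([j]) for j in range(freq.shape[1])],
        n_points=freq.shape[1],
    )
    return ViewResult(
        shuffle_id=shuffle_id,
        seed=0,
        cover=cover,
        freq=freq,
        sample_ids=[f"S{k}" for k in range(freq.shape[0])],
        empty_rows=np.flatnonzero(~freq.any(axis=1)),
    )


class TestPoolRums:
    def test_single_sample_conservation(self):
        pooled = pool_rums([make_rums("A", np.eye(2)[[0, 1, 0]])])
        assert pooled.J == 3

    def test_published_counts_sum(self):
        counts = wine_marker_counts()
        sets = [
            make_rums(row.sample_id, [[1.0, 0.0]] * int(row.n_rums))
            for row in counts.itertuples()
        ]
        pooled = pool_rums(sets)
        assert pooled.J == counts["n_rums"].sum() == 2792

    def test_conservation_on_synthetic(self):
        rng = np.random.default_rng(0)
        sets = [
            make_rums(f"S{k}", rng.normal(size=(int(rng.integers(0, 5)), 2)))
            for k in range(6)
        ]
        if all(s.n == 0 for s in sets):
            pytest.skip("degenerate draw")
        pooled = pool_rums(sets)
        assert pooled.J == sum(s.n for s in sets)
        # every vector traceable to its source sample
        for k, s in enumerate(sets):
            assert (pooled.sample_of == k).sum() == s.n

    def test_all_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            pool_rums([make_rums("A", [])])


class TestFrequencyMatrix:
    def test_single_node_concentration(self):
        pooled = pool_rums([make_rums("A", [[1, 0], [1, 0.001]])])
        view = frequency_matrix(pooled, gamma=0.5, seed=None)
        assert view.freq.shape == (1, 1)
        assert view.freq[0, 0] == 1.0

    def test_two_sample_toy(self):
        # 1-D-like geometry on the circle: A near angle 0, B near angle 0.6
        a = [[np.cos(0.0), np.sin(0.0)], [np.cos(0.07), np.sin(0.07)]]
        b = [[np.cos(0.6), np.sin(0.6)]]
        pooled = pool_rums([make_rums("A", a), make_rums("B", b)])
        view = frequency_matrix(pooled, gamma=0.1, seed=None)
        assert view.L == 2
        np.testing.assert_allclose(view.freq, [[1.0, 0.0], [0.0, 1.0]])

    def test_overlapping_balls_count_twice(self):
        # middle vector lies in both balls: its sample's row sums beyond 1
        a = [[np.cos(0.0), np.sin(0.0)], [np.cos(0.08), np.sin(0.08)],
             [np.cos(0.16), np.sin(0.16)]]
        pooled = pool_rums([make_rums("A", a)])
        view = frequency_matrix(pooled, gamma=0.1, seed=None)
        assert view.L == 2
        assert view.freq.sum() > 1.0
        assert view.freq.max() <= 1.0

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(1)
        sets = [
            make_rums(f"S{k}", rng.normal(size=(6, 2))) for k in range(4)
        ]
        view = frequency_matrix(pool_rums(sets), gamma=0.4, seed=9)
        assert (view.freq >= 0).all() and (view.freq <= 1).all()


# --- ARI ------------------------------------------------------------------


def bruteforce_ari(a, b):
    """Pair-counting ARI oracle: O(n^2) over element pairs."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    n11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    n00 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] != b[j])
    n10 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] != b[j])
    n01 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] == b[j])
    total = len(pairs)
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def all_partitions(n):
    """Every set partition of range(n) as a label array."""
    if n == 0:
        yield []
        return
    for part in all_partitions(n - 1):
        k = max(part, default=-1) + 1
        for lab in range(k + 1):
            yield part + [lab]


class TestAdjustedRandIndex:
    def test_identical_partition_scores_one(self):
        p = Partition([0, 0, 1, 2, 2])
        assert adjusted_rand_index(p, p) == 1.0

    def test_crossed_four_element_example(self):
        a = Partition([0, 0, 1, 1])  # {1,2},{3,4}
        b = Partition([0, 1, 0, 1])  # {1,3},{2,4}
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 3, size=10)
            b = rng.integers(0, 4, size=10)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_index(b, a)
            )

    def test_matches_bruteforce_on_all_small_partitions(self):
        # exhaustive over every pair of partitions of 4 and 5 elements
        for n in (4, 5):
            parts = [list(p) for p in all_partitions(n)]
            for a in parts:
                for b in parts:
                    got = adjusted_rand_index(np.array(a), np.array(b))
                    assert got == pytest.approx(bruteforce_ari(a, b), abs=1e-12)

    def test_matches_bruteforce_and_sklearn_on_random(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        for n in (6, 7, 8):
            for _ in range(50):
                a = rng.integers(0, 4, size=n)
                b = rng.integers(0, 4, size=n)
                got = adjusted_rand_index(a, b)
                assert got == pytest.approx(bruteforce_ari(a, b), abs=1e-12)
                assert got == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_too_few_elements_is_error(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(np.array([0]), np.array([0]))

    def test_mismatched_lengths_is_error(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(np.array([0, 1]), np.array([0, 1, 2]))


class TestClusterRows:
    def test_q_equals_k_gives_singletons(self):
        view = view_from_freq(np.eye(4))
        part = cluster_rows(view, 4)
        assert part.Q == 4

    def test_planted_bipartition_recovered(self):
        freq = np.array([[1, 0, 0.0]] * 3 + [[0, 1, 0.0]] * 3)
        part = cluster_rows(view_from_freq(freq), 2)
        # compare against exhaustive best bipartition: the planted one
        assert part.labels[:3].tolist() == [part.labels[0]] * 3
        assert part.labels[3:].tolist() == [part.labels[3]] * 3
        assert part.labels[0] != part.labels[3]

    def test_q_one_is_error(self):
        with pytest.raises(ValueError):
            cluster_rows(view_from_freq(np.eye(3)), 1)

    def test_q_above_k_is_error(self):
        with pytest.raises(ValueError):
            cluster_rows(view_from_freq(np.eye(3)), 4)

    def test_zero_rows_become_singletons_with_warning(self):
        freq = np.array([[1, 0.0], [1, 0.01], [0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero rows"):
            part = cluster_rows(view_from_freq(freq), 2)
        assert part.Q == 2
        assert part.labels[2] not in part.labels[:2]


class TestBootstrapARI:
    def test_duplicated_groups_are_perfectly_stable(self):
        freq = np.array([[1, 0, 0.0]] * 4 + [[0, 1, 0.0]] * 4)
        assert bootstrap_ari(view_from_freq(freq), 2, B=50, seed=0) == 1.0

    def test_iid_noise_rows_score_below_structured_rows(self):
        # bootstrap partitions are clustered from the same rows as the
        # reference, so even structureless data scores above the ARI null
        # for independent partitions; it must still sit well below the
        # perfect stability of duplicated group structure.
        rng = np.random.default_rng(4)
        vals = [
            bootstrap_ari(
                view_from_freq(rng.uniform(size=(20, 12))), 4, B=100, seed=s
            )
            for s in range(5)
        ]
        assert np.mean(vals) < 0.7
        assert min(vals) > -0.15

    def test_independent_partitions_have_near_zero_ari(self):
        # the ≈0 null belongs to the ARI itself under independence
        rng = np.random.default_rng(11)
        vals = [
            adjusted_rand_index(
                rng.integers(0, 4, size=20), rng.integers(0, 4, size=20)
            )
            for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.03

    def test_zero_bootstraps_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_ari(view_from_freq(np.eye(3)), 2, B=0)


class TestConsistencyScan:
    def test_published_pq_row_selects_eleven(self):
        assert ConsistencyTable.select_q_star(wine_consistency_scores()) == 11

    def test_tie_break_prefers_smallest_q(self):
        assert ConsistencyTable.select_q_star({2: 7, 5: 7, 3: 7}) == 2

    def test_hand_built_threshold_crossings(self):
        # three views with designed stability: views 1–2 stable at Q=2
        stable = np.array([[1, 0, 0.0]] * 3 + [[0, 1, 0.0]] * 3)
        rng = np.random.default_rng(5)
        noisy = rng.uniform(size=(6, 3))
        views = [
            view_from_freq(stable, 1),
            view_from_freq(stable, 2),
            view_from_freq(noisy, 3),
        ]
        table = consistency_scan(views, q_range=[2, 3], B=40, seed=6)
        assert table.P[2] >= 2
        assert set(table.P) == {2, 3}
        assert 0 <= min(table.P.values()) <= max(table.P.values()) <= 3

    def test_p_invariant_to_view_order(self):
        rng = np.random.default_rng(7)
        freqs = [rng.uniform(size=(5, 4)) for _ in range(4)]
        views = [view_from_freq(f, i + 1) for i, f in enumerate(freqs)]
        t1 = consistency_scan(views, q_range=[2, 3], B=30, seed=8)
        t2 = consistency_scan(views[::-1], q_range=[2, 3], B=30, seed=8)
        assert t1.P == t2.P

    def test_q_range_excludes_all_singletons(self):
        views = [view_from_freq(np.eye(4), 1)]
        table = consistency_scan(views, q_range=range(2, 16), B=10, seed=0)
        assert max(table.q_range) == 3  # K - 1


class TestExtractGroups:
    def test_degenerate_multiset(self):
        part = Partition([0, 0, 1])
        partitions = {s: part for s in (1, 2, 3)}
        ari = {1: 0.6, 2: 0.8, 3: 1.0}
        groups = extract_representative_groups(partitions, ari, min_phi=1)
        assert len(groups) == 2
        for g in groups:
            assert g.phi == 3
            assert g.A == pytest.approx(0.8)

    def test_hand_written_multiset_matches_enumeration(self):
        parts = {
            1: Partition([0, 0, 1, 1, 2, 2]),
            2: Partition([0, 0, 1, 1, 2, 2]),
            3: Partition([0, 0, 0, 1, 2, 2]),
            4: Partition([0, 1, 1, 1, 2, 2]),
            5: Partition([0, 0, 1, 1, 1, 2]),
        }
        ari = {s: 0.5 + 0.1 * s for s in parts}
        groups = extract_representative_groups(parts, ari, min_phi=1)
        # brute-force recount over all subsets of the 6 samples
        from collections import Counter

        multiset = Counter()
        occurrences = {}
        for s, p in parts.items():
            for c in p.clusters():
                multiset[c] += 1
                occurrences.setdefault(c, []).append(s)
        assert len(groups) == len(multiset)
        by_members = {g.members: g for g in groups}
        for c, phi in multiset.items():
            g = by_members[c]
            assert g.phi == phi
            assert g.A == pytest.approx(np.mean([ari[s] for s in occurrences[c]]))
        # {4,5} = {0-indexed samples 4,5} recurs in views 1..4
        assert by_members[frozenset({4, 5})].phi == 4

    def test_min_phi_filter_and_sort_order(self):
        parts = {
            1: Partition([0, 0, 1]),
            2: Partition([0, 0, 1]),
            3: Partition([0, 1, 1]),
        }
        ari = {1: 1.0, 2: 1.0, 3: 1.0}
        groups = extract_representative_groups(parts, ari, min_phi=2)
        assert all(g.phi >= 2 for g in groups)
        phis = [g.phi for g in groups]
        assert phis == sorted(phis, reverse=True)

    def test_invariant_to_multiset_permutation(self):
        parts = {
            1: Partition([0, 0, 1, 1]),
            2: Partition([0, 1, 1, 1]),
            3: Partition([0, 0, 0, 1]),
        }
        ari = {1: 0.7, 2: 0.9, 3: 0.5}
        g1 = extract_representative_groups(parts, ari, min_phi=1)
        shuffled = {k: parts[k] for k in (3, 1, 2)}
        g2 = extract_representative_groups(shuffled, ari, min_phi=1)
        assert [(g.members, g.phi, g.A) for g in g1] == [
            (g.members, g.phi, g.A) for g in g2
        ]

    def test_empty_stable_set_is_error(self):
        with pytest.raises(ValueError):
            extract_representative_groups({}, {}, min_phi=1)

    def test_sample_ids_label_members(self):
        parts = {1: Partition([0, 0, 1])}
        groups = extract_representative_groups(
            parts, {1: 0.9}, min_phi=1, sample_ids=["AU1", "AU2", "FR1"]
        )
        assert {frozenset({"AU1", "AU2"}), frozenset({"FR1"})} == {
            g.members for g in groups
        }
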