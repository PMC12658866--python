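"""Stable sample-group discovery from pooled unique spectral vectors.

The ruMS vectors of all samples are pooled and summarized by Ball Mapper at
a coarser radius γ (= 3ε by default).  Because the greedy net is
order-dependent, a seeded shuffle of the pooled vectors yields a different
*view*: a cover with L(s) nodes and a K × L(s) frequency matrix M(s) whose
entry (k, l) is the fraction of sample k's ruMS vectors lying in node l.

Sample similarity is then read off the rows of M(s): hierarchical
clustering (cosine dissimilarity, average linkage) cut at Q clusters gives
a partition of the samples for each view.  Stability is scored by
bootstrapping the rows: ARI(s, Q) is the mean Adjusted Rand Index between
the original partition and partitions of bootstrap resamples.  The
consistency score P(Q) counts views whose Q-cluster solution is stable
(ARI ≥ 0.5); the optimal Q* maximizes it.  Finally, clusters recurring
across the stable views form *representative groups*, reported with their
occurrence frequency φ(C) and mean stable-view ARI A(C).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

from .ballmapper import BallCover, greedy_epsilon_net
from .unique import RuMSSet

logger = logging.getLogger(__name__)

__all__ = [
    "PooledRuMS",
    "ViewResult",
    "Partition",
    "ConsistencyTable",
    "RepresentativeGroup",
    "pool_rums",
    "frequency_matrix",
    "adjusted_rand_index",
    "cluster_rows",
    "bootstrap_ari",
    "consistency_scan",
    "extract_representative_groups",
]


@dataclass
class PooledRuMS:
    """All samples' ruMS vectors stacked, with provenance.

    ``vectors`` is (J, d); ``sample_of[j]`` gives the index (into
    ``sample_ids``) of the sample that contributed vector j; J equals the
    sum of the per-sample ruMS counts.
    """

    vectors: np.ndarray
    sample_of: np.ndarray
    sample_ids: list[str]
    counts: np.ndarray  # per-sample ruMS counts, aligned with sample_ids

    @property
    def J(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def K(self) -> int:
        return len(self.sample_ids)


def pool_rums(rums_sets: dict[str, RuMSSet] | list[RuMSSet]) -> PooledRuMS:
    """Concatenate per-sample ruMS vectors into one traceable pool.

    Samples with no ruMS vectors keep a slot (zero count) so downstream
    frequency rows stay aligned with the sample list; an error is raised
    only when *every* set is empty.
    """
    sets = list(rums_sets.values()) if isinstance(rums_sets, dict) else list(rums_sets)
    if not sets:
        raise ValueError("no RuMSSets given")
    counts = np.array([s.n for s in sets], dtype=int)
    if counts.sum() == 0:
        raise ValueError("all RuMSSets are empty: nothing to pool")
    sample_ids = [s.sample_id for s in sets]
    vectors = np.vstack([s.vectors for s in sets if s.n])
    sample_of = np.repeat(
        [i for i, s in enumerate(sets) if s.n], [s.n for s in sets if s.n]
    )
    return PooledRuMS(
        vectors=vectors,
        sample_of=np.asarray(sample_of, dtype=int),
        sample_ids=sample_ids,
        counts=counts,
    )


@dataclass
class ViewResult:
    """One randomized Ball Mapper view of the pooled ruMS vectors.

    ``freq`` is the K × L(s) frequency matrix: row k holds the fraction of
    sample k's ruMS vectors falling in each node (a vector in two
    overlapping balls counts in both columns, so row sums may exceed 1).
    Rows of samples with no ruMS vectors are zero and flagged in
    ``empty_rows``.
    """

    shuffle_id: int
    seed: int
    cover: BallCover
    freq: np.ndarray
    sample_ids: list[str]
    empty_rows: np.ndarray

    @property
    def L(self) -> int:
        return self.cover.n_landmarks


def frequency_matrix(
    pooled: PooledRuMS, gamma: float, seed: int | None, shuffle_id: int = 0
) -> ViewResult:
    """Build one randomized coarse view and its frequency matrix.

    The pooled vectors are permuted by the seeded shuffle, a greedy net at
    radius ``gamma`` is built in that order, and each sample's ruMS vectors
    are counted over the resulting nodes, normalized by the sample's ruMS
    count.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    perm = (
        np.random.default_rng(seed).permutation(pooled.J)
        if seed is not None
        else None
    )
    cover = greedy_epsilon_net(pooled.vectors, gamma, perm)
    K, L = pooled.K, cover.n_landmarks
    freq = np.zeros((K, L), dtype=float)
    for l, mem in enumerate(cover.membership):
        ks, cnt = np.unique(pooled.sample_of[mem], return_counts=True)
        freq[ks, l] = cnt
    empty = pooled.counts == 0
    denom = np.where(empty, 1, pooled.counts).astype(float)
    freq /= denom[:, None]
    if empty.any():
        logger.warning(
            "samples with no ruMS vectors have all-zero frequency rows: %s",
            [pooled.sample_ids[i] for i in np.flatnonzero(empty)],
        )
    return ViewResult(
        shuffle_id=shuffle_id,
        seed=-1 if seed is None else int(seed),
        cover=cover,
        freq=freq,
        sample_ids=list(pooled.sample_ids),
        empty_rows=np.flatnonzero(empty),
    )


# ---------------------------------------------------------------------------
# partitions and the Adjusted Rand Index


@dataclass(frozen=True)
class Partition:
    """Cluster labels over a fixed element set; exactly Q non-empty clusters."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=int).ravel()
        )

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def Q(self) -> int:
        return int(np.unique(self.labels).size)

    def clusters(self, ids: list | None = None) -> list[frozenset]:
        """Clusters as frozensets of element ids (default: integer positions)."""
        ids = list(range(self.n)) if ids is None else list(ids)
        out: dict[int, set] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(int(lab), set()).add(ids[i])
        return [frozenset(s) for s in out.values()]


def _ari_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """Hubert–Arabie ARI from two label arrays (vectorized contingency)."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    R, C = ai.max() + 1, bi.max() + 1
    cont = np.bincount(ai * C + bi, minlength=R * C).reshape(R, C)
    n = cont.sum()
    sum_comb = (cont * (cont - 1) // 2).sum()
    rows = cont.sum(axis=1)
    cols = cont.sum(axis=0)
    comb_r = (rows * (rows - 1) // 2).sum()
    comb_c = (cols * (cols - 1) // 2).sum()
    total = n * (n - 1) // 2
    expected = comb_r * comb_c / total if total else 0.0
    max_index = 0.5 * (comb_r + comb_c)
    if max_index == expected:  # both partitions trivial (all-singletons/one cluster)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def adjusted_rand_index(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Chance-corrected agreement of two partitions of the same elements.

    1 for identical partitions, ≈0 for independent ones; symmetric;
    computed under the permutation model from the contingency table.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.size != b.size:
        raise ValueError("partitions must cover the same element set")
    if a.size < 2:
        raise ValueError("ARI needs at least 2 elements")
    return _ari_from_labels(a, b)


# ---------------------------------------------------------------------------
# row clustering


def _cut_rows(matrix: np.ndarray, q_values: list[int]) -> np.ndarray:
    """Average-linkage/cosine cuts of the rows at each Q; (n, len(q)) labels.

    Rows that are all-zero have no direction under the cosine dissimilarity
    and are split off as their own clusters; the remaining rows are cut to
    make up the requested totals.
    """
    n = matrix.shape[0]
    zero = ~matrix.any(axis=1)
    nz = np.flatnonzero(~zero)
    n_zero = int(zero.sum())
    out = np.empty((n, len(q_values)), dtype=int)
    if n_zero:
        warnings.warn(
            f"{n_zero} all-zero rows assigned to singleton clusters",
            stacklevel=3,
        )
    if len(nz) == 0:
        raise ValueError("all rows are zero; nothing to cluster")
    q_eff = []
    for q in q_values:
        qe = q - n_zero
        if qe < 1:
            raise ValueError(
                f"Q={q} leaves no clusters for the {len(nz)} non-zero rows "
                f"after {n_zero} singleton zero rows"
            )
        q_eff.append(qe)
    cuttable = sorted({qe for qe in q_eff if qe < len(nz)})
    cuts: dict[int, np.ndarray] = {}
    if cuttable:
        dis = pdist(matrix[nz], metric="cosine")
        # cosine of nonnegative rows is in [0, 1]; clip fp jitter
        np.clip(dis, 0.0, None, out=dis)
        Z = linkage(dis, method="average")
        all_cuts = cut_tree(Z, n_clusters=cuttable)
        cuts = {qe: all_cuts[:, i] for i, qe in enumerate(cuttable)}
    for col, qe in enumerate(q_eff):
        labels_nz = cuts[qe] if qe < len(nz) else np.arange(len(nz))
        out[nz, col] = labels_nz
        out[np.flatnonzero(zero), col] = qe + np.arange(n_zero)
    return out


def cluster_rows(view: ViewResult, Q: int) -> Partition:
    """Partition the view's samples into exactly Q clusters.

    Agglomerative clustering of the K frequency rows under cosine
    dissimilarity with average linkage, cut to Q clusters (merge-order cut,
    so tied heights still yield exactly Q).
    """
    K = view.freq.shape[0]
    if not 2 <= Q <= K:
        raise ValueError(f"Q must satisfy 2 <= Q <= K={K}, got {Q}")
    labels = _cut_rows(view.freq, [Q])[:, 0]
    return Partition(labels)


def _bootstrap_replicate_aris(
    freq: np.ndarray,
    ref_labels: np.ndarray,
    q_values: list[int],
    rng: np.random.Generator,
) -> np.ndarray | None:
    """ARI at each Q for one row resample; None when <2 distinct samples."""
    K = freq.shape[0]
    draw = rng.integers(0, K, size=K)
    distinct, first_pos = np.unique(draw, return_index=True)
    if distinct.size < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boot = _cut_rows(freq[draw], q_values)
    out = np.empty(len(q_values))
    for col in range(len(q_values)):
        out[col] = _ari_from_labels(
            ref_labels[distinct, col], boot[first_pos, col]
        )
    return out


def bootstrap_ari(
    view: ViewResult, Q: int, B: int, seed: int | None = None
) -> float:
    """Bootstrap stability of the view's Q-cluster solution.

    The K rows are resampled with replacement B times; each resample is
    clustered and compared (ARI) to the reference partition, restricted to
    the distinct samples present in the resample (a duplicated row enters
    clustering once per draw but contributes a single label).  Returns the
    mean over the non-degenerate replicates; resamples with fewer than two
    distinct samples are skipped and logged.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    ref = _cut_rows(view.freq, [Q])
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(B):
        a = _bootstrap_replicate_aris(view.freq, ref, [Q], rng)
        if a is None:
            skipped += 1
        else:
            vals.append(a[0])
    if skipped:
        logger.info("bootstrap_ari: skipped %d degenerate resamples", skipped)
    if not vals:
        raise ValueError("every bootstrap resample was degenerate")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# the consistency scan


@dataclass
class ConsistencyTable:
    """ARI(s, Q) for every view and Q, the scores P(Q), and the optimum Q*.

    ``ari`` has shape (S, len(q_range)); ``partitions_qstar`` holds each
    stable view's Q*-cluster partition, keyed by shuffle id.
    """

    q_range: list[int]
    shuffle_ids: list[int]
    ari: np.ndarray
    P: dict[int, int]
    q_star: int
    s_star: list[int]
    ari_threshold: float
    B: int
    partitions_qstar: dict[int, Partition] = field(default_factory=dict)
    ari_qstar: dict[int, float] = field(default_factory=dict)

    @staticmethod
    def select_q_star(P: dict[int, int]) -> int:
        """argmax of P(Q); ties broken toward the smallest Q (parsimony)."""
        best = max(P.values())
        return min(q for q, v in P.items() if v == best)


def consistency_scan(
    views: list[ViewResult],
    q_range: range | list[int] = range(2, 16),
    B: int = 1000,
    threshold: float = 0.5,
    seed: int | None = None,
) -> ConsistencyTable:
    """Score cluster-count stability across randomized views.

    For each view s and each Q, ARI(s, Q) is the bootstrap stability of the
    Q-cluster solution (bootstrap resamples are shared across Q within a
    view: one linkage per resample, cut at every Q).  P(Q) counts views
    with ARI(s, Q) ≥ threshold; Q* maximizes P with smallest-Q tie-break,
    and the stable set S* collects views with ARI(s, Q*) ≥ threshold.

    Q values above K - 1 are dropped with a log message: Q = K (all
    singletons) is reproduced perfectly by construction under any resample,
    so its stability carries no information about cluster structure, and
    larger Q cannot be cut from K rows at all.
    """
    if not views:
        raise ValueError("need at least one view")
    K = views[0].freq.shape[0]
    q_values = [q for q in q_range if 2 <= q <= K - 1]
    if not q_values:
        raise ValueError(f"no feasible Q in {list(q_range)} for K={K}")
    if len(q_values) < len(list(q_range)):
        logger.info("restricted Q range to %s for K=%d", q_values, K)
    base = seed if seed is not None else 0
    ari = np.empty((len(views), len(q_values)))
    ref_labels: list[np.ndarray] = []
    for vi, view in enumerate(views):
        ref = _cut_rows(view.freq, q_values)
        ref_labels.append(ref)
        # seeded by shuffle id, not list position: P is order-invariant
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(base, view.shuffle_id))
        )
        acc = np.zeros(len(q_values))
        cnt = 0
        for _ in range(B):
            a = _bootstrap_replicate_aris(view.freq, ref, q_values, rng)
            if a is not None:
                acc += a
                cnt += 1
        if cnt == 0:
            raise ValueError(f"view {view.shuffle_id}: all resamples degenerate")
        ari[vi] = acc / cnt
    P = {
        q: int((ari[:, col] >= threshold).sum())
        for col, q in enumerate(q_values)
    }
    q_star = ConsistencyTable.select_q_star(P)
    col_star = q_values.index(q_star)
    stable = np.flatnonzero(ari[:, col_star] >= threshold)
    shuffle_ids = [v.shuffle_id for v in views]
    partitions = {
        shuffle_ids[vi]: Partition(ref_labels[vi][:, col_star]) for vi in stable
    }
    ari_qstar = {shuffle_ids[vi]: float(ari[vi, col_star]) for vi in stable}
    return ConsistencyTable(
        q_range=q_values,
        shuffle_ids=shuffle_ids,
        ari=ari,
        P=P,
        q_star=q_star,
        s_star=[shuffle_ids[vi] for vi in stable],
        ari_threshold=threshold,
        B=B,
        partitions_qstar=partitions,
        ari_qstar=ari_qstar,
    )


# ---------------------------------------------------------------------------
# representative groups


@dataclass(frozen=True)
class RepresentativeGroup:
    """A sample subset recurring as a cluster across stable views.

    ``phi`` is its multiplicity in the multiset of all stable-view
    clusters; ``A`` the mean ARI(s, Q*) over the views in which it occurs.
    """

    members: frozenset
    phi: int
    A: float

    def sorted_members(self) -> list:
        return sorted(self.members)


def extract_representative_groups(
    partitions: dict[int, Partition],
    ari_values: dict[int, float],
    min_phi: int = 50,
    sample_ids: list[str] | None = None,
) -> list[RepresentativeGroup]:
    """Mine recurring clusters from the stable views' partitions.

    Every distinct cluster (as a set of samples) in the multiset of
    stable-view clusters is enumerated; φ(C) is its multiplicity and A(C)
    the mean ARI(s, Q*) over the views containing it.  Groups with
    φ ≥ min_phi are returned sorted by φ descending, ties by size
    descending then lexicographic members.  Groups may overlap and a
    sample may appear in several — clusters vary slightly across views
    while stable cores recur.
    """
    if not partitions:
        raise ValueError("empty stable-view set")
    phi: dict[frozenset, int] = {}
    ari_sum: dict[frozenset, float] = {}
    for s, part in partitions.items():
        a = ari_values[s]
        for cluster in part.clusters(sample_ids):
            phi[cluster] = phi.get(cluster, 0) + 1
            ari_sum[cluster] = ari_sum.get(cluster, 0.0) + a
    groups = [
        RepresentativeGroup(members=c, phi=m, A=ari_sum[c] / m)
        for c, m in phi.items()
        if m >= min_phi
    ]
    groups.sort(key=lambda g: (-g.phi, -len(g.members), g.sorted_members()))
    return groups
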