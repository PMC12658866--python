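"""Representative (rMS) and relatively unique (ruMS) spectral vectors.

The landmarks of a greedy ε-net over one sample's normalized spectra are
its *representative* mass spectral vectors (rMS): a compact set that covers
the sample's spectral variety while keeping representatives pairwise more
than ε apart.  A representative is *relatively unique* (ruMS) when it lies
more than 3δ from every representative of every other sample — "relatively"
because uniqueness is judged against the other samples in the study, not
against chemical space at large.  The factor 3 buys a buffer: neighbors of
a ruMS vector within δ are intended to stay at least δ away from other
samples, which the locality audit checks empirically.

Parameters follow the regime δ = r·ε with 3δ < ε < 4δ (i.e. 0.25 < r < 1/3),
so the uniqueness distance 3δ sits just below the representative resolution ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ballmapper import greedy_epsilon_net
from .preprocess import SampleFeatureMatrix

__all__ = [
    "SeparationParams",
    "RMSSet",
    "RuMSSet",
    "LocalityViolation",
    "LocalityReport",
    "representative_vectors",
    "relatively_unique",
    "verify_locality",
]


@dataclass(frozen=True)
class SeparationParams:
    """Resolution ε and separation ratio r; δ = r·ε, coarse radius γ = 3ε.

    The constructor enforces 3δ < ε < 4δ, the regime in which the
    uniqueness cut 3δ is strictly inside the representative resolution ε
    while δ-neighborhoods still provide local support.
    """

    epsilon: float = 0.08
    r: float = 0.3

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.r <= 0:
            raise ValueError("epsilon and r must be positive")
        d = self.delta
        if not (3 * d < self.epsilon < 4 * d):
            raise ValueError(
                f"separation parameters must satisfy 3δ < ε < 4δ "
                f"(got ε={self.epsilon}, δ=rε={d}: 3δ={3 * d}, 4δ={4 * d}); "
                f"choose r in (0.25, 1/3)"
            )

    @property
    def delta(self) -> float:
        return self.r * self.epsilon

    @property
    def three_delta(self) -> float:
        return 3.0 * self.delta

    @property
    def gamma(self) -> float:
        return 3.0 * self.epsilon


@dataclass
class RMSSet:
    """One sample's representative vectors: ε-net landmarks over its nMS rows.

    ``indices`` are row positions into the sample's feature matrix (in
    landmark discovery order); ``retention_index`` maps them back to the
    sample's original retention ordering.
    """

    sample_id: str
    indices: np.ndarray
    vectors: np.ndarray
    retention_index: np.ndarray
    epsilon: float

    @property
    def n(self) -> int:
        return int(self.indices.size)


@dataclass
class RuMSSet:
    """One sample's relatively unique vectors (subset of its RMSSet).

    ``nearest_foreign`` is the distance from each ruMS vector to the
    closest representative of any other sample (inf when there is none).
    """

    sample_id: str
    indices: np.ndarray
    vectors: np.ndarray
    retention_index: np.ndarray
    nearest_foreign: np.ndarray
    three_delta: float

    @property
    def n(self) -> int:
        return int(self.indices.size)


def representative_vectors(
    matrix: SampleFeatureMatrix,
    params: SeparationParams,
    ordering: np.ndarray | int | None = None,
) -> RMSSet:
    """Select a sample's rMS vectors as greedy ε-net landmarks.

    For clustered spectra the landmark count is far below the spectrum
    count, making cross-sample comparison tractable.
    """
    if matrix.n == 0:
        raise ValueError(f"sample {matrix.sample_id!r}: empty feature matrix")
    cover = greedy_epsilon_net(matrix.values, params.epsilon, ordering)
    idx = cover.landmark_indices
    return RMSSet(
        sample_id=matrix.sample_id,
        indices=idx,
        vectors=matrix.values[idx],
        retention_index=matrix.retention_index[idx],
        epsilon=params.epsilon,
    )


_CHUNK_ROWS = 2048


def _min_cross_dist(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each query row to any ref row (chunked)."""
    out = np.full(query.shape[0], np.inf)
    for s in range(0, ref.shape[0], _CHUNK_ROWS):
        blk = cdist(query, ref[s : s + _CHUNK_ROWS])
        np.minimum(out, blk.min(axis=1), out=out)
    return out


def relatively_unique(
    rms_sets: list[RMSSet],
    params: SeparationParams,
    exhaustive_matrices: dict[str, SampleFeatureMatrix] | None = None,
) -> dict[str, RuMSSet]:
    """Keep each sample's representatives farther than 3δ from all others.

    Cross-sample comparison uses the other samples' representatives — that
    reduction is what makes the comparison tractable at scale.  Passing
    ``exhaustive_matrices`` switches to an audit mode that compares against
    the other samples' *full* spectrum sets instead (stricter, feasible
    only for small data).

    With a single sample the cross-sample condition is vacuous and every
    representative qualifies.  The strict inequality means a distance of
    exactly 3δ disqualifies.
    """
    if not rms_sets:
        raise ValueError("need at least one RMSSet")
    out: dict[str, RuMSSet] = {}
    cut = params.three_delta
    for k, rms in enumerate(rms_sets):
        if exhaustive_matrices is not None:
            others = [
                exhaustive_matrices[o.sample_id].values
                for j, o in enumerate(rms_sets)
                if j != k and exhaustive_matrices[o.sample_id].n
            ]
        else:
            others = [o.vectors for j, o in enumerate(rms_sets) if j != k and o.n]
        if others:
            foreign = np.vstack(others)
            nearest = _min_cross_dist(rms.vectors, foreign)
        else:
            nearest = np.full(rms.n, np.inf)
        keep = nearest > cut
        out[rms.sample_id] = RuMSSet(
            sample_id=rms.sample_id,
            indices=rms.indices[keep],
            vectors=rms.vectors[keep],
            retention_index=rms.retention_index[keep],
            nearest_foreign=nearest[keep],
            three_delta=cut,
        )
    return out


@dataclass(frozen=True)
class LocalityViolation:
    """One failed locality check: a δ-neighbor of a ruMS vector lies within
    δ of some other sample's spectrum."""

    sample_id: str
    rums_row: int
    neighbor_row: int
    other_sample_id: str
    other_row: int
    distance: float


@dataclass
class LocalityReport:
    """Outcome of the locality audit over all ruMS vectors."""

    violations: list[LocalityViolation] = field(default_factory=list)
    n_rums_checked: int = 0
    n_neighbor_pairs: int = 0

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_locality(
    rums: dict[str, RuMSSet],
    matrices: dict[str, SampleFeatureMatrix],
    params: SeparationParams,
) -> LocalityReport:
    """Audit the locality property of ruMS vectors.

    For every ruMS vector F of sample k, every same-sample spectrum F̄
    strictly within δ of F is checked against every spectrum of every other
    sample: the audit records a violation whenever that cross-sample
    distance fails to exceed δ.  The property is checked empirically, not
    assumed: in the working regime 3δ < ε < 4δ the triangle inequality
    alone does not guarantee it.
    """
    delta = params.delta
    report = LocalityReport()
    for sid, rset in rums.items():
        if rset.n == 0:
            continue
        mat = matrices[sid]
        report.n_rums_checked += rset.n
        # same-sample δ-neighbors of each ruMS vector
        d_self = cdist(rset.vectors, mat.values)
        for q in range(rset.n):
            nb = np.flatnonzero(d_self[q] < delta)
            nb = nb[nb != rset.indices[q]]  # the vector itself is not a neighbor
            if nb.size == 0:
                continue
            report.n_neighbor_pairs += int(nb.size)
            neighbors = mat.values[nb]
            for osid, omat in matrices.items():
                if osid == sid or omat.n == 0:
                    continue
                d_cross = cdist(neighbors, omat.values)
                bad = np.argwhere(d_cross <= delta)
                for bi, bj in bad:
                    report.violations.append(
                        LocalityViolation(
                            sample_id=sid,
                            rums_row=int(rset.indices[q]),
                            neighbor_row=int(nb[bi]),
                            other_sample_id=osid,
                            other_row=int(bj),
                            distance=float(d_cross[bi, bj]),
                        )
                    )
    return report
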