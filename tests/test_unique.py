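"""Separation parameters, rMS selection, ruMS detection, locality audit."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mapperms import (
    BinRange,
    RawSpectrum,
    SampleFeatureMatrix,
    SampleRun,
    SeparationParams,
    SynthConfig,
    generate_dataset,
    relatively_unique,
    representative_vectors,
    vectorize_run,
    verify_locality,
)
from tests.conftest import on_sphere


def matrix_from_rows(rows, sid="A"):
    rows = np.asarray(rows, float)
    rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
    n = rows.shape[0]
    return SampleFeatureMatrix(
        sample_id=sid,
        values=rows,
        bins=BinRange(1, rows.shape[1]),
        retention=np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
        retention_index=np.arange(n),
    )


class TestSeparationParams:
    def test_default_arithmetic(self, params):
        assert params.delta == pytest.approx(0.024)
        assert params.three_delta == pytest.approx(0.072)
        assert params.gamma == pytest.approx(0.24)

    @pytest.mark.parametrize("r", [0.2, 0.25, 0.34, 0.5])
    def test_regime_boundaries_rejected(self, r):
        with pytest.raises(ValueError, match="3δ < ε < 4δ"):
            SeparationParams(epsilon=0.08, r=r)

    @pytest.mark.parametrize("r", [0.26, 0.3, 0.33])
    def test_valid_ratios_accepted(self, r):
        p = SeparationParams(epsilon=0.08, r=r)
        assert 3 * p.delta < p.epsilon < 4 * p.delta


class TestRepresentativeVectors:
    def test_identical_spectra_give_single_representative(self, params):
        m = matrix_from_rows([[1, 0, 0]] * 10)
        assert representative_vectors(m, params).n == 1

    def test_two_motifs_give_two_representatives(self, params):
        rng = np.random.default_rng(0)
        d = 30
        a = np.zeros(d); a[:3] = 1.0
        b = np.zeros(d); b[10:13] = 1.0
        rows = []
        for base in (a, b):
            for _ in range(20):
                noisy = base + rng.normal(0, 0.004, size=d)
                rows.append(np.clip(noisy, 0, None))
        m = matrix_from_rows(rows)
        rms = representative_vectors(m, params)
        assert rms.n == 2
        # cover properties at radius ε over the sample's own vectors
        dist = cdist(m.values, rms.vectors)
        assert (dist < params.epsilon).any(axis=1).all()
        assert np.linalg.norm(rms.vectors[0] - rms.vectors[1]) > params.epsilon

    def test_empty_matrix_is_error(self, params):
        m = matrix_from_rows(np.eye(3))
        m.values = m.values[:0]
        with pytest.raises(ValueError, match="empty"):
            representative_vectors(m, params)


class TestRelativelyUnique:
    def test_single_sample_is_vacuously_unique(self, params):
        m = matrix_from_rows(np.eye(4))
        rms = representative_vectors(m, params)
        ru = relatively_unique([rms], params)
        assert ru["A"].n == rms.n
        assert np.isinf(ru["A"].nearest_foreign).all()

    def test_identical_samples_have_no_unique_vectors(self, params):
        a = representative_vectors(matrix_from_rows(np.eye(4), "A"), params)
        b = representative_vectors(matrix_from_rows(np.eye(4), "B"), params)
        ru = relatively_unique([a, b], params)
        assert ru["A"].n == 0 and ru["B"].n == 0

    def test_orthogonal_toy_both_unique(self, params):
        a = representative_vectors(matrix_from_rows([[1.0, 0.0]], "A"), params)
        b = representative_vectors(matrix_from_rows([[0.0, 1.0]], "B"), params)
        ru = relatively_unique([a, b], params)
        assert ru["A"].n == 1 and ru["B"].n == 1
        assert ru["A"].nearest_foreign[0] == pytest.approx(np.sqrt(2))

    def test_distance_exactly_three_delta_is_excluded(self, params):
        f = on_sphere({})
        g = on_sphere({1: params.three_delta})  # chordal ≈ 3δ to ~1e-7
        a = representative_vectors(matrix_from_rows([f], "A"), params)
        b = representative_vectors(matrix_from_rows([g], "B"), params)
        d = np.linalg.norm(f - g)
        ru = relatively_unique([a, b], params)
        expect = 1 if d > params.three_delta else 0
        assert ru["A"].n == expect

    def test_subset_and_cardinality_chain(self, params, small_matrices):
        rms = [representative_vectors(m, params) for m in small_matrices.values()]
        ru = relatively_unique(rms, params)
        for r in rms:
            u = ru[r.sample_id]
            assert set(u.indices) <= set(r.indices)
            m = small_matrices[r.sample_id]
            assert u.n <= r.n <= m.n

    def test_removing_a_sample_never_shrinks_others(self, params, small_matrices):
        rms = [representative_vectors(m, params) for m in small_matrices.values()]
        full = relatively_unique(rms, params)
        reduced = relatively_unique(rms[:-1], params)
        for r in rms[:-1]:
            assert set(full[r.sample_id].indices) <= set(reduced[r.sample_id].indices)

    def test_exhaustive_mode_is_at_most_as_permissive(self, params, small_matrices):
        # comparing against full spectrum sets adds constraints, so the
        # exhaustive ruMS sets are subsets of the representative-based ones
        rms = [representative_vectors(m, params) for m in small_matrices.values()]
        fast = relatively_unique(rms, params)
        strict = relatively_unique(rms, params, exhaustive_matrices=small_matrices)
        for sid in fast:
            assert set(strict[sid].indices) <= set(fast[sid].indices)

    def test_separation_reverifiable_by_bruteforce(self, params, small_matrices):
        rms = [representative_vectors(m, params) for m in small_matrices.values()]
        ru = relatively_unique(rms, params)
        for k, r in enumerate(rms):
            others = np.vstack([o.vectors for j, o in enumerate(rms) if j != k])
            d = cdist(r.vectors, others).min(axis=1)
            expect = set(r.indices[d > params.three_delta])
            assert set(ru[r.sample_id].indices) == expect


class TestEndToEndScaleInvariance:
    def test_scaling_raw_intensities_preserves_marker_sets(self, params):
        cfg = SynthConfig(
            K=3, n_spectra=60, bins=BinRange(29, 108), n_shared=4,
            planted_groups=((0, 1), (2,)), n_group_templates_per_member=2,
            seed=3,
        )
        runs, _ = generate_dataset(cfg)
        def markers(runs):
            mats = {r.sample_id: vectorize_run(r, cfg.bins) for r in runs}
            rms = [representative_vectors(mats[s], params) for s in sorted(mats)]
            ru = relatively_unique(rms, params)
            return (
                {r.sample_id: r.indices.tolist() for r in rms},
                {s: u.indices.tolist() for s, u in ru.items()},
            )
        base = markers(runs)
        scaled_runs = [
            SampleRun(
                r.sample_id,
                [
                    RawSpectrum(s.t_r1, s.t_r2, s.mz, 10.0 * s.intensity)
                    for s in r.spectra
                ],
                dict(r.metadata),
            )
            if r.sample_id == "S2" else r
            for r in runs
        ]
        assert markers(scaled_runs) == base


class TestVerifyLocality:
    def test_no_neighbors_within_delta_is_vacuous(self, params):
        a = matrix_from_rows(np.eye(4)[:2], "A")
        b = matrix_from_rows(np.eye(4)[2:], "B")
        rms = [representative_vectors(m, params) for m in (a, b)]
        ru = relatively_unique(rms, params)
        report = verify_locality(ru, {"A": a, "B": b}, params)
        assert report.ok and report.n_neighbor_pairs == 0

    def test_constructed_violation_reported_exactly_once(self, params):
        # sample A: ruMS F with neighbor F̄ at 0.02 < δ; sample B: point X at
        # 0.015 from F̄ (violation) plus B's landmark at > 3δ from F.
        F = on_sphere({})
        Fbar = on_sphere({1: 0.02})
        X = on_sphere({1: 0.02, 2: 0.015})
        LB = on_sphere({1: 0.02, 2: 0.075})  # |F−LB| ≈ 0.0776 > 3δ; covers X
        a = matrix_from_rows([F, Fbar], "A")
        b = matrix_from_rows([LB, X], "B")
        rms = [representative_vectors(m, params) for m in (a, b)]
        assert rms[0].n == 1 and rms[1].n == 1  # F and LB
        ru = relatively_unique(rms, params)
        assert ru["A"].n == 1  # F survives the 3δ rule
        report = verify_locality(ru, {"A": a, "B": b}, params)
        assert report.n_violations == 1
        v = report.violations[0]
        assert (v.sample_id, v.other_sample_id) == ("A", "B")
        assert v.distance == pytest.approx(0.015, abs=1e-4)

    def test_compliant_construction_has_zero_violations(self, params):
        # cross-sample points at ≥ 3δ from every ruMS vector: triangle
        # inequality guarantees δ-neighbors stay > δ away (3δ − δ > δ).
        F = on_sphere({})
        Fbar = on_sphere({1: 0.02})
        far = on_sphere({2: 0.09})  # 0.09 > 3δ from F, > 0.07 from F̄
        a = matrix_from_rows([F, Fbar], "A")
        b = matrix_from_rows([far], "B")
        rms = [representative_vectors(m, params) for m in (a, b)]
        ru = relatively_unique(rms, params)
        assert ru["A"].n >= 1
        report = verify_locality(ru, {"A": a, "B": b}, params)
        assert report.ok and report.n_neighbor_pairs >= 1
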