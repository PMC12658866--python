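"""Detect per-sample unique spectral markers (ruMS) on synthetic data.

Generates three samples sharing a background of common templates, each
carrying planted unique spectra, then runs representative-vector selection
and the 3δ cross-sample uniqueness rule.
"""

from mapperms import (
    BinRange,
    SeparationParams,
    SynthConfig,
    evaluate_recovery,
    generate_dataset,
    relatively_unique,
    representative_vectors,
    vectorize_run,
    verify_locality,
)

cfg = SynthConfig(
    K=3, n_spectra=150, bins=BinRange(29, 128), n_shared=6,
    n_unique_per_sample=2, planted_groups=((0,), (1,), (2,)), seed=7,
)
runs, truth = generate_dataset(cfg)
params = SeparationParams()  # ε = 0.08, r = 0.3 → δ = 0.024, 3δ = 0.072

matrices = {r.sample_id: vectorize_run(r, cfg.bins) for r in runs}
rms_sets = [representative_vectors(matrices[s], params) for s in sorted(matrices)]
rums = relatively_unique(rms_sets, params)

print(f"{'sample':<8}{'spectra':>8}{'rMS':>6}{'ruMS':>6}")
for r in rms_sets:
    print(f"{r.sample_id:<8}{matrices[r.sample_id].n:>8}{r.n:>6}{rums[r.sample_id].n:>6}")
# Each sample's ~150 spectra reduce to a handful of representatives (one
# per spectral motif); of those, only the planted unique templates survive
# the 3δ separation test against the other samples' representatives.

scores = evaluate_recovery(rums, truth, epsilon=params.epsilon)
print(f"planted-marker recall: {scores['recall']:.2f}, "
      f"precision: {scores['precision']:.2f}")

report = verify_locality(rums, matrices, params)
print(f"locality audit: {report.n_violations} violations over "
      f"{report.n_rums_checked} ruMS vectors")
# recall/precision of 1.00 means the detected ruMS vectors are exactly the
# planted unique templates; 0 locality violations means every δ-neighbor of
# a ruMS vector keeps > δ distance from all other samples' spectra.
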