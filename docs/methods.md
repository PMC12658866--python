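# Methods

This note documents the models and procedures implemented in `mapperms`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Spectral vectorization

A sample is a set of mass spectra indexed by the two retention times
(t_R1, t_R2) of a modulated GC×GC separation, ordered lexicographically.
Vectorization has three steps:

1. **Binning.** Bin *n* collects peaks with m/z in the half-open window
   [n − ½, n + ½); the bin value is the *maximum* intensity in the window.
   Max-binning emphasizes the most prominent (chemically relevant) features
   and suppresses baseline; a peak exactly at n + ½ belongs to bin n + 1.
   The global bin range [m, M] is the smallest integer range intersecting
   every observed m/z across all samples (d = M − m + 1 dimensions;
   default 29–600, d = 572). A peak outside the global range is a hard
   error — it means the range was computed from different data.
2. **Window exclusion.** Only spectra with t_R1 inside a closed retention
   window are analyzed; the beginning and end of a run (solvent front,
   bleed) are excluded rather than baseline-corrected. No baseline or blank
   subtraction is applied anywhere: max-binning, unit normalization and
   window exclusion are the only mitigations.
3. **Normalization.** Each binned vector is projected to the unit sphere
   (l2). This removes overall signal amount exactly: scaling every
   intensity of a sample by any c > 0 leaves the feature matrix unchanged
   to ≤ 1e−12 and every downstream marker/group output unchanged exactly
   (tested end-to-end). All-zero spectra have no direction; they are
   dropped with a logged count rather than imputed.

The retention index of a spectrum is its 0-based position in the
lexicographic ordering; original times are carried as metadata only — the
method uses retention solely for ordering, window exclusion and replicate
matching.

## Resolution calibration

The Ball Mapper radius ε should separate instrumental variability from
chemical difference. Given ≥ 2 replicate runs of the same material on the
same bin grid, distances between retention-matched normalized spectra are
collected over all replicate pairs and ε is their `coverage` empirical
quantile (default 0.95), computed as the lower (type-1) order statistic.
Matching is by identical (t_R1, t_R2) coordinates; when grids differ,
nearest-neighbor matching within a caller-supplied tolerance (typically
half the modulation period) is applied and logged — the pairing rule is a
package decision, exposed rather than hidden. Identical replicates give
all-zero distances; a configurable floor (default 1e−6) keeps ε positive.
The working default ε = 0.08 corresponds to such a calibration on
replicate wine measurements.

## Greedy ε-net and the Ball Mapper graph

Landmarks are selected greedily in a stated order: the first uncovered
point becomes a landmark; all points strictly within ε (open ball,
Euclidean metric on the ambient space of the unit sphere — no cosine
shortcut) are marked covered. This guarantees coverage (every point in at
least one ball) and separation (landmarks pairwise > ε; a point at
distance exactly ε is uncovered and later promoted). Node membership is
the *full* open-ball membership, not the greedy "first-coverer" set, so a
point may belong to several nodes; edges join nodes sharing at least one
point. Distance computations are chunked (~64 MB blocks) with results
independent of chunking (tested). Node identity is the landmark's point
index, stable across runs with the same ordering.

The net is order-dependent. The default is the dataset's native order;
ensemble modes permute points with a seeded generator. This
non-uniqueness is exploited deliberately: randomized orderings give an
ensemble of equally valid summaries over which stability can be measured.

Two node colorings are provided: mean component-sum of member vectors
(a proxy for how spread a unit-norm spectrum is over bins) and per-node
category proportions (summing to 1 per node).

## Markers: representative and relatively unique vectors

Per sample, the rMS set is the landmark set of the greedy ε-net over its
feature matrix — a compact cover of the sample's spectral variety that
makes cross-sample comparison tractable. With δ = rε and the regime
3δ < ε < 4δ enforced at construction (defaults ε = 0.08, r = 0.3 ⇒
δ = 0.024, 3δ = 0.072), a representative is *relatively unique* (ruMS)
when its distance to every representative of every other sample exceeds 3δ
strictly (a tie at exactly 3δ disqualifies). Cross-sample comparison uses
representatives only, not full spectra — that is the point of the
reduction; exact chunked brute-force distances are used rather than a
spatial index (d = 120–572 is too high for KD-trees to win, and exactness
is the contract). With a single sample the condition is vacuous and every
representative is unique.

The intended *locality* property — every same-sample neighbor within δ of
a ruMS vector stays > δ from every other sample's spectra — is **not** a
theorem in the working regime: the triangle inequality gives other-sample
representatives ≥ 3δ − δ = 2δ from the neighbor, but a non-representative
spectrum of another sample can sit up to ε > 3δ − 2δ closer. It is
therefore checked empirically by `verify_locality`, which reports every
violating (ruMS, neighbor, other-sample spectrum) triple. The trivial
self-pair (a ruMS vector as its own δ-neighbor) is excluded — it only
restates the 3δ rule.

## Group discovery

Pooled ruMS vectors (J = Σ_k |ruMS_k|, each traceable to its sample) are
summarized at the coarser radius γ = 3ε (default 0.24) across S seeded
random orderings. For view s, the frequency matrix M(s) ∈ [0,1]^{K×L(s)}
has entry (k, l) = (# of sample k's ruMS vectors in node l)/|ruMS_k| —
the codomain constrains but does not define the entry, and this definition
makes rows comparable across samples of different fingerprint richness. A
vector in two overlapping balls counts in both columns, so row sums may
exceed 1. Samples with no ruMS vectors get zero rows, flagged, and are
split off as singleton clusters during row clustering (cosine has no
direction for a zero row).

Rows are clustered agglomeratively under cosine dissimilarity with
*average linkage* (the dissimilarity is the method's stated choice; the
linkage is ours — average linkage is the common default for cosine and is
robust to unequal cluster sizes) and cut to exactly Q clusters by merge
order (`cut_tree`), so tied merge heights still yield exactly Q clusters.

Stability of a (view, Q) pair is the mean over B bootstrap resamples of
the rows of the ARI between the reference partition and the resample's
partition, restricted to the distinct samples present in the resample
(duplicated rows enter clustering once per draw but contribute one label);
resamples with < 2 distinct samples are skipped and logged. The ARI is the
Hubert–Arabie permutation-model form, implemented from the contingency
table (and cross-checked in the test suite against scikit-learn and a
brute-force pair-counting oracle). Within `consistency_scan`, bootstrap
resamples are shared across Q in a view — one linkage per resample, cut at
every Q — which changes nothing statistically and makes the S × Q × B scan
tractable; per-view randomness is seeded by the view's shuffle id, so
P(Q) is invariant to the order in which views are supplied.

P(Q) counts views with ARI(s, Q) ≥ 0.5; Q\* is the argmax with
smallest-Q tie-break (parsimony). The scanned range is clipped to
2 ≤ Q ≤ K − 1: the Q = K all-singleton partition is reproduced perfectly
by *any* resample by construction, so its "stability" is vacuous and would
shadow genuine structure whenever K ≤ q_max (with K = 34 samples and
Q ≤ 15 the issue never arises; it does at desk scale).

Representative groups are mined by brute force from the multiset of all
clusters occurring in the stable views' Q\*-partitions: φ(C) is the
multiplicity of the sample set C and A(C) the mean ARI(s, Q\*) over the
views containing it. Groups with φ ≥ min_phi (default 50 at S = 1000;
scale proportionally for smaller ensembles) are returned sorted by φ, then
size, then members; groups may overlap and one sample may appear in
several — cluster boundaries drift across views while stable cores recur.

### Defaults

| parameter | default | meaning |
|---|---|---|
| ε | 0.08 | representative resolution (replicate-calibrated) |
| r | 0.3 | δ = rε; constructor enforces 3δ < ε < 4δ, i.e. r ∈ (0.25, ⅓) |
| γ | 3ε = 0.24 | coarse radius of the pooled views |
| S | 1000 | randomized views |
| B | 1000 | bootstrap resamples per (view, Q) |
| Q range | 2–15 | scanned cluster counts (clipped to ≤ K − 1) |
| ARI threshold | 0.5 | stability cut for P(Q) and S\* |
| min_phi | 50 | reporting cut for representative groups |

All randomness flows from one base seed; per-view seeds are base + s and
per-view bootstrap streams are seeded by (base, shuffle id).

## Synthetic data: what it emulates and what it does not

The generator plants known structure so every stage is testable without
instrument data. Templates are sparse nonnegative vectors on pairwise
disjoint m/z support blocks (mutual normalized distance ≈ √2): a *shared*
background pool drawn by all samples, *unique* templates owned by one
sample, and *group* templates realized as perturbations of a per-group
anchor direction, v = cos(θ)·a + sin(θ)·u with member-specific orthogonal
u and sin(θ) = 0.10 — pairwise distance √2·sin(θ) ≈ 0.14 > 5δ (so each
member's copy survives the 3δ uniqueness rule against its siblings) while
all stay within ≈ 0.1 < γ of the anchor (so they co-locate in one node of
the coarse views and carry group signal). A template literally shared by
group members would be excluded by the uniqueness rule and carry no
signal — the anchor construction is what makes "group-specific chemistry"
representable. Planted templates are verified at generation time to sit
> 5δ from every other template; violations raise.

Each spectrum is scale × (template + truncated-Gaussian noise clipped at
0), with per-spectrum multiplicative scale (default U(0.5, 2)) — the
nuisance the normalization cancels — and peaks jittered uniformly within
their bins. Retention coordinates are a regular grid carrying no signal,
which the tests exploit. Defaults (support 3 bins, peak intensities
U(50, 150), noise sd 0.5 per bin) put the post-normalization perturbation
of a template copy at ~0.02–0.03: well inside ε (copies of one template
cover as one representative) and small against the 0.072 uniqueness cut.

Not emulated: chromatographic peak shapes, co-elution, retention drift,
mass-calibration error, heteroscedastic detector noise, and correlated
backgrounds. Passing recovery tests therefore show the *pipeline logic* is
sound under the stated geometry — they do not certify performance on real
chromatograms, where ε calibration and the noise structure do real work.

## Operating characteristics measured

At K = 8 samples, 400 spectra/sample, d = 120 (bins 29–148), planted
groups {3, 3, 2}, S = 100 views, B = 100 bootstraps, over 20 seeded runs
the pipeline attains planted-marker recall 1.0, selects Q\* equal to the
planted group count, and recovers all planted groups among the top-φ
representative groups in every run (see `scripts/acceptance.py` and
`tests/test_acceptance.py`, which recompute these rates). These problem
sizes are the package's validation scale; study-scale runs (S = B = 1000,
d = 572) use the same code paths.

A note on the bootstrap-stability null: because bootstrap partitions are
clustered from the same rows as the reference, structureless (i.i.d.) rows
score well above the ARI≈0 null of independent partitions — typically
0.3–0.6. The 0.5 threshold should be read as "more stable than typical
noise", not "better than chance agreement"; the ≈0 null applies to the ARI
itself under independence and is tested there.

## Known limitations

- The greedy net gives no approximation guarantee on landmark count; only
  coverage and separation are guaranteed.
- ruMS detection compares representatives, not full spectra; a sample's
  spectrum can be near another sample's spectrum without either being a
  representative. The `verify_locality` audit (and an exhaustive mode at
  small scale) bounds, but does not eliminate, this gap.
- Bootstrap stability of K rows with small K is granular; with K = 8,
  P(Q) resolves group structure but A(C) values cluster tightly.
- mzML ingestion assumes scan start times on a regular modulation grid;
  vendor-specific raw formats are out of scope.
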