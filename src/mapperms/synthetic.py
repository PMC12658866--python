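"""Synthetic GC×GC–MS-like datasets with planted ground truth.

Real runs contain hundreds of thousands of spectra per sample; the
generator emulates the same statistical structure at desk scale: most
spectra are noisy copies of *shared* background templates common to all
samples, a few are copies of *unique* templates planted for one sample
(the ground-truth fingerprints), and samples belonging to a planted group
carry *group* templates concentrated in a group-specific spectral region.

Geometry of the planted templates (after unit normalization):

* shared, unique and group-region templates live on pairwise disjoint m/z
  support blocks, so their mutual distances are ≈ √2 — far above every
  pipeline threshold;
* within a planted group, each member's group templates are perturbations
  of a common anchor direction: ``v = cos(θ)·anchor + sin(θ)·u`` with
  member-specific orthogonal directions u, giving pairwise distances
  √2·sin(θ) (kept above 5δ so each member's copy survives the ruMS cut)
  while all stay within ≈ θ of the anchor (well inside the coarse radius
  γ, so they co-locate in one node of the pooled views).

Each emitted spectrum is ``scale × (template + truncated Gaussian noise)``
with a per-spectrum multiplicative scale — the quantity the unit-norm
projection is designed to cancel — and peaks jittered inside their integer
m/z bins.  Retention coordinates are a regular grid carrying no signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import BinRange, RawSpectrum, SampleRun
from .unique import RuMSSet, SeparationParams

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "evaluate_recovery",
    "evaluate_group_recovery",
]

_SIN_THETA = 0.10  # group-template perturbation: pairwise √2·sinθ ≈ 0.141


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults emulate the study regime scaled down: a handful of samples,
    ~2,000 spectra each over integer m/z bins 29–600, a shared background
    of templates, one-to-few planted unique templates per sample, planted
    sample groups, per-spectrum multiplicative intensity variation, and
    small additive noise.
    """

    K: int = 8
    n_spectra: int = 2000
    bins: BinRange = field(default_factory=lambda: BinRange(29, 600))
    n_shared: int = 10
    n_unique_per_sample: int = 1
    planted_groups: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5), (6, 7))
    n_group_templates_per_member: int = 3
    n_copies_planted: int = 5
    noise_sd: float = 0.5
    scale_range: tuple[float, float] = (0.5, 2.0)
    support_size: int = 3
    peak_intensity: tuple[float, float] = (50.0, 150.0)
    modulation_s: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_spectra < 1:
            raise ValueError("K and n_spectra must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive and ordered")
        flat = [k for g in self.planted_groups for k in g]
        if sorted(flat) != list(range(self.K)):
            raise ValueError(
                "planted_groups must partition sample indices 0..K-1"
            )

    @property
    def n_groups(self) -> int:
        return len(self.planted_groups)


@dataclass
class GroundTruth:
    """What was planted: templates, per-spectrum assignments, the partition.

    ``template_catalog`` maps template id → {"vector": unit vector,
    "role": "shared" | "unique" | "group", "sample": owner sample id or
    None, "group": group index or None}.  ``spectrum_assignments`` maps
    (sample_id, spectrum position) → template id.  ``planted_partition``
    lists the planted groups as tuples of sample ids.
    """

    template_catalog: dict[str, dict]
    spectrum_assignments: dict[tuple[str, int], str]
    planted_partition: list[tuple[str, ...]]
    config: SynthConfig

    def planted_unique_templates(self) -> dict[str, list[str]]:
        """Template ids a sample should recover as ruMS (unique + group)."""
        out: dict[str, list[str]] = {}
        for tid, rec in self.template_catalog.items():
            if rec["role"] in ("unique", "group") and rec["sample"] is not None:
                out.setdefault(rec["sample"], []).append(tid)
        return out

    def to_json(self) -> str:
        cat = {
            tid: {
                "role": rec["role"],
                "sample": rec["sample"],
                "group": rec["group"],
                "support": np.flatnonzero(rec["vector"]).tolist(),
            }
            for tid, rec in self.template_catalog.items()
        }
        return json.dumps(
            {
                "template_catalog": cat,
                "spectrum_assignments": {
                    f"{sid}:{i}": tid
                    for (sid, i), tid in self.spectrum_assignments.items()
                },
                "planted_partition": [list(g) for g in self.planted_partition],
            }
        )


def _allocate_supports(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Assign pairwise-disjoint bin blocks to every template/direction."""
    d = cfg.bins.d
    s = cfg.support_size
    n_members_grouped = sum(len(g) for g in cfg.planted_groups if len(g) > 1)
    need = (
        cfg.n_shared * s
        + cfg.K * cfg.n_unique_per_sample * s
        + sum(s for g in cfg.planted_groups if len(g) > 1)  # anchors
        + n_members_grouped * cfg.n_group_templates_per_member  # 1-bin dirs
    )
    if need > d:
        raise ValueError(
            f"template separation unachievable: need {need} disjoint bins "
            f"but d={d}; reduce counts or support_size, or widen the bin range"
        )
    blocks: dict[str, np.ndarray] = {}
    cursor = 0

    def take(name: str, width: int) -> None:
        nonlocal cursor
        blocks[name] = np.arange(cursor, cursor + width)
        cursor += width

    for t in range(cfg.n_shared):
        take(f"shared_{t}", s)
    for k in range(cfg.K):
        for t in range(cfg.n_unique_per_sample):
            take(f"unique_s{k}_{t}", s)
    for g, grp in enumerate(cfg.planted_groups):
        if len(grp) > 1:
            take(f"anchor_g{g}", s)
            for k in grp:
                for t in range(cfg.n_group_templates_per_member):
                    take(f"dir_g{g}_s{k}_{t}", 1)
    return blocks


def _sparse_vector(d: int, support: np.ndarray, rng, lo: float, hi: float) -> np.ndarray:
    v = np.zeros(d)
    v[support] = rng.uniform(lo, hi, size=support.size)
    return v


def generate_dataset(cfg: SynthConfig) -> tuple[list[SampleRun], GroundTruth]:
    """Generate sample runs and the ground truth they were built from.

    Fully reproducible from ``cfg.seed``.  Raises when the requested
    template counts cannot be given disjoint supports within the bin range.
    Planted (unique and group) templates are verified to sit farther than
    5δ from every other template after normalization.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.bins.d
    lo_i, hi_i = cfg.peak_intensity
    blocks = _allocate_supports(cfg)
    sample_ids = [f"S{k + 1}" for k in range(cfg.K)]

    catalog: dict[str, dict] = {}
    for t in range(cfg.n_shared):
        v = _sparse_vector(d, blocks[f"shared_{t}"], rng, lo_i, hi_i)
        catalog[f"shared_{t}"] = {
            "vector": v, "role": "shared", "sample": None, "group": None,
        }
    for k, sid in enumerate(sample_ids):
        for t in range(cfg.n_unique_per_sample):
            v = _sparse_vector(d, blocks[f"unique_s{k}_{t}"], rng, lo_i, hi_i)
            catalog[f"unique_s{k}_{t}"] = {
                "vector": v, "role": "unique", "sample": sid, "group": None,
            }
    sin_t = _SIN_THETA
    cos_t = float(np.sqrt(1.0 - sin_t**2))
    for g, grp in enumerate(cfg.planted_groups):
        if len(grp) <= 1:
            continue
        anchor = _sparse_vector(d, blocks[f"anchor_g{g}"], rng, lo_i, hi_i)
        anchor = anchor / np.linalg.norm(anchor)
        for k in grp:
            for t in range(cfg.n_group_templates_per_member):
                u = np.zeros(d)
                u[blocks[f"dir_g{g}_s{k}_{t}"]] = 1.0
                vec = cos_t * anchor + sin_t * u
                amp = rng.uniform(lo_i, hi_i) * np.sqrt(cfg.support_size)
                catalog[f"group_g{g}_s{k}_{t}"] = {
                    "vector": amp * vec,
                    "role": "group",
                    "sample": sample_ids[k],
                    "group": g,
                }

    _check_separation(catalog)

    assignments: dict[tuple[str, int], str] = {}
    runs: list[SampleRun] = []
    slo, shi = cfg.scale_range
    for k, sid in enumerate(sample_ids):
        planted = [
            tid for tid, rec in catalog.items()
            if rec["role"] in ("unique", "group") and rec["sample"] == sid
        ]
        schedule = [tid for tid in planted for _ in range(cfg.n_copies_planted)]
        n_background = cfg.n_spectra - len(schedule)
        if n_background < 0:
            raise ValueError(
                "n_spectra too small for the planted template copies"
            )
        if cfg.n_shared:
            shared_ids = [f"shared_{t}" for t in range(cfg.n_shared)]
            schedule += [
                shared_ids[i]
                for i in rng.integers(0, cfg.n_shared, size=n_background)
            ]
        rng.shuffle(schedule)
        spectra = []
        grid_w = int(np.ceil(np.sqrt(len(schedule))))
        for i, tid in enumerate(schedule):
            assignments[(sid, i)] = tid
            template = catalog[tid]["vector"]
            noise = rng.normal(0.0, cfg.noise_sd, size=d) if cfg.noise_sd else 0.0
            inten = np.clip(template + noise, 0.0, None)
            inten *= rng.uniform(slo, shi)
            nz = np.flatnonzero(inten)
            mz = cfg.bins.m + nz + rng.uniform(-0.4, 0.4, size=nz.size)
            t_r1 = 60.0 + cfg.modulation_s * (i // grid_w)
            t_r2 = 0.5 + 7.0 * (i % grid_w) / grid_w
            spectra.append(
                RawSpectrum(t_r1=t_r1, t_r2=t_r2, mz=mz, intensity=inten[nz])
            )
        runs.append(
            SampleRun(
                sample_id=sid,
                spectra=spectra,
                metadata={
                    "country": f"G{_group_of(cfg, k)}",
                    "winery": f"W{k}",
                    "category": "synthetic",
                    "vintage": "n/a",
                },
            )
        )

    truth = GroundTruth(
        template_catalog=catalog,
        spectrum_assignments=assignments,
        planted_partition=[
            tuple(sample_ids[k] for k in grp) for grp in cfg.planted_groups
        ],
        config=cfg,
    )
    return runs, truth


def _group_of(cfg: SynthConfig, k: int) -> int:
    for g, grp in enumerate(cfg.planted_groups):
        if k in grp:
            return g
    raise ValueError(k)


def _check_separation(catalog: dict[str, dict], margin: float | None = None) -> None:
    """Planted templates must be > 5δ from every other template (normalized)."""
    if margin is None:
        margin = 5 * SeparationParams().delta
    ids = list(catalog)
    normed = np.array(
        [catalog[t]["vector"] / np.linalg.norm(catalog[t]["vector"]) for t in ids]
    )
    dist = squareform(pdist(normed))
    np.fill_diagonal(dist, np.inf)
    planted = [i for i, t in enumerate(ids) if catalog[t]["role"] != "shared"]
    for i in planted:
        j = int(np.argmin(dist[i]))
        if dist[i, j] <= margin:
            raise ValueError(
                f"template separation unachievable: {ids[i]} is within "
                f"{dist[i, j]:.4f} (≤ 5δ = {margin:.4f}) of {ids[j]}"
            )


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_recovery(
    rums: dict[str, RuMSSet],
    truth: GroundTruth,
    epsilon: float = SeparationParams().epsilon,
) -> dict:
    """Precision/recall of planted unique templates against detected ruMS.

    A planted template counts as recovered when some ruMS vector of its
    owner sample lies within ε of the normalized template; a ruMS vector
    counts as a true positive when it lies within ε of some planted
    template of its own sample.  With no predictions at all, recall is 0
    and precision is reported as NaN (undefined).
    """
    planted = truth.planted_unique_templates()
    if set(rums) - set(s for g in truth.planted_partition for s in g):
        raise ValueError("predictions reference samples absent from the truth")
    n_planted = sum(len(v) for v in planted.values())
    n_recovered = 0
    n_pred = 0
    n_true_pos = 0
    for sid, tids in planted.items():
        rset = rums.get(sid)
        vecs = rset.vectors if rset is not None and rset.n else None
        templates = np.array(
            [
                truth.template_catalog[t]["vector"]
                / np.linalg.norm(truth.template_catalog[t]["vector"])
                for t in tids
            ]
        )
        if vecs is None:
            continue
        dist = np.linalg.norm(
            vecs[:, None, :] - templates[None, :, :], axis=2
        )
        n_recovered += int((dist.min(axis=0) < epsilon).sum())
        n_true_pos += int((dist.min(axis=1) < epsilon).sum())
    for rset in rums.values():
        n_pred += rset.n
    recall = n_recovered / n_planted if n_planted else float("nan")
    precision = n_true_pos / n_pred if n_pred else float("nan")
    return {
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "n_predicted": n_pred,
        "recall": recall,
        "precision": precision,
    }


def evaluate_group_recovery(
    groups,
    truth: GroundTruth,
    top: int | None = None,
) -> dict:
    """Exact-set match rate of planted groups among the top-φ groups.

    ``groups`` is the φ-sorted output of the representative-group miner.
    A planted group is recovered when its exact member set appears among
    the top ``top`` groups (default: twice the number of planted groups).
    """
    planted = [frozenset(g) for g in truth.planted_partition]
    if top is None:
        top = 2 * len(planted)
    found = {g.members for g in groups[:top]}
    recovered = [tuple(sorted(p)) for p in planted if p in found]
    return {
        "n_planted_groups": len(planted),
        "n_recovered_groups": len(recovered),
        "recovered": recovered,
        "match_rate": len(recovered) / len(planted) if planted else float("nan"),
    }
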