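"""End-to-end pipeline: raw point tables → markers → stable sample groups.

Stages, in order: vectorize every sample (bin + normalize, retention-window
exclusion), select per-sample representative vectors (ε-net landmarks),
detect relatively unique vectors (3δ cross-sample rule), pool them, build S
randomized coarse views with frequency matrices, scan cluster counts for
bootstrap stability, and mine representative groups from the stable views.

Outputs in the artifact directory:

* ``summary.csv`` — per-sample |I_k|, |rMS|, |ruMS| (the data-reduction
  narrative, one row per sample);
* ``rums_<sample>.csv`` — per-sample ruMS rows with retention coordinates
  and distance to the nearest foreign representative;
* ``consistency.csv`` — the S × |Q| ARI table; ``pq.csv`` — P(Q) and Q*;
* ``groups.csv`` — representative groups with members, φ(C), A(C);
* ``manifest.json`` — parameters, seeds, per-stage counts and content
  hashes of every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .groups import (
    consistency_scan,
    extract_representative_groups,
    frequency_matrix,
    pool_rums,
)
from .io import read_metadata, read_sample_table, write_feature_matrix
from .preprocess import BinRange, SampleFeatureMatrix, SampleRun, vectorize_run
from .unique import relatively_unique, representative_vectors, verify_locality

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_pipeline_from_runs"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline from on-disk inputs named in the config."""
    if not config.input_dir:
        raise ValueError("config.input_dir is required")
    in_dir = Path(config.input_dir)
    meta = (
        read_metadata(config.metadata_path).set_index("sample_id")
        if config.metadata_path
        else None
    )
    runs = []
    paths = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in (".csv", ".parquet") and p.stem != "metadata"
    )
    if not paths:
        raise FileNotFoundError(f"no sample tables found in {in_dir}")
    for p in paths:
        md = (
            meta.loc[p.stem].to_dict()
            if meta is not None and p.stem in meta.index
            else {}
        )
        runs.append(read_sample_table(p, metadata=md))
    return run_pipeline_from_runs(runs, config)


def run_pipeline_from_runs(
    runs: list[SampleRun], config: PipelineConfig
) -> Path:
    """Run the pipeline on in-memory sample runs; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mapperms",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }
    params = config.separation
    bins = BinRange(config.mz_min, config.mz_max)

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    # --- stage: vectorize -------------------------------------------------
    try:
        matrices: dict[str, SampleFeatureMatrix] = {}
        for run in runs:
            m = vectorize_run(run, bins, config.retention_window)
            matrices[run.sample_id] = m
        manifest["stages"]["vectorize"] = {
            run.sample_id: {
                "n_spectra_in": len(run),
                "n_vectors": matrices[run.sample_id].n,
                "n_dropped": matrices[run.sample_id].n_dropped,
            }
            for run in runs
        }
    except Exception as exc:
        raise StageError("vectorize", exc) from exc

    # --- stage: representative vectors -----------------------------------
    try:
        rms_sets = [
            representative_vectors(matrices[sid], params)
            for sid in sorted(matrices)
        ]
    except Exception as exc:
        raise StageError("representative_vectors", exc) from exc

    # --- stage: relatively unique -----------------------------------------
    try:
        rums = relatively_unique(rms_sets, params)
    except Exception as exc:
        raise StageError("relatively_unique", exc) from exc

    counts = {
        r.sample_id: {
            "n_vectors": matrices[r.sample_id].n,
            "n_rms": r.n,
            "n_rums": rums[r.sample_id].n,
        }
        for r in rms_sets
    }
    manifest["stages"]["markers"] = counts
    for sid, c in counts.items():
        assert c["n_rums"] <= c["n_rms"] <= c["n_vectors"], sid
    summary = pd.DataFrame(
        [
            {"sample_id": sid, **c}
            for sid, c in counts.items()
        ]
    )
    emit("summary.csv", lambda p: summary.to_csv(p, index=False))
    for sid in sorted(rums):
        rset = rums[sid]
        mat = matrices[sid]
        pos = {int(ri): j for j, ri in enumerate(mat.retention_index)}
        rows = pd.DataFrame(
            {
                "retention_index": rset.retention_index,
                "t_r1_s": [
                    mat.retention[pos[int(ri)], 0] for ri in rset.retention_index
                ],
                "t_r2_s": [
                    mat.retention[pos[int(ri)], 1] for ri in rset.retention_index
                ],
                "nearest_foreign_rms_distance": rset.nearest_foreign,
            }
        )
        emit(f"rums_{sid}.csv", lambda p, rows=rows: rows.to_csv(p, index=False))

    # --- stage: pooled views + consistency scan ---------------------------
    try:
        pooled = pool_rums(rums)
        gamma = config.effective_gamma
        views = [
            frequency_matrix(pooled, gamma, seed=config.base_seed + s, shuffle_id=s)
            for s in range(1, config.shuffles + 1)
        ]
        table = consistency_scan(
            views,
            q_range=config.q_range,
            B=config.bootstraps,
            threshold=config.ari_threshold,
            seed=config.base_seed,
        )
    except Exception as exc:
        raise StageError("consistency_scan", exc) from exc
    manifest["stages"]["pool"] = {"J": pooled.J, "K": pooled.K}
    manifest["stages"]["consistency"] = {
        "P": {str(q): v for q, v in table.P.items()},
        "q_star": table.q_star,
        "n_stable": len(table.s_star),
    }
    ari_df = pd.DataFrame(
        table.ari, index=table.shuffle_ids, columns=table.q_range
    )
    ari_df.index.name = "shuffle"
    emit("consistency.csv", lambda p: ari_df.to_csv(p))
    pq = pd.DataFrame(
        {"Q": list(table.P), "P": list(table.P.values())}
    )
    pq["q_star"] = (pq["Q"] == table.q_star)
    emit("pq.csv", lambda p: pq.to_csv(p, index=False))

    # --- stage: representative groups -------------------------------------
    try:
        groups = extract_representative_groups(
            table.partitions_qstar,
            table.ari_qstar,
            min_phi=config.min_phi,
            sample_ids=views[0].sample_ids,
        )
    except Exception as exc:
        raise StageError("extract_representative_groups", exc) from exc
    gdf = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "members": ";".join(str(m) for m in g.sorted_members()),
                "size": len(g.members),
                "phi": g.phi,
                "A": round(g.A, 6),
            }
            for i, g in enumerate(groups)
        ],
        columns=["rank", "members", "size", "phi", "A"],
    )
    emit("groups.csv", lambda p: gdf.to_csv(p, index=False))

    if config.export_views:
        from .ballmapper import build_graph

        for view in views:
            g = build_graph(pooled.vectors, view.cover)
            emit(
                f"view_{view.shuffle_id}.graphml",
                lambda p, g=g: g.write_graphml(p),
            )
            emit(
                f"view_{view.shuffle_id}.json",
                lambda p, g=g: Path(p).write_text(g.to_json(include_members=False)),
            )

    # locality audit is cheap relative to the scan and surfaces in the manifest
    audit = verify_locality(rums, matrices, params)
    manifest["stages"]["locality_audit"] = {
        "n_rums_checked": audit.n_rums_checked,
        "n_neighbor_pairs": audit.n_neighbor_pairs,
        "n_violations": audit.n_violations,
    }
    for sid in sorted(matrices):
        emit(
            f"matrix_{sid}.parquet",
            lambda p, sid=sid: write_feature_matrix(matrices[sid], p),
        )
        manifest["files"][f"matrix_{sid}.parquet.json"] = _sha256(
            out / f"matrix_{sid}.parquet.json"
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
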