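"""Readers and writers for the package's on-disk formats.

The canonical per-sample input is a long-format table (CSV or Parquet by
extension) with columns ``t_r1_s, t_r2_s, mz, intensity``: one row per
detected peak, grouped by retention coordinate into spectra.  Sample
metadata travels in a separate CSV with columns
``sample_id, country, winery, category, vintage``.  An optional mzML
reader maps scan start times onto the (t_r1, t_r2) grid via the stated
modulation period.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BinRange, RawSpectrum, SampleFeatureMatrix, SampleRun

__all__ = [
    "REQUIRED_COLUMNS",
    "read_sample_table",
    "write_sample_table",
    "read_metadata",
    "write_metadata",
    "write_feature_matrix",
    "read_feature_matrix",
    "read_mzml",
]

REQUIRED_COLUMNS = ("t_r1_s", "t_r2_s", "mz", "intensity")


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def read_sample_table(
    path, sample_id: str | None = None, metadata: dict | None = None
) -> SampleRun:
    """Read one sample's long-format peak table into a SampleRun.

    Rows sharing a (t_r1_s, t_r2_s) coordinate form one spectrum; spectra
    are ordered lexicographically.  Malformed cells are reported with the
    offending row and column; row count is conserved into peak counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"{path}: empty sample table")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at row {row}"
            )
        df[col] = vals
    if (df["intensity"] < 0).any():
        row = int(df.index[df["intensity"] < 0][0])
        raise ValueError(
            f"{path}: negative intensity at row {row} (column 'intensity')"
        )
    if (df["mz"] <= 0).any():
        row = int(df.index[df["mz"] <= 0][0])
        raise ValueError(f"{path}: non-positive m/z at row {row} (column 'mz')")
    spectra = []
    for (t1, t2), grp in df.groupby(["t_r1_s", "t_r2_s"], sort=True):
        spectra.append(
            RawSpectrum(
                t_r1=float(t1),
                t_r2=float(t2),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    sid = sample_id if sample_id is not None else path.stem
    return SampleRun(sample_id=sid, spectra=spectra, metadata=metadata or {})


def write_sample_table(run: SampleRun, path) -> None:
    """Write a SampleRun back to the canonical long format."""
    path = Path(path)
    rows = {
        "t_r1_s": np.concatenate(
            [np.full(s.n_peaks, s.t_r1) for s in run.spectra]
        ) if run.spectra else np.array([]),
        "t_r2_s": np.concatenate(
            [np.full(s.n_peaks, s.t_r2) for s in run.spectra]
        ) if run.spectra else np.array([]),
        "mz": np.concatenate([s.mz for s in run.spectra])
        if run.spectra else np.array([]),
        "intensity": np.concatenate([s.intensity for s in run.spectra])
        if run.spectra else np.array([]),
    }
    df = pd.DataFrame(rows)
    if path.suffix.lower() == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


METADATA_COLUMNS = ("sample_id", "country", "winery", "category", "vintage")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata CSV (sample_id, country, winery, category, vintage)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_metadata(runs: list[SampleRun], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            **{c: r.metadata.get(c, "") for c in METADATA_COLUMNS[1:]},
        }
        for r in runs
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)


def write_feature_matrix(matrix: SampleFeatureMatrix, path) -> None:
    """Write a vectorized sample as Parquet plus a JSON sidecar.

    The sidecar records the bin range, dropped-spectrum count and
    metadata, so the matrix is self-describing on re-read.
    """
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, columns=[str(b) for b in matrix.bins.bins]
    )
    df.insert(0, "retention_index", matrix.retention_index)
    df.insert(1, "t_r1_s", matrix.retention[:, 0])
    df.insert(2, "t_r2_s", matrix.retention[:, 1])
    df.to_parquet(path, index=False)
    sidecar = {
        "sample_id": matrix.sample_id,
        "bin_range": [matrix.bins.m, matrix.bins.M],
        "n_spectra": matrix.n,
        "n_dropped": matrix.n_dropped,
        "metadata": matrix.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_matrix(path) -> SampleFeatureMatrix:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_parquet(path)
    bins = BinRange(*meta["bin_range"])
    return SampleFeatureMatrix(
        sample_id=meta["sample_id"],
        values=df[[str(b) for b in bins.bins]].to_numpy(),
        bins=bins,
        retention=df[["t_r1_s", "t_r2_s"]].to_numpy(),
        retention_index=df["retention_index"].to_numpy(dtype=int),
        n_dropped=meta["n_dropped"],
        metadata=meta.get("metadata", {}),
    )


def read_mzml(path, modulation_s: float = 8.0, sample_id: str | None = None) -> SampleRun:
    """Read an mzML file, folding scan start times onto the (t_r1, t_r2) grid.

    The first retention time is the start of the modulation cycle
    containing the scan; the second is the offset within the cycle.
    Requires pyteomics (optional dependency).
    """
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "mzML input requires the optional 'pyteomics' dependency"
        ) from exc
    path = Path(path)
    spectra = []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level", 1) != 1:
                continue
            t = float(
                scan["scanList"]["scan"][0]["scan start time"]
            )  # minutes per mzML convention
            t_s = t * 60.0
            t_r1 = (t_s // modulation_s) * modulation_s
            t_r2 = t_s - t_r1
            spectra.append(
                RawSpectrum(
                    t_r1=t_r1,
                    t_r2=t_r2,
                    mz=np.asarray(scan["m/z array"], dtype=float),
                    intensity=np.asarray(scan["intensity array"], dtype=float),
                )
            )
    return SampleRun(
        sample_id=sample_id or path.stem, spectra=spectra, metadata={}
    )
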