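"""Vectorization of GC×GC HR-TOF-MS point data.

Each sample is a collection of high-resolution mass spectra indexed by the
two retention times (t_R1, t_R2) of the modulated separation.  A spectrum is
turned into a *discrete mass spectral* (dMS) vector by taking, in every
integer m/z bin ``[n - 1/2, n + 1/2)``, the maximum intensity observed there
(max-binning emphasizes the most prominent, chemically relevant features and
damps baseline noise).  Projecting the dMS vector onto the unit sphere gives
the *normalized* (nMS) vector, which is invariant to the overall signal
amount, so only the shape of the spectrum — the compound mixture — matters.

The resolution parameter ``epsilon`` used downstream by the Ball Mapper
cover is calibrated here from replicate runs of the same material: it is the
coverage-quantile (default 95%) of Euclidean distances between
retention-matched nMS vectors of the replicates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectrum",
    "SampleRun",
    "BinRange",
    "SampleFeatureMatrix",
    "EmptySpectrumError",
    "discretize_spectrum",
    "global_bin_range",
    "normalize",
    "exclude_retention_window",
    "vectorize_run",
    "calibrate_resolution",
]

UNIT_NORM_TOL = 1e-9


class EmptySpectrumError(ValueError):
    """Raised when an all-zero spectrum is normalized."""


@dataclass(frozen=True)
class RawSpectrum:
    """One mass spectrum at a single (t_R1, t_R2) retention coordinate.

    Parameters
    ----------
    t_r1, t_r2 : float
        First- and second-dimension retention times in seconds.
    mz : ndarray
        Peak m/z values in Da, strictly positive.
    intensity : ndarray
        Peak intensities in counts, nonnegative; same length as ``mz``.
    """

    t_r1: float
    t_r2: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and mz.min() <= 0:
            raise ValueError("m/z values must be strictly positive")
        if inten.size and inten.min() < 0:
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class SampleRun:
    """All spectra of one sample, ordered lexicographically by (t_r1, t_r2)."""

    sample_id: str
    spectra: list[RawSpectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(s.t_r1, s.t_r2) for s in self.spectra]
        if keys != sorted(keys):
            self.spectra = sorted(self.spectra, key=lambda s: (s.t_r1, s.t_r2))
            keys = [(s.t_r1, s.t_r2) for s in self.spectra]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"sample {self.sample_id!r}: duplicate (t_r1, t_r2) coordinates"
            )

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class BinRange:
    """Global integer m/z bin range [m, M]; dimension d = M - m + 1."""

    m: int
    M: int

    def __post_init__(self) -> None:
        if self.m > self.M:
            raise ValueError(f"BinRange requires m <= M, got ({self.m}, {self.M})")

    @property
    def d(self) -> int:
        return self.M - self.m + 1

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.m, self.M + 1)


@dataclass
class SampleFeatureMatrix:
    """Unit-norm nMS vectors of one sample as rows of a feature matrix.

    ``values`` has shape (n_spectra, d); every row has l2 norm 1.
    ``retention`` holds the (t_r1, t_r2) coordinate of each row and
    ``retention_index`` the 0-based position of each row in the sample's
    original lexicographic retention ordering (rows of all-zero spectra are
    dropped, so indices need not be contiguous).
    """

    sample_id: str
    values: np.ndarray
    bins: BinRange
    retention: np.ndarray  # (n, 2) of (t_r1, t_r2)
    retention_index: np.ndarray  # (n,) int
    n_dropped: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.bins.d:
            raise ValueError("values must be (n, d) matching the BinRange")
        norms = np.linalg.norm(v, axis=1)
        if v.shape[0] and np.max(np.abs(norms - 1.0)) > UNIT_NORM_TOL:
            raise ValueError("every row must be unit-norm within 1e-9")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def discretize_spectrum(spectrum: RawSpectrum, bins: BinRange) -> np.ndarray:
    """Bin a spectrum to the integer m/z grid by per-bin maximum intensity.

    Bin ``n`` collects peaks with m/z in the half-open window
    ``[n - 1/2, n + 1/2)``; bins with no peak are 0.  A peak outside the
    global window ``[m - 1/2, M + 1/2)`` violates the dataset-wide range and
    raises.
    """
    out = np.zeros(bins.d, dtype=float)
    if spectrum.n_peaks == 0:
        return out
    # nearest integer with half-open right edge: floor(mz + 1/2)
    idx = np.floor(spectrum.mz + 0.5).astype(int) - bins.m
    if idx.min() < 0 or idx.max() >= bins.d:
        bad = spectrum.mz[(idx < 0) | (idx >= bins.d)][0]
        raise ValueError(
            f"peak at m/z {bad} outside global bin range "
            f"[{bins.m - 0.5}, {bins.M + 0.5})"
        )
    np.maximum.at(out, idx, spectrum.intensity)
    return out


def global_bin_range(samples: Iterable[SampleRun]) -> BinRange:
    """Smallest integer bin range whose bins intersect every observed m/z.

    The lower edge is the smallest integer ``n`` with
    ``[n - 1/2, n + 1/2)`` meeting some peak's m/z across all samples; the
    upper edge the largest.
    """
    lo = math.inf
    hi = -math.inf
    for run in samples:
        for sp in run.spectra:
            if sp.n_peaks:
                lo = min(lo, float(sp.mz.min()))
                hi = max(hi, float(sp.mz.max()))
    if lo is math.inf or not np.isfinite(lo):
        raise ValueError("no non-empty spectrum found in any sample")
    return BinRange(int(math.floor(lo + 0.5)), int(math.floor(hi + 0.5)))


def normalize(v: np.ndarray) -> np.ndarray:
    """Project a nonnegative dMS vector onto the unit sphere (l2 norm 1).

    Invariant to positive scaling of the input.  An all-zero vector has no
    direction and raises :class:`EmptySpectrumError`; callers drop the
    retention index of such spectra.
    """
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise EmptySpectrumError("empty spectrum: all-zero vector cannot be normalized")
    return v / nrm


def exclude_retention_window(
    run: SampleRun, window: tuple[float, float]
) -> SampleRun:
    """Keep only spectra with first retention time inside ``window`` (closed).

    The beginning and end of a measurement lie outside the region of
    interest (solvent front, column bleed); they are excluded before
    vectorization rather than baseline-corrected.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"retention window has t_r1_min > t_r1_max: {window}")
    kept = [s for s in run.spectra if lo <= s.t_r1 <= hi]
    if not kept:
        warnings.warn(
            f"sample {run.sample_id!r}: retention window {window} excluded "
            "every spectrum",
            stacklevel=2,
        )
    return SampleRun(run.sample_id, kept, dict(run.metadata))


def vectorize_run(
    run: SampleRun,
    bins: BinRange,
    window: tuple[float, float] | None = None,
) -> SampleFeatureMatrix:
    """Full per-sample vectorization: window exclusion, binning, normalization.

    All-zero spectra (no peaks inside the window/bin range) cannot be
    normalized and are dropped; the count is logged and recorded on the
    returned matrix.
    """
    if window is not None:
        run = exclude_retention_window(run, window)
    rows: list[np.ndarray] = []
    ret: list[tuple[float, float]] = []
    idx: list[int] = []
    dropped = 0
    for i, sp in enumerate(run.spectra):
        d = discretize_spectrum(sp, bins)
        try:
            rows.append(normalize(d))
        except EmptySpectrumError:
            dropped += 1
            continue
        ret.append((sp.t_r1, sp.t_r2))
        idx.append(i)
    if dropped:
        logger.info(
            "sample %s: dropped %d all-zero spectra of %d",
            run.sample_id, dropped, len(run.spectra),
        )
    values = np.array(rows, dtype=float).reshape(len(rows), bins.d)
    return SampleFeatureMatrix(
        sample_id=run.sample_id,
        values=values,
        bins=bins,
        retention=np.array(ret, dtype=float).reshape(len(ret), 2),
        retention_index=np.array(idx, dtype=int),
        n_dropped=dropped,
        metadata=dict(run.metadata),
    )


def _match_pairs(
    a: SampleFeatureMatrix,
    b: SampleFeatureMatrix,
    max_offset: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of retention-matched rows between two replicate matrices."""
    key_a = {tuple(np.round(r, 6)): i for i, r in enumerate(a.retention)}
    ia, ib = [], []
    exact = True
    for j, r in enumerate(b.retention):
        i = key_a.get(tuple(np.round(r, 6)))
        if i is not None:
            ia.append(i)
            ib.append(j)
        else:
            exact = False
    if exact and ia:
        return np.array(ia), np.array(ib)
    if max_offset is None:
        raise ValueError(
            "replicate retention grids differ and no matching tolerance "
            "(half modulation period) was given"
        )
    # grids differ: nearest-neighbor matching within half a modulation period
    logger.warning(
        "replicate grids differ between %s and %s: using nearest-neighbor "
        "matching within %.3g s", a.sample_id, b.sample_id, max_offset,
    )
    ia, ib = [], []
    for j, r in enumerate(b.retention):
        dist = np.abs(a.retention - r).max(axis=1)
        i = int(np.argmin(dist))
        if dist[i] <= max_offset:
            ia.append(i)
            ib.append(j)
    if not ia:
        raise ValueError("no retention-matched pairs between replicates")
    return np.array(ia), np.array(ib)


def calibrate_resolution(
    replicates: Sequence[SampleFeatureMatrix],
    coverage: float = 0.95,
    epsilon_floor: float = 1e-6,
    match_tolerance: float | None = None,
) -> float:
    """Calibrate the Ball Mapper radius ε from replicate runs.

    Distances between retention-matched nMS vectors of replicate
    measurements of the same material estimate pure measurement
    variability; ε is the ``coverage`` empirical quantile (lower/type-1
    order statistic) of those distances, so that the stated fraction of
    replicate pairs falls within one ball.  Differences beyond ε are then
    interpretable as chemical rather than instrumental.

    Parameters
    ----------
    replicates : sequence of SampleFeatureMatrix
        At least two vectorized runs of the same material on the same bin
        grid.
    coverage : float
        Fraction of replicate pair distances that must fall below ε.
    epsilon_floor : float
        Lower bound returned for degenerate (identical) replicates.
    match_tolerance : float, optional
        Maximum retention offset (s) for nearest-neighbor matching when the
        grids differ; typically half the modulation period.
    """
    if len(replicates) < 2:
        raise ValueError("calibration requires at least 2 replicate runs")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    bins = replicates[0].bins
    for r in replicates[1:]:
        if r.bins != bins:
            raise ValueError("replicates must share the same BinRange")
    dists: list[np.ndarray] = []
    for i in range(len(replicates)):
        for j in range(i + 1, len(replicates)):
            ia, ib = _match_pairs(replicates[i], replicates[j], match_tolerance)
            diff = replicates[i].values[ia] - replicates[j].values[ib]
            dists.append(np.linalg.norm(diff, axis=1))
    all_d = np.concatenate(dists)
    if all_d.size == 0:
        raise ValueError("no matched replicate pairs found")
    eps = float(np.quantile(all_d, coverage, method="inverted_cdf"))
    return max(eps, epsilon_floor)
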