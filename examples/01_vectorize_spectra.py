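"""Vectorize GC×GC–MS point data: binning and unit-sphere normalization.

Builds a tiny three-spectrum sample, discretizes each spectrum to integer
m/z bins by per-bin maximum intensity, and projects onto the unit sphere.
"""

import numpy as np

from mapperms import BinRange, RawSpectrum, SampleRun, global_bin_range, vectorize_run

run = SampleRun(
    sample_id="demo",
    spectra=[
        RawSpectrum(600.0, 1.0, np.array([29.3, 29.6, 30.9]), np.array([5.0, 7.0, 2.0])),
        RawSpectrum(3000.0, 1.0, np.array([30.1, 30.4]), np.array([4.0, 9.0])),
        RawSpectrum(5400.0, 1.0, np.array([29.0]), np.array([3.0])),
    ],
)

bins = global_bin_range([run])
print(f"global bin range: m={bins.m}, M={bins.M}, d={bins.d}")

matrix = vectorize_run(run, bins)
print(f"feature matrix shape: {matrix.values.shape}")
print("row norms:", np.linalg.norm(matrix.values, axis=1))
print("first nMS vector:", np.round(matrix.values[0], 3))
# Each row is one spectrum reduced to a direction on the unit sphere: the
# per-bin maxima [5, 7, 2] normalized to length 1. Overall intensity is
# gone; only the spectral shape remains, which is what makes spectra
# comparable across samples and acquisition scales.
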