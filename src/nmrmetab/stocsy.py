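"""Statistical total correlation spectroscopy (STOCSY) and pairwise
region correlations.

STOCSY correlates one spectral variable (the driver bin) against every
other bin across samples: resonances of the same molecule vary together
with concentration, so they light up with correlations near one, which
helps connect multiplets during assignment.  The region-level
correlation supports targeted questions such as whether phenylalanine
and tyrosine co-vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nmrproc import BinnedMatrix, ProcessingError

__all__ = [
    "StocsyTrace",
    "stocsy_trace",
    "peak_correlation",
    "PHE_REGION",
    "TYR_REGION",
]

# default literature multiplet windows for the aromatic resonances
PHE_REGION = (7.30, 7.45)
TYR_REGION = (6.86, 6.94)


@dataclass(frozen=True)
class StocsyTrace:
    """Covariance and correlation of every bin with the driver bin."""

    driver_ppm: float
    bin_ppm: np.ndarray
    covariance: np.ndarray
    correlation: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ppm": self.bin_ppm,
                "covariance": self.covariance,
                "correlation": self.correlation,
            }
        )


def stocsy_trace(matrix: BinnedMatrix, driver_ppm: float) -> StocsyTrace:
    """Correlate the driver bin against all bins across samples."""
    if matrix.n_samples < 4:
        raise ValueError("need at least 4 samples for a STOCSY trace")
    j = matrix.index_of(driver_ppm)  # raises if the driver was excluded
    x = matrix.values
    xc = x - x.mean(axis=0)
    driver = xc[:, j]
    n = x.shape[0]
    cov = xc.T @ driver / (n - 1)
    sd = np.sqrt((xc**2).sum(axis=0))
    denom = sd * sd[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, xc.T @ driver / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return StocsyTrace(
        driver_ppm=float(matrix.bin_centers[j]),
        bin_ppm=matrix.bin_centers,
        covariance=cov,
        correlation=corr,
    )


def _region_sum(matrix: BinnedMatrix, region) -> np.ndarray:
    if np.isscalar(region):
        idx = np.array([matrix.index_of(float(region))])
    else:
        idx = matrix.bins_in_region(tuple(region))
        if idx.size == 0:
            raise ProcessingError(f"region {region} maps to no surviving bin")
    return matrix.values[:, idx].sum(axis=1)


def peak_correlation(
    matrix: BinnedMatrix, region_a, region_b
) -> tuple[float, float]:
    """Pearson correlation between two summed peak regions.

    Regions are (lo, hi) ppm intervals (or a single ppm mapping to one
    bin).  The two-tailed p-value uses the exact t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom.
    """
    a = _region_sum(matrix, region_a)
    b = _region_sum(matrix, region_b)
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    for series in (a, b):
        scale = max(1.0, float(np.abs(series).max()))
        if np.std(series) <= 1e-12 * scale:
            raise ValueError("zero-variance region")
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p
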