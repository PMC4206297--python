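"""Per-pixel intensity distributions within nuclear masks.

Histograms use 4096 unit-width bins over the 12-bit range 0..4095, pooled
across all sampled nuclei of a condition.  Distribution comparisons (median
shift, two-sample Kolmogorov–Smirnov distance, tail fractions relative to a
baseline quantile) are computed from the histograms alone, so any two pooled
histograms with the same binning are comparable regardless of how many nuclei
or pixels contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Union

import numpy as np

from .simulate import MAX_INTENSITY

N_BINS = MAX_INTENSITY + 1


@dataclass
class PixelHistogram:
    counts: np.ndarray              # int64[4096], unit-width bins 0..4095
    n_nuclei: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"counts must have shape ({N_BINS},), got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def cdf(self) -> np.ndarray:
        """Empirical CDF evaluated at each bin's upper edge."""
        if self.n_pixels == 0:
            raise ValueError("empty histogram has no CDF")
        return np.cumsum(self.counts) / self.n_pixels

    def quantile(self, q: float) -> int:
        """Smallest intensity whose CDF reaches ``q`` (lower empirical quantile)."""
        if not (0.0 < q <= 1.0):
            raise ValueError("q must be in (0, 1]")
        return int(np.searchsorted(self.cdf(), q))

    def median(self) -> int:
        return self.quantile(0.5)

    def mean(self) -> float:
        if self.n_pixels == 0:
            raise ValueError("empty histogram has no mean")
        return float(np.arange(N_BINS) @ self.counts / self.n_pixels)


PixelCollections = Union[Mapping[int, np.ndarray], Iterable[np.ndarray]]


def pixel_histogram(pixel_collections: PixelCollections, condition: str = "") -> PixelHistogram:
    """Pool per-nucleus pixel multisets into one unit-bin histogram.

    Out-of-range intensities are an error, never clipped: a value outside
    0..4095 means the caller's data are not on the 12-bit scale.
    """
    if isinstance(pixel_collections, Mapping):
        arrays = list(pixel_collections.values())
    else:
        arrays = list(pixel_collections)
    counts = np.zeros(N_BINS, dtype=np.int64)
    for arr in arrays:
        arr = np.asarray(arr)
        if arr.size == 0:
            continue
        if np.any(arr < 0) or np.any(arr > MAX_INTENSITY):
            raise ValueError(f"pixel intensity outside [0, {MAX_INTENSITY}]")
        vals = arr.astype(np.int64).ravel()
        if not np.array_equal(vals, np.asarray(arr, dtype=float).ravel()):
            raise ValueError("pixel intensities must be integers for unit binning")
        counts += np.bincount(vals, minlength=N_BINS)
    return PixelHistogram(counts=counts, n_nuclei=len(arrays), condition=condition)


def histogram_window(hist: PixelHistogram, lo: int, hi: int) -> PixelHistogram:
    """Restrict a histogram to the closed intensity window [lo, hi]."""
    if not (0 <= lo <= hi <= MAX_INTENSITY):
        raise ValueError(f"require 0 <= lo <= hi <= {MAX_INTENSITY}, got [{lo}, {hi}]")
    counts = np.zeros_like(hist.counts)
    counts[lo:hi + 1] = hist.counts[lo:hi + 1]
    return replace(hist, counts=counts)


@dataclass
class DistributionComparison:
    """Summary of how distribution B departs from baseline distribution A."""

    median_a: int
    median_b: int
    median_shift: int                  # median_b - median_a, intensity units
    ks_distance: float                 # sup |CDF_A - CDF_B|
    baseline_quantile: float           # q used for the tail comparison
    baseline_quantile_intensity: int   # q-quantile of A
    fraction_above_baseline: float     # share of B's pixels strictly above it
    fraction_below_median: float       # share of B's pixels strictly below A's median


def compare_distributions(
    hist_a: PixelHistogram, hist_b: PixelHistogram, q: float = 0.99
) -> DistributionComparison:
    """Compare two pooled pixel-intensity histograms (A = baseline)."""
    if hist_a.n_pixels == 0 or hist_b.n_pixels == 0:
        raise ValueError("cannot compare empty histograms")
    cdf_a, cdf_b = hist_a.cdf(), hist_b.cdf()
    ks = float(np.max(np.abs(cdf_a - cdf_b)))
    med_a, med_b = hist_a.median(), hist_b.median()
    q_int = hist_a.quantile(q)
    above = int(hist_b.counts[q_int + 1:].sum())
    below = int(hist_b.counts[:med_a].sum())
    return DistributionComparison(
        median_a=med_a,
        median_b=med_b,
        median_shift=med_b - med_a,
        ks_distance=ks,
        baseline_quantile=q,
        baseline_quantile_intensity=q_int,
        fraction_above_baseline=above / hist_b.n_pixels,
        fraction_below_median=below / hist_b.n_pixels,
    )
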