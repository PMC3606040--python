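"""Resolution binning uniform in ln(d) with a per-bin count floor.

Conventional schemes put equal numbers of reflections per bin (uniform in
d⁻³), which leaves the sparse low-resolution region with one or two bins —
too coarse to follow the bulk-solvent scale curve where it varies fastest.
Binning uniformly in ln(d) instead gives detailed low-resolution bins while
high-resolution bins simply hold more reflections, and since the scale
factors vary roughly exponentially with resolution their change per bin is
approximately uniform.

The algorithm lays a uniform ln(d) grid of at most ``max_bins`` slices over
the data range, then sweeps from low resolution (large d) to high, greedily
merging slices toward higher resolution until every bin holds at least
``min_count`` reflections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["BinPartition", "log_d_bins", "assign_bins", "equal_count_d3_bins"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 300
DEFAULT_MAX_BINS = 30


@dataclass
class BinPartition:
    """A partition of reflections into resolution bins.

    ``boundaries`` is a strictly decreasing array of d values (length
    n_bins + 1, outer bounds closed); ``bin_of`` maps each reflection to its
    bin id, contiguous from 0 (bin 0 = lowest resolution / largest d).
    """

    boundaries: np.ndarray
    bin_of: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_of, minlength=self.n_bins)

    def centers_s2(self) -> np.ndarray:
        """Bin centers in s² = 1/d², midpoint of the bin's s² range."""
        s2 = 1.0 / self.boundaries**2
        return 0.5 * (s2[:-1] + s2[1:])

    def to_dict(self) -> dict:
        return {
            "boundaries_d": self.boundaries.tolist(),
            "counts": self.counts.tolist(),
        }


def log_d_bins(
    d: np.ndarray,
    min_count: int = DEFAULT_MIN_COUNT,
    max_bins: int = DEFAULT_MAX_BINS,
) -> BinPartition:
    """Partition reflections into bins uniform in ln(d), honouring a count floor.

    Parameters
    ----------
    d : array of per-reflection resolutions in Å, all > 0.
    min_count : minimum reflections per bin (floor; default 300).
    max_bins : upper limit on the number of bins; the uniform ln(d) step is
        widened to keep the slice count at or below it.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty reflection set")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    d_max, d_min = float(d.max()), float(d.min())
    if d_min <= 0:
        raise ValueError("all d must be positive")
    if d.size < min_count or d_max == d_min or max_bins == 1:
        boundaries = np.array([d_max, d_min])
        return BinPartition(boundaries, np.zeros(d.size, dtype=int))

    n_slices = max_bins
    edges = np.exp(np.linspace(np.log(d_max), np.log(d_min), n_slices + 1))
    edges[0], edges[-1] = d_max, d_min  # exact closed outer bounds

    # Slice counts on the uniform grid (tie rule: boundary d goes to the
    # larger-d slice, i.e. slice i is (edges[i+1], edges[i]]).
    slice_ids = _assign(d, edges)
    slice_counts = np.bincount(slice_ids, minlength=n_slices)

    # Greedy descending-d sweep: accumulate slices until >= min_count.
    kept = []  # indices into edges that survive as boundaries
    acc = 0
    for i in range(n_slices):
        acc += slice_counts[i]
        if acc >= min_count:
            kept.append(i + 1)
            acc = 0
    if not kept or kept[-1] != n_slices:
        # trailing under-populated remainder: merge into the previous bin
        if kept:
            kept[-1] = n_slices
        else:
            kept = [n_slices]
    boundaries = np.concatenate([[edges[0]], edges[kept]])
    bin_of = _assign(d, boundaries)
    return BinPartition(boundaries, bin_of)


def _assign(d: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Bin ids against descending boundaries: bin i covers (b[i+1], b[i]],
    so a d exactly on an interior boundary joins the bin in which it is the
    lowest-resolution (largest-d) member; both outer bounds are closed."""
    # boundaries descending; searchsorted on the negated (ascending) scale.
    ids = np.searchsorted(-boundaries, -d, side="right") - 1
    return np.clip(ids, 0, len(boundaries) - 2)


def assign_bins(d: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Assign reflections to bins given descending d boundaries.

    Reflections outside the full range are clamped to the nearest bin and
    logged. Reflection with d equal to a shared boundary is assigned to the
    lower-resolution (larger-d) bin; the outer bounds are closed.
    """
    d = np.asarray(d, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.ndim != 1 or len(boundaries) < 2 or np.any(np.diff(boundaries) >= 0):
        raise ValueError("boundaries must be a strictly decreasing d array")
    n_out = int(np.sum((d > boundaries[0]) | (d < boundaries[-1])))
    if n_out:
        logger.warning("%d reflections outside binning range; clamped", n_out)
    return _assign(d, boundaries)


def equal_count_d3_bins(d: np.ndarray, n_bins: int) -> BinPartition:
    """Comparison utility: bins of (approximately) equal count, i.e. uniform
    sampling of the resolution range in d⁻³."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty reflection set")
    n_bins = max(1, min(n_bins, d.size))
    qs = np.linspace(0, 1, n_bins + 1)
    boundaries = np.quantile(np.sort(d)[::-1], qs)[::-1]  # descending in d
    boundaries = np.unique(boundaries)[::-1]
    boundaries[0], boundaries[-1] = d.max(), d.min()
    return BinPartition(boundaries, _assign(d, boundaries))
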