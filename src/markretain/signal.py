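"""Binned coverage tracks and the raw-signal processing chain.

A :class:`BinnedTrack` holds fixed-width, consecutive genomic bins for one
mark in one condition (e.g. H3K4me3 in ether-exposed embryos).  The
processing chain turns raw binned read counts into comparable signal:

1. :func:`smooth_track` — centred moving-window average (default 100 bp);
2. :func:`percentile_normalize` — global rank transform to the percentile
   scale, removing sequencing-depth differences between samples;
3. :func:`apply_background_threshold` — zero everything below a global
   quantile (default 95 %), separating signal from background.

Percentile normalization is *global*: ranks are computed over every bin of
every chromosome of one sample, not per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "BinnedTrack",
    "smooth_track",
    "percentile_normalize",
    "apply_background_threshold",
]


@dataclass
class BinnedTrack:
    """Fixed-width binned signal for one mark x condition.

    Parameters
    ----------
    bin_width:
        Width of every bin in base pairs.
    values:
        Mapping ``chrom -> 1-D array`` of non-negative per-bin signal, one
        entry per consecutive bin.
    offsets:
        Optional mapping ``chrom -> start of the first bin`` (0-based);
        chromosomes absent from the mapping start at 0.
    """

    bin_width: int
    values: Dict[str, np.ndarray]
    offsets: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.bin_width) <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.bin_width = int(self.bin_width)
        clean: Dict[str, np.ndarray] = {}
        for chrom, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"values for {chrom!r} must be 1-D")
            if arr.size and np.nanmin(arr) < 0:
                raise ValueError(f"negative signal values on {chrom!r}")
            clean[chrom] = arr
        self.values = clean
        for chrom in self.offsets:
            if chrom not in self.values:
                raise ValueError(f"offset given for unknown chromosome {chrom!r}")
        self.offsets = {c: int(self.offsets.get(c, 0)) for c in self.values}

    # -- basic views -------------------------------------------------------
    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self.values))

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    def all_values(self) -> np.ndarray:
        """All bin values concatenated in sorted chromosome order."""
        if not self.values:
            return np.empty(0)
        return np.concatenate([self.values[c] for c in self.chroms])

    def midpoints(self, chrom: str) -> np.ndarray:
        """Midpoint coordinate of every bin on ``chrom`` (bp, float)."""
        n = self.values[chrom].size
        return self.offsets[chrom] + (np.arange(n) + 0.5) * self.bin_width

    def iter_bins(self) -> Iterator[Tuple[str, int, int, float]]:
        """Yield ``(chrom, start, end, value)`` in sorted genomic order."""
        for chrom in self.chroms:
            off = self.offsets[chrom]
            for i, v in enumerate(self.values[chrom]):
                start = off + i * self.bin_width
                yield chrom, start, start + self.bin_width, float(v)

    def same_binning(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chroms == other.chroms
            and all(self.values[c].size == other.values[c].size for c in self.chroms)
            and all(self.offsets[c] == other.offsets[c] for c in self.chroms)
        )

    def _like(self, new_values: Dict[str, np.ndarray]) -> "BinnedTrack":
        return BinnedTrack(self.bin_width, new_values, dict(self.offsets))


def _truncated_moving_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Centred moving mean over ``w`` bins; the window truncates at the
    edges and the mean is renormalized to the bins actually available."""
    n = values.size
    if n == 0 or w == 1:
        return values.copy()
    left = (w - 1) // 2  # extra bin goes to the right for even w
    right = w // 2
    cs = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def smooth_track(track: BinnedTrack, window_bp: int = 100) -> BinnedTrack:
    """Moving-window average of a binned track.

    ``window_bp`` must be a positive multiple of the track's bin width; the
    window is centred on each bin and truncated (with renormalized mean) at
    chromosome edges, so no signal is invented beyond the data.  A constant
    track is returned unchanged.
    """
    if window_bp <= 0 or window_bp % track.bin_width != 0:
        raise ValueError(
            f"window_bp ({window_bp}) must be a positive multiple of "
            f"bin_width ({track.bin_width})"
        )
    w = window_bp // track.bin_width
    return track._like({c: _truncated_moving_mean(v, w) for c, v in track.values.items()})


def percentile_normalize(track: BinnedTrack) -> BinnedTrack:
    """Global percentile normalization of one sample.

    Every bin value is replaced by ``100 * (rank - 0.5) / N`` where the rank
    is taken over *all* bins of *all* chromosomes of the sample (average
    ranks for ties, ``N`` = total bin count).  Output values lie in (0, 100),
    the rank order is preserved, and the transform is idempotent.
    """
    if track.n_bins == 0:
        raise ValueError("cannot percentile-normalize an empty track")
    order = track.chroms
    ranks = rankdata(track.all_values(), method="average")
    pct = 100.0 * (ranks - 0.5) / track.n_bins
    out: Dict[str, np.ndarray] = {}
    pos = 0
    for chrom in order:
        n = track.values[chrom].size
        out[chrom] = pct[pos : pos + n]
        pos += n
    return track._like(out)


def apply_background_threshold(track: BinnedTrack, quantile: float = 95.0) -> BinnedTrack:
    """Zero all bins below the global ``quantile``-th percentile.

    The cutoff is the smallest observed value whose empirical quantile is at
    least ``quantile/100``; bins with value >= cutoff are kept unchanged
    (ties at the cutoff are kept).  For a percentile-normalized track with
    distinct values this keeps exactly ``ceil((1 - q/100) * N)`` bins.
    """
    if quantile < 0 or quantile >= 100:
        raise ValueError(f"quantile must lie in [0, 100), got {quantile}")
    if quantile == 0:
        warnings.warn("quantile=0 keeps every bin; track returned unchanged")
        return track._like({c: v.copy() for c, v in track.values.items()})
    allv = track.all_values()
    if allv.size == 0:
        raise ValueError("cannot threshold an empty track")
    if np.nanmax(allv) > 100.0:
        warnings.warn(
            "track values exceed 100; expected a percentile-normalized track"
        )
    cutoff = np.quantile(allv, quantile / 100.0, method="higher")
    return track._like(
        {c: np.where(v >= cutoff, v, 0.0) for c, v in track.values.items()}
    )
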