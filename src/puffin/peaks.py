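"""Candidate nucleosome detection on landscape functions.

A candidate is a local maximum q of a landscape N_α; its width s is the
distance to the nearest local minimum.  Because landscape peaks need not be
symmetric, each candidate is recentered on the centroid of the midpoints of
the fragments in its basin (the interval between the two flanking minima),
so the reported position represents the reads that formed the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import FragmentRecord
from .profiles import Landscape

log = logging.getLogger(__name__)


@dataclass
class Peak:
    """A candidate nucleosome (q, s) from one landscape.

    ``q_raw`` is the integer local-max position before recentering; ``q`` the
    (possibly fractional) position after.  ``basin`` is the genomic interval
    between the flanking local minima, used for fragment assignment.
    """

    q: float
    s: float
    alpha: float
    height: float
    q_raw: int
    support: int = 0
    chrom: str = ""
    basin: tuple[float, float] | None = field(default=None, repr=False)


@dataclass
class PeakSet:
    """All candidates from a single landscape, sorted by position."""

    alpha: float
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: p.q)

    def __len__(self) -> int:
        return len(self.peaks)


def find_extrema(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima of a sampled curve, in one linear scan.

    A flat plateau that is a maximum (minimum) contributes a single extremum
    at its midpoint, floored to an integer index.  The two region endpoints
    are always reported as minima, so every maximum has flanking minima.
    Curves shorter than 3 samples have no extrema.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    d = np.sign(np.diff(v))
    nz = np.nonzero(d)[0]
    maxima: list[int] = []
    minima: list[int] = []
    s = d[nz]
    for i in range(len(nz) - 1):
        if s[i] > 0 and s[i + 1] < 0:
            run_start = nz[i] + 1          # first index of the plateau/run
            run_end = nz[i + 1]            # last index of the run
            maxima.append((run_start + run_end) // 2)
        elif s[i] < 0 and s[i + 1] > 0:
            run_start = nz[i] + 1
            run_end = nz[i + 1]
            minima.append((run_start + run_end) // 2)
    minima = [0] + minima + [v.size - 1]
    return np.asarray(maxima, dtype=np.int64), np.asarray(minima, dtype=np.int64)


def detect_peaks(landscape: Landscape, min_height: float = 0.0) -> PeakSet:
    """One Peak per local maximum of a landscape.

    Candidates whose landscape height is not above ``min_height`` are
    dropped: a maximum at or below 0 means the fine-scale profile is not
    enriched over the low-resolution background there (such maxima arise in
    coverage gaps purely from the shape of the reference profile).
    """
    v = landscape.values
    if not np.all(np.isfinite(v)):
        raise ValueError("landscape contains non-finite values")
    maxima, minima = find_extrema(v)
    start = landscape.region.start
    peaks: list[Peak] = []
    for q_idx in maxima:
        h = float(v[q_idx])
        if h <= min_height:
            continue
        # flanking minima exist because the endpoints count as minima
        pos = int(np.searchsorted(minima, q_idx))
        left = int(minima[pos - 1])
        right = int(minima[pos])
        s = float(min(q_idx - left, right - q_idx))
        peaks.append(
            Peak(
                q=float(start + q_idx),
                s=s,
                alpha=landscape.alpha,
                height=h,
                q_raw=int(start + q_idx),
                chrom=landscape.region.chrom,
                basin=(float(start + left), float(start + right)),
            )
        )
    return PeakSet(alpha=landscape.alpha, peaks=peaks)


def recenter_peak(peak: Peak, fragments: Sequence[FragmentRecord]) -> Peak:
    """Replace q by the centroid of midpoints of the fragments in the basin.

    A fragment belongs to the peak when its midpoint lies in [left, right)
    of the peak's basin, which partitions fragments uniquely per scale.  If
    no fragment falls in the basin, q stays at the raw maximum.
    """
    if peak.basin is None:
        raise ValueError("peak has no basin; was it produced by detect_peaks?")
    left, right = peak.basin
    mids = [
        f.midpoint
        for f in fragments
        if (not peak.chrom or f.chrom == peak.chrom) and left <= f.midpoint < right
    ]
    if not mids:
        log.warning("peak at %s:%d has no supporting fragments", peak.chrom, peak.q_raw)
        return replace(peak, support=0)
    return replace(peak, q=float(np.mean(mids)), support=len(mids))


def recenter_peakset(peak_set: PeakSet, sorted_midpoints: np.ndarray) -> PeakSet:
    """Vectorized recentering of a whole PeakSet.

    ``sorted_midpoints`` must be the sorted midpoints of the region's
    fragments (one chromosome).  Semantics match :func:`recenter_peak`.
    """
    mids = np.asarray(sorted_midpoints)
    out: list[Peak] = []
    for p in peak_set.peaks:
        left, right = p.basin  # type: ignore[misc]
        lo = int(np.searchsorted(mids, left, side="left"))
        hi = int(np.searchsorted(mids, right, side="left"))
        if hi > lo:
            out.append(replace(p, q=float(mids[lo:hi].mean()), support=hi - lo))
        else:
            log.warning("peak at %s:%d has no supporting fragments", p.chrom, p.q_raw)
            out.append(replace(p, support=0))
    return PeakSet(alpha=peak_set.alpha, peaks=out)
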