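"""Greedy fine-to-coarse consensus of per-scale candidate peaks.

Two candidates overlap when their centers are closer than the nucleosome
size (146 bp).  Peak sets are processed from the smallest (sharpest) α to
the largest: a peak is admitted to the consensus C when it overlaps no
other peak of its own set and no peak already in C; admitted peaks are
never removed.  Sharply positioned nucleosomes therefore enter at fine
scales, while fuzzy ones — whose fine-scale peaks mutually collide and
annihilate — are rescued at coarser scales once smoothing has merged their
sub-peaks.  By construction the final map is non-overlapping.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FragmentRecord, GenomicRegion
from .peaks import Peak, PeakSet, detect_peaks, recenter_peakset
from .profiles import ProfileConfig, build_landscape_family

log = logging.getLogger(__name__)

DEFAULT_NUC_SIZE = 146


def overlaps(p1: Peak, p2: Peak, nuc_size: int = DEFAULT_NUC_SIZE) -> bool:
    """True iff the two centers are closer than one nucleosome."""
    if p1.chrom != p2.chrom:
        return False
    return abs(p1.q - p2.q) < nuc_size


@dataclass
class NucleosomeMap:
    """Final consensus set of non-overlapping nucleosome calls.

    Each call keeps the α of the landscape that produced it.  The map is
    sorted by (chrom, q) and every same-chromosome pair of calls is at
    least ``nuc_size`` apart.
    """

    calls: list[Peak]
    region: GenomicRegion | None = None
    config: ProfileConfig | None = None
    nuc_size: int = DEFAULT_NUC_SIZE
    validate: bool = True

    def __post_init__(self) -> None:
        self.calls.sort(key=lambda p: (p.chrom, p.q))
        if self.validate:
            self._check_non_overlap()

    def _check_non_overlap(self) -> None:
        for a, b in zip(self.calls, self.calls[1:]):
            if a.chrom == b.chrom and b.q - a.q < self.nuc_size:
                raise ValueError(
                    f"overlapping calls at {a.chrom}:{a.q:.1f} and {b.q:.1f}"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def centers(self, chrom: str | None = None) -> np.ndarray:
        qs = [p.q for p in self.calls if chrom is None or p.chrom == chrom]
        return np.asarray(qs)


def _check_sorted_alphas(peak_sets: Sequence[PeakSet]) -> None:
    alphas = [ps.alpha for ps in peak_sets]
    if any(b <= a for a, b in zip(alphas, alphas[1:])):
        raise ValueError("peak sets must be ordered by strictly increasing alpha")


def build_consensus(peak_sets: Sequence[PeakSet],
                    nuc_size: int = DEFAULT_NUC_SIZE) -> NucleosomeMap:
    """Accumulate the consensus from fine to coarse scales.

    Within one set, any peak with another same-set peak closer than
    ``nuc_size`` is rejected for that scale (both members of a colliding
    pair are — they stay eligible at coarser scales).  Surviving peaks are
    processed left to right and admitted unless they collide with a call
    already in the consensus.  Recentered positions are used throughout.
    """
    _check_sorted_alphas(peak_sets)
    admitted: list[Peak] = []
    by_chrom: dict[str, list[float]] = {}
    for ps in peak_sets:
        chrom_groups: dict[str, list[Peak]] = {}
        for p in sorted(ps.peaks, key=lambda p: (p.chrom, p.q)):
            chrom_groups.setdefault(p.chrom, []).append(p)
        for chrom, group in chrom_groups.items():
            qs = [p.q for p in group]
            accepted = by_chrom.setdefault(chrom, [])
            for i, p in enumerate(group):
                # nearest same-set neighbours decide the within-set rule
                if i > 0 and qs[i] - qs[i - 1] < nuc_size:
                    continue
                if i + 1 < len(qs) and qs[i + 1] - qs[i] < nuc_size:
                    continue
                j = bisect.bisect_left(accepted, p.q)
                if j > 0 and p.q - accepted[j - 1] < nuc_size:
                    continue
                if j < len(accepted) and accepted[j] - p.q < nuc_size:
                    continue
                accepted.insert(j, p.q)
                admitted.append(p)
    return NucleosomeMap(calls=admitted, nuc_size=nuc_size)


def brute_force_consensus(peak_sets: Sequence[PeakSet],
                          nuc_size: int = DEFAULT_NUC_SIZE,
                          max_peaks: int = 1000) -> NucleosomeMap:
    """Replay the greedy rule by exhaustive pair checking (test oracle).

    Independent of :func:`build_consensus`: quadratic scans, no sorting
    tricks.  Guarded to small inputs.
    """
    _check_sorted_alphas(peak_sets)
    total = sum(len(ps.peaks) for ps in peak_sets)
    if total > max_peaks:
        raise ValueError(f"brute-force oracle limited to {max_peaks} peaks, got {total}")
    chosen: list[Peak] = []
    for ps in peak_sets:
        for p in sorted(ps.peaks, key=lambda p: (p.chrom, p.q)):
            clash = False
            for other in ps.peaks:
                if other is p:
                    continue
                if other.chrom == p.chrom and abs(other.q - p.q) < nuc_size:
                    clash = True
                    break
            if clash:
                continue
            for c in chosen:
                if c.chrom == p.chrom and abs(c.q - p.q) < nuc_size:
                    clash = True
                    break
            if not clash:
                chosen.append(p)
    return NucleosomeMap(calls=chosen, nuc_size=nuc_size)


def infer_region(fragments: Sequence[FragmentRecord],
                 config: ProfileConfig) -> GenomicRegion:
    """Smallest region covering all fragments plus full kernel support."""
    chroms = {f.chrom for f in fragments}
    if len(chroms) != 1:
        raise ValueError("fragments span multiple chromosomes; pass a region")
    (chrom,) = chroms
    max_w = max(f.length for f in fragments)
    pad = int(math.ceil(config.truncation * config.low_res_alpha * max_w))
    start = max(0, min(f.start for f in fragments) - pad)
    end = max(f.end for f in fragments) + pad
    return GenomicRegion(chrom, start, end)


def call_nucleosomes(
    fragments: Sequence[FragmentRecord],
    region: GenomicRegion | None = None,
    config: ProfileConfig | None = None,
) -> NucleosomeMap:
    """End-to-end caller: landscapes -> candidates -> recenter -> consensus.

    Chromosomes are processed independently.  When no region is given, each
    chromosome's region is inferred from its fragment span padded by the
    reference-kernel support, so no probability mass is clipped.
    """
    cfg = config or ProfileConfig()
    if not fragments:
        return NucleosomeMap(calls=[], region=region, config=cfg)
    groups: dict[str, list[FragmentRecord]] = {}
    for f in fragments:
        groups.setdefault(f.chrom, []).append(f)
    if region is not None:
        if region.chrom not in groups:
            return NucleosomeMap(calls=[], region=region, config=cfg)
        groups = {region.chrom: groups[region.chrom]}
    all_calls: list[Peak] = []
    for chrom in sorted(groups):
        frags = groups[chrom]
        reg = region if region is not None else infer_region(frags, cfg)
        landscapes, _ = build_landscape_family(frags, reg, cfg)
        mids = np.sort(np.asarray([f.midpoint for f in frags]))
        peak_sets = [
            recenter_peakset(detect_peaks(ls), mids) for ls in landscapes
        ]
        n_cand = sum(len(ps) for ps in peak_sets)
        chrom_map = build_consensus(peak_sets, cfg.nuc_size)
        log.info("%s: %d fragments, %d candidates across %d scales, %d calls",
                 chrom, len(frags), n_cand, len(peak_sets), len(chrom_map))
        all_calls.extend(chrom_map.calls)
    return NucleosomeMap(calls=all_calls, region=region, config=cfg)
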