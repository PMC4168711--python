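"""Synthetic nucleosome maps and reads, plus benchmark metrics.

Two generators cover the standard evaluation setups for paired-end
nucleosome callers:

* :func:`simulate_toy` — a single nucleosome probed at low coverage:
  146 bp fragments whose midpoints scatter as Normal(center, sd) around one
  dyad (defaults: center 300, sd 40, 20 reads, i.e. ~20-fold coverage).

* :func:`synthetic_nuc_map` — a chromosome-scale map in the style of
  nucleR's ``syntheticNucMap``: well-positioned nucleosomes on a regular
  grid of 147 bp cores separated by fixed linkers (midpoint sd 30), plus
  fuzzy nucleosomes dropped uniformly at random anywhere on the chromosome
  (midpoint sd 50), which may overlap others.  ``max_cover`` caps the
  per-nucleosome read depth.

The metrics mirror the usual benchmark readouts: positioning error against
the truth map, the adjacent-call distance histogram (whose mode should sit
at the core+linker period for a regular array), and the tight-pair filter
that collapses calls ≤148 bp apart to flag over-reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import NucleosomeMap
from .io import FragmentRecord

WELL_POSITIONED_SD = 30.0
FUZZY_SD = 50.0


@dataclass(frozen=True)
class TrueNucleosome:
    """Ground-truth nucleosome of a synthetic map."""

    center: float
    kind: str  # "well-positioned" | "fuzzy"
    midpoint_sd: float

    def __post_init__(self) -> None:
        if self.midpoint_sd <= 0:
            raise ValueError("midpoint_sd must be > 0")


@dataclass
class SyntheticMap:
    """A generated truth map and the parameters that produced it."""

    nucleosomes: list[TrueNucleosome]
    chrom: str
    chrom_length: int
    params: dict
    seed: int

    def __len__(self) -> int:
        return len(self.nucleosomes)

    def centers(self) -> np.ndarray:
        return np.asarray(sorted(n.center for n in self.nucleosomes))


def simulate_toy(center: float = 300.0, sd: float = 40.0, n_reads: int = 20,
                 read_len: int = 146, seed: int = 0,
                 chrom: str = "chrT") -> list[FragmentRecord]:
    """Fragments for a single (possibly fuzzy) nucleosome at low coverage."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    mids = np.rint(rng.normal(center, sd, size=n_reads)).astype(np.int64)
    starts = mids - read_len // 2
    starts = np.maximum(starts, 0)
    return [FragmentRecord(chrom, int(s), int(s) + read_len) for s in np.sort(starts)]


def synthetic_nuc_map(
    wp_num: int = 1100,
    wp_del: int = 100,
    wp_var: float = WELL_POSITIONED_SD,
    fuz_num: int = 0,
    fuz_var: float = FUZZY_SD,
    max_cover: int = 70,
    nuc_len: int = 147,
    lin_len: int = 20,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[SyntheticMap, list[FragmentRecord]]:
    """Regular well-positioned array with deletions plus random fuzzy extras.

    Grid positions sit every ``nuc_len + lin_len`` bp; ``wp_del`` of the
    ``wp_num`` grid nucleosomes are removed uniformly at random.  Fuzzy
    centers are uniform over the chromosome and may overlap anything.  The
    number of fragments per nucleosome is Uniform{⌈max_cover/2⌉..max_cover},
    so ``max_cover`` bounds per-nucleosome coverage.  Fragments have length
    ``nuc_len`` with midpoints Normal(center, sd of their nucleosome).
    """
    if wp_del > wp_num:
        raise ValueError("wp_del cannot exceed wp_num")
    if min(wp_num, fuz_num, wp_del) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    period = nuc_len + lin_len
    chrom_length = wp_num * period + lin_len

    nucs: list[TrueNucleosome] = []
    grid = np.arange(wp_num) * period + lin_len + nuc_len / 2.0
    keep = np.ones(wp_num, dtype=bool)
    if wp_del:
        keep[rng.choice(wp_num, size=wp_del, replace=False)] = False
    for c in grid[keep]:
        nucs.append(TrueNucleosome(float(c), "well-positioned", wp_var))
    half = nuc_len / 2.0
    for _ in range(fuz_num):
        c = rng.uniform(half, chrom_length - half)
        nucs.append(TrueNucleosome(float(c), "fuzzy", fuz_var))

    fragments: list[FragmentRecord] = []
    lo = max(1, int(np.ceil(max_cover / 2)))
    for nuc in nucs:
        count = int(rng.integers(lo, max_cover + 1))
        mids = rng.normal(nuc.center, nuc.midpoint_sd, size=count)
        starts = np.rint(mids).astype(np.int64) - nuc_len // 2
        starts = np.clip(starts, 0, max(0, chrom_length - nuc_len))
        fragments.extend(
            FragmentRecord(chrom, int(s), int(s) + nuc_len) for s in starts
        )
    fragments.sort(key=lambda f: f.start)
    params = dict(wp_num=wp_num, wp_del=wp_del, wp_var=wp_var, fuz_num=fuz_num,
                  fuz_var=fuz_var, max_cover=max_cover, nuc_len=nuc_len,
                  lin_len=lin_len)
    return SyntheticMap(nucs, chrom, chrom_length, params, seed), fragments


@dataclass
class MatchResult:
    """Greedy nearest-pair matching of calls to truth nucleosomes."""

    distances: np.ndarray
    unmatched_calls: int
    unmatched_truths: int

    @property
    def n_matched(self) -> int:
        return len(self.distances)


def positioning_error(true_map: SyntheticMap, called: NucleosomeMap,
                      max_distance: float = 100.0) -> MatchResult:
    """Distances between true centers and the matched call centers.

    Pairs are matched greedily by increasing distance, each truth and each
    call used at most once; pairs farther than ``max_distance`` apart are
    never matched and count as unmatched.
    """
    truths = true_map.centers()
    calls = called.centers(chrom=true_map.chrom if called.calls else None)
    if len(calls) == 0 or len(truths) == 0:
        return MatchResult(np.array([]), len(calls), len(truths))
    # candidate pairs within the cap, via a sorted window
    pairs: list[tuple[float, int, int]] = []
    for ci, q in enumerate(calls):
        lo = int(np.searchsorted(truths, q - max_distance))
        hi = int(np.searchsorted(truths, q + max_distance, side="right"))
        for ti in range(lo, hi):
            pairs.append((abs(q - truths[ti]), ti, ci))
    pairs.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    dists: list[float] = []
    for d, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        dists.append(d)
    return MatchResult(
        np.asarray(dists),
        unmatched_calls=len(calls) - len(used_c),
        unmatched_truths=len(truths) - len(used_t),
    )


def adjacent_distances(nuc_map: NucleosomeMap) -> np.ndarray:
    """Center-to-center distances between consecutive same-chromosome calls."""
    out: list[np.ndarray] = []
    chroms = sorted({p.chrom for p in nuc_map.calls})
    for chrom in chroms:
        qs = nuc_map.centers(chrom)
        if len(qs) >= 2:
            out.append(np.diff(qs))
    if not out:
        return np.array([])
    return np.concatenate(out)


def adjacent_distance_distribution(
    nuc_map: NucleosomeMap, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of adjacent-call distances."""
    d = adjacent_distances(nuc_map)
    if len(d) == 0:
        return np.array([], dtype=np.int64), np.array([])
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return counts, edges


def filter_close_nucleosomes(nuc_map: NucleosomeMap, threshold: float = 148.0) -> int:
    """Count calls after merging tight chains.

    Consecutive calls ≤ ``threshold`` bp apart are chained and each chain
    counts once, so a pair of tightly packed calls contributes a single
    nucleosome to the count.  This is the standard readout for detecting
    over-reporting in callers that pack calls back-to-back.
    """
    n = len(nuc_map.calls)
    if n == 0:
        return 0
    merged = 0
    chroms = sorted({p.chrom for p in nuc_map.calls})
    for chrom in chroms:
        qs = nuc_map.centers(chrom)
        if len(qs) >= 2:
            merged += int(np.count_nonzero(np.diff(qs) <= threshold))
    return n - merged


def subsample_fragments(fragments: Sequence[FragmentRecord], fraction: float,
                        seed: int = 0) -> list[FragmentRecord]:
    """Uniform random subset of ⌊fraction·n⌋ fragments, order-preserving."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(fragments)
    rng = np.random.default_rng(seed)
    n = len(fragments)
    k = int(np.floor(fraction * n))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [fragments[i] for i in idx]


def coverage_track(fragments: Sequence[FragmentRecord], length: int) -> np.ndarray:
    """Per-base fragment coverage over [0, length) of one chromosome."""
    cov = np.zeros(length + 1)
    for f in fragments:
        cov[max(0, f.start)] += 1
        cov[min(length, f.end)] -= 1
    return np.cumsum(cov)[:length]
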