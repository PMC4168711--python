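"""Fragment and nucleosome-map I/O.

Paired-end alignments (SAM/BAM, via pysam) or plain BED3 fragment tables are
turned into :class:`FragmentRecord` sequences; final nucleosome maps are
written as BED6.  All coordinates are 0-based half-open.  Fragment midpoints
are kept fractional (a fragment of odd length has a half-integer midpoint) to
avoid a systematic half-bp bias in downstream centroids.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: Insert-size filter bounds (bp): mates closer than 40 bp or farther than
#: 1000 bp apart are discarded.  Both bounds are inclusive on retention.
DEFAULT_MIN_INSERT = 40
DEFAULT_MAX_INSERT = 1000

#: Reported nucleosome footprint in BED output: center - 73 .. center + 74.
NUC_FOOTPRINT_LEFT = 73
NUC_FOOTPRINT_RIGHT = 74


@dataclass(frozen=True)
class FragmentRecord:
    """One mapped paired-end fragment (template).

    ``start`` is the leftmost aligned base of the left mate, ``end`` the
    exclusive right bound of the right mate.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        """Insert size w (bp)."""
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Fragment center µ = start + w/2; half-integer when w is odd."""
        return self.start + self.length / 2.0


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fragments(
    alignment_path: str | os.PathLike,
    region: GenomicRegion | None = None,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
    require_unique: bool = True,
) -> list[FragmentRecord]:
    """Read properly paired alignments and combine mates into fragments.

    Each template yields one fragment spanning the leftmost to the rightmost
    aligned base of the pair; it is taken from the leftmost mate (positive
    template length), so each pair is counted once.  Secondary, supplementary
    and unmapped records are skipped.  With ``require_unique``, records with
    mapping quality 0 (the usual multi-mapper convention) are skipped too.
    Fragments with insert size outside ``[min_insert, max_insert]`` are
    discarded; the bounds themselves are retained.
    """
    import pysam

    if min_insert >= max_insert:
        raise ValueError("min_insert must be < max_insert")
    path = os.fspath(alignment_path)
    if not os.path.exists(path):
        raise IOError(f"alignment file not found: {path}")
    mode = "rb" if path.endswith(".bam") else "r"
    af = pysam.AlignmentFile(path, mode)
    try:
        if region is not None:
            if region.chrom not in af.references:
                raise ValueError(
                    f"chromosome {region.chrom!r} absent from {path}; "
                    f"available: {', '.join(af.references)}"
                )
            try:
                it: Iterable = af.fetch(region.chrom, region.start, region.end)
            except ValueError as exc:
                raise IOError(
                    f"region query on {path} requires a coordinate-sorted, "
                    f"indexed file: {exc}"
                ) from exc
        else:
            it = af
        n_seen = n_nonproper = n_nonunique = n_insert = 0
        fragments: list[FragmentRecord] = []
        for aln in it:
            if not aln.is_paired or aln.is_unmapped or aln.mate_is_unmapped:
                n_nonproper += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                n_nonproper += 1
                continue
            if not aln.is_proper_pair:
                n_nonproper += 1
                continue
            tlen = aln.template_length
            if tlen <= 0:  # right mate (or degenerate pair): template counted at left mate
                continue
            n_seen += 1
            if require_unique and aln.mapping_quality == 0:
                n_nonunique += 1
                continue
            if tlen < min_insert or tlen > max_insert:
                n_insert += 1
                continue
            fragments.append(
                FragmentRecord(aln.reference_name, aln.reference_start,
                               aln.reference_start + tlen)
            )
    finally:
        af.close()
    log.info(
        "read %d templates from %s: kept %d, dropped %d non-proper records, "
        "%d non-unique, %d by insert size",
        n_seen, path, len(fragments), n_nonproper, n_nonunique, n_insert,
    )
    return fragments


def read_fragment_table(
    path: str | os.PathLike,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> list[FragmentRecord]:
    """Read a BED3-style fragment table (chrom, start, end; 0-based half-open).

    Applies the same insert-size filter as :func:`read_fragments`.
    """
    path = os.fspath(path)
    fragments: list[FragmentRecord] = []
    n_insert = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            w = end - start
            if w < min_insert or w > max_insert:
                n_insert += 1
                continue
            fragments.append(FragmentRecord(chrom, start, end))
    if n_insert:
        log.info("%s: dropped %d fragments by insert size", path, n_insert)
    return fragments


def write_fragment_table(fragments: Sequence[FragmentRecord],
                         path: str | os.PathLike) -> None:
    """Write fragments as BED3."""
    with open(os.fspath(path), "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def write_nucleosome_map(nuc_map, path: str | os.PathLike) -> None:
    """Write final calls as BED6 with a fixed 147 bp footprint.

    Columns: chrom, center-73, center+74, nuc<k>, score, ".".  The score is
    the landscape height at the call center mapped linearly onto [0, 1000]
    (negative heights clip to 0; an all-zero map scores 0).  Centers are
    rounded to the nearest base for the BED interval.
    """
    calls = sorted(nuc_map.calls, key=lambda p: (p.chrom, p.q))
    heights = [p.height for p in calls if p.height is not None]
    hmax = max((h for h in heights if h > 0), default=0.0)
    with open(os.fspath(path), "w") as fh:
        for k, p in enumerate(calls, start=1):
            center = int(round(p.q))
            if p.height is None or hmax <= 0:
                score = 0
            else:
                score = int(round(1000.0 * max(p.height, 0.0) / hmax))
            fh.write(
                f"{p.chrom}\t{center - NUC_FOOTPRINT_LEFT}\t"
                f"{center + NUC_FOOTPRINT_RIGHT}\tnuc{k}\t{score}\t.\n"
            )


def read_nucleosome_map(path: str | os.PathLike):
    """Read a BED nucleosome map back; centers are ``start + 73``.

    Returns a :class:`puffin.consensus.NucleosomeMap` whose calls carry only
    chromosome, center and score.
    """
    from .consensus import NucleosomeMap
    from .peaks import Peak

    calls = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start = parts[0], int(parts[1])
            center = start + NUC_FOOTPRINT_LEFT
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            calls.append(Peak(q=float(center), s=0.0, alpha=float("nan"),
                              height=score, q_raw=center, chrom=chrom))
    calls.sort(key=lambda p: (p.chrom, p.q))
    return NucleosomeMap(calls=calls, region=None, config=None, validate=False)


def write_wiggle(region: GenomicRegion, values, path: str | os.PathLike,
                 name: str = "track") -> None:
    """Dump a sampled per-base track (profile or landscape) as fixedStep wiggle."""
    with open(os.fspath(path), "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        # wiggle is 1-based
        fh.write(f"fixedStep chrom={region.chrom} start={region.start + 1} step=1\n")
        for v in values:
            fh.write(f"{v:.6g}\n")
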