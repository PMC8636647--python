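"""Core genomic-interval model: BED I/O, overlap detection, multi-track
consensus and seeded genome-wide shuffling.

All coordinates are 0-based half-open (BED convention). Two intervals that
merely abut — ``[100, 200)`` and ``[200, 300)`` — do not overlap; a single
shared base pair is enough to count as an overlap. Features are treated as
strandless throughout: the analyses built on this module use positional
overlap only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "IntervalTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "overlap_flags",
    "consensus_intervals",
    "merge_intervals",
    "shuffle_track",
    "subseed",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines (bad coordinates, unknown chromosome)."""


class GenomicInterval(NamedTuple):
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "GenomicInterval":
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        return self

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome build: chromosome names and their lengths in bp."""

    name: str
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("assembly needs at least one chromosome")
        for chrom, size in self.chrom_sizes.items():
            if int(size) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    def size(self, chrom: str) -> int:
        try:
            return int(self.chrom_sizes[chrom])
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly {self.name!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def check(self, iv: GenomicInterval) -> GenomicInterval:
        if iv.end > self.size(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.size(iv.chrom)} in assembly {self.name!r}"
            )
        return iv


@dataclass
class IntervalTrack:
    """An ordered collection of intervals (e.g. one ENCODE TFBS dataset).

    ``sorted`` records whether ``intervals`` is ordered by
    ``(chrom, start, end)``; overlap and consensus operations require it.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    sorted: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalTrack):
            return NotImplemented
        return self.name == other.name and self.intervals == other.intervals

    def sort(self) -> "IntervalTrack":
        """Return a copy sorted by (chrom, start, end)."""
        return IntervalTrack(self.name, sorted(self.intervals), sorted=True)

    def dedupe(self) -> "IntervalTrack":
        """Return a sorted copy with exact-duplicate intervals collapsed."""
        uniq = sorted(set(self.intervals))
        return IntervalTrack(self.name, uniq, sorted=True)

    def merged(self) -> "IntervalTrack":
        """Return a sorted copy with overlapping/abutting-free coverage.

        Overlapping intervals are unioned into maximal runs; abutting
        intervals stay separate (they share no base).
        """
        track = self if self.sorted else self.sort()
        return IntervalTrack(self.name, merge_intervals(track.intervals), sorted=True)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays; requires a sorted track."""
        if not self.sorted:
            raise ValueError(f"track {self.name!r} is unsorted: call .sort() first")
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        i = 0
        ivs = self.intervals
        n = len(ivs)
        while i < n:
            chrom = ivs[i].chrom
            j = i
            while j < n and ivs[j].chrom == chrom:
                j += 1
            out[chrom] = (
                np.fromiter((iv.start for iv in ivs[i:j]), dtype=np.int64, count=j - i),
                np.fromiter((iv.end for iv in ivs[i:j]), dtype=np.int64, count=j - i),
            )
            i = j
        return out


# ---------------------------------------------------------------------------
# BED and chromosome-sizes I/O
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    dedupe: bool = False,
    name: str | None = None,
) -> IntervalTrack:
    """Read a BED3+ file into a sorted :class:`IntervalTrack`.

    Columns beyond the first three are ignored; ``track``/``browser``/``#``
    header lines are skipped. With an assembly bound, intervals on unknown
    chromosomes or past the chromosome end are errors; without one, rows are
    kept as-is.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} "
                    "(require 0 <= start < end)"
                )
            iv = GenomicInterval(chrom, start, end)
            if assembly is not None:
                if chrom not in assembly:
                    raise BedParseError(
                        f"{path}:{lineno}: chromosome {chrom!r} not in assembly "
                        f"{assembly.name!r}"
                    )
                try:
                    assembly.check(iv)
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from None
            intervals.append(iv)
    track = IntervalTrack(name or path.stem, intervals)
    return track.dedupe() if dedupe else track.sort()


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    """Write a track as BED3 (tab-separated, 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a two-column ``<chrom>\\t<length>`` table into an assembly."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected '<chrom>\\t<length>'")
            chrom, size = fields[0], int(fields[1])
            if chrom in sizes:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = size
    return GenomeAssembly(name or path.stem, sizes)


# ---------------------------------------------------------------------------
# Overlap detection
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping intervals in a (chrom,start,end)-sorted sequence.

    Abutting intervals are not joined: coverage semantics only, and two
    half-open intervals sharing just an endpoint share no base.
    """
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def overlap_flags(query: IntervalTrack, subject: IntervalTrack) -> np.ndarray:
    """One boolean per query interval: does it share >=1 bp with the subject?

    Any degree of intersection counts. Both tracks must be sorted; the sweep
    merges the subject per chromosome and binary-searches each query against
    the resulting disjoint runs.
    """
    for t in (query, subject):
        if not t.sorted:
            raise ValueError(f"track {t.name!r} is unsorted: call .sort() first")
    subj = {
        chrom: (s, e)
        for chrom, (s, e) in IntervalTrack("m", merge_intervals(subject.intervals), True)
        .by_chrom()
        .items()
    }
    flags = np.zeros(len(query), dtype=bool)
    pos = 0
    for chrom, (qs, qe) in query.by_chrom().items():
        n = qs.size
        if chrom in subj:
            ss, se = subj[chrom]
            idx = np.searchsorted(ss, qe, side="left")
            hit = idx > 0
            hit[hit] = se[idx[hit] - 1] > qs[hit]
            flags[pos : pos + n] = hit
        pos += n
    return flags


def _coords_overlap_flags(
    query_by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
    subject: IntervalTrack,
) -> np.ndarray:
    """Overlap sweep against pre-extracted query coordinate arrays.

    Fast path used by the permutation loop, which re-tests the same query
    set against many shuffled subjects.
    """
    merged = merge_intervals(sorted(subject.intervals))
    subj: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    i = 0
    while i < len(merged):
        chrom = merged[i].chrom
        j = i
        while j < len(merged) and merged[j].chrom == chrom:
            j += 1
        subj[chrom] = (
            np.fromiter((iv.start for iv in merged[i:j]), dtype=np.int64, count=j - i),
            np.fromiter((iv.end for iv in merged[i:j]), dtype=np.int64, count=j - i),
        )
        i = j
    total = sum(qs.size for qs, _ in query_by_chrom.values())
    flags = np.zeros(total, dtype=bool)
    pos = 0
    for chrom, (qs, qe) in query_by_chrom.items():
        n = qs.size
        if chrom in subj:
            ss, se = subj[chrom]
            idx = np.searchsorted(ss, qe, side="left")
            hit = idx > 0
            hit[hit] = se[idx[hit] - 1] > qs[hit]
            flags[pos : pos + n] = hit
        pos += n
    return flags


# ---------------------------------------------------------------------------
# Multi-track consensus
# ---------------------------------------------------------------------------

def consensus_intervals(
    tracks: Sequence[IntervalTrack], name: str = "consensus"
) -> IntervalTrack:
    """Maximal intervals covered simultaneously by every input track.

    Each track is first merged to disjoint coverage, then coverage is
    intersected across tracks (per-base agreement of all datasets). The
    result is sorted and non-overlapping. With a single track this is just
    its merged coverage.
    """
    if not tracks:
        raise ValueError("consensus requires at least one track")
    result = tracks[0].merged().intervals
    for track in tracks[1:]:
        result = _intersect_sorted(result, track.merged().intervals)
        if not result:
            break
    return IntervalTrack(name, result, sorted=True)


def _intersect_sorted(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Two-pointer intersection of sorted, per-track-disjoint interval lists."""
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        start = max(x.start, y.start)
        end = min(x.end, y.end)
        if start < end:
            out.append(GenomicInterval(x.chrom, start, end))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def track_overlap_union(
    tracks: Sequence[IntervalTrack], name: str = "agreement"
) -> IntervalTrack:
    """Alternative agreement rule: regions of the first track's coverage that
    overlap (anywhere, >=1 bp) every other track.

    This reads "all datasets agreed" as each dataset having *some* overlap
    with the region rather than covering the same bases. Kept selectable so
    both readings of the agreement rule are available; per-base consensus
    (:func:`consensus_intervals`) is the default throughout.
    """
    if not tracks:
        raise ValueError("agreement requires at least one track")
    base = tracks[0].merged()
    keep = np.ones(len(base), dtype=bool)
    for other in tracks[1:]:
        keep &= overlap_flags(base, other.sort() if not other.sorted else other)
    return IntervalTrack(
        name, [iv for iv, k in zip(base.intervals, keep) if k], sorted=True
    )


# ---------------------------------------------------------------------------
# Genome-wide shuffling (the permutation-null primitive)
# ---------------------------------------------------------------------------

def subseed(seed: int, index: int) -> int:
    """Deterministic, platform-stable sub-seed for permutation ``index``.

    splitmix64 finalizer applied to ``seed * 2^32 + index`` (mod 2^64),
    truncated to 31 bits so derived seeds stay small non-negative integers.
    """
    z = ((int(seed) << 32) + int(index)) & 0xFFFFFFFFFFFFFFFF
    z = (z + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def shuffle_track(
    track: IntervalTrack,
    assembly: GenomeAssembly,
    seed: int | np.random.Generator,
) -> IntervalTrack:
    """Randomly replace each interval elsewhere in the genome, length kept.

    For an interval of length L, a chromosome is drawn with probability
    proportional to its number of valid placements (chrom_length - L + 1)
    and the start uniformly among them — i.e. uniform over all genome-wide
    placements. Shuffled intervals may overlap one another; no regions are
    excluded. Deterministic given an integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(assembly.chrom_sizes)
    sizes = np.array([assembly.chrom_sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.fromiter((iv.length for iv in track), dtype=np.int64, count=len(track))
    if lengths.size == 0:
        return IntervalTrack(track.name, [], sorted=True)
    npos = sizes[None, :] - lengths[:, None] + 1  # valid starts per (interval, chrom)
    np.clip(npos, 0, None, out=npos)
    row_tot = npos.sum(axis=1)
    if (row_tot == 0).any():
        bad = lengths[row_tot == 0].max()
        raise ValueError(
            f"interval of length {bad} exceeds every chromosome in {assembly.name!r}"
        )
    cum = np.cumsum(npos, axis=1)
    # one uniform draw picks (chromosome, start) jointly
    u = rng.integers(0, row_tot)  # np.int64 draws in [0, row_tot)
    ci = (u[:, None] >= cum).sum(axis=1)
    prev = np.where(ci > 0, cum[np.arange(lengths.size), ci - 1], 0)
    starts = u - prev
    out = [
        GenomicInterval(chroms[c], int(s), int(s + l))
        for c, s, l in zip(ci, starts, lengths)
    ]
    return IntervalTrack(track.name, sorted(out), sorted=True)
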