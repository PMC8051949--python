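"""Genomic interval accounting: maintained / gained / lost peaks over named regions.

Peak sets are plain sorted interval lists (0-based, half-open) loaded from
3+ column BED.  Overlapping intervals within one set are merged on load, so
the comparison below operates on disjoint intervals per condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from .errors import BedParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "PeakSet",
    "RegionComparison",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "peaks_in_region",
    "compare_peaksets",
    "make_flanks",
    "merge_replicates",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """Sorted, within-set disjoint peaks for one condition."""

    condition: str = ""
    peaks: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self):
        self.peaks, n_merged = merge_intervals(self.peaks)
        if n_merged:
            logger.info(
                "peak set %r: merged %d overlapping input intervals",
                self.condition,
                n_merged,
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class RegionComparison:
    """Maintained / gained / lost accounting for two peak sets over one region.

    ``maintained`` counts peaks of B that overlap (>= 1 bp) some peak of A;
    ``maintained_in_a`` is the A-side analogue.  The two differ only when a
    single peak spans several peaks of the other set.
    """

    region: str
    n_a: int
    n_b: int
    maintained: int
    gained_in_b: int
    lost_in_b: int
    maintained_in_a: int
    pct_novel_a: float
    pct_novel_b: float


def merge_intervals(
    peaks: list[GenomicRegion],
) -> tuple[list[GenomicRegion], int]:
    """Sort by (chrom, start) and merge any intervals sharing >= 1 bp.

    Returns the merged list and the number of input intervals that were
    absorbed into another.
    """
    if not peaks:
        return [], 0
    out: list[GenomicRegion] = []
    n_merged = 0
    for p in sorted(peaks):
        if out and out[-1].chrom == p.chrom and p.start < out[-1].end:
            prev = out[-1]
            out[-1] = replace(prev, end=max(prev.end, p.end))
            n_merged += 1
        else:
            out.append(p)
    return out, n_merged


def read_bed(path, condition: str = "") -> PeakSet:
    """Read a 3+ column BED file (0-based, half-open) into a :class:`PeakSet`.

    Malformed lines raise :class:`BedParseError` carrying the line number.
    Track/browser/comment lines and blank lines are skipped.
    """
    peaks = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"expected >= 3 columns, got {len(fields)}", i)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates: {exc}", i) from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                peaks.append(GenomicRegion(chrom, start, end, name))
            except ValueError as exc:
                raise BedParseError(str(exc), i) from exc
    if condition == "":
        condition = str(path)
    return PeakSet(condition=condition, peaks=peaks)


def write_bed(peakset: PeakSet, path) -> None:
    """Write a peak set as 3- or 4-column BED."""
    with open(path, "w") as fh:
        for p in peakset:
            cols = [p.chrom, str(p.start), str(p.end)]
            if p.name:
                cols.append(p.name)
            fh.write("\t".join(cols) + "\n")


def peaks_in_region(peakset: PeakSet, region: GenomicRegion) -> PeakSet:
    """Peaks whose midpoint lies within ``[region.start, region.end)``.

    The midpoint rule assigns each peak to exactly one of a set of
    contiguous windows.
    """
    kept = [
        p
        for p in peakset
        if p.chrom == region.chrom and region.start <= p.midpoint < region.end
    ]
    return PeakSet(condition=peakset.condition, peaks=kept)


def _overlap_flags(query: list[GenomicRegion], subject: list[GenomicRegion]) -> list[bool]:
    """For each (sorted, disjoint) query peak: does it overlap any subject peak?

    Linear sweep over the two sorted lists, per chromosome.
    """
    flags = [False] * len(query)
    by_chrom: dict[str, list[tuple[int, GenomicRegion]]] = {}
    for i, q in enumerate(query):
        by_chrom.setdefault(q.chrom, []).append((i, q))
    subj_by_chrom: dict[str, list[GenomicRegion]] = {}
    for s in subject:
        subj_by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, items in by_chrom.items():
        subs = subj_by_chrom.get(chrom, [])
        j = 0
        for i, q in items:
            # advance past subjects ending at or before the query start
            while j < len(subs) and subs[j].end <= q.start:
                j += 1
            if j < len(subs) and subs[j].start < q.end:
                flags[i] = True
    return flags


def compare_peaksets(
    a: PeakSet,
    b: PeakSet,
    region: GenomicRegion | None = None,
) -> RegionComparison:
    """Count maintained / gained / lost peaks of ``b`` relative to ``a``.

    If ``region`` is given, both sets are first restricted to peaks whose
    midpoint falls in the region.  A peak of B is *maintained* iff it
    overlaps >= 1 bp some peak of A, else *gained*; a peak of A with no
    overlap in B is *lost*.
    """
    if region is not None:
        a = peaks_in_region(a, region)
        b = peaks_in_region(b, region)
        name = region.name or f"{region.chrom}:{region.start}-{region.end}"
    else:
        name = "all"
    b_flags = _overlap_flags(b.peaks, a.peaks)
    a_flags = _overlap_flags(a.peaks, b.peaks)
    maintained = sum(b_flags)
    maintained_in_a = sum(a_flags)
    gained = len(b) - maintained
    lost = len(a) - maintained_in_a
    return RegionComparison(
        region=name,
        n_a=len(a),
        n_b=len(b),
        maintained=maintained,
        gained_in_b=gained,
        lost_in_b=lost,
        maintained_in_a=maintained_in_a,
        pct_novel_a=100.0 * lost / len(a) if len(a) else float("nan"),
        pct_novel_b=100.0 * gained / len(b) if len(b) else float("nan"),
    )


def make_flanks(
    region: GenomicRegion,
    n_per_side: int,
    chrom_length: int | None = None,
) -> list[GenomicRegion]:
    """Contiguous same-width windows on each side of ``region``.

    Windows are named ``5p-1..`` (nearest first, walking away from the
    region) and ``3p-1..``.  Windows truncated by the chromosome start (or
    ``chrom_length``) are shortened with a warning; fully out-of-range
    windows are dropped.
    """
    width = region.length
    flanks: list[GenomicRegion] = []
    for k in range(1, n_per_side + 1):
        start = region.start - k * width
        end = region.start - (k - 1) * width
        if end <= 0:
            warnings.warn(f"5' flank {k} of {region.name or region.chrom} out of range; dropped")
            continue
        if start < 0:
            warnings.warn(f"5' flank {k} of {region.name or region.chrom} truncated at 0")
            start = 0
        flanks.append(GenomicRegion(region.chrom, start, end, f"5p-{k}"))
    for k in range(1, n_per_side + 1):
        start = region.end + (k - 1) * width
        end = region.end + k * width
        if chrom_length is not None:
            if start >= chrom_length:
                warnings.warn(f"3' flank {k} of {region.name or region.chrom} out of range; dropped")
                continue
            if end > chrom_length:
                warnings.warn(f"3' flank {k} of {region.name or region.chrom} truncated")
                end = chrom_length
        flanks.append(GenomicRegion(region.chrom, start, end, f"3p-{k}"))
    return flanks


def merge_replicates(sets: list[PeakSet], how: str = "intersection") -> PeakSet:
    """Collapse replicate peak sets into one per-condition set.

    ``intersection`` (default) keeps the overlapping portions present in all
    replicates; ``union`` merges everything.
    """
    if not sets:
        raise ValueError("no peak sets given")
    if how == "union":
        peaks = [p for s in sets for p in s]
        return PeakSet(condition=sets[0].condition, peaks=peaks)
    if how != "intersection":
        raise ValueError(f"unknown merge mode: {how!r}")
    current = list(sets[0])
    for other in sets[1:]:
        nxt = []
        for p in current:
            for q in other:
                if p.overlaps(q):
                    nxt.append(
                        GenomicRegion(
                            p.chrom, max(p.start, q.start), min(p.end, q.end), p.name
                        )
                    )
        current = nxt
    return PeakSet(condition=sets[0].condition, peaks=current)
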