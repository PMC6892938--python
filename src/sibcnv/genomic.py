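"""Genomic interval primitives shared by every pipeline stage.

Coordinates are internally 0-based half-open throughout the package.
Array-style CNV call tables are parsed as 1-based inclusive and converted
on read (see :mod:`sibcnv.io`); BED tracks are already 0-based half-open.
Chromosome labels are normalized by stripping any ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: Recognized chromosome labels after normalization.
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

DELETION = "deletion"
DUPLICATION = "duplication"
COPY_STATES = frozenset({DELETION, DUPLICATION})

_COPY_STATE_ALIASES = {
    "del": DELETION,
    "deletion": DELETION,
    "loss": DELETION,
    "dup": DUPLICATION,
    "duplication": DUPLICATION,
    "gain": DUPLICATION,
}


class GenomicsError(ValueError):
    """Raised on invalid genomic records or coordinates."""


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and validate against the known chromosome set."""
    if not label:
        raise GenomicsError("empty chromosome label")
    chrom = label[3:] if label.lower().startswith("chr") else label
    if chrom not in VALID_CHROMS:
        raise GenomicsError(f"unknown chromosome label: {label!r}")
    return chrom


def parse_copy_state(value: str) -> str:
    try:
        return _COPY_STATE_ALIASES[value.strip().lower()]
    except KeyError:
        raise GenomicsError(f"unknown copy state: {value!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end <= self.start:
            raise GenomicsError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise GenomicsError(f"negative start: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvCall:
    """A single-algorithm CNV call for one sample."""

    sample_id: str
    interval: GenomicInterval
    copy_state: str
    n_probes: int
    algorithm: str

    def __post_init__(self) -> None:
        if self.copy_state not in COPY_STATES:
            raise GenomicsError(f"invalid copy state: {self.copy_state!r}")
        if self.n_probes < 1:
            raise GenomicsError(f"n_probes must be >= 1, got {self.n_probes}")


@dataclass(frozen=True)
class TrackRecord:
    """One annotation-track interval with optional metadata."""

    interval: GenomicInterval
    name: str | None = None
    fields: tuple[str, ...] = ()


@dataclass
class AnnotationTrack:
    """A named collection of intervals; coverage uses their union."""

    name: str
    records: list[TrackRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[TrackRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[GenomicInterval]) -> "AnnotationTrack":
        return cls(name, [TrackRecord(iv) for iv in intervals])

    def merged(self, chrom: str) -> list[tuple[int, int]]:
        """Union of track intervals on ``chrom``, as sorted disjoint spans."""
        spans = sorted(
            (r.interval.start, r.interval.end)
            for r in self.records
            if r.interval.chrom == chrom
        )
        out: list[tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out


def interval_overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); the standard CNV matching criterion."""
    olap = interval_overlap_length(a, b)
    if olap == 0:
        return 0.0
    return min(olap / a.length, olap / b.length)


def coverage_fraction(target: GenomicInterval, track: AnnotationTrack) -> float:
    """Fraction of ``target`` covered by the union of track intervals."""
    covered = 0
    for s, e in track.merged(target.chrom):
        covered += max(0, min(target.end, e) - max(target.start, s))
    return covered / target.length
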