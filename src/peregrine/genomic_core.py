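"""Interval data model and overlap predicates.

All coordinates are 0-based half-open (BED convention). One-based external
coordinates (VCF POS, GTEx variant positions) are converted at the I/O
boundary, never here. Threshold comparisons are inclusive (``>=``) and are
evaluated in exact rational arithmetic so that boundary cases such as "exactly
50% of the enhancer" or "exactly 90% contained" are decided correctly
regardless of binary floating-point representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Sequence, Tuple, TypeVar, Generic, Union

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "StrandedPoint",
    "ValidationError",
    "ParameterError",
    "overlap_bp",
    "fraction_of",
    "reciprocal_or",
    "contained_fraction",
    "point_in",
    "IntervalIndex",
    "build_index",
]


class ValidationError(ValueError):
    """An input record violates a structural invariant."""


class ParameterError(ValueError):
    """A threshold or option is outside its admissible range."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Zero- and negative-length intervals are rejected: every region handled by
    the pipeline (enhancer, ChIA-PET anchor, TAD, promoter-interacting region)
    covers at least one base.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end})"


@dataclass(frozen=True)
class StrandedPoint:
    """A single 0-based genomic position with a strand.

    Used for gene transcription start sites and for eQTL positions (for which
    the strand carries no meaning and defaults to ``+``).
    """

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.chrom:
            raise ValidationError("point chromosome name is empty")


def _as_exact_fraction(t: float) -> Fraction:
    # Fraction(str(t)) so a caller's 0.9 means exactly 9/10; Fraction(0.9)
    # would be the binary neighbour just below and misjudge the boundary.
    return Fraction(str(t))


def _check_threshold(t: float) -> Fraction:
    ft = _as_exact_fraction(t)
    if not (0 < ft <= 1):
        raise ParameterError(f"overlap threshold must be in (0, 1], got {t}")
    return ft


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def fraction_of(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of *a* covered by *b* (asymmetric; in [0, 1])."""
    return overlap_bp(a, b) / a.length


def reciprocal_or(a: GenomicInterval, b: GenomicInterval, t: float) -> bool:
    """True when at least fraction *t* of **either** interval is covered by the other.

    This is the reciprocal-OR rule used to decide whether a ChIA-PET anchor
    "contains" an enhancer or a promoter: a short element fully inside a broad
    anchor qualifies via its own fraction, and a broad element engulfed by a
    short anchor qualifies via the anchor's fraction.
    """
    ft = _check_threshold(t)
    ov = overlap_bp(a, b)
    if ov == 0:
        return False
    # ov / len >= p/q  <=>  ov * q >= p * len  (exact integer comparison)
    p, q = ft.numerator, ft.denominator
    return ov * q >= p * a.length or ov * q >= p * b.length


def contained_fraction(a: GenomicInterval, region: GenomicInterval, t: float) -> bool:
    """True when at least fraction *t* of *a* lies inside *region* (one-directional)."""
    ft = _check_threshold(t)
    ov = overlap_bp(a, region)
    p, q = ft.numerator, ft.denominator
    return ov * q >= p * a.length


def point_in(p: Union[StrandedPoint, int], a: GenomicInterval, chrom: str | None = None) -> bool:
    """True when the point lies inside the half-open interval.

    Accepts either a :class:`StrandedPoint` or a bare integer position plus an
    explicit ``chrom``.
    """
    if isinstance(p, StrandedPoint):
        pc, pos = p.chrom, p.pos
    else:
        if chrom is None:
            raise ParameterError("bare positions require an explicit chrom")
        pc, pos = chrom, int(p)
    return pc == a.chrom and a.start <= pos < a.end


T = TypeVar("T")


@dataclass
class IntervalIndex(Generic[T]):
    """Per-chromosome interval tree over (interval, payload) pairs.

    Query results are returned deterministically sorted by
    (chrom, start, end, insertion rank) and are exactly the set an all-pairs
    scan would return; the tree is an acceleration structure only.
    """

    _trees: dict = field(default_factory=dict)
    _items: list = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[GenomicInterval, T]]) -> "IntervalIndex[T]":
        idx: IntervalIndex[T] = cls()
        for iv, payload in pairs:
            idx._add(iv, payload)
        return idx

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex[GenomicInterval]":
        return cls.from_pairs((iv, iv) for iv in intervals)

    def _add(self, iv: GenomicInterval, payload: T) -> None:
        rank = len(self._items)
        self._items.append((iv, payload))
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rank)

    def __len__(self) -> int:
        return len(self._items)

    def query(self, q: Union[GenomicInterval, StrandedPoint]) -> list:
        """All (interval, payload) pairs overlapping the query by >= 1 bp.

        Point queries use the half-open convention (a point at ``end`` does
        not hit).
        """
        if isinstance(q, StrandedPoint):
            tree = self._trees.get(q.chrom)
            hits = tree[q.pos] if tree is not None else ()
        else:
            tree = self._trees.get(q.chrom)
            hits = tree.overlap(q.start, q.end) if tree is not None else ()
        ranks = sorted(h.data for h in hits)
        out = [self._items[r] for r in ranks]
        out.sort(key=lambda item: (item[0].chrom, item[0].start, item[0].end))
        return out

    def __iter__(self) -> Iterator[Tuple[GenomicInterval, T]]:
        return iter(self._items)


def build_index(intervals: Sequence[GenomicInterval]) -> IntervalIndex[GenomicInterval]:
    """Index a list of intervals for overlap queries (payload = the interval)."""
    return IntervalIndex.from_intervals(intervals)
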