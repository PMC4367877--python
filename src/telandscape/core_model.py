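"""Shared coordinate types, filter settings, and elementary interval arithmetic.

Everything downstream — annotation parsing, repeat-hit parsing, distribution
panels, TE-gene proximity — speaks in terms of :class:`SeqRegion`, a stranded
1-based inclusive interval on a named chromosome.  This module is pure and
touches no files and no nucleotide sequence; it deals only in coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."

_VALID_STRANDS = (FORWARD, REVERSE, UNSTRANDED)


class IncomparableRegionsError(ValueError):
    """Raised when an operation mixes regions from different chromosomes."""


@dataclass(frozen=True)
class SeqRegion:
    """A stranded genomic interval, 1-based and inclusive at both ends.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    start, end : int
        First and last base of the interval (1-based, both inclusive).
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        # integer midpoint; for even lengths this is the left-of-centre base
        return (self.start + self.end) // 2

    def overlaps(self, other: "SeqRegion") -> bool:
        if self.chrom != other.chrom:
            return False
        return self.start <= other.end and other.start <= self.end


class RegionCategory(Enum):
    """Position of a TE copy relative to its nearest gene."""

    PROXIMAL_PROMOTER = "ProximalPromoter"
    PROXIMAL_3_END = "Proximal3End"
    EXON_INTRON_UTR = "ExonIntronUTR"
    INTERGENIC = "Intergenic"

    def __str__(self) -> str:  # used when writing TSVs
        return self.value


@dataclass(frozen=True)
class FilterSettings:
    """Size and similarity windows applied to TE copies before any panel.

    Similarity bounds default to the 50-100% window; size bounds default to
    ``None``, meaning "the observed minimum/maximum of the copies being
    filtered".  All bounds are inclusive.
    """

    size_min: Optional[int] = None
    size_max: Optional[int] = None
    sim_min: float = 50.0
    sim_max: float = 100.0

    def __post_init__(self) -> None:
        if self.size_min is not None and self.size_max is not None:
            if self.size_min > self.size_max:
                raise ValueError("size_min > size_max")
        if not (0.0 <= self.sim_min <= 100.0 and 0.0 <= self.sim_max <= 100.0):
            raise ValueError("similarity bounds must lie in [0, 100]")
        if self.sim_min > self.sim_max:
            raise ValueError("sim_min > sim_max")


@dataclass(frozen=True)
class ProximityConfig:
    """Parameters of the TE-gene proximity analyses.

    ``proximal_distance`` is the promoter/3'-end distance cutoff in bp
    (inclusive).  ``region_bins`` is the number of intervals of the
    within-region distance histogram; ``family_limit`` caps how many TE
    families one run may select; ``display_threshold`` is the fraction below
    which GO slices are pooled into "other" for display; ``min_organisms`` is
    the minimum number of organisms a TE-gene couple must appear in.
    """

    proximal_distance: int = 3000
    region_bins: int = 20
    family_limit: int = 20
    display_threshold: float = 0.01
    min_organisms: int = 1

    def __post_init__(self) -> None:
        if self.proximal_distance < 0:
            raise ValueError("proximal_distance must be >= 0")
        if self.region_bins < 1 or self.family_limit < 1:
            raise ValueError("region_bins and family_limit must be >= 1")
        if not 0.0 <= self.display_threshold <= 1.0:
            raise ValueError("display_threshold must lie in [0, 1]")
        if self.min_organisms < 1:
            raise ValueError("min_organisms must be >= 1")


@dataclass(frozen=True)
class BinnedCurve:
    """Bin boundaries plus one count per bin (len(counts) == len(edges) - 1)."""

    edges: tuple
    counts: tuple

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("need exactly one count per bin")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def region_gap(a: SeqRegion, b: SeqRegion) -> int:
    """Number of bases strictly between two regions on the same chromosome.

    Overlapping or book-ended (adjacent) regions have gap 0.  Symmetric in
    its arguments.

    Raises
    ------
    IncomparableRegionsError
        If the regions lie on different chromosomes.
    """
    if a.chrom != b.chrom:
        raise IncomparableRegionsError(
            f"cannot measure a gap across chromosomes {a.chrom!r} and {b.chrom!r}"
        )
    if a.start > b.start:
        a, b = b, a
    gap = b.start - a.end - 1
    return max(gap, 0)


def union_length(regions: Sequence[SeqRegion]) -> int:
    """Distinct base positions covered by at least one region.

    All regions must share one chromosome; duplicates and overlaps count
    each base once.  An empty list covers 0 bp.
    """
    if not regions:
        return 0
    chroms = {r.chrom for r in regions}
    if len(chroms) > 1:
        raise IncomparableRegionsError(
            f"union_length needs a single chromosome, got {sorted(chroms)}"
        )
    ivals = sorted((r.start, r.end) for r in regions)
    covered = 0
    cur_start, cur_end = ivals[0]
    for s, e in ivals[1:]:
        if s <= cur_end + 1:  # overlap or adjacency: extend
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    covered += cur_end - cur_start + 1
    return covered


def apply_filters(tes: Sequence, settings: FilterSettings) -> list:
    """Keep TE copies passing the size and similarity windows (inclusive).

    ``None`` size bounds resolve to the observed minimum/maximum length of
    the input, i.e. the default slider positions.  Order is preserved and the
    operation is idempotent.
    """
    tes = list(tes)
    if not tes:
        return []
    lengths = [t.region.length for t in tes]
    lo = settings.size_min if settings.size_min is not None else min(lengths)
    hi = settings.size_max if settings.size_max is not None else max(lengths)
    if lo > hi:
        raise ValueError(f"resolved size window is empty: [{lo}, {hi}]")
    return [
        t
        for t, n in zip(tes, lengths)
        if lo <= n <= hi and settings.sim_min <= t.similarity <= settings.sim_max
    ]
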