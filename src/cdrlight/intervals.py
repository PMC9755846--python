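"""Deletion-interval cohorts: coverage profiles, common deletion regions,
amplicon containment.

A *common deletion region* (CDR) of a gene is the sub-interval contained in
(nearly) all somatic deletion fragments observed for that gene across a
cohort.  Coverage here is plain interval stabbing depth: the depth at a
genomic position is the number of deletion fragments whose interval contains
it.  The CDR candidate is the maximal-depth run of the coverage step
function; whether it is *called* a CDR depends on a support-fraction and a
minimum-length rule.

Coordinates are 1-based inclusive throughout, matching how genomic
coordinates are printed (e.g. ``chr9:21,970,277-21,975,386``).  BED input is
converted on read by :mod:`cdrlight.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, InputError

__all__ = [
    "GenomicInterval",
    "Source",
    "Zygosity",
    "DeletionRecord",
    "DeletionCohort",
    "CoverageProfile",
    "CdrResult",
    "Amplicon",
    "coverage_profile",
    "find_cdr",
    "amplicon_coverage",
    "combined_amplicon_coverage",
    "interval_length_kb",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval.

    ``length`` is ``end - start + 1``; a single base has length 1.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("interval chromosome must be non-empty")
        if self.start < 1:
            raise InputError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InputError(
                f"interval end < start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully within this interval (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:  # chr9:21970277-21975386
        return f"{self.chrom}:{self.start}-{self.end}"


class Source(str, enum.Enum):
    """Provenance of a deletion call: SNP-array estimate vs base-resolution sequencing."""

    SNP_ARRAY_ESTIMATED = "snp_array_estimated"
    SEQUENCING_BASE_RESOLUTION = "sequencing_base_resolution"
    UNKNOWN = "unknown"


class Zygosity(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DeletionRecord:
    """One contiguous somatic deletion fragment in one sample.

    A sample may contribute several fragments; coverage counts fragments,
    not samples.
    """

    sample_id: str
    interval: GenomicInterval
    source: Source = Source.UNKNOWN
    zygosity: Zygosity = Zygosity.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise InputError("sample_id must be non-empty")


@dataclass(frozen=True)
class DeletionCohort:
    """A cohort of deletion fragments over one analysis window (*locus*)."""

    records: tuple[DeletionRecord, ...]
    locus: GenomicInterval
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if rec.interval.chrom != self.locus.chrom:
                raise InputError(
                    f"record {rec.sample_id} ({rec.interval}) is not on locus "
                    f"chromosome {self.locus.chrom}"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def filter_zygosity(self, zygosity: Zygosity) -> "DeletionCohort":
        kept = tuple(r for r in self.records if r.zygosity == zygosity)
        return DeletionCohort(kept, self.locus, self.genome_build)


@dataclass(frozen=True)
class CoverageProfile:
    """Step function of deletion depth along the chromosome.

    ``breakpoints`` are the sorted coordinates where the depth may change;
    ``depths[i]`` is the depth on the half-open segment
    ``[breakpoints[i], breakpoints[i+1])``.  Depth is 0 outside
    ``[breakpoints[0], breakpoints[-1])``.
    """

    chrom: str
    breakpoints: tuple[int, ...]
    depths: tuple[int, ...]

    def depth_at(self, pos: int) -> int:
        i = np.searchsorted(self.breakpoints, pos, side="right") - 1
        if i < 0 or i >= len(self.depths):
            return 0
        return self.depths[i]

    def max_depth(self) -> int:
        return max(self.depths)

    def max_depth_runs(self) -> list[GenomicInterval]:
        """Maximal-depth runs, adjacent equal-depth segments merged,
        as closed intervals."""
        target = self.max_depth()
        runs: list[GenomicInterval] = []
        open_start: int | None = None
        for i, d in enumerate(self.depths):
            seg_start = self.breakpoints[i]
            seg_end = self.breakpoints[i + 1] - 1  # inclusive
            if d == target:
                if open_start is None:
                    open_start = seg_start
                run_end = seg_end
            else:
                if open_start is not None:
                    runs.append(GenomicInterval(self.chrom, open_start, run_end))
                    open_start = None
        if open_start is not None:
            runs.append(GenomicInterval(self.chrom, open_start, run_end))
        return runs


@dataclass(frozen=True)
class Amplicon:
    """A named PCR amplicon; product size equals the interval length."""

    name: str
    interval: GenomicInterval

    @property
    def product_size(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class CdrResult:
    """Outcome of CDR discovery.

    ``support_count`` is the number of fragments whose interval fully
    contains ``region`` (containment, not mere overlap); in degenerate
    cohorts where the maximal-depth run is stitched from different fragment
    sets it can be lower than the coverage depth.  ``alternates`` lists the
    other maximal-depth runs when several disjoint runs tie on depth.
    """

    region: GenomicInterval
    support_count: int
    n_total: int
    is_cdr: bool
    alternates: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    @property
    def support_fraction(self) -> float:
        return self.support_count / self.n_total


def _require_nonempty(cohort: DeletionCohort) -> None:
    if cohort.n_records == 0:
        raise AnalysisError("empty cohort")


def coverage_profile(cohort: DeletionCohort) -> CoverageProfile:
    """Sweep-line deletion depth over the cohort.

    Events are +1 at each fragment start and -1 at ``end + 1``; the running
    sum between consecutive event coordinates is the exact stabbing depth
    ``#{r : r.start <= x <= r.end}``.
    """
    _require_nonempty(cohort)
    events: dict[int, int] = {}
    for rec in cohort.records:
        events[rec.interval.start] = events.get(rec.interval.start, 0) + 1
        events[rec.interval.end + 1] = events.get(rec.interval.end + 1, 0) - 1
    bps = sorted(events)
    depths = np.cumsum([events[b] for b in bps])[:-1]
    return CoverageProfile(cohort.locus.chrom, tuple(bps), tuple(int(d) for d in depths))


def find_cdr(
    cohort: DeletionCohort,
    min_fraction: float = 0.8,
    min_length: int = 1000,
) -> CdrResult:
    """Locate the candidate common deletion region of a cohort.

    The candidate is the maximal-depth run of the coverage profile; among
    several disjoint maximal runs the longest wins (ties broken by smaller
    start) and the rest are reported as ``alternates``.  The run is called
    a CDR iff its containment support fraction is at least ``min_fraction``
    and its length at least ``min_length`` bp.
    """
    if not (0 < min_fraction <= 1):
        raise InputError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if min_length < 1:
        raise InputError(f"min_length must be >= 1, got {min_length}")
    _require_nonempty(cohort)
    profile = coverage_profile(cohort)
    runs = profile.max_depth_runs()
    runs_ranked = sorted(runs, key=lambda r: (-r.length, r.start))
    region = runs_ranked[0]
    alternates = tuple(r for r in runs_ranked[1:])
    support = sum(1 for rec in cohort.records if rec.interval.contains(region))
    n_total = cohort.n_records
    is_cdr = (support / n_total) >= min_fraction and region.length >= min_length
    return CdrResult(region, support, n_total, is_cdr, alternates)


def amplicon_coverage(
    cohort: DeletionCohort, amplicon: Amplicon
) -> tuple[int, int, float]:
    """Fraction of deletion fragments that *fully contain* the amplicon.

    Containment, not overlap: a fragment only counts if the whole amplicon
    would be lost with it, i.e. the PCR product cannot be made from the
    deleted allele.  Returns ``(count, n_total, fraction)``.
    """
    _require_nonempty(cohort)
    count = sum(1 for rec in cohort.records if rec.interval.contains(amplicon.interval))
    return count, cohort.n_records, count / cohort.n_records


def combined_amplicon_coverage(
    cohort: DeletionCohort, amplicons: Sequence[Amplicon]
) -> tuple[int, int, float]:
    """Fraction of fragments containing *at least one* of the amplicons."""
    if not amplicons:
        raise InputError("at least one amplicon required")
    _require_nonempty(cohort)
    count = sum(
        1
        for rec in cohort.records
        if any(rec.interval.contains(a.interval) for a in amplicons)
    )
    return count, cohort.n_records, count / cohort.n_records


def interval_length_kb(interval: GenomicInterval) -> float:
    """Interval length in kb, rounded half-up to one decimal.

    Matches how region sizes are printed (5110 bp -> 5.1 kb).
    """
    kb = Decimal(interval.length) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
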