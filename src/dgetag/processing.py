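"""Read-side tag extraction, counting, and clean-tag filtering.

A tag read begins with the CATG anchor (left by adaptor-1 trimming) and
carries the 17 nt payload immediately after it.  Raw tags are counted as-is,
N calls included.  Cleaning then applies three rules, in a fixed order so
per-rule removal counts are reproducible:

1. drop tags containing any non-ACGT character (N calls),
2. drop tags equal to, or a prefix of, a configured adaptor sequence
   (adaptor self-ligation products carry adaptor-derived payloads),
3. drop tags whose copy number is below ``min_copy`` (default 2 — low-copy
   tags are dominated by single-position sequencing errors).

Singleton statistics are computed on the *pre-filter* distinct-tag
distribution: once copy-number filtering has run there are no singletons
left by construction, so the ">50% singletons" property of SAGE-style
libraries is only visible on raw counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .reference import DEFAULT_ANCHOR, DEFAULT_TAG_LENGTH

STAGES = ("embryo", "larva", "pupa", "adult")

#: 17 nt prefix of the Illumina DGE adaptor-2 sequence; kit-specific, so
#: overridable in FilterConfig.
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class FilterConfig:
    min_copy: int = 2
    adaptor_sequences: tuple[str, ...] = (DEFAULT_ADAPTOR,)
    drop_n: bool = True

    def __post_init__(self):
        if self.min_copy < 1:
            raise ValueError(f"min_copy must be >= 1, got {self.min_copy}")


@dataclass
class FilterReport:
    """Distinct-tag and total-count removals per cleaning rule."""

    n_removed: int = 0
    adaptor_removed: int = 0
    low_copy_removed: int = 0
    input_distinct: int = 0
    output_distinct: int = 0
    input_total: int = 0
    output_total: int = 0


class ExtractionStats(NamedTuple):
    raw_reads: int
    discarded_no_anchor: int
    discarded_short: int


class SingletonStats(NamedTuple):
    singleton_count: int
    distinct_raw: int
    singleton_fraction: float


def extract_read_tags(
    reads: Iterable,
    anchor: str = DEFAULT_ANCHOR,
    tag_length: int = DEFAULT_TAG_LENGTH,
    scan_anchor: bool = False,
) -> tuple[dict[str, int], ExtractionStats]:
    """Count raw tags from a stream of reads (strings or SeqRecords).

    Reads are expected to start with the anchor; a read that does not is
    counted as discarded (``scan_anchor=True`` instead searches for the
    first internal anchor with a full tag downstream).  N calls are kept:
    quality filtering happens in :func:`filter_tags`.
    """
    counts: Counter[str] = Counter()
    raw_reads = no_anchor = short = 0
    min_len = len(anchor) + tag_length
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        seq = seq.upper()
        raw_reads += 1
        if len(seq) < min_len:
            short += 1
            continue
        if seq.startswith(anchor):
            off = 0
        elif scan_anchor:
            off = seq.find(anchor)
            if off < 0 or off + min_len > len(seq):
                no_anchor += 1
                continue
        else:
            no_anchor += 1
            continue
        counts[seq[off + len(anchor): off + min_len]] += 1
    return dict(counts), ExtractionStats(raw_reads, no_anchor, short)


def _is_adaptor(tag: str, adaptors: tuple[str, ...]) -> bool:
    return any(a == tag or a.startswith(tag) for a in adaptors)


def filter_tags(
    raw: dict[str, int], cfg: FilterConfig = FilterConfig()
) -> tuple[dict[str, int], FilterReport]:
    """Apply the three cleaning rules (N -> adaptor -> copy number) to raw counts."""
    report = FilterReport(
        input_distinct=len(raw), input_total=sum(raw.values())
    )
    clean: dict[str, int] = {}
    for tag, count in raw.items():
        if count < 1:
            raise ValueError(f"non-positive raw count for tag {tag!r}")
        if cfg.drop_n and not _ACGT.issuperset(tag):
            report.n_removed += 1
            continue
        if _is_adaptor(tag, cfg.adaptor_sequences):
            report.adaptor_removed += 1
            continue
        if count < cfg.min_copy:
            report.low_copy_removed += 1
            continue
        clean[tag] = count
    report.output_distinct = len(clean)
    report.output_total = sum(clean.values())
    return clean, report


def singleton_stats(raw: dict[str, int]) -> SingletonStats:
    """Singletons (count == 1) among distinct raw tags."""
    distinct = len(raw)
    singles = sum(1 for c in raw.values() if c == 1)
    return SingletonStats(singles, distinct, singles / distinct if distinct else 0.0)


@dataclass
class TagLibrary:
    """Raw and clean tag counts for one (species, stage) library."""

    species: str
    stage: str
    raw_counts: dict[str, int]
    raw_reads: int = 0
    clean_counts: dict[str, int] | None = None
    filter_report: FilterReport | None = None
    extraction: ExtractionStats | None = None

    @property
    def library_id(self) -> tuple[str, str]:
        return (self.species, self.stage)

    @property
    def raw_tag_total(self) -> int:
        return sum(self.raw_counts.values())

    @property
    def distinct_raw(self) -> int:
        return len(self.raw_counts)

    @property
    def clean_tag_total(self) -> int:
        return sum(self.clean_counts.values()) if self.clean_counts else 0

    @property
    def distinct_clean(self) -> int:
        return len(self.clean_counts) if self.clean_counts else 0

    @property
    def singleton_fraction(self) -> float:
        return singleton_stats(self.raw_counts).singleton_fraction

    @classmethod
    def from_reads(cls, species: str, stage: str, reads: Iterable, **kwargs) -> "TagLibrary":
        counts, stats = extract_read_tags(reads, **kwargs)
        return cls(species, stage, counts, raw_reads=stats.raw_reads, extraction=stats)

    def clean(self, cfg: FilterConfig = FilterConfig()) -> "TagLibrary":
        self.clean_counts, self.filter_report = filter_tags(self.raw_counts, cfg)
        return self
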