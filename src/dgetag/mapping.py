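"""Tag-to-gene assignment allowing at most one mismatch.

Each clean tag is looked up in the exact-tag index first; only if no exact
hit exists are its Hamming-1 neighbors (17 positions x 3 substitutions = 51
variants) looked up, and the union of their transcript hits taken.  The two
tiers never blend: an exact hit always beats any 1-mismatch hit.  A tag
whose winning tier hits >= 2 transcripts is *ambiguous*; by default such
tags count as "mapped" in library-level statistics (they did land on the
reference) but contribute nothing to per-transcript expression counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .reference import TagIndex

MatchClass = Literal["exact", "one_mismatch", "ambiguous", "unmapped"]

_BASES = "ACGT"

AmbiguousPolicy = Literal["count", "distribute", "drop"]


@dataclass(frozen=True)
class TagAssignment:
    tag17: str
    match_class: MatchClass
    transcript_ids: frozenset[str]
    mismatch_position: int | None = None


@dataclass
class MappingResult:
    assignments: dict[str, TagAssignment] = field(default_factory=dict)
    mapped_unique_tags: int = 0
    genes_hit: int = 0
    distinct_clean: int = 0

    @property
    def mapping_ratio(self) -> float:
        return self.mapped_unique_tags / self.distinct_clean if self.distinct_clean else 0.0

    def class_counts(self) -> dict[str, int]:
        counts = {"exact": 0, "one_mismatch": 0, "ambiguous": 0, "unmapped": 0}
        for a in self.assignments.values():
            counts[a.match_class] += 1
        return counts


def map_tag(tag17: str, index: TagIndex) -> TagAssignment:
    """Classify one tag against the reference index (exact tier wins)."""
    if len(tag17) != index.tag_length or not set(tag17) <= set(_BASES):
        raise ValueError(f"malformed tag {tag17!r}: expected {index.tag_length} nt over ACGT")
    exact = index.exact.get(tag17)
    if exact:
        cls = "exact" if len(exact) == 1 else "ambiguous"
        return TagAssignment(tag17, cls, frozenset(exact), None)
    hits: set[str] = set()
    first_pos: int | None = None
    for pos in range(len(tag17)):
        orig = tag17[pos]
        for base in _BASES:
            if base == orig:
                continue
            neighbor = tag17[:pos] + base + tag17[pos + 1:]
            ids = index.exact.get(neighbor)
            if ids:
                if first_pos is None:
                    first_pos = pos
                hits.update(ids)
    if not hits:
        return TagAssignment(tag17, "unmapped", frozenset(), None)
    if len(hits) == 1:
        return TagAssignment(tag17, "one_mismatch", frozenset(hits), first_pos)
    return TagAssignment(tag17, "ambiguous", frozenset(hits), None)


def map_library(
    clean: dict[str, int],
    index: TagIndex,
    ambiguous: AmbiguousPolicy = "count",
) -> tuple[MappingResult, dict[str, float]]:
    """Map every distinct clean tag; return stats and per-transcript counts.

    Ambiguous-tag policy:

    - ``count`` (default): ambiguous tags count toward ``mapped_unique_tags``
      but are excluded from per-transcript quantification;
    - ``distribute``: additionally split their clean count equally across
      their candidate transcripts;
    - ``drop``: excluded from both the mapped statistic and quantification.
    """
    if ambiguous not in ("count", "distribute", "drop"):
        raise ValueError(f"unknown ambiguous policy {ambiguous!r}")
    result = MappingResult(distinct_clean=len(clean))
    per_transcript: dict[str, float] = {}
    unambiguous_hit: set[str] = set()
    for tag in clean:
        a = map_tag(tag, index)
        result.assignments[tag] = a
        if a.match_class in ("exact", "one_mismatch"):
            result.mapped_unique_tags += 1
            (tid,) = a.transcript_ids
            per_transcript[tid] = per_transcript.get(tid, 0.0) + clean[tag]
            unambiguous_hit.add(tid)
        elif a.match_class == "ambiguous":
            if ambiguous in ("count", "distribute"):
                result.mapped_unique_tags += 1
            if ambiguous == "distribute":
                share = clean[tag] / len(a.transcript_ids)
                for tid in a.transcript_ids:
                    per_transcript[tid] = per_transcript.get(tid, 0.0) + share
    result.genes_hit = len(unambiguous_hit)
    return result, per_transcript


def assignment_table(result: MappingResult):
    """Flat per-tag table for TSV export."""
    import pandas as pd

    rows = [
        (
            a.tag17,
            a.match_class,
            ",".join(sorted(a.transcript_ids)),
            "" if a.mismatch_position is None else a.mismatch_position,
        )
        for a in sorted(result.assignments.values(), key=lambda a: a.tag17)
    ]
    return pd.DataFrame(rows, columns=["tag", "class", "transcript_ids", "mismatch_pos"])
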