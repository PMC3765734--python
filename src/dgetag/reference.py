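"""Virtual tag database construction from a transcript reference.

In NlaIII/MmeI tag profiling the anchoring enzyme NlaIII cuts at every CATG
in the cDNA, and the tagging enzyme MmeI releases the 17 nt immediately
downstream of the anchor.  Because the library is built on oligo-dT beads,
the fragment that stays bead-bound — and therefore the tag that is actually
sequenced — is the one at the 3'-most CATG site.  This module extracts those
"virtual tags" from transcript sequences and indexes them for tag-to-gene
assignment.

Coordinates are 0-based offsets of the C of the anchor on the sense strand.
Tags are reported without the anchor (17 nt), matching the clean-tag
convention of the sequenced libraries; the anchored 21-mer is retained for
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

DEFAULT_ANCHOR = "CATG"
DEFAULT_TAG_LENGTH = 17

_VALID_BASES = frozenset("ACGTN")


class InputError(ValueError):
    """Malformed input sequence or identifier."""


@dataclass(frozen=True)
class VirtualTag:
    """One reference tag: a 17 nt sequence anchored at a CATG site."""

    transcript_id: str
    tag17: str
    site_offset: int
    is_canonical: bool
    anchor: str = DEFAULT_ANCHOR

    @property
    def anchored21(self) -> str:
        return self.anchor + self.tag17


@dataclass
class TagIndex:
    """Exact-lookup index of reference tags: tag17 -> set of transcript ids."""

    exact: dict[str, set[str]] = field(default_factory=dict)
    reference_size: int = 0
    taggable_count: int = 0
    anchor: str = DEFAULT_ANCHOR
    tag_length: int = DEFAULT_TAG_LENGTH


def extract_virtual_tags(
    transcript_id: str,
    sequence: str,
    mode: Literal["canonical", "all_sites"] = "canonical",
    anchor: str = DEFAULT_ANCHOR,
    tag_length: int = DEFAULT_TAG_LENGTH,
) -> list[VirtualTag]:
    """Extract virtual tags from one transcript.

    A site qualifies when the anchor is followed by at least ``tag_length``
    bases none of which is N (an N in the window would never match a clean
    read tag).  ``canonical`` mode returns only the 3'-most qualifying site;
    ``all_sites`` returns every qualifying site 5'->3' with ``is_canonical``
    set on the 3'-most.
    """
    if not sequence:
        raise InputError(f"{transcript_id}: empty sequence")
    sequence = sequence.upper()
    for pos, base in enumerate(sequence):
        if base not in _VALID_BASES:
            raise InputError(
                f"{transcript_id}: invalid character {base!r} at position {pos}"
            )

    sites: list[int] = []
    start = 0
    while True:
        off = sequence.find(anchor, start)
        if off < 0:
            break
        window = sequence[off + len(anchor): off + len(anchor) + tag_length]
        if len(window) == tag_length and "N" not in window:
            sites.append(off)
        start = off + 1
    if not sites:
        return []
    if mode == "canonical":
        sites = sites[-1:]
    elif mode != "all_sites":
        raise InputError(f"unknown extraction mode {mode!r}")
    last = sites[-1]
    return [
        VirtualTag(
            transcript_id=transcript_id,
            tag17=sequence[off + len(anchor): off + len(anchor) + tag_length],
            site_offset=off,
            is_canonical=(off == last),
            anchor=anchor,
        )
        for off in sites
    ]


def build_index(
    reference: Iterable[tuple[str, str]],
    mode: Literal["canonical", "all_sites"] = "canonical",
    anchor: str = DEFAULT_ANCHOR,
    tag_length: int = DEFAULT_TAG_LENGTH,
) -> TagIndex:
    """Build a :class:`TagIndex` over (transcript_id, sequence) pairs.

    Accepts any iterable of id/sequence pairs, including Biopython
    SeqRecords (via ``(rec.id, str(rec.seq))``) — see :func:`index_records`.
    """
    index = TagIndex(anchor=anchor, tag_length=tag_length)
    seen: set[str] = set()
    for transcript_id, sequence in reference:
        if transcript_id in seen:
            raise InputError(f"duplicate transcript id {transcript_id!r}")
        seen.add(transcript_id)
        index.reference_size += 1
        tags = extract_virtual_tags(transcript_id, sequence, mode, anchor, tag_length)
        if tags:
            index.taggable_count += 1
        for tag in tags:
            index.exact.setdefault(tag.tag17, set()).add(transcript_id)
    return index


def index_records(records, mode="canonical", anchor=DEFAULT_ANCHOR,
                  tag_length=DEFAULT_TAG_LENGTH) -> TagIndex:
    """Convenience: build an index from Biopython SeqRecords."""
    return build_index(
        ((rec.id, str(rec.seq)) for rec in records), mode, anchor, tag_length
    )


def virtual_tag_table(reference, mode="canonical", anchor=DEFAULT_ANCHOR,
                      tag_length=DEFAULT_TAG_LENGTH):
    """Flat per-tag table for TSV export: one row per virtual tag."""
    import pandas as pd

    rows = []
    for transcript_id, sequence in reference:
        for t in extract_virtual_tags(transcript_id, sequence, mode, anchor, tag_length):
            rows.append((t.transcript_id, t.tag17, t.site_offset, t.is_canonical))
    return pd.DataFrame(
        rows, columns=["transcript_id", "tag17", "site_offset", "is_canonical"]
    )


def index_from_table(df, anchor=DEFAULT_ANCHOR, tag_length=DEFAULT_TAG_LENGTH) -> TagIndex:
    """Rebuild a TagIndex from a virtual-tag table written by :func:`virtual_tag_table`."""
    index = TagIndex(anchor=anchor, tag_length=tag_length)
    ids = set(df["transcript_id"])
    index.reference_size = len(ids)
    index.taggable_count = len(ids)
    for tag17, tid in zip(df["tag17"], df["transcript_id"]):
        index.exact.setdefault(tag17, set()).add(tid)
    return index
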