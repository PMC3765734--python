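"""Set-overlap (Venn) analysis of expressed tags/genes and library summaries.

The summary table mirrors the classic DGE-library report: per-(species,
stage) raw reads, clean tags, distinct clean tags (uni-tags), mapped
uni-tags, genes hit, with per-species totals and mapping ratios.  Ratios
are percentages rounded half-up to two decimals (exact decimal arithmetic,
so 73.345 -> 73.35, never banker's rounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib.resources import files
from itertools import combinations

import pandas as pd

from .processing import STAGES

SUMMARY_COUNT_COLUMNS = (
    "raw_reads",
    "clean_tags",
    "unique_clean_tags",
    "mapped_unique_tags",
    "genes_hit",
)


class UniverseMismatchError(ValueError):
    """Sets being compared do not share a universe (tags vs genes)."""


@dataclass(frozen=True)
class ExpressedSet:
    """Membership set of one library: tag sequences or transcript ids."""

    library_id: str
    universe: str  # "tags" or "genes"
    members: frozenset[str]
    threshold: int = 1

    @classmethod
    def from_counts(cls, library_id, counts: dict, universe: str = "tags",
                    threshold: int = 1) -> "ExpressedSet":
        return cls(
            str(library_id),
            universe,
            frozenset(k for k, v in counts.items() if v >= threshold),
            threshold,
        )


def _check_universe(sets):
    universes = {s.universe for s in sets}
    if len(universes) > 1:
        raise UniverseMismatchError(f"mixed universes: {sorted(universes)}")


def venn_partition(sets: list[ExpressedSet]) -> dict[str, int]:
    """Exclusive region counts for 2-4 sets.

    Region labels are '&'-joined sorted library ids; all 2^k - 1 regions are
    reported (zero counts included) and the counts sum to |union|.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_partition takes 2-4 sets, got {len(sets)}")
    _check_universe(sets)
    ids = [s.library_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library ids")
    by_id = {s.library_id: s.members for s in sets}
    regions: dict[str, int] = {}
    for k in range(1, len(sets) + 1):
        for combo in combinations(sorted(ids), k):
            inside = set.intersection(*(set(by_id[i]) for i in combo))
            for other in ids:
                if other not in combo:
                    inside -= by_id[other]
            regions["&".join(combo)] = len(inside)
    return regions


def coexpression_fraction(
    set_a: ExpressedSet, set_b: ExpressedSet
) -> tuple[int, float, float]:
    """(|A ∩ B|, share of A, share of B) — the coexpressed fraction of each library."""
    _check_universe([set_a, set_b])
    shared = len(set_a.members & set_b.members)
    frac = lambda s: shared / len(s.members) if s.members else 0.0
    return shared, frac(set_a), frac(set_b)


def round_ratio(numerator: float, denominator: float, places: int = 2) -> float:
    """Percentage numerator/denominator rounded half-up to ``places`` decimals."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-places)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LibrarySummary:
    """Per-stage counts plus per-species totals and mapping ratios."""

    per_stage: pd.DataFrame  # species, stage, count columns, mapping_tag_ratio
    species_totals: pd.DataFrame  # species, count columns, mapping_tag_ratio

    def to_table(self) -> pd.DataFrame:
        """Long-format table with total rows appended (for TSV export)."""
        totals = self.species_totals.copy()
        totals.insert(1, "stage", "total")
        return pd.concat([self.per_stage, totals], ignore_index=True)


def summarize_libraries(
    rows: pd.DataFrame,
    reference_size: int | None = None,
    stages: tuple[str, ...] = STAGES,
) -> LibrarySummary:
    """Assemble the library summary from per-(species, stage) counts.

    ``rows`` needs columns species, stage and the five count columns.
    Species totals sum the stage values per column; every ratio is
    100 * mapped_unique_tags / unique_clean_tags rounded half-up to 2
    decimals.  When ``reference_size`` is given, a mapping_gene_ratio
    (genes_hit / reference size) is added; note this denominator is the
    user's reference, as the sequenced transcript universe of a library is
    not knowable from counts.
    """
    required = {"species", "stage", *SUMMARY_COUNT_COLUMNS}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"summary input missing columns: {sorted(missing)}")
    per_stage = rows.copy()
    for species, group in per_stage.groupby("species"):
        absent = set(stages) - set(group["stage"])
        if absent:
            warnings.warn(
                f"species {species!r}: missing stages {sorted(absent)}; "
                "totals computed over present stages"
            )
    order = {s: i for i, s in enumerate(stages)}
    per_stage = per_stage.sort_values(
        ["species", "stage"], key=lambda c: c.map(order).fillna(len(order)) if c.name == "stage" else c
    ).reset_index(drop=True)
    per_stage["mapping_tag_ratio"] = [
        round_ratio(m, u)
        for m, u in zip(per_stage["mapped_unique_tags"], per_stage["unique_clean_tags"])
    ]
    totals = (
        per_stage.groupby("species", sort=False)[list(SUMMARY_COUNT_COLUMNS)]
        .sum()
        .reset_index()
    )
    totals["mapping_tag_ratio"] = [
        round_ratio(m, u)
        for m, u in zip(totals["mapped_unique_tags"], totals["unique_clean_tags"])
    ]
    if reference_size is not None:
        for df in (per_stage, totals):
            df["mapping_gene_ratio"] = [
                round_ratio(g, reference_size) for g in df["genes_hit"]
            ]
    return LibrarySummary(per_stage, totals)


def load_table1_fixture() -> pd.DataFrame:
    """Packaged per-stage library counts of the two-species study (test fixture)."""
    path = files("dgetag.data").joinpath("table1.tsv")
    return pd.read_csv(path, sep="\t")


def load_table2_fixture() -> pd.DataFrame:
    """Packaged cross-species tag-count exemplar rows with published S/D labels."""
    path = files("dgetag.data").joinpath("table2_patterns.tsv")
    return pd.read_csv(path, sep="\t")
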