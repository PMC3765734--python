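"""1-mismatch tag-to-gene mapping against a brute-force Hamming oracle."""

import pytest

from dgetag.mapping import map_library, map_tag
from dgetag.reference import TagIndex, build_index

TAG = "ACGTACGTACGTACGTA"
BASES = "ACGT"


def make_index(tag_to_ids: dict[str, set[str]]) -> TagIndex:
    index = TagIndex()
    for tag, ids in tag_to_ids.items():
        index.exact[tag] = set(ids)
    ids = {i for v in tag_to_ids.values() for i in v}
    index.reference_size = index.taggable_count = len(ids)
    return index


def mutate(tag: str, pos: int, offset: int = 1) -> str:
    new = BASES[(BASES.index(tag[pos]) + offset) % 4]
    return tag[:pos] + new + tag[pos + 1:]


def brute_force_assign(tag: str, tag_to_ids: dict[str, set[str]]):
    """Oracle: full Hamming scan over all reference tags, exact tier first."""
    exact, near = set(), set()
    for ref_tag, ids in tag_to_ids.items():
        dist = sum(a != b for a, b in zip(tag, ref_tag))
        if dist == 0:
            exact |= ids
        elif dist == 1:
            near |= ids
    if exact:
        return ("exact" if len(exact) == 1 else "ambiguous", exact)
    if near:
        return ("one_mismatch" if len(near) == 1 else "ambiguous", near)
    return ("unmapped", set())


class TestMapTag:
    def test_exact_unique_hit(self):
        index = make_index({TAG: {"t1"}})
        a = map_tag(TAG, index)
        assert (a.match_class, a.transcript_ids, a.mismatch_position) == (
            "exact", frozenset({"t1"}), None)

    def test_one_mismatch_records_position(self):
        index = make_index({TAG: {"t1"}})
        a = map_tag(mutate(TAG, 9), index)
        assert a.match_class == "one_mismatch"
        assert a.transcript_ids == frozenset({"t1"})
        assert a.mismatch_position == 9

    def test_hamming_two_unmapped(self):
        index = make_index({TAG: {"t1"}})
        a = map_tag(mutate(mutate(TAG, 2), 11), index)
        assert a.match_class == "unmapped" and a.transcript_ids == frozenset()

    def test_shared_tag_is_ambiguous(self):
        index = make_index({TAG: {"t1", "t2"}})
        a = map_tag(TAG, index)
        assert a.match_class == "ambiguous"
        assert a.transcript_ids == frozenset({"t1", "t2"})

    def test_exact_tier_beats_one_mismatch(self):
        index = make_index({TAG: {"t1"}, mutate(TAG, 0): {"t2"}})
        a = map_tag(TAG, index)
        assert a.match_class == "exact" and a.transcript_ids == frozenset({"t1"})

    def test_two_distinct_one_mismatch_hits_ambiguous(self):
        index = make_index({mutate(TAG, 3): {"t1"}, mutate(TAG, 8): {"t2"}})
        a = map_tag(TAG, index)
        assert a.match_class == "ambiguous"
        assert a.transcript_ids == frozenset({"t1", "t2"})

    def test_malformed_tag_rejected(self):
        index = make_index({TAG: {"t1"}})
        with pytest.raises(ValueError):
            map_tag("ACGTN" + "A" * 12, index)
        with pytest.raises(ValueError):
            map_tag("ACGT", index)

    def test_monotone_in_reference(self, rng):
        """Adding a transcript never shrinks any tag's candidate set."""
        tags = ["".join(rng.choice(list(BASES), 17)) for _ in range(30)]
        small = make_index({t: {f"t{i}"} for i, t in enumerate(tags[:20])})
        big = make_index({t: {f"t{i}"} for i, t in enumerate(tags)})
        for query in tags + [mutate(t, 5) for t in tags]:
            assert map_tag(query, small).transcript_ids <= map_tag(query, big).transcript_ids


class TestMapLibrary:
    def test_perfect_recovery_limit(self):
        ref = [(f"t{i}", "CATG" + mutate(TAG, i)) for i in range(5)]
        index = build_index(ref)
        clean = {mutate(TAG, i): 10 * (i + 1) for i in range(5)}
        result, counts = map_library(clean, index)
        assert result.mapping_ratio == 1.0
        assert result.genes_hit == 5
        assert counts == {f"t{i}": 10 * (i + 1) for i in range(5)}

    def test_class_partition_covers_all_tags(self, rng):
        tags = ["".join(rng.choice(list(BASES), 17)) for _ in range(40)]
        index = make_index({t: {f"t{i}"} for i, t in enumerate(tags[:25])})
        clean = {t: 1 for t in tags}
        result, _ = map_library(clean, index)
        assert sum(result.class_counts().values()) == result.distinct_clean == 40

    def test_empty_index_all_unmapped(self):
        result, counts = map_library({TAG: 4}, make_index({}))
        assert result.mapped_unique_tags == 0 and counts == {}

    @pytest.mark.parametrize("policy,mapped,per_transcript", [
        ("count", 1, {}),
        ("distribute", 1, {"t1": 3.0, "t2": 3.0}),
        ("drop", 0, {}),
    ])
    def test_ambiguous_policies(self, policy, mapped, per_transcript):
        index = make_index({TAG: {"t1", "t2"}})
        result, counts = map_library({TAG: 6}, index, ambiguous=policy)
        assert result.mapped_unique_tags == mapped
        assert counts == per_transcript

    def test_matches_brute_force_on_random_instances(self, rng):
        """Neighborhood lookup equals the quadratic Hamming scan."""
        for _ in range(20):
            ref_tags = ["".join(rng.choice(list(BASES), 17)) for _ in range(50)]
            tag_to_ids = {}
            for i, t in enumerate(ref_tags):
                tag_to_ids.setdefault(t, set()).add(f"t{i}")
            index = make_index(tag_to_ids)
            queries = (
                [rng.choice(ref_tags) for _ in range(10)]
                + [mutate(rng.choice(ref_tags), int(rng.integers(17))) for _ in range(10)]
                + ["".join(rng.choice(list(BASES), 17)) for _ in range(10)]
            )
            for q in queries:
                got = map_tag(q, index)
                cls, ids = brute_force_assign(q, tag_to_ids)
                assert (got.match_class, set(got.transcript_ids)) == (cls, ids)
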