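"""Tag deduplication: ranking rules, one-mismatch collapse, truth recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from temposeq.dedup import (
    TaggedRead,
    TagLengthError,
    dedup_stats,
    group_by_position,
    mark_duplicates,
    rank_tags,
)
from temposeq.sim import SimConfig, simulate_tagged_reads


def read(rid, tag, phred=30, chrom="2L", pos=100, strand="+", n_quals=4):
    return TaggedRead(
        read_id=rid, chrom=chrom, pos=pos, strand=strand, tag=tag,
        quals=(phred,) * n_quals,
    )


# --- independent brute-force oracle: a literal transcription of the rules ---

def oracle_flags(reads):
    """Naive re-derivation of the duplicate-marking rules for small inputs."""
    flags = {r.read_id: True for r in reads}
    positions = sorted({(r.chrom, r.strand, r.pos) for r in reads})
    for key in positions:
        group = [r for r in reads if (r.chrom, r.strand, r.pos) == key]
        counts = {}
        for r in group:
            counts[r.tag] = counts.get(r.tag, 0) + 1
        ranked = sorted(counts, key=lambda t: (-counts[t], t))
        accepted = []
        for tag in ranked:
            near = False
            for other in accepted:
                assert len(other) == len(tag)
                if sum(a != b for a, b in zip(tag, other)) == 1:
                    near = True
            if near:
                continue
            accepted.append(tag)
            candidates = sorted(
                (r for r in group if r.tag == tag),
                key=lambda r: (-r.mean_phred, r.read_id),
            )
            flags[candidates[0].read_id] = False
    return flags


class TestGrouping:
    def test_strand_separates_groups(self):
        reads = [read("a", "AAAA"), read("b", "AAAA"), read("c", "AAAA", strand="-")]
        groups = group_by_position(reads)
        assert sorted(len(g) for g in groups.values()) == [1, 2]

    def test_empty_input(self):
        assert group_by_position([]) == {}

    def test_groups_partition_input(self):
        rng = np.random.default_rng(1)
        reads = [
            read(f"r{i}", "ACGT", phred=int(rng.integers(10, 40)),
                 pos=int(rng.integers(0, 5)), strand="+-"[int(rng.integers(0, 2))])
            for i in range(1000)
        ]
        groups = group_by_position(reads)
        assert sum(len(g) for g in groups.values()) == 1000

    def test_ignore_strand_merges(self):
        reads = [read("a", "AAAA"), read("b", "AAAA", strand="-")]
        assert len(group_by_position(reads, ignore_strand=True)) == 1


class TestRankTags:
    def test_count_descending(self):
        group = [read("a", "AAAA"), read("b", "AAAA"), read("c", "AAAA"), read("d", "CCCC")]
        assert [t for t, _ in rank_tags(group)] == ["AAAA", "CCCC"]

    def test_alphanumeric_tie_break(self):
        group = [read("a", "TTTT"), read("b", "TTTT"), read("c", "AAAA"), read("d", "AAAA")]
        assert [t for t, _ in rank_tags(group)] == ["AAAA", "TTTT"]

    def test_reads_sorted_by_phred_then_id(self):
        group = [read("b", "AAAA", phred=30), read("a", "AAAA", phred=30), read("c", "AAAA", phred=35)]
        (_, reads), = rank_tags(group)
        assert [r.read_id for r in reads] == ["c", "a", "b"]

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(7)
        tags = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(50)]
        group = [read(f"r{i}", t, phred=int(rng.integers(10, 40))) for i, t in enumerate(tags)]
        expected = sorted(
            {t: tags.count(t) for t in tags}.items(), key=lambda kv: (-kv[1], kv[0])
        )
        assert [t for t, _ in rank_tags(group)] == [t for t, _ in expected]


class TestMarkDuplicates:
    def test_single_read_is_unique(self):
        result = mark_duplicates([read("a", "ACGT")])
        assert result.duplicate == {"a": False}
        assert result.accepted_tags[("2L", "+", 100)] == ["ACGT"]

    def test_hand_worked_group(self):
        # AAAA x3 (phreds 30, 35, 20) + AAAT: AAAT is Hamming-1 from AAAA, so
        # the only non-duplicate is the PHRED-35 AAAA read.
        reads = [
            read("r1", "AAAA", phred=30),
            read("r2", "AAAA", phred=35),
            read("r3", "AAAA", phred=20),
            read("r4", "AAAT", phred=39),
        ]
        result = mark_duplicates(reads)
        assert result.duplicate == {"r1": True, "r2": False, "r3": True, "r4": True}
        assert result.representative[(("2L", "+", 100), "AAAA")] == "r2"

    def test_distinct_tags_both_kept(self):
        reads = [read("a", "AAAA"), read("b", "GGTT")]
        result = mark_duplicates(reads)
        assert result.n_unique == 2

    def test_unequal_tag_lengths_error(self):
        with pytest.raises(TagLengthError):
            mark_duplicates([read("a", "AAAA"), read("b", "AAA")])

    def test_n_base_mismatches_everything(self):
        # ANAA mismatches AAAA at the N, so it is Hamming-1 and collapsed
        reads = [read("a", "AAAA"), read("b", "AAAA"), read("c", "ANAA")]
        result = mark_duplicates(reads)
        assert result.duplicate["c"] is True

    def test_discard_n_tags(self):
        reads = [read("a", "NNNN")]
        result = mark_duplicates(reads, discard_n_tags=True)
        assert result.duplicate["a"] is True

    def test_conservation(self):
        cfg = SimConfig(seed=3, n_molecules=300, genome=(("2L", 5000),))
        reads, _ = simulate_tagged_reads(cfg)
        result = mark_duplicates(reads)
        assert result.n_unique + result.n_duplicates == len(reads)

    def test_permutation_invariance(self):
        cfg = SimConfig(seed=4, n_molecules=150, genome=(("2L", 800),), tag_length=3)
        reads, _ = simulate_tagged_reads(cfg)
        result = mark_duplicates(reads)
        rng = np.random.default_rng(0)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert mark_duplicates(shuffled).duplicate == result.duplicate

    def test_exact_recovery_error_free_collision_free(self):
        cfg = SimConfig(seed=11, n_molecules=2000, tag_error_rate=0.0)
        reads, truth = simulate_tagged_reads(cfg)
        assert truth.collision_molecule_ids() == []
        result = mark_duplicates(reads)
        assert result.n_unique == truth.n_molecules
        stats = dedup_stats(result, truth)
        assert stats["precision"] == 1.0 and stats["recall"] == 1.0


class TestOracleEquivalence:
    def test_exhaustive_two_tag_positions(self):
        """All ways of splitting <= 6 reads between two length-2 tags."""
        for tag_a, tag_b in [("AA", "AC"), ("AA", "CC"), ("AC", "CA")]:
            for n_a, n_b in itertools.product(range(1, 4), range(0, 4)):
                phreds = itertools.cycle([30, 35, 20, 35, 10, 25])
                reads = [
                    read(f"r{i}", tag, phred=next(phreds), n_quals=2)
                    for i, tag in enumerate([tag_a] * n_a + [tag_b] * n_b)
                ]
                assert mark_duplicates(reads).duplicate == oracle_flags(reads)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["AAAA", "AAAC", "AACC", "CCCC", "GCTA"]),
                st.integers(min_value=2, max_value=40),
                st.sampled_from([0, 1]),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_random_groups_match_oracle(self, spec):
        reads = [
            read(f"r{i}", tag, phred=phred, pos=pos)
            for i, (tag, phred, pos) in enumerate(spec)
        ]
        assert mark_duplicates(reads).duplicate == oracle_flags(reads)


class TestStats:
    def test_all_unique_zero_fraction(self):
        reads = [read("a", "AAAA"), read("b", "GGTT", pos=200)]
        stats = dedup_stats(mark_duplicates(reads))
        assert stats["duplicate_fraction"] == 0.0

    def test_precision_at_most_one(self):
        cfg = SimConfig(seed=9, n_molecules=400, tag_error_rate=0.05)
        reads, truth = simulate_tagged_reads(cfg)
        stats = dedup_stats(mark_duplicates(reads), truth)
        assert 0.0 <= stats["precision"] <= 1.0
        assert 0.0 <= stats["recall"] <= 1.0
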