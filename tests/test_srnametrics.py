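"""Read collapsing, exact mapping, RPM, accuracy, polarity, phasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amirnakit import (
    GuideRNA,
    ReadRecord,
    ValidationError,
    build_precursor,
    collapse_reads,
    expand_reads,
    get_backbone,
    locate_cleavage_site,
    map_exact,
    phasing_registers,
    processing_accuracy,
    reverse_complement,
    rpm_normalize,
    strand_polarity,
)


def naive_hits(read: str, ref: str) -> list[int]:
    """Independent sliding-window oracle: per-position character comparison."""
    L = len(read)
    return [
        i + 1
        for i in range(len(ref) - L + 1)
        if all(ref[i + k] == read[k] for k in range(L))
    ]


class TestCollapse:
    def test_counts_identical_reads(self):
        recs = collapse_reads(["AAA", "AAA", "CCC"])
        assert recs == [ReadRecord("AAA", 2), ReadRecord("CCC", 1)]

    def test_distinct_reads_keep_count_one(self):
        recs = collapse_reads(["ACG", "CGT", "GTA"])
        assert all(r.count == 1 for r in recs) and len(recs) == 3

    def test_expand_then_collapse_is_idempotent(self):
        recs = collapse_reads(["ACGT", "ACGT", "TTTT", "ACGT"])
        assert collapse_reads(expand_reads(recs)) == recs

    def test_non_nucleotide_reads_rejected_not_raised(self, caplog):
        recs = collapse_reads(["ACGT", "ACXT"])
        assert recs == [ReadRecord("ACGT", 1)]

    def test_empty_input_is_empty_not_error(self):
        assert collapse_reads([]) == []


class TestMapExact:
    def test_read_equal_to_reference(self):
        prof = map_exact([ReadRecord("ACGTA", 3)], "ACGTA")
        assert prof.hits == {(1, 5, "+"): 3}
        assert prof.total_mapped == 3

    def test_multi_position_read_counted_at_each_hit_once_in_total(self):
        ref = "AAGGAAGG"
        prof = map_exact([ReadRecord("AAGG", 5)], ref)
        assert prof.hits == {(1, 4, "+"): 5, (5, 4, "+"): 5}
        assert prof.total_mapped == 5

    def test_minus_strand_five_prime_coordinate(self):
        ref = "AACCCGGTT"
        read = reverse_complement("CCCGG")  # matches ref[3..7] on the (-) strand
        prof = map_exact([ReadRecord(read, 1)], ref, strands="both")
        assert (7, 5, "-") in prof.hits  # 5' end of the (-) read at position 7

    def test_agreement_with_sliding_window_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 201))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            L = int(rng.integers(3, 25))
            start = int(rng.integers(0, n - L + 1))
            read = ref[start : start + L] if rng.random() < 0.7 else "".join(
                rng.choice(list("ACGT"), size=L)
            )
            prof = map_exact([ReadRecord(read, 2)], ref)
            expected = {(p, L, "+"): 2 for p in naive_hits(read, ref)}
            assert prof.hits == expected

    def test_unmapped_reads_absent(self):
        prof = map_exact([ReadRecord("TTTT", 4)], "ACACACAC")
        assert prof.hits == {} and prof.empty


class TestRPM:
    def test_single_hit_is_one_million(self):
        prof = map_exact([ReadRecord("ACG", 2)], "TACGT")
        assert prof.rpm == {(2, 3, "+"): 1_000_000.0}

    def test_proportional_split(self):
        prof = map_exact([ReadRecord("AAAA", 1), ReadRecord("CCCC", 3)], "AAAACCCC")
        assert prof.rpm[(1, 4, "+")] == 250_000.0
        assert prof.rpm[(5, 4, "+")] == 750_000.0

    def test_conservation_on_unique_mapping_profiles(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        reads = [
            ReadRecord(ref[i : i + 21], int(rng.integers(1, 50)))
            for i in range(0, 250, 7)
        ]
        prof = map_exact(reads, ref)
        assert np.isclose(sum(prof.rpm.values()), 1_000_000.0)

    def test_empty_profile_flagged(self):
        prof = rpm_normalize(map_exact([ReadRecord("GGGG", 1)], "AAAA"))
        assert prof.empty and prof.rpm == {}


def _shc_precursor(seed: int = 5):
    g = GuideRNA("".join(np.random.default_rng(seed).choice(list("ACGU"), size=21)), "amiR")
    return build_precursor(g, get_backbone("shc"))


class TestProcessingAccuracy:
    def test_all_exact_guide_reads_give_accuracy_one(self):
        prec = _shc_precursor()
        guide = prec.sequence[prec.guide_start - 1 : prec.guide_start + 20]
        prof = map_exact([ReadRecord(guide.replace("U", "T"), 10)], prec.sequence)
        rep = processing_accuracy(prof, prec)
        assert rep.accuracy == 1.0 and rep.window_reads == 10

    def test_constructed_mixture_gives_point_eight(self):
        prec = _shc_precursor()
        gs = prec.guide_start
        seq = prec.sequence.replace("U", "T")
        exact = seq[gs - 1 : gs + 20]
        off = seq[gs - 2 : gs + 20]  # 22-nt read starting at guide_start - 1
        prof = map_exact([ReadRecord(exact, 8), ReadRecord(off, 2)], seq)
        rep = processing_accuracy(prof, prec)
        assert rep.window_reads == 10 and rep.exact_guide_reads == 8
        assert rep.accuracy == pytest.approx(0.8)

    def test_read_outside_window_excluded(self):
        prec = _shc_precursor()
        gs = prec.guide_start
        seq = prec.sequence.replace("U", "T")
        outside = seq[gs - 6 : gs + 15]  # 21-nt read with 5' end at guide_start - 5
        prof = map_exact([ReadRecord(outside, 7)], seq)
        rep = processing_accuracy(prof, prec)
        assert rep.window_reads == 0 and rep.accuracy is None and rep.undefined

    def test_invariant_under_count_rescaling(self):
        prec = _shc_precursor()
        gs = prec.guide_start
        seq = prec.sequence.replace("U", "T")
        base = [ReadRecord(seq[gs - 1 : gs + 20], 9), ReadRecord(seq[gs + 1 : gs + 21], 3)]
        scaled = [ReadRecord(r.sequence, r.count * 17) for r in base]
        a1 = processing_accuracy(map_exact(base, seq), prec).accuracy
        a2 = processing_accuracy(map_exact(scaled, seq), prec).accuracy
        assert a1 == pytest.approx(a2)


class TestStrandPolarity:
    def test_balanced_mixture(self):
        ref = "ACGGTACCGGATTAACCGGTT"
        fwd = ReadRecord(ref[2:12], 5)
        rev = ReadRecord(reverse_complement(ref[5:15]), 5)
        assert strand_polarity([fwd, rev], ref) == (0.5, 0.5)

    def test_forward_only(self):
        ref = "ACGGTACCGGATTAACCGGTT"
        assert strand_polarity([ReadRecord(ref[1:11], 4)], ref) == (1.0, 0.0)

    def test_nothing_mapped_is_flagged(self):
        assert strand_polarity([ReadRecord("T" * 10, 1)], "ACACACACACAC") == (None, None)


class TestCleavageAndPhasing:
    def test_cleavage_site_opposite_guide_positions_ten_eleven(self, rng):
        g = GuideRNA("".join(rng.choice(list("ACGU"), size=21)), "g")
        site = reverse_complement(g.sequence).replace("U", "T")
        flank = "".join(rng.choice(list("ACGT"), size=40))
        target = flank + site + flank
        assert locate_cleavage_site(target, g) == 41 + 10

    def test_zero_or_multiple_sites_rejected(self, rng):
        g = GuideRNA("".join(rng.choice(list("ACGU"), size=21)), "g")
        site = reverse_complement(g.sequence).replace("U", "T")
        with pytest.raises(ValidationError, match="0"):
            locate_cleavage_site("A" * 60, g)
        with pytest.raises(ValidationError, match="2"):
            locate_cleavage_site(site + "AAAA" + site, g)

    def test_single_phased_read_lands_in_register_one(self, nbsu_like_reference):
        c = 100
        read = nbsu_like_reference[c : c + 21]  # starts at c+1
        table = phasing_registers([ReadRecord(read, 4)], nbsu_like_reference, c)
        assert table.registers[0] == 1.0 and table.n_reads == 4

    def test_register_assignment_cycles_every_21_nt(self, nbsu_like_reference):
        c = 100
        r1 = nbsu_like_reference[c : c + 21]
        r2 = nbsu_like_reference[c + 21 : c + 42]  # one full cycle later
        table = phasing_registers([ReadRecord(r1, 1), ReadRecord(r2, 1)], nbsu_like_reference, c)
        assert table.registers[0] == 1.0

    def test_proportions_sum_to_one(self, rng, nbsu_like_reference):
        c = 50
        reads = []
        for _ in range(30):
            p = int(rng.integers(c + 1, len(nbsu_like_reference) - 20))
            reads.append(nbsu_like_reference[p - 1 : p + 20])
        table = phasing_registers(collapse_reads(reads), nbsu_like_reference, c)
        assert table.n_reads > 0
        assert np.isclose(table.registers.sum(), 1.0)

    def test_no_qualifying_reads_gives_zero_table(self, nbsu_like_reference):
        table = phasing_registers([ReadRecord("G" * 21, 1)], nbsu_like_reference, 10)
        assert table.empty and table.registers.sum() == 0.0
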