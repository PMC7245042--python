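import random

import numpy as np
import pytest

from casmap import (
    Mapping,
    OccurrenceIndex,
    Reference,
    Seed,
    build_cas_table,
    collapse_best_per_locus,
    extract_mems,
    greedy_select,
    map_read,
    naive_pigeonhole_seeds,
    pigeonhole_split,
    seed_read,
    vicinity_check,
    vicinity_check_wrt_read,
)
from casmap.brute_oracle import brute_valid_mappings

from conftest import random_reference


def make_seed(read_start, s, occ, radius=None, freq=None):
    return Seed(
        read_start=read_start,
        read_end=read_start + len(s),
        string=s,
        occurrences=np.asarray(occ, dtype=np.int64),
        frequency=len(occ) if freq is None else freq,
        radius=radius,
    )


class TestVicinity:
    def test_window_example(self):
        # AACC at inclusive [1,4] inside GAACCG; query interval [0,5], c=2
        assert vicinity_check(np.array([1]), 4, l1=0, l2=5, c=2)

    def test_exact_interval_c1(self):
        assert vicinity_check(np.array([10]), 5, l1=10, l2=14, c=1)

    def test_far_occurrence_rejected(self):
        assert not vicinity_check(np.array([30]), 4, l1=0, l2=5, c=2)

    def test_distance_one_neighbors_inside_one_letter_window(self):
        # each edit-distance-1 neighbor of AACC in GAACCG occurs inside the
        # 1-letter extended window of the AACC occurrence
        text = "GAACCG"
        for s in ("AAC", "ACC", "GAACC", "AACCG"):
            p = text.find(s)
            assert vicinity_check(np.array([1]), 4, l1=p, l2=p + len(s) - 1, c=1), s

    def test_empty_occurrences(self):
        assert not vicinity_check(np.empty(0, dtype=int), 4, 0, 10, 3)

    def test_projection_onto_read(self):
        seed = make_seed(5, "ACGT", [50])
        # mapping starting at 45 projects the seed interval to [50, 53]
        assert vicinity_check_wrt_read(seed, l1=45, c=1)
        assert not vicinity_check_wrt_read(seed, l1=70, c=2)


class TestExtractMems:
    def test_read_fully_in_reference(self, rng):
        ref = random_reference(rng, 150)
        index = OccurrenceIndex(ref.sequence)
        read = ref.sequence[30:70]
        seeds = extract_mems(read, index)
        assert len(seeds) == 1
        assert seeds[0].string == read
        assert 30 in seeds[0].occurrences

    def test_error_splits_with_skip_two(self):
        rng = random.Random(9)
        text = "".join(rng.choice("ACG") for _ in range(300))
        index = OccurrenceIndex(text)
        read = text[40:80] + "T" + text[81:120]  # T absent from the alphabet used
        assert "T" not in text
        seeds = extract_mems(read, index)
        assert seeds[0].string == text[40:80]
        # next seed starts after skipping two positions past the MEM end
        assert seeds[1].read_start == len(seeds[0]) + 2
        for a, b in zip(seeds, seeds[1:]):
            assert a.read_end <= b.read_start

    def test_letter_absent_everywhere_advances(self):
        index = OccurrenceIndex("AAAA")
        seeds = extract_mems("CCC", index)
        assert seeds == []
        seeds = extract_mems("CAA", index, min_length=1)
        assert len(seeds) == 1 and seeds[0].read_start == 1

    def test_sub_floor_matches_not_emitted(self):
        index = OccurrenceIndex("ACGTGGTTACA" * 3)
        seeds = extract_mems("ACG", index)
        assert seeds == []  # below the default minimum seed length
        assert extract_mems("ACG", index, min_length=3)[0].string == "ACG"

    def test_probe_count_scales_linearly_in_read_length(self, rng):
        ref = random_reference(rng, 2000)
        index = OccurrenceIndex(ref.sequence)
        reads = {n: ref.sequence[100 : 100 + n] for n in (100, 200, 400)}
        probes = {}
        for n, read in reads.items():
            index.n_probes = 0
            extract_mems(read, index)
            probes[n] = index.n_probes
        assert probes[200] <= 3 * probes[100]
        assert probes[400] <= 3 * probes[200]


class TestPigeonholeSplit:
    @pytest.mark.parametrize(
        "n,t,lengths",
        [(100, 4, [25, 25, 25, 25]), (10, 3, [4, 3, 3]), (7, 1, [7])],
    )
    def test_split_lengths(self, n, t, lengths):
        read = "A" * n
        seeds = pigeonhole_split(read, t)
        assert [len(s) for s in seeds] == lengths
        assert seeds[0].read_start == 0
        assert seeds[-1].read_end == n
        for a, b in zip(seeds, seeds[1:]):
            assert a.read_end == b.read_start

    def test_oversized_t_rejected(self):
        with pytest.raises(ValueError):
            pigeonhole_split("ACGT", 5)


class TestGreedySelect:
    def test_two_radius_two_seeds_cover_t4(self):
        seeds = [
            make_seed(0, "AACC", [5], radius=2),
            make_seed(10, "TTGG", [40], radius=2),
        ]
        sel = greedy_select(seeds, t=4, R="A" * 20)
        assert sel.mode == "cas"
        assert len(sel.seeds) == 2 and sel.total_radius == 4

    def test_unit_radii_degenerate_to_pigeonhole_count(self):
        seeds = [make_seed(6 * i, "ACGTAC", [i], radius=1) for i in range(5)]
        sel = greedy_select(seeds, t=3, R="A" * 30)
        assert sel.mode == "cas" and len(sel.seeds) == 3

    def test_insufficient_radius_falls_back(self):
        seeds = [make_seed(0, "ACGT", [3], radius=1)]
        sel = greedy_select(seeds, t=3, R="ACGTACGTAC")
        assert sel.mode == "pigeonhole_fallback"
        assert len(sel.seeds) == 3

    def test_frequency_orders_selection(self):
        rare = make_seed(20, "GGGG", [7], radius=1, freq=1)
        common = make_seed(0, "AAAA", [1, 9, 30], radius=1, freq=3)
        sel = greedy_select([common, rare], t=1, R="A" * 30)
        assert sel.seeds == [rare]
        assert sel.raw[0] is rare

    def test_t_validation(self):
        with pytest.raises(ValueError):
            greedy_select([], t=0, R="ACGT")
        with pytest.raises(ValueError):
            greedy_select([], t=10, R="ACGT")


@pytest.fixture(scope="module")
def setup():
    rng = random.Random(31)
    ref = random_reference(rng, 600)
    table = build_cas_table(ref, P=10, theta=2, I=1)
    index = OccurrenceIndex(ref.sequence)
    return ref, table, index


class TestMapRead:
    def test_exact_unique_read_t1(self, setup):
        ref, table, index = setup
        read = ref.sequence[200:260]
        assert index.occ(read) == 1
        maps = map_read(read, 1, table, index)
        assert maps == [Mapping(start=200, end=259, distance=0)]

    def test_planted_edits_recovered_and_oracle_equal(self, setup):
        ref, table, index = setup
        rng = random.Random(7)
        for t in (2, 3):
            for _ in range(15):
                start = rng.randint(0, len(ref) - 80)
                read = list(ref.sequence[start : start + 80])
                for _e in range(t - 1):
                    read[rng.randrange(len(read))] = rng.choice("ACGT")
                read = "".join(read)
                got = map_read(read, t, table, index)
                want = brute_valid_mappings(read, ref, t)
                assert got == want
                assert any(m.start <= start <= m.start + t for m in got)

    def test_selection_never_exceeds_t_seeds(self, setup):
        ref, table, index = setup
        rng = random.Random(13)
        for t in (2, 4):
            for _ in range(10):
                start = rng.randint(0, len(ref) - 100)
                sel = seed_read(ref.sequence[start : start + 100], t, table, index)
                assert len(sel.seeds) <= t
                if sel.mode == "cas":
                    assert sel.total_radius >= t
                for a, b in zip(
                    sorted(sel.seeds, key=lambda s: s.read_start),
                    sorted(sel.seeds, key=lambda s: s.read_start)[1:],
                ):
                    assert a.read_end <= b.read_start

    def test_theta_one_degenerates_to_pigeonhole(self, setup):
        ref, _, index = setup
        table1 = build_cas_table(ref, P=10, theta=1, I=1)
        rng = random.Random(17)
        for t in (2, 3, 4):
            for _ in range(5):
                start = rng.randint(0, len(ref) - 100)
                sel = seed_read(ref.sequence[start : start + 100], t, table1, index)
                assert len(sel.seeds) == t

    def test_vicinity_coverage_of_all_valid_mappings(self, setup):
        ref, table, index = setup
        rng = random.Random(23)
        for t in (2, 3):
            for _ in range(10):
                start = rng.randint(0, len(ref) - 90)
                read = list(ref.sequence[start : start + 90])
                read.insert(rng.randrange(len(read)), rng.choice("ACGT"))
                read = "".join(read)
                sel = seed_read(read, t, table, index)
                for m in brute_valid_mappings(read, ref, t):
                    assert any(
                        vicinity_check_wrt_read(s, m.start, t) for s in sel.seeds
                    )


class TestNaiveComparator:
    def test_consecutive_twelvemers(self, rng):
        ref = random_reference(rng, 400)
        index = OccurrenceIndex(ref.sequence)
        read = ref.sequence[50:150]
        sel = naive_pigeonhole_seeds(read, 3, index)
        assert [s.read_start for s in sel.seeds] == [0, 12, 24]
        assert all(len(s) == 12 for s in sel.seeds)
        assert sel.total_frequency >= 3

    def test_read_too_short(self):
        index = OccurrenceIndex("ACGT" * 30)
        with pytest.raises(ValueError):
            naive_pigeonhole_seeds("ACGTACGTACG", 1, index)


def test_collapse_best_per_locus():
    maps = [
        Mapping(10, 50, 2),
        Mapping(11, 51, 1),
        Mapping(12, 52, 2),
        Mapping(200, 240, 3),
    ]
    assert collapse_best_per_locus(maps) == [Mapping(11, 51, 1), Mapping(200, 240, 3)]
    assert collapse_best_per_locus([]) == []
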