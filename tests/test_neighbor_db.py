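import itertools
import random

import numpy as np
import pytest

from casmap import (
    ImmediateFlags,
    Reference,
    build_neighbor_db,
    build_suffix_trie,
    confidence_radius,
    edit_distance_step,
    init_root_neighbors,
    is_immediate,
    propagate_immediate_flags,
)
from casmap.brute_oracle import (
    brute_all_radii,
    brute_neighbors,
    declarative_flags,
    levenshtein,
)

from conftest import random_reference


def build(text: str, theta: int, max_depth: int | None = None, alphabet="ACGT"):
    ref = Reference("t", text, alphabet=alphabet)
    trie = build_suffix_trie(ref, max_depth or len(text))
    return trie, build_neighbor_db(trie, theta)


def db_pairs(trie, db) -> dict[tuple[str, str], int]:
    strings = [trie.node_string(v) for v in range(trie.n_nodes)]
    out = {}
    for v in range(1, trie.n_nodes):
        for u, d in zip(db.X[v], db.Y[v]):
            if u:
                out[(strings[v], strings[int(u)])] = int(d)
    return out


@pytest.mark.parametrize(
    "args,expected",
    [((0, 1, 1, 0), 0), ((0, 1, 1, 1), 1), ((2, 1, 3, 1), 2), ((5, 0, 9, 0), 1)],
)
def test_edit_distance_step(args, expected):
    assert edit_distance_step(*args) == expected


class TestRootInit:
    def test_theta_one_only_root(self):
        trie = build_suffix_trie(Reference("t", "ACGT"), 4)
        ids, dists, flags = init_root_neighbors(trie, 1)
        assert ids == [0] and dists == [0]
        assert flags[0].as_tuple()[:4] == (True, True, True, True)

    def test_two_letter_example(self):
        trie = build_suffix_trie(Reference("t", "AC"), 2)
        ids, dists, _ = init_root_neighbors(trie, 2)
        spelled = sorted(trie.node_string(v) for v in ids)
        assert spelled == ["", "A", "C"]
        assert sorted(dists) == [0, 1, 1]

    @pytest.mark.parametrize("theta", [1, 2, 3, 5])
    def test_max_distance(self, rng, theta):
        trie = build_suffix_trie(random_reference(rng, 30), 4)
        _, dists, _ = init_root_neighbors(trie, theta)
        assert max(dists) == min(theta, int(trie.depth.max())) - 1

    def test_invalid_theta(self):
        trie = build_suffix_trie(Reference("t", "A"), 1)
        with pytest.raises(ValueError):
            init_root_neighbors(trie, 0)


class TestFlags:
    def test_self_pair_conditions_one_to_four(self):
        f = propagate_immediate_flags(
            ImmediateFlags.from_mask(15), None, None, True, False, nodes_equal=True
        )
        assert f.as_tuple()[:4] == (True, True, True, True)
        assert not f.u_internal_substring_of_v and not f.v_internal_substring_of_u

    def test_is_immediate(self):
        assert not is_immediate(ImmediateFlags())
        assert is_immediate(ImmediateFlags(prefix_of_u_is_suffix_of_v=True))
        assert is_immediate(ImmediateFlags.from_mask(15))

    def test_declarative_suffix_example(self):
        flags = declarative_flags("AACC", "ACC")
        assert flags.u_suffix_of_v
        assert not flags.u_prefix_of_v
        assert is_immediate(flags)

    def test_mirror_invariant(self, rng):
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            assert declarative_flags(a, b).mirror() == declarative_flags(b, a)

    def test_propagation_equals_declarative_on_stored_pairs(self):
        """Pipeline Z flags must equal literal string-relationship tests for
        every stored pair, over an exhaustive family of tiny references."""
        for L in range(1, 8):
            for tup in itertools.product("AC", repeat=L):
                text = "".join(tup)
                trie, db = build(text, theta=2, max_depth=6, alphabet="AC")
                for v in range(1, trie.n_nodes):
                    sv = trie.node_string(v)
                    for u, z in zip(db.X[v], db.Z[v]):
                        if not u:
                            continue
                        su = trie.node_string(int(u))
                        assert int(z) == declarative_flags(sv, su).to_mask(), (
                            text,
                            sv,
                            su,
                        )


class TestBuilder:
    def test_gaaccg_distance_one_neighbors(self):
        trie, db = build("GAACCG", theta=2)
        v = trie.find("AACC")
        at_one = {
            trie.node_string(int(u))
            for u, d in zip(db.X[v], db.Y[v])
            if d == 1
        }
        assert {"AAC", "ACC", "GAACC", "AACCG"} <= at_one

    def test_theta_one_self_only(self, rng):
        trie, db = build(random_reference(rng, 40).sequence, theta=1, max_depth=5)
        for v in range(trie.n_nodes):
            assert list(db.X[v]) == [v]
            assert list(db.Y[v]) == [0]

    def test_exhaustive_equivalence_tiny(self):
        for L in range(1, 8):
            for tup in itertools.product("AC", repeat=L):
                text = "".join(tup)
                trie, db = build(text, theta=2, max_depth=6, alphabet="AC")
                assert db_pairs(trie, db) == brute_neighbors(text, 4, 2), text

    @pytest.mark.parametrize("seed,theta", [(0, 2), (1, 3), (2, 3)])
    def test_random_equivalence(self, seed, theta):
        rng = random.Random(seed)
        ref = random_reference(rng, rng.randint(40, 90))
        trie = build_suffix_trie(ref, 8 + theta)
        db = build_neighbor_db(trie, theta)
        assert db_pairs(trie, db) == brute_neighbors(ref.sequence, 8, theta)

    def test_structural_invariants(self, rng):
        ref = random_reference(rng, 70)
        trie = build_suffix_trie(ref, 9)
        db = build_neighbor_db(trie, 3)
        seen = {}
        for v in range(trie.n_nodes):
            ids = db.X[v]
            assert np.all(np.diff(ids) > 0), "X_v not strictly rank-sorted"
            assert v in set(int(u) for u in ids)
            for u, d in zip(ids, db.Y[v]):
                seen[(v, int(u))] = int(d)
                assert 0 <= d < 3
        # symmetry with equal distances
        for (v, u), d in seen.items():
            assert seen.get((u, v)) == d
        # closure: a stored pair's parents are a stored pair
        parent = trie.parent
        for (v, u), _ in seen.items():
            if v and u:
                assert (int(parent[v]), int(parent[u])) in seen
        assert db.M == sum(len(x) for x in db.X)

    def test_debug_dump(self, tmp_path):
        trie, db = build("GAACCG", theta=2)
        db.dump_tsv(tmp_path / "dump.tsv")
        lines = (tmp_path / "dump.tsv").read_text().splitlines()
        assert lines[0] == "node\tneighbor\tdistance\tflags"
        assert len(lines) == 1 + db.M
        with pytest.raises(ValueError):
            db.dump_tsv(tmp_path / "x.tsv", max_nodes=3)

    def test_theta_validation(self, rng):
        trie = build_suffix_trie(random_reference(rng, 10), 3)
        with pytest.raises(ValueError):
            build_neighbor_db(trie, 0)


class TestRadius:
    def test_cap_when_no_nontrivial_neighbor(self, rng):
        # a long unique seed in a random reference has no neighbor within
        # theta at all, so its radius is the cap
        ref = random_reference(rng, 300)
        trie = build_suffix_trie(ref, 24)
        db = build_neighbor_db(trie, 4)
        deep = [
            v
            for v in range(trie.n_nodes)
            if trie.depth[v] == 21 and trie.occ_count[v] == 1
        ]
        assert deep
        result = confidence_radius(db, deep[0])
        assert result.radius == 4

    def test_radius_bounds_and_equality_with_oracle(self):
        rng = random.Random(5)
        for _ in range(4):
            ref = random_reference(rng, rng.randint(40, 100))
            trie = build_suffix_trie(ref, 11)
            db = build_neighbor_db(trie, 3)
            got = db.radii(max_len=8)
            want = brute_all_radii(ref, 8, 3)
            for v in range(1, trie.n_nodes):
                s = trie.node_string(v)
                assert 1 <= got[v] <= 3
                if len(s) <= 8:
                    assert int(got[v]) == want[s], s

    def test_radius_result_counts_non_immediate(self):
        trie, db = build("GAACCG", theta=2)
        v = trie.find("AACC")
        res = confidence_radius(db, v)
        assert res.n_non_immediate == int((db.Z[v] == 0).sum())
        assert res.radius >= 1

    def test_theta_mismatch_rejected(self):
        trie, db = build("ACGT", theta=2)
        with pytest.raises(ValueError):
            confidence_radius(db, 1, theta=5)

    def test_non_immediate_min_overshoots_definitional(self):
        """Documented finding: minimizing over non-immediate neighbors only
        (the piggybacked shortcut) can exceed the definitional radius when
        every closest nontrivial neighbor is a substring or overlapping
        string of the seed, as happens around repeats.  The seeding pipeline
        therefore uses the exact definitional radius."""
        text = "CTAAAGACAATTACATAACATACACGTCAGCACGAAACTTGTTGGCCCAG"
        trie, db = build(text, theta=3, max_depth=11)
        fast = db.radii(method="non_immediate_min")
        exact = db.radii(max_len=8)
        overshoot = [
            trie.node_string(v)
            for v in range(1, trie.n_nodes)
            if len(trie.node_string(v)) <= 8 and fast[v] > exact[v]
        ]
        assert "AACATA" in overshoot  # ACATA repeats; all close nontrivial
        # neighbors of AACATA overlap it, so the shortcut reports theta
        want = brute_all_radii(ref := Reference("t", text), 8, 3)
        for v in range(1, trie.n_nodes):
            s = trie.node_string(v)
            if len(s) <= 8:
                # the exact path never overshoots the definitional value
                assert int(exact[v]) == want[s]

    def test_levenshtein_agrees_with_stored_distances(self, rng):
        ref = random_reference(rng, 50)
        trie = build_suffix_trie(ref, 7)
        db = build_neighbor_db(trie, 3)
        for v in rng.sample(range(1, trie.n_nodes), 25):
            sv = trie.node_string(v)
            for u, d in zip(db.X[v], db.Y[v]):
                if u:
                    assert levenshtein(sv, trie.node_string(int(u))) == d
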