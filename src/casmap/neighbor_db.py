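"""All-pairs bounded edit-distance neighbors over the suffix trie.

For every trie node ``v`` this module computes the rank-sorted array of
neighbors ``X_v`` (nodes ``u`` with ``D(u, v) < theta``), the aligned edit
distances ``Y_v``, and immediateness flags ``Z_v`` classifying each neighbor
as a substring / superstring / overlapping string of ``v`` or none of those.
The minimum distance to a *non-immediate* neighbor, capped at ``theta``, is
the node's confidence radius.

The traversal visits nodes in BFS-rank order and derives each child pair's
distance from three previously computed pairs (the two parents, and the two
parent-child cross pairs) in constant time, using forward-only pointers into
the rank-sorted arrays.  Distances of unstored pairs (``>= theta``) enter the
recurrence as the sentinel ``theta + 1``, which can never produce a stored
value, so the sentinel never leaks.

Immediateness is propagated alongside the distances.  The recurrences below
are derived from the string definitions (see ``docs/methods.md``); they are
validated in the test suite against a declarative oracle that inspects the
spelled strings directly.  Conditions 7/8 (overlap) depend on cross pairs
that can fall exactly on the storage threshold and be absent; in that case
the builder evaluates the overlap on the spelled strings directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .suffix_trie import SuffixTrie

__all__ = [
    "ImmediateFlags",
    "NeighborDB",
    "RadiusResult",
    "edit_distance_step",
    "init_root_neighbors",
    "propagate_immediate_flags",
    "is_immediate",
    "build_neighbor_db",
    "confidence_radius",
]

# bitmask layout for the eight immediate conditions (bit k-1 <-> condition k)
C1 = 1  # u is a prefix of v
C2 = 2  # u is a suffix of v
C3 = 4  # v is a prefix of u
C4 = 8  # v is a suffix of u
C5 = 16  # u is an internal (non-prefix, non-suffix) substring of v
C6 = 32  # v is an internal substring of u
C7 = 64  # a prefix of u is a suffix of v
C8 = 128  # a suffix of u is a prefix of v

_SELF_MASK = C1 | C2 | C3 | C4


@dataclass(frozen=True)
class ImmediateFlags:
    """The eight immediate conditions for an ordered pair ``(v, u)``.

    Condition numbering matches the bit layout above.  The mirror pair
    ``F(u, v)`` is obtained by swapping 1<->3, 2<->4, 5<->6 and 7<->8.
    """

    u_prefix_of_v: bool = False
    u_suffix_of_v: bool = False
    v_prefix_of_u: bool = False
    v_suffix_of_u: bool = False
    u_internal_substring_of_v: bool = False
    v_internal_substring_of_u: bool = False
    prefix_of_u_is_suffix_of_v: bool = False
    suffix_of_u_is_prefix_of_v: bool = False

    def to_mask(self) -> int:
        m = 0
        for bit, flag in zip(
            (C1, C2, C3, C4, C5, C6, C7, C8), self.as_tuple()
        ):
            if flag:
                m |= bit
        return m

    @classmethod
    def from_mask(cls, mask: int) -> "ImmediateFlags":
        return cls(*(bool(mask & b) for b in (C1, C2, C3, C4, C5, C6, C7, C8)))

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.u_prefix_of_v,
            self.u_suffix_of_v,
            self.v_prefix_of_u,
            self.v_suffix_of_u,
            self.u_internal_substring_of_v,
            self.v_internal_substring_of_u,
            self.prefix_of_u_is_suffix_of_v,
            self.suffix_of_u_is_prefix_of_v,
        )

    def mirror(self) -> "ImmediateFlags":
        """Flags of the transposed pair ``F(u, v)``."""
        t = self.as_tuple()
        return ImmediateFlags(t[2], t[3], t[0], t[1], t[5], t[4], t[7], t[6])


def is_immediate(flags: "ImmediateFlags | int") -> bool:
    """True iff any of conditions 1-8 holds (substring, superstring or
    overlapping string)."""
    if isinstance(flags, ImmediateFlags):
        return flags.to_mask() != 0
    return flags != 0


def edit_distance_step(
    d_parents: int, d_parent_child: int, d_child_parent: int, delta: int
) -> int:
    """One cell of the edit-distance recurrence on trie pairs.

    ``d_parents`` is ``D(p(v), p(u))``, the two cross terms are
    ``D(p(v), u)`` and ``D(v, p(u))``, and ``delta`` is 0 when the two edge
    letters agree and 1 otherwise.  Distances that were not stored because
    they reached the threshold are passed as a large sentinel meaning
    infinity (the builder uses ``theta + 1``).
    """
    return min(d_parents + delta, d_parent_child + 1, d_child_parent + 1)


def _occurrences_covered(
    occ_u: np.ndarray, len_u: int, occ_v: np.ndarray, len_v: int, d: int
) -> bool:
    """Trivialness geometry: every occurrence ``[p, p+len_u-1]`` of the
    neighbor must contain an occurrence ``[q, q+len_v-1]`` of the seed
    within its d-expanded window (``p - d <= q`` and
    ``q + len_v - 1 <= p + len_u - 1 + d``)."""
    lo = occ_u - d
    hi = occ_u + len_u + d - len_v
    left = np.searchsorted(occ_v, lo, side="left")
    right = np.searchsorted(occ_v, hi, side="right")
    return bool(np.all(right > left))


def _ps_overlap(x: str, y: str, min_overlap: int = 1) -> bool:
    """True iff some prefix of ``y`` of length >= min_overlap equals a
    suffix of ``x`` (overlap length capped at min(|x|, |y|))."""
    top = min(len(x), len(y))
    for k in range(min_overlap, top + 1):
        if y[:k] == x[len(x) - k :]:
            return True
    return False


def _propagate_mask(
    m_vu: int,
    m_v_uc: int,
    m_vc_u: int,
    same_letter: bool,
    nodes_equal: bool,
    len_vc: int,
    len_uc: int,
    min_overlap: int,
    has_v_uc: bool,
    has_vc_u: bool,
    str_vc: str | None,
    str_uc: str | None,
) -> int:
    """Child-pair flags from the three ancestor-pair flag masks.

    ``m_vu`` = F(v, u) for the parents, ``m_v_uc`` = F(v, u'),
    ``m_vc_u`` = F(v', u); an absent cross pair contributes an all-false
    mask, which is provably safe for conditions 1-6.  For conditions 7/8 an
    absent cross pair is resolved on the spelled strings when provided
    (``has_* = False`` and strings given); otherwise absent means false.
    """
    if nodes_equal:
        c1 = c2 = c3 = c4 = True
        c5 = c6 = False
    else:
        c1 = bool(m_v_uc & C1)
        c2 = bool(m_vu & C2) and same_letter
        c3 = bool(m_vc_u & C3)
        c4 = bool(m_vu & C4) and same_letter
        c5 = bool(m_v_uc & (C1 | C2 | C5)) and not (c1 or c2)
        c6 = bool(m_vc_u & (C3 | C4 | C6)) and not (c3 or c4)

    # condition 7: an overlap of length <= |u| propagates from F(v', u);
    # the new maximal overlap length |u'| is exactly "u' is a suffix of v'".
    c7 = bool(m_vc_u & C7) or (c2 and len_uc >= min_overlap)
    if not c7 and not has_vc_u and str_vc is not None:
        c7 = _ps_overlap(str_vc, str_uc, min_overlap)
    # condition 8 mirrors with the other cross pair F(v, u').
    c8 = bool(m_v_uc & C8) or (c4 and len_vc >= min_overlap)
    if not c8 and not has_v_uc and str_vc is not None:
        c8 = _ps_overlap(str_uc, str_vc, min_overlap)

    m = 0
    if c1:
        m |= C1
    if c2:
        m |= C2
    if c3:
        m |= C3
    if c4:
        m |= C4
    if c5:
        m |= C5
    if c6:
        m |= C6
    if c7:
        m |= C7
    if c8:
        m |= C8
    return m


def propagate_immediate_flags(
    f_parents: ImmediateFlags,
    f_v_uchild: ImmediateFlags | None,
    f_vchild_u: ImmediateFlags | None,
    same_edge_letter: bool,
    v_is_root: bool,
    nodes_equal: bool,
    *,
    v_child_len: int | None = None,
    u_child_len: int | None = None,
    min_overlap: int = 1,
) -> ImmediateFlags:
    """Flags of the child pair ``(v', u')`` from its three ancestor pairs.

    Absent cross-pair inputs are treated as all-false, which is exact for
    conditions 1-6 and a safe under-approximation for 7/8 (the database
    builder closes that gap with a declarative check on the strings).  The
    ``v_is_root`` argument is accepted for interface symmetry: once the
    empty-string pairs carry their truthful prefix/suffix flags (the root is
    a prefix and a suffix of every neighbor), the recurrences need no root
    special case; tests confirm this.
    """
    del v_is_root
    m_vu = f_parents.to_mask()
    m_v_uc = f_v_uchild.to_mask() if f_v_uchild is not None else 0
    m_vc_u = f_vchild_u.to_mask() if f_vchild_u is not None else 0
    # lengths only matter when min_overlap > 1; default keeps conditions
    # 7/8 length checks vacuous
    len_vc = v_child_len if v_child_len is not None else min_overlap
    len_uc = u_child_len if u_child_len is not None else min_overlap
    mask = _propagate_mask(
        m_vu,
        m_v_uc,
        m_vc_u,
        same_edge_letter,
        nodes_equal,
        len_vc,
        len_uc,
        min_overlap,
        has_v_uc=f_v_uchild is not None,
        has_vc_u=f_vchild_u is not None,
        str_vc=None,
        str_uc=None,
    )
    return ImmediateFlags.from_mask(mask)


def init_root_neighbors(
    trie: SuffixTrie, theta: int
) -> tuple[list[int], list[int], list[ImmediateFlags]]:
    """Neighbor arrays of the root: all nodes of depth <= theta.

    The distance from the root (the empty string) to a node is the node's
    depth minus 1.  The root's flags record the empty string as a prefix and
    a suffix of every neighbor, and the root pairs with itself under
    conditions 1-4.
    """
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    # BFS ids are depth-sorted, so depth <= theta is a contiguous id prefix
    limit = int(np.searchsorted(trie.depth, theta, side="right"))
    ids = list(range(limit))
    dists = [int(trie.depth[u]) - 1 for u in ids]
    flags = [ImmediateFlags.from_mask(C3 | C4) for _ in ids]
    flags[0] = ImmediateFlags.from_mask(_SELF_MASK)
    return ids, dists, flags


class NeighborDB:
    """Per-node neighbor arrays (ids, distances, immediateness masks).

    ``X[v]``, ``Y[v]``, ``Z[v]`` are numpy arrays aligned by position and
    sorted by neighbor rank.  ``M`` is the total (ordered) neighbor-pair
    count, ``n_candidate_evals`` the number of candidate pairs examined by
    the builder (the operation count of the traversal).
    """

    def __init__(
        self,
        trie: SuffixTrie,
        theta: int,
        min_overlap: int,
        X: list[np.ndarray],
        Y: list[np.ndarray],
        Z: list[np.ndarray],
        n_candidate_evals: int,
    ) -> None:
        self.trie = trie
        self.theta = theta
        self.min_overlap = min_overlap
        self.X = X
        self.Y = Y
        self.Z = Z
        self.n_candidate_evals = n_candidate_evals
        self.M = int(sum(len(x) for x in X))

    def neighbors(self, node_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        self.trie._check_id(node_id)
        return self.X[node_id], self.Y[node_id], self.Z[node_id]

    def neighbor_flags(self, node_id: int) -> list[ImmediateFlags]:
        return [ImmediateFlags.from_mask(int(m)) for m in self.Z[node_id]]

    def radii(
        self, method: str = "definitional", max_len: int | None = None
    ) -> np.ndarray:
        """Confidence radius of every node (vector over node ids).

        ``method="definitional"`` (the pipeline default) returns the exact
        radius: the minimum distance to a *nontrivial* neighbor, capped at
        theta.  Neighbors are scanned in ascending distance; a non-immediate
        neighbor of a seed longer than the distance is provably nontrivial
        (a trivial neighbor's occurrences would have to overlap the seed's
        occurrences by at least ``len - d`` letters, which forces a string
        relationship), and immediate candidates are settled by an explicit
        occurrence-geometry check against the trie's occurrence lists.

        ``method="non_immediate_min"`` returns the minimum distance over
        non-immediate neighbors only.  This shortcut can *overshoot* the
        definitional radius when every closest nontrivial neighbor is a
        substring or overlapping string of the seed (common around repeats);
        it is kept for profiling, not for seeding guarantees.

        Nodes longer than ``max_len`` (and the root) receive theta without
        inspection.
        """
        cache = getattr(self, "_radii_cache", None)
        if cache is None:
            cache = self._radii_cache = {}
        key = (method, max_len)
        if key in cache:
            return cache[key]
        n = self.trie.n_nodes
        theta = self.theta
        out = np.full(n, theta, dtype=np.int64)
        if method == "non_immediate_min":
            for v in range(1, n):
                y = self.Y[v][self.Z[v] == 0]
                if len(y):
                    out[v] = int(y.min())
            cache[key] = out
            return out
        if method != "definitional":
            raise ValueError(f"unknown radius method {method!r}")
        occ = self.trie.occurrence_lists()
        depths = self.trie.depth
        shortcut_ok = self.min_overlap == 1
        for v in range(1, n):
            len_v = int(depths[v]) - 1
            if max_len is not None and len_v > max_len:
                continue
            Xv, Yv, Zv = self.X[v], self.Y[v], self.Z[v]
            occ_v = occ[v]
            for i in np.argsort(Yv, kind="stable"):
                u = int(Xv[i])
                if u == v or u == 0:
                    # the node itself is trivial; the root spells the empty
                    # string, which is not a reference substring and not a
                    # neighbor in the seed sense
                    continue
                d = int(Yv[i])
                if (shortcut_ok and Zv[i] == 0 and len_v > d) or (
                    not _occurrences_covered(
                        occ[u], int(depths[u]) - 1, occ_v, len_v, d
                    )
                ):
                    out[v] = d
                    break
        cache[key] = out
        return out

    def dump_tsv(self, path: str | Path, max_nodes: int = 5000) -> None:
        """Debug dump of (node string, neighbor string, distance, flags)."""
        if self.trie.n_nodes > max_nodes:
            raise ValueError(
                f"refusing to dump {self.trie.n_nodes} nodes (> {max_nodes})"
            )
        with open(path, "w") as fh:
            fh.write("node\tneighbor\tdistance\tflags\n")
            for v in range(self.trie.n_nodes):
                sv = self.trie.node_string(v)
                for u, d, z in zip(self.X[v], self.Y[v], self.Z[v]):
                    su = self.trie.node_string(int(u))
                    fh.write(f"{sv}\t{su}\t{int(d)}\t{int(z):08b}\n")


def build_neighbor_db(
    trie: SuffixTrie, theta: int, min_overlap: int = 1
) -> NeighborDB:
    """Compute, for every trie node, all neighbors within edit distance
    ``< theta``, with exact distances and immediateness flags.

    Storage is strictly ``D < theta``: a pair at distance exactly theta
    cannot lower any radius below the theta cap, so the boundary shell is
    not kept.  ``min_overlap`` is the minimum overlap length for conditions
    7/8 (1 = a single shared letter already counts as overlap).
    """
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    n = trie.n_nodes
    INF = theta + 1

    # spelled strings, for the rare declarative overlap fallback
    strings: list[str] = [""] * n
    parent = trie.parent
    letters = trie.edge_letter
    sigma = trie.alphabet
    for v in range(1, n):
        strings[v] = strings[parent[v]] + sigma[letters[v]]
    depths = trie.depth

    X: list[list[int]] = [[] for _ in range(n)]
    Y: list[list[int]] = [[] for _ in range(n)]
    Z: list[list[int]] = [[] for _ in range(n)]

    # initialization: the root neighbors every node of depth <= theta, and
    # (by symmetry) seeds itself as the rank-1 first entry of each of them
    limit = int(np.searchsorted(depths, theta, side="right"))
    X[0] = list(range(limit))
    Y[0] = [int(depths[u]) - 1 for u in X[0]]
    Z[0] = [C3 | C4] * limit
    Z[0][0] = _SELF_MASK
    for u in range(1, limit):
        X[u] = [0]
        Y[u] = [int(depths[u]) - 1]
        Z[u] = [C1 | C2]

    kids: list[list[tuple[int, int]]] = [
        [(a, int(c)) for a, c in enumerate(row) if c >= 0]
        for row in trie.children
    ]

    ops = 0
    for v in range(n):
        kids_v = kids[v]
        if not kids_v:
            continue
        Xv, Yv, Zv = X[v], Y[v], Z[v]
        len_xv = len(Xv)
        for a, vc in kids_v:
            Xc, Yc, Zc = X[vc], Y[vc], Z[vc]
            str_vc = strings[vc]
            len_vc = int(depths[vc]) - 1
            kv = 0  # forward pointer: candidate u' within X_v
            kc = 0  # forward pointer: u within X_{v'}
            for iu in range(len_xv):
                u = Xv[iu]
                kids_u = kids[u]
                if not kids_u:
                    continue
                d_vu = Yv[iu]
                m_vu = Zv[iu]
                lc = len(Xc)
                while kc < lc and Xc[kc] < u:
                    kc += 1
                if kc < lc and Xc[kc] == u:
                    d_vc_u = Yc[kc]
                    m_vc_u = Zc[kc]
                    has_vc_u = True
                else:
                    d_vc_u = INF
                    m_vc_u = 0
                    has_vc_u = False
                for b, uc in kids_u:
                    ops += 1
                    while kv < len_xv and Xv[kv] < uc:
                        kv += 1
                    if kv < len_xv and Xv[kv] == uc:
                        d_v_uc = Yv[kv]
                        m_v_uc = Zv[kv]
                        has_v_uc = True
                    else:
                        d_v_uc = INF
                        m_v_uc = 0
                        has_v_uc = False
                    d = d_vu if a == b else d_vu + 1
                    if d_v_uc + 1 < d:
                        d = d_v_uc + 1
                    if d_vc_u + 1 < d:
                        d = d_vc_u + 1
                    if d < theta:
                        mask = _propagate_mask(
                            m_vu,
                            m_v_uc,
                            m_vc_u,
                            a == b,
                            uc == vc,
                            len_vc,
                            int(depths[uc]) - 1,
                            min_overlap,
                            has_v_uc,
                            has_vc_u,
                            str_vc,
                            strings[uc],
                        )
                        Xc.append(uc)
                        Yc.append(d)
                        Zc.append(mask)

    Xa = [np.asarray(x, dtype=np.int64) for x in X]
    Ya = [np.asarray(y, dtype=np.int64) for y in Y]
    Za = [np.asarray(z, dtype=np.int64) for z in Z]
    return NeighborDB(trie, theta, min_overlap, Xa, Ya, Za, ops)


@dataclass(frozen=True)
class RadiusResult:
    """Confidence radius of one node and its non-immediate neighbor count."""

    node_id: int
    radius: int
    n_non_immediate: int


def confidence_radius(
    db: NeighborDB,
    node_id: int,
    theta: int | None = None,
    method: str = "definitional",
) -> RadiusResult:
    """Confidence radius of one node, capped at theta.

    The default is the exact definitional radius (minimum distance to a
    nontrivial neighbor); seeds with no nontrivial neighbor within the
    threshold — typical for long, unique seeds — receive the cap.  The
    result is always in ``[1, theta]``: a distance-0 neighbor is the node
    itself, which is trivial (and immediate) by definition.

    ``method="non_immediate_min"`` gives the immediateness-only lower
    scan instead; see :meth:`NeighborDB.radii` for why that shortcut is
    not used for seeding.
    """
    if theta is None:
        theta = db.theta
    if theta != db.theta:
        raise ValueError(
            f"theta={theta} does not match the database threshold {db.theta}"
        )
    db.trie._check_id(node_id)
    _, Y, Z = db.neighbors(node_id)
    n_non_immediate = int((Z == 0).sum())
    if node_id == db.trie.root:
        return RadiusResult(node_id, int(theta), n_non_immediate)
    radius = int(db.radii(method=method)[node_id])
    return RadiusResult(node_id=node_id, radius=radius, n_non_immediate=n_non_immediate)
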