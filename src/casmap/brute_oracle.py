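"""Definition-level reference implementations used to validate the fast
paths.

Everything here works directly from the definitions — full dynamic
programming on string pairs, exhaustive enumeration of substrings and
intervals, occurrence scans — deliberately ignoring the incremental
structure the production code exploits.  Input sizes are guarded so an
accidental call on a full genome fails fast instead of running forever.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighbor_db import ImmediateFlags
from .seeding import Mapping
from .suffix_trie import Reference

__all__ = [
    "OraclePair",
    "levenshtein",
    "declarative_flags",
    "brute_neighbors",
    "brute_trivial",
    "brute_confidence_radius",
    "brute_all_radii",
    "brute_valid_mappings",
    "classify_pair",
]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by the full O(|a||b|) table."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def declarative_flags(v: str, u: str, min_overlap: int = 1) -> ImmediateFlags:
    """The eight immediate conditions evaluated literally on the strings."""

    def overlap(x: str, y: str) -> bool:
        # some prefix of y (length >= min_overlap) is a suffix of x
        return any(
            y[:k] == x[len(x) - k :]
            for k in range(min_overlap, min(len(x), len(y)) + 1)
        )

    u_pre = v.startswith(u)
    u_suf = v.endswith(u)
    v_pre = u.startswith(v)
    v_suf = u.endswith(v)
    return ImmediateFlags(
        u_prefix_of_v=u_pre,
        u_suffix_of_v=u_suf,
        v_prefix_of_u=v_pre,
        v_suffix_of_u=v_suf,
        u_internal_substring_of_v=(u in v) and not (u_pre or u_suf),
        v_internal_substring_of_u=(v in u) and not (v_pre or v_suf),
        prefix_of_u_is_suffix_of_v=overlap(v, u),
        suffix_of_u_is_prefix_of_v=overlap(u, v),
    )


def _distinct_substrings(text: str, max_len: int) -> dict[int, list[str]]:
    by_len: dict[int, set[str]] = {}
    n = len(text)
    for length in range(1, min(max_len, n) + 1):
        by_len[length] = {text[x : x + length] for x in range(n - length + 1)}
    return {length: sorted(group) for length, group in by_len.items()}


def _encode(strings: list[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(strings).encode(), dtype=np.uint8)
    return buf.reshape(len(strings), length)


def _pairwise_distances(
    A: np.ndarray, B: np.ndarray, cap: int
) -> np.ndarray:
    """Edit distances between every row of A and every row of B, exact below
    ``cap`` and clamped at ``cap`` otherwise (clamping is sound: a clamped
    ancestor cell can never pull a true sub-cap value above or below it)."""
    nA, la = A.shape
    nB, lb = B.shape
    cols = np.arange(lb + 1, dtype=np.int16)
    dp = np.broadcast_to(cols, (nA, nB, lb + 1)).astype(np.int16).copy()
    np.minimum(dp, cap, out=dp)
    cand = np.empty_like(dp)
    for i in range(1, la + 1):
        sub = (A[:, i - 1][:, None, None] != B[None, :, :]).astype(np.int16)
        cand[..., 0] = min(i, cap)
        np.minimum(dp[..., 1:] + 1, dp[..., :-1] + sub, out=cand[..., 1:])
        cand -= cols
        np.minimum.accumulate(cand, axis=-1, out=cand)
        dp, cand = cand, dp
        dp += cols
        np.minimum(dp, cap, out=dp)
    return dp[..., lb].astype(np.int64)


def brute_neighbors(
    reference: Reference | str, P: int, theta: int
) -> dict[tuple[str, str], int]:
    """All ordered pairs of distinct substrings (lengths <= P + theta, the
    trie universe) at edit distance < theta, with exact distances.

    Guarded to |T| <= 300 — the pair count is quadratic in the substring
    count and this path exists for validation only.
    """
    text = reference.sequence if isinstance(reference, Reference) else reference
    if len(text) > 300:
        raise ValueError(
            f"brute_neighbors guarded to |T| <= 300 (got {len(text)})"
        )
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    by_len = _distinct_substrings(text, P + theta)
    encoded = {
        length: _encode(strings, length) for length, strings in by_len.items()
    }
    pairs: dict[tuple[str, str], int] = {}
    lengths = sorted(by_len)
    for la in lengths:
        A = encoded[la]
        names_a = by_len[la]
        for lb in lengths:
            if lb < la or lb - la >= theta:
                continue
            B = encoded[lb]
            names_b = by_len[lb]
            dist = _pairwise_distances(A, B, cap=theta)
            ii, jj = np.nonzero(dist < theta)
            for i, j in zip(ii, jj):
                a, b = names_a[int(i)], names_b[int(j)]
                d = int(dist[i, j])
                pairs[(a, b)] = d
                pairs[(b, a)] = d
    return pairs


def _occurrences(text: str, s: str) -> np.ndarray:
    out = []
    start = text.find(s)
    while start != -1:
        out.append(start)
        start = text.find(s, start + 1)
    return np.asarray(out, dtype=np.int64)


def _all_occurrences_covered(
    occ_sp: np.ndarray, len_sp: int, occ_s: np.ndarray, len_s: int, d: int
) -> bool:
    """Every occurrence [p, p+len_sp-1] of s' must contain an occurrence
    [q, q+len_s-1] of s inside its d-expanded window (inclusive bounds)."""
    # need q with p - d <= q and q + len_s - 1 <= p + len_sp - 1 + d
    lo = occ_sp - d
    hi = occ_sp + len_sp + d - len_s  # inclusive upper bound for q
    left = np.searchsorted(occ_s, lo, side="left")
    right = np.searchsorted(occ_s, hi, side="right")
    return bool(np.all(right > left))


def brute_trivial(
    reference: Reference | str, s: str, s_prime: str
) -> bool:
    """Trivial-neighbor test by scanning every occurrence of ``s_prime``.

    ``s_prime`` is trivial when each of its occurrences lies in the vicinity
    of ``s`` under their edit distance — i.e. it can never reveal a mapping
    location that ``s`` does not already point at.  A seed is trivial to
    itself by definition.
    """
    text = reference.sequence if isinstance(reference, Reference) else reference
    occ_s = _occurrences(text, s)
    occ_sp = _occurrences(text, s_prime)
    if len(occ_s) == 0 or len(occ_sp) == 0:
        raise ValueError("both strings must occur in the reference")
    if s_prime == s:
        return True
    d = levenshtein(s, s_prime)
    return _all_occurrences_covered(occ_sp, len(s_prime), occ_s, len(s), d)


def brute_confidence_radius(
    reference: Reference | str, s: str, theta: int
) -> int:
    """Definitional confidence radius: the minimum edit distance from ``s``
    to a nontrivial neighbor among all substrings of the reference, capped
    at theta."""
    text = reference.sequence if isinstance(reference, Reference) else reference
    occ_s = _occurrences(text, s)
    if len(occ_s) == 0:
        raise ValueError(f"{s!r} does not occur in the reference")
    by_len = _distinct_substrings(text, len(s) + theta)
    candidates: list[tuple[int, str]] = []
    for length, strings in by_len.items():
        if abs(length - len(s)) >= theta:
            continue
        for sp in strings:
            if sp == s:
                continue
            d = levenshtein(s, sp)
            if d < theta:
                candidates.append((d, sp))
    candidates.sort()
    for d, sp in candidates:
        occ_sp = _occurrences(text, sp)
        if not _all_occurrences_covered(occ_sp, len(sp), occ_s, len(s), d):
            return d
    return theta


def brute_all_radii(
    reference: Reference | str,
    P: int,
    theta: int,
    pairs: dict[tuple[str, str], int] | None = None,
) -> dict[str, int]:
    """Definitional radii of every substring of length <= P, computed in
    bulk (shared pair enumeration, then an ascending-distance trivialness
    scan with early exit per seed).  A precomputed ``brute_neighbors``
    result may be passed to avoid re-enumerating the pairs."""
    text = reference.sequence if isinstance(reference, Reference) else reference
    if pairs is None:
        pairs = brute_neighbors(reference, P, theta)
    occ_cache: dict[str, np.ndarray] = {}

    def occ(s: str) -> np.ndarray:
        if s not in occ_cache:
            occ_cache[s] = _occurrences(text, s)
        return occ_cache[s]

    neighbors: dict[str, list[tuple[int, str]]] = {}
    for (a, b), d in pairs.items():
        if len(a) <= P and a != b:
            neighbors.setdefault(a, []).append((d, b))
    radii: dict[str, int] = {}
    by_len = _distinct_substrings(text, P)
    for length, strings in by_len.items():
        for s in strings:
            radius = theta
            for d, sp in sorted(neighbors.get(s, [])):
                if not _all_occurrences_covered(
                    occ(sp), len(sp), occ(s), len(s), d
                ):
                    radius = d
                    break
            radii[s] = radius
    return radii


def brute_valid_mappings(
    R: str, reference: Reference | str, t: int
) -> list[Mapping]:
    """Every inclusive interval [l1, l2] with D(R, T[l1, l2]) < t, by
    exhaustive dynamic programming over all candidate starts.

    The tolerance must be >= 1 (D < 0 is an empty criterion).  Interval
    lengths range over (|R| - t, |R| + t).
    """
    text = reference.sequence if isinstance(reference, Reference) else reference
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if len(text) > 50_000 or len(R) > 2_000:
        raise ValueError("brute_valid_mappings guarded to small instances")
    n = len(text)
    len_r = len(R)
    min_len = max(1, len_r - t + 1)
    max_start = n - min_len
    if max_start < 0:
        return []
    starts = np.arange(max_start + 1, dtype=np.int64)
    W = len_r + t - 1
    enc_t = np.frombuffer(text.encode(), dtype=np.uint8)
    enc_r = np.frombuffer(R.encode(), dtype=np.uint8)
    idx = starts[:, None] + np.arange(W)[None, :]
    inb = idx < n
    chars = np.where(inb, enc_t[np.clip(idx, 0, n - 1)], 0)
    cols = np.arange(W + 1, dtype=np.int32)
    dp = np.broadcast_to(cols, (len(starts), W + 1)).astype(np.int32).copy()
    cand = np.empty_like(dp)
    for i in range(1, len_r + 1):
        sub = (chars != enc_r[i - 1]).astype(np.int32)
        cand[:, 0] = i
        np.minimum(dp[:, 1:] + 1, dp[:, :-1] + sub, out=cand[:, 1:])
        cand -= cols
        np.minimum.accumulate(cand, axis=1, out=cand)
        dp, cand = cand, dp
        dp += cols
    out: list[Mapping] = []
    for row in range(len(starts)):
        l1 = int(starts[row])
        top = min(W, n - l1)
        for j in range(min_len, top + 1):
            d = int(dp[row, j])
            if d < t:
                out.append(Mapping(start=l1, end=l1 + j - 1, distance=d))
    return sorted(set(out))


@dataclass(frozen=True)
class OraclePair:
    """A fully classified substring pair: distance, trivialness (an
    occurrence-geometry property of the reference) and immediateness (a pure
    string relationship)."""

    a: str
    b: str
    distance: int
    trivial: bool
    immediate: bool


def classify_pair(
    reference: Reference | str, a: str, b: str, min_overlap: int = 1
) -> OraclePair:
    d = levenshtein(a, b)
    return OraclePair(
        a=a,
        b=b,
        distance=d,
        trivial=brute_trivial(reference, a, b),
        immediate=declarative_flags(a, b, min_overlap).to_mask() != 0,
    )
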