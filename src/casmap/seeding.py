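"""Greedy context-aware seeding and vicinity-based read mapping.

A read ``R`` maps validly to a reference interval when the edit distance is
strictly below the tolerance ``t``.  Classic pigeonhole seeding splits ``R``
into ``t`` non-overlapping seeds; the weighted form used here instead selects
non-overlapping seeds whose confidence radii sum to at least ``t`` — any
valid mapping then sits in the vicinity of at least one selected seed, since
a mapping missed by every seed would cost at least one radius of edits per
seed, i.e. at least ``t`` edits in total.

Seeds are maximal exact matches (MEMs) extracted left to right; after each
MEM two positions are skipped heuristically (a mismatch that ended the MEM
likely sits there).  Seeds are ranked by occurrence frequency and the
cheapest prefix reaching total radius ``t`` is selected; if the read cannot
muster total radius ``t`` the scheme degrades to the plain pigeonhole split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cas_table import CASTable, OccurrenceIndex, infer_radius

__all__ = [
    "Seed",
    "SeedSelection",
    "Mapping",
    "vicinity_check",
    "vicinity_check_wrt_read",
    "extract_mems",
    "assign_radii",
    "greedy_select",
    "pigeonhole_split",
    "naive_pigeonhole_seeds",
    "seed_read",
    "map_read",
    "collapse_best_per_locus",
]


@dataclass(frozen=True)
class Seed:
    """A read substring with its reference occurrences and radius.

    ``read_start``/``read_end`` are 0-based half-open read coordinates.
    ``provenance`` records how the radius was obtained: ``direct``,
    ``inferred``, ``substituted`` or ``pigeonhole``.
    """

    read_start: int
    read_end: int
    string: str
    occurrences: np.ndarray | None = None
    frequency: int = 0
    radius: int | None = None
    provenance: str = "mem"

    def __len__(self) -> int:
        return self.read_end - self.read_start


@dataclass
class SeedSelection:
    """The greedy-chosen seed set of one read."""

    seeds: list[Seed]
    raw: list[Seed]
    total_radius: int
    mode: str  # "cas" | "pigeonhole_fallback"
    t: int

    @property
    def total_frequency(self) -> int:
        return int(sum(s.frequency for s in self.seeds))


@dataclass(frozen=True, order=True)
class Mapping:
    """A reference interval (0-based inclusive) with its edit distance."""

    start: int
    end: int
    distance: int


def vicinity_check(
    occurrences: np.ndarray,
    s_length: int,
    l1: int,
    l2: int,
    c: int,
) -> bool:
    """True iff the seed occurs at an interval [ls1, ls2] (inclusive) with
    ``l1 - c <= ls1`` and ``ls2 <= l2 + c``.

    The bounds are inclusive: the window is the query interval extended by
    ``c`` letters on each side.  This is the only convention under which a
    seed's own occurrence is in its vicinity at c = 0 (self-trivialness)
    and under which every distance-1 neighbor of a seed sits inside its
    1-letter extended window.
    """
    if len(occurrences) == 0:
        return False
    ls1 = np.asarray(occurrences)
    ls2 = ls1 + s_length - 1
    return bool(np.any((l1 - c <= ls1) & (ls2 <= l2 + c)))


def vicinity_check_wrt_read(seed: Seed, l1: int, c: int) -> bool:
    """Vicinity test after projecting the seed's read interval onto the
    mapping that starts at reference position ``l1``."""
    occ = seed.occurrences if seed.occurrences is not None else np.empty(0, int)
    return vicinity_check(
        occ,
        len(seed),
        l1 + seed.read_start,
        l1 + seed.read_end - 1,
        c,
    )


def extract_mems(
    R: str,
    index: OccurrenceIndex,
    skip: int = 2,
    interval: int | None = None,
    min_length: int = 5,
) -> list[Seed]:
    """Left-to-right maximal-exact-match seeds.

    Each seed is the longest prefix of the unscanned read suffix that occurs
    in the reference; after a seed, ``skip`` positions are passed over to
    jump a likely error.  A position whose letter ends every match at length
    zero (letter absent from the reference, or outside the alphabet) is
    simply advanced past.  When ``interval`` is given, the skip is
    suppressed if it would shrink a still-usable tail (at least ``interval``
    letters) below usability.

    Matches shorter than ``min_length`` (typically 1-2 bp stubs at the read
    tail) are scanned past without emitting a seed: such fragments occur
    hundreds of times in even a kilobase reference and cannot discriminate
    loci, while contributing the same unit of radius as a proper seed.
    Dropping them is always safe — the greedy step simply reverts to the
    pigeonhole split when the surviving seeds cannot reach total radius t.
    """
    seeds: list[Seed] = []
    i = 0
    n = len(R)
    floor = max(min_length, interval or 1)
    while i < n:
        length, lo, hi = index.longest_prefix_match(R[i:])
        if length == 0:
            i += 1
            continue
        if length < floor:
            i += length + skip
            continue
        seeds.append(
            Seed(
                read_start=i,
                read_end=i + length,
                string=R[i : i + length],
                occurrences=index.positions_of_range(lo, hi),
                frequency=hi - lo,
                radius=None,
                provenance="mem",
            )
        )
        nxt = i + length + skip
        if (
            interval is not None
            and n - nxt < interval <= n - (i + length)
        ):
            nxt = i + length
        i = nxt
    return seeds


def assign_radii(
    seeds: list[Seed], table: CASTable, index: OccurrenceIndex
) -> list[Seed]:
    """Attach a confidence radius to every seed via the table.

    Seeds of sampled length resolve directly; others through
    frequency-matching inference.  A seed with no frequency-matching
    substring is replaced by its substitute substring (interval, string and
    occurrences updated).  Seeds shorter than the sampling interval cannot
    be supported and are dropped (the greedy step falls back to pigeonhole
    seeding if the survivors cannot reach total radius t).
    """
    out: list[Seed] = []
    for seed in seeds:
        if len(seed) < table.I:
            continue
        pos = int(seed.occurrences[0])
        assignment = infer_radius(table, index, seed.string, pos)
        if assignment.provenance == "substituted":
            start = seed.read_start + assignment.offset
            sub = seed.string[
                assignment.offset : assignment.offset + assignment.length
            ]
            occ = index.positions(sub)
            out.append(
                Seed(
                    read_start=start,
                    read_end=start + assignment.length,
                    string=sub,
                    occurrences=occ,
                    frequency=len(occ),
                    radius=assignment.radius,
                    provenance="substituted",
                )
            )
        else:
            out.append(
                replace(seed, radius=assignment.radius, provenance=assignment.provenance)
            )
    return out


def pigeonhole_split(R: str, t: int) -> list[Seed]:
    """Partition the read into ``t`` contiguous seeds (longer ones first).

    Every seed implicitly carries radius 1 — the unweighted pigeonhole
    scheme.  Occurrences are left unset; the mapper fills them in.
    """
    n = len(R)
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if t > n:
        raise ValueError(f"cannot split a length-{n} read into {t} seeds")
    base, extra = divmod(n, t)
    seeds = []
    pos = 0
    for i in range(t):
        length = base + (1 if i < extra else 0)
        seeds.append(
            Seed(
                read_start=pos,
                read_end=pos + length,
                string=R[pos : pos + length],
                occurrences=None,
                frequency=0,
                radius=1,
                provenance="pigeonhole",
            )
        )
        pos += length
    return seeds


def greedy_select(seeds: list[Seed], t: int, R: str) -> SeedSelection:
    """Frequency-greedy selection of the minimum prefix with total radius
    >= t; reverts to the pigeonhole split when the budget cannot be met.

    Ties in frequency prefer the longer seed, then the leftmost.  In CAS
    mode at most ``t`` seeds are ever chosen, since every radius is >= 1.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if t > len(R):
        raise ValueError(f"t={t} exceeds the read length {len(R)}")
    raw = sorted(
        seeds, key=lambda s: (s.frequency, -(len(s)), s.read_start)
    )
    chosen: list[Seed] = []
    total = 0
    for seed in raw:
        chosen.append(seed)
        total += int(seed.radius or 0)
        if total >= t:
            return SeedSelection(
                seeds=chosen, raw=raw, total_radius=total, mode="cas", t=t
            )
    fallback = pigeonhole_split(R, t)
    return SeedSelection(
        seeds=fallback, raw=raw, total_radius=t, mode="pigeonhole_fallback", t=t
    )


def naive_pigeonhole_seeds(
    R: str, t: int, index: OccurrenceIndex, k: int = 12
) -> SeedSelection:
    """The naive comparator: the first ``t`` consecutive non-overlapping
    k-bp seeds (k = 12 by default), each with implicit radius 1."""
    if t * k > len(R):
        raise ValueError(
            f"read of length {len(R)} too short for {t} seeds of {k} bp"
        )
    seeds = []
    for i in range(t):
        start = i * k
        s = R[start : start + k]
        occ = index.positions(s)
        seeds.append(
            Seed(
                read_start=start,
                read_end=start + k,
                string=s,
                occurrences=occ,
                frequency=len(occ),
                radius=1,
                provenance="pigeonhole",
            )
        )
    return SeedSelection(seeds=seeds, raw=seeds, total_radius=t, mode="naive12", t=t)


def seed_read(
    R: str, t: int, table: CASTable, index: OccurrenceIndex
) -> SeedSelection:
    """MEM extraction -> radius assignment -> greedy selection, with seed
    occurrences resolved (also for pigeonhole-fallback seeds)."""
    mems = extract_mems(R, index, interval=table.I)
    with_radii = assign_radii(mems, table, index)
    selection = greedy_select(with_radii, t, R)
    if selection.mode == "pigeonhole_fallback":
        resolved = []
        for seed in selection.seeds:
            occ = index.positions(seed.string)
            resolved.append(
                replace(seed, occurrences=occ, frequency=len(occ))
            )
        selection.seeds = resolved
    return selection


def _interval_distances(
    text: str, R: str, starts: np.ndarray, t: int
) -> np.ndarray:
    """Edit distances D(R, text[l1 : l1+j]) for each candidate start l1 and
    every window length j in one batched DP.

    Returns an array of shape (len(starts), W+1) with W = |R| + t - 1; cells
    whose window would overrun the text are filled against a non-matching
    pad and must be masked by the caller.
    """
    n = len(text)
    W = len(R) + t - 1
    enc_t = np.frombuffer(text.encode(), dtype=np.uint8)
    enc_r = np.frombuffer(R.encode(), dtype=np.uint8)
    idx = starts[:, None] + np.arange(W)[None, :]
    inb = idx < n
    chars = np.where(inb, enc_t[np.clip(idx, 0, n - 1)], 255)
    cols = np.arange(W + 1)
    dp = np.broadcast_to(cols, (len(starts), W + 1)).astype(np.int32).copy()
    cand = np.empty_like(dp)
    for i in range(1, len(R) + 1):
        sub = (chars != enc_r[i - 1]).astype(np.int32)
        cand[:, 0] = i
        np.minimum(dp[:, 1:] + 1, dp[:, :-1] + sub, out=cand[:, 1:])
        # dp_new[j] = min_{k<=j} cand[k] + (j-k): prefix-min cascade
        cand -= cols
        np.minimum.accumulate(cand, axis=1, out=cand)
        dp, cand = cand, dp
        dp += cols
    return dp


def map_read(
    R: str,
    t: int,
    table: CASTable,
    index: OccurrenceIndex,
    reference=None,
    best_per_locus: bool = False,
    selection: SeedSelection | None = None,
) -> list[Mapping]:
    """All valid mappings of a read: inclusive intervals [l1, l2] of the
    reference with ``D(R, T[l1, l2]) < t``.

    Around every occurrence of every selected seed, the projected read
    placement widened by ``t`` on both sides is verified exhaustively by
    semi-global dynamic programming (free end gaps on the reference side);
    the widening matches the vicinity window under c = t, so the weighted
    pigeonhole guarantee makes this candidate set complete.
    ``reference`` is accepted for interface completeness; the index carries
    the text.  Pass ``best_per_locus=True`` to collapse overlapping
    reported intervals to the minimum-distance one.
    """
    if selection is None:
        selection = seed_read(R, t, table, index)
    text = index.text
    n = len(text)
    len_r = len(R)
    min_len = max(1, len_r - t + 1)

    starts: set[int] = set()
    for seed in selection.seeds:
        if seed.occurrences is None:
            continue
        for p0 in seed.occurrences:
            p = int(p0) - seed.read_start
            lo = max(0, p - t)
            hi = min(n - min_len, p + t)
            starts.update(range(lo, hi + 1))
    if not starts:
        return []
    start_arr = np.asarray(sorted(starts), dtype=np.int64)
    dp = _interval_distances(text, R, start_arr, t)

    mappings: set[Mapping] = set()
    W = len_r + t - 1
    for row, l1 in enumerate(start_arr):
        max_len = min(W, n - int(l1))
        for j in range(min_len, max_len + 1):
            d = int(dp[row, j])
            if d < t:
                mappings.add(Mapping(start=int(l1), end=int(l1) + j - 1, distance=d))
    result = sorted(mappings)
    if best_per_locus:
        result = collapse_best_per_locus(result)
    return result


def collapse_best_per_locus(mappings: list[Mapping]) -> list[Mapping]:
    """Collapse chains of mutually overlapping intervals to the
    minimum-distance member (leftmost on ties)."""
    if not mappings:
        return []
    out: list[Mapping] = []
    cluster: list[Mapping] = []
    cluster_end = -1
    for m in sorted(mappings):
        if cluster and m.start > cluster_end:
            out.append(min(cluster, key=lambda x: (x.distance, x.start, x.end)))
            cluster = []
            cluster_end = -1
        cluster.append(m)
        cluster_end = max(cluster_end, m.end)
    out.append(min(cluster, key=lambda x: (x.distance, x.start, x.end)))
    return out
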