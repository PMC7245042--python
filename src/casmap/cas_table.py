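"""Confidence-radius table with interval sampling, plus the occurrence index.

The table stores, for every reference start position ``x`` and every sampled
seed length ``y`` (multiples of the sampling interval ``I``, capped at the
maximum seed length ``P``), the confidence radius of the seed ``T[x, x+y)``.
Radii of seeds whose length is not sampled are inferred at mapping time: a
substring with the same occurrence frequency as the seed has a radius that is
a valid (possibly loose) lower bound for the seed, so the maximum radius
among frequency-matching sampled substrings is used; if no substring
frequency-matches, the seed is withdrawn and replaced by a sampled substring.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .neighbor_db import build_neighbor_db
from .suffix_trie import Reference, build_suffix_trie

__all__ = [
    "OccurrenceIndex",
    "CASTable",
    "RadiusAssignment",
    "build_cas_table",
    "lookup",
    "infer_radius",
]


class OccurrenceIndex:
    """Suffix-array occurrence lookup: ``occ(s)`` and the sorted start
    positions of any query string.

    Any index with this contract would do (the asymptotic arguments use a
    BWT index); a plain suffix array is simplest at the scales this package
    targets.  ``n_probes`` counts binary-search probes, used by the seeding
    complexity checks.
    """

    def __init__(self, text: str) -> None:
        self.text = text
        n = len(text)
        self.sa = np.asarray(
            sorted(range(n), key=lambda i: text[i:]), dtype=np.int64
        )
        self.n_probes = 0

    def __len__(self) -> int:
        return len(self.text)

    # -- low-level range machinery ----------------------------------------

    def _range(self, s: str) -> tuple[int, int]:
        """Suffix-array interval [lo, hi) of suffixes starting with ``s``."""
        text, sa = self.text, self.sa
        m = len(s)
        lo, hi = 0, len(sa)
        # lower bound
        a, b = lo, hi
        while a < b:
            mid = (a + b) // 2
            self.n_probes += 1
            p = sa[mid]
            if text[p : p + m] < s:
                a = mid + 1
            else:
                b = mid
        lo2 = a
        a, b = lo2, hi
        while a < b:
            mid = (a + b) // 2
            self.n_probes += 1
            p = sa[mid]
            if text[p : p + m] <= s:
                a = mid + 1
            else:
                b = mid
        return lo2, a

    def _extend_range(
        self, lo: int, hi: int, depth: int, letter: str
    ) -> tuple[int, int]:
        """Refine [lo, hi) (suffixes sharing a ``depth``-prefix) to those
        whose next letter equals ``letter``; single-character probes."""
        text, sa, n = self.text, self.sa, len(self.text)
        a, b = lo, hi
        while a < b:
            mid = (a + b) // 2
            self.n_probes += 1
            p = sa[mid] + depth
            # exhausted suffixes (p >= n) sort before every extension and
            # must fall outside the refined interval
            if p >= n or text[p] < letter:
                a = mid + 1
            else:
                b = mid
        new_lo = a
        a, b = new_lo, hi
        while a < b:
            mid = (a + b) // 2
            self.n_probes += 1
            p = sa[mid] + depth
            if p < n and text[p] <= letter:
                a = mid + 1
            else:
                b = mid
        return new_lo, a

    # -- public contract ---------------------------------------------------

    def occ(self, s: str) -> int:
        lo, hi = self._range(s)
        return hi - lo

    def positions(self, s: str) -> np.ndarray:
        lo, hi = self._range(s)
        return np.sort(self.sa[lo:hi])

    def longest_prefix_match(self, q: str) -> tuple[int, int, int]:
        """Longest prefix of ``q`` occurring in the text.

        Returns ``(length, lo, hi)`` with [lo, hi) the suffix-array interval
        of the match (the whole array for an empty match).
        """
        lo, hi = 0, len(self.sa)
        depth = 0
        for letter in q:
            nlo, nhi = self._extend_range(lo, hi, depth, letter)
            if nlo >= nhi:
                break
            lo, hi, depth = nlo, nhi, depth + 1
        return depth, lo, hi

    def positions_of_range(self, lo: int, hi: int) -> np.ndarray:
        return np.sort(self.sa[lo:hi])


@dataclass
class CASTable:
    """Dense per-position, per-sampled-length table of confidence radii.

    ``radii[x, j]`` holds the radius of the seed of length
    ``sampled_lengths[j]`` starting at position ``x`` (1..theta), or 0 when
    the seed would overrun the reference.  Radii are properties of the seed
    string, so equal strings at different positions hold equal entries.
    """

    reference_name: str
    length: int
    P: int
    theta: int
    I: int
    checksum: str
    sampled_lengths: list[int] = field(default_factory=list)
    radii: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), np.uint8))

    def lookup(self, position: int, length: int) -> int | None:
        """Stored radius of the seed at ``[position, position+length)``, or
        ``None`` when that (position, length) is not sampled or out of range."""
        if length not in self._length_col:
            return None
        if position < 0 or position + length > self.length:
            return None
        return int(self.radii[position, self._length_col[length]])

    @property
    def _length_col(self) -> dict[int, int]:
        return {y: j for j, y in enumerate(self.sampled_lengths)}

    @property
    def max_sampled_length(self) -> int:
        return self.sampled_lengths[-1]

    def entry_count(self) -> int:
        return int((self.radii > 0).sum())

    def min_radius(self) -> int:
        vals = self.radii[self.radii > 0]
        return int(vals.min())

    # -- serialization: text header + one byte per entry -------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "reference_name": self.reference_name,
            "length": self.length,
            "P": self.P,
            "theta": self.theta,
            "I": self.I,
            "checksum": self.checksum,
            "sampled_lengths": list(self.sampled_lengths),
        }
        with open(directory / "header.yaml", "w") as fh:
            yaml.safe_dump(header, fh, sort_keys=True)
        self.radii.astype(np.uint8).tofile(directory / "radii.bin")

    @classmethod
    def load(cls, directory: str | Path) -> "CASTable":
        directory = Path(directory)
        with open(directory / "header.yaml") as fh:
            header = yaml.safe_load(fh)
        radii = np.fromfile(directory / "radii.bin", dtype=np.uint8)
        n_cols = len(header["sampled_lengths"])
        radii = radii.reshape(header["length"], n_cols)
        return cls(
            reference_name=header["reference_name"],
            length=header["length"],
            P=header["P"],
            theta=header["theta"],
            I=header["I"],
            checksum=header["checksum"],
            sampled_lengths=list(header["sampled_lengths"]),
            radii=radii,
        )


def sampled_lengths(P: int, I: int) -> list[int]:
    """Seed lengths kept under interval sampling: multiples of I up to P."""
    return list(range(I, P + 1, I))


def reference_checksum(reference: Reference) -> str:
    return hashlib.md5(reference.sequence.encode()).hexdigest()


def build_cas_table(
    reference: Reference,
    P: int,
    theta: int,
    I: int = 1,
    min_overlap: int = 1,
) -> CASTable:
    """Build the confidence-radius table of a reference.

    The suffix trie is built to depth ``P + theta``; neighbors of length-P
    seeds within distance < theta need strings no longer than
    P + theta - 1, so the last level is a harmless superset kept for
    simplicity.  The neighbor database is computed once; identical seed
    strings share one radius through their shared trie node.
    """
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    if not 1 <= I <= P:
        raise ValueError(f"need 1 <= I <= P, got I={I}, P={P}")
    n = len(reference)
    if P + theta > n:
        warnings.warn(
            f"P + theta = {P + theta} exceeds |T| = {n}; the trie truncates "
            "naturally",
            stacklevel=2,
        )
    trie = build_suffix_trie(reference, P + theta)
    db = build_neighbor_db(trie, theta, min_overlap=min_overlap)
    node_radius = db.radii(max_len=P)

    lengths = sampled_lengths(P, I)
    col = {y: j for j, y in enumerate(lengths)}
    radii = np.zeros((n, len(lengths)), dtype=np.uint8)
    children = trie.children
    letter_index = {c: i for i, c in enumerate(reference.alphabet)}
    encoded = [letter_index[c] for c in reference.sequence]
    max_len = lengths[-1]
    for x in range(n):
        v = 0
        for d in range(x, min(n, x + max_len)):
            v = int(children[v, encoded[d]])
            y = d - x + 1
            j = col.get(y)
            if j is not None:
                radii[x, j] = node_radius[v]
    return CASTable(
        reference_name=reference.name,
        length=n,
        P=P,
        theta=theta,
        I=I,
        checksum=reference_checksum(reference),
        sampled_lengths=lengths,
        radii=radii,
    )


def lookup(table: CASTable, position: int, length: int) -> int | None:
    """Module-level alias of :meth:`CASTable.lookup`."""
    return table.lookup(position, length)


@dataclass(frozen=True)
class RadiusAssignment:
    """Outcome of a radius query for a seed.

    ``provenance`` is ``direct`` (sampled length), ``inferred`` (radius of a
    frequency-matching sampled substring) or ``substituted`` (the seed must
    be replaced by the sampled substring at ``[offset, offset+length)``
    relative to the seed's own start).
    """

    radius: int
    provenance: str
    offset: int = 0
    length: int = 0


def infer_radius(
    table: CASTable, index: OccurrenceIndex, s: str, s_position: int
) -> RadiusAssignment:
    """Radius of a seed whose length may not be sampled.

    Sampled lengths resolve by direct lookup.  Otherwise every substring of
    the next-smaller sampled length is enumerated; among those whose
    occurrence frequency equals the seed's, the maximum radius is a valid
    radius for the seed itself (an equal-frequency substring occurs exactly
    where the seed does, so any nontrivial neighbor it has would betray one
    of the seed too).  With no frequency match the seed cannot be supported
    and the substring with the minimum frequency (ties: maximum radius, then
    leftmost) is offered as a substitute.
    """
    L = len(s)
    if L < table.I:
        raise ValueError(
            f"seed of length {L} is shorter than the sampling interval "
            f"{table.I}; fall back to pigeonhole seeding"
        )
    if L <= table.max_sampled_length and L % table.I == 0:
        r = table.lookup(s_position, L)
        if r is None:
            raise ValueError(
                f"seed at position {s_position} length {L} out of range"
            )
        return RadiusAssignment(radius=r, provenance="direct", offset=0, length=L)

    target = min(table.I * (L // table.I), table.max_sampled_length)
    occ_s = index.occ(s)
    best_match: tuple[int, int] | None = None  # (radius, offset)
    candidates: list[tuple[int, int, int]] = []  # (occ, radius, offset)
    for off in range(0, L - target + 1):
        sub_pos = s_position + off
        r = table.lookup(sub_pos, target)
        if r is None:
            continue
        occ_sub = index.occ(s[off : off + target])
        candidates.append((occ_sub, r, off))
        if occ_sub == occ_s and (best_match is None or r > best_match[0]):
            best_match = (r, off)
    if best_match is not None:
        return RadiusAssignment(
            radius=best_match[0], provenance="inferred", offset=0, length=L
        )
    if not candidates:
        raise ValueError(
            f"no database-supported substring for seed of length {L}"
        )
    # substitution: minimum frequency, then maximum radius, then leftmost
    occ_min = min(c[0] for c in candidates)
    pool = [c for c in candidates if c[0] == occ_min]
    r_max = max(c[1] for c in pool)
    off = min(c[2] for c in pool if c[1] == r_max)
    return RadiusAssignment(
        radius=r_max, provenance="substituted", offset=off, length=target
    )
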