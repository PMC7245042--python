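"""Bounded-depth suffix trie of a reference sequence, with BFS ranks.

The trie contains one node for every distinct substring of the reference
``T`` of length at most ``max_depth``.  Node ranks follow a breadth-first,
depth-major order (root first, then depth by depth; within a depth, children
of lower-ranked parents first; siblings in fixed alphabet order).  The
neighbor-database traversal relies on this ordering: neighbor arrays sorted
by rank can then be merged with forward-only pointers.

Coordinates are 0-based, half-open ``[start, end)`` everywhere in this
package; inclusive interval notation appears only at documented CLI output
boundaries.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DNA_ALPHABET = "ACGT"

__all__ = [
    "DNA_ALPHABET",
    "Reference",
    "TrieNode",
    "SuffixTrie",
    "build_suffix_trie",
    "node_string",
]


@dataclass(frozen=True)
class Reference:
    """A single named sequence over a finite alphabet (default A/C/G/T).

    Raises ``ValueError`` on an empty sequence or on the first letter outside
    the alphabet (the error names the offending 0-based position).
    """

    name: str
    sequence: str
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.name!r}: sequence is empty")
        allowed = set(self.alphabet)
        for i, letter in enumerate(self.sequence):
            if letter not in allowed:
                raise ValueError(
                    f"reference {self.name!r}: letter {letter!r} at position "
                    f"{i} is outside the alphabet {self.alphabet!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        alphabet: str = DNA_ALPHABET,
        hard_mask: bool = False,
    ) -> "Reference":
        """Read a single-record FASTA file.

        Multi-record files are refused: a database is built for one contig so
        that occurrence counts stay unambiguous.  With ``hard_mask=True``,
        letters outside the alphabet (e.g. N) are excised before validation;
        note this shifts downstream coordinates relative to the input file.
        """
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) == 0:
            raise ValueError(f"{path}: no FASTA records found")
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records found; one contig per "
                "database build (concatenation is refused)"
            )
        rec = records[0]
        seq = str(rec.seq).upper()
        if hard_mask:
            allowed = set(alphabet)
            seq = "".join(c for c in seq if c in allowed)
        return cls(name=rec.id, sequence=seq, alphabet=alphabet)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")


@dataclass(frozen=True)
class TrieNode:
    """Read-only view of one trie node.

    ``depth`` counts the root as 1, so the node's string has length
    ``depth - 1``.  ``rank`` is the 1-based BFS rank (root has rank 1).
    ``children`` maps edge letters to child ids in fixed alphabet order.
    """

    id: int
    parent: int | None
    edge_letter: str | None
    depth: int
    rank: int
    occurrence_count: int
    position: int
    children: dict[str, int] = field(default_factory=dict)


class SuffixTrie:
    """Array-backed trie; node ids coincide with BFS order (rank = id + 1)."""

    def __init__(
        self,
        reference: Reference,
        max_depth: int,
        parent: np.ndarray,
        edge_letter: np.ndarray,
        depth: np.ndarray,
        occ_count: np.ndarray,
        rep_pos: np.ndarray,
        children: np.ndarray,
    ) -> None:
        self.reference = reference
        self.alphabet = reference.alphabet
        self.max_depth = max_depth
        self.parent = parent  # -1 for root
        self.edge_letter = edge_letter  # alphabet index; -1 for root
        self.depth = depth  # root = 1
        self.occ_count = occ_count
        self.rep_pos = rep_pos  # one representative start offset; -1 for root
        self.children = children  # (n_nodes, |alphabet|) child ids, -1 absent

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def rank(self, node_id: int) -> int:
        self._check_id(node_id)
        return node_id + 1

    def node(self, node_id: int) -> TrieNode:
        self._check_id(node_id)
        kids = {
            self.alphabet[a]: int(c)
            for a, c in enumerate(self.children[node_id])
            if c >= 0
        }
        parent = int(self.parent[node_id])
        letter = int(self.edge_letter[node_id])
        return TrieNode(
            id=node_id,
            parent=parent if parent >= 0 else None,
            edge_letter=self.alphabet[letter] if letter >= 0 else None,
            depth=int(self.depth[node_id]),
            rank=node_id + 1,
            occurrence_count=int(self.occ_count[node_id]),
            position=int(self.rep_pos[node_id]),
            children=kids,
        )

    def child(self, node_id: int, letter: str) -> int | None:
        self._check_id(node_id)
        c = int(self.children[node_id, self.alphabet.index(letter)])
        return c if c >= 0 else None

    def iter_children(self, node_id: int):
        """Yield ``(alphabet_index, child_id)`` in fixed letter order."""
        for a, c in enumerate(self.children[node_id]):
            if c >= 0:
                yield a, int(c)

    def node_string(self, node_id: int) -> str:
        """Spell the node by walking edge letters from the root.

        The root (depth 1) spells the empty string; in general the string has
        length ``depth - 1``.
        """
        self._check_id(node_id)
        letters: list[str] = []
        v = node_id
        while v != 0:
            letters.append(self.alphabet[int(self.edge_letter[v])])
            v = int(self.parent[v])
        return "".join(reversed(letters))

    def find(self, s: str) -> int | None:
        """Return the id of the node spelling ``s``, or None."""
        v = 0
        for letter in s:
            nxt = self.child(v, letter)
            if nxt is None:
                return None
            v = nxt
        return v

    def occurrence_lists(self) -> list[np.ndarray]:
        """Sorted start offsets of every node's string (cached).

        Built by walking the reference once; total size is at most
        ``|T| * max_depth`` positions, which is what makes the exact
        trivialness checks of the radius computation affordable.
        """
        cached = getattr(self, "_occ_lists", None)
        if cached is not None:
            return cached
        lists: list[list[int]] = [[] for _ in range(self.n_nodes)]
        seq = self.reference.sequence
        letter_index = {c: i for i, c in enumerate(self.alphabet)}
        children = self.children
        n = len(seq)
        for x in range(n):
            v = 0
            for d in range(x, min(n, x + self.max_depth)):
                v = int(children[v, letter_index[seq[d]]])
                lists[v].append(x)
        out = [np.asarray(lst, dtype=np.int64) for lst in lists]
        out[0] = np.arange(n, dtype=np.int64)  # the empty string: everywhere
        self._occ_lists = out
        return out

    def _check_id(self, node_id: int) -> None:
        if not 0 <= node_id < self.n_nodes:
            raise KeyError(f"unknown trie node id {node_id}")


def build_suffix_trie(reference: Reference, max_depth: int) -> SuffixTrie:
    """Insert every suffix of the reference, truncated at ``max_depth``.

    Naive O(|T| * max_depth) insertion; the linear-time claims of the
    neighbor-database construction concern the trie traversal, not this step.
    Occurrence counts are accumulated during insertion (every start offset
    walks the full path of its prefix), and the representative position of a
    node is the smallest start offset of its string.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    seq = reference.sequence
    sigma = reference.alphabet
    letter_index = {c: i for i, c in enumerate(sigma)}
    k = len(sigma)

    # growable first-pass structure (insertion order, not BFS order)
    children: list[list[int]] = [[-1] * k]
    occ: list[int] = [0]
    pos: list[int] = [-1]

    encoded = [letter_index[c] for c in seq]
    n = len(seq)
    for x in range(n):
        v = 0
        occ[0] += 1
        for d in range(x, min(n, x + max_depth)):
            a = encoded[d]
            nxt = children[v][a]
            if nxt < 0:
                nxt = len(children)
                children.append([-1] * k)
                occ.append(0)
                pos.append(x)
                children[v][a] = nxt
            v = nxt
            occ[v] += 1

    # BFS renumbering so that node id order == rank order
    n_nodes = len(children)
    order = np.empty(n_nodes, dtype=np.int64)
    new_id = np.empty(n_nodes, dtype=np.int64)
    parent_new = np.full(n_nodes, -1, dtype=np.int32)
    letter_new = np.full(n_nodes, -1, dtype=np.int8)
    depth_new = np.empty(n_nodes, dtype=np.int32)
    queue: deque[int] = deque([0])
    order[0] = 0
    new_id[0] = 0
    depth_new[0] = 1
    count = 1
    head = 0
    # BFS over new ids: process nodes in assignment order
    bfs: deque[tuple[int, int]] = deque([(0, 0)])  # (old id, new id)
    while bfs:
        old_v, v = bfs.popleft()
        for a in range(k):
            old_c = children[old_v][a]
            if old_c >= 0:
                c = count
                count += 1
                new_id[old_c] = c
                order[c] = old_c
                parent_new[c] = v
                letter_new[c] = a
                depth_new[c] = depth_new[v] + 1
                bfs.append((old_c, c))

    occ_arr = np.asarray(occ, dtype=np.int64)[order]
    pos_arr = np.asarray(pos, dtype=np.int64)[order]
    child_arr = np.full((n_nodes, k), -1, dtype=np.int32)
    for v in range(n_nodes):
        old_v = order[v]
        for a in range(k):
            old_c = children[old_v][a]
            if old_c >= 0:
                child_arr[v, a] = new_id[old_c]

    return SuffixTrie(
        reference=reference,
        max_depth=max_depth,
        parent=parent_new,
        edge_letter=letter_new,
        depth=depth_new,
        occ_count=occ_arr,
        rep_pos=pos_arr,
        children=child_arr,
    )


def node_string(trie: SuffixTrie, node_id: int) -> str:
    """Module-level alias of :meth:`SuffixTrie.node_string`."""
    return trie.node_string(node_id)
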