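"""Synthetic references and reads with planted truth, plus profiling
reports.

The generator emulates the benchmark setting of short-read mapping at desk
scale: a uniform-random background genome, optionally seeded with mutated
repeat families (the regime where context-aware seeds pay off), and
fixed-length reads sampled uniformly with a bounded number of planted edits
so that every read retains at least one valid mapping at its origin.  All
randomness flows from a single integer seed through one numpy generator;
equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cas_table import CASTable, OccurrenceIndex, sampled_lengths
from .neighbor_db import NeighborDB
from .seeding import naive_pigeonhole_seeds, seed_read
from .suffix_trie import DNA_ALPHABET, Reference

logger = logging.getLogger("casmap")

__all__ = [
    "SyntheticSpec",
    "SimulatedRead",
    "StatsReport",
    "generate_reference",
    "generate_reads",
    "write_fastq",
    "read_fastq",
    "write_truth",
    "read_truth",
    "run_stats",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the package's standard benchmark conditions: a 2 kb
    reference, 100 bp reads, and a small planted-edit budget (the error
    tolerance used downstream must exceed ``max_edits``).
    """

    length: int = 2000
    alphabet: str = DNA_ALPHABET
    n_repeat_families: int = 0
    repeat_length: int = 200
    repeat_copies: int = 4
    repeat_mutation_rate: float = 0.0
    read_count: int = 50
    read_length: int = 100
    max_edits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("reference length must be >= 1")
        for name in (
            "n_repeat_families",
            "repeat_length",
            "repeat_copies",
            "read_count",
            "read_length",
            "max_edits",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_repeat_families > 0 and self.repeat_length > self.length:
            raise ValueError("repeat longer than the reference")
        if self.read_length > self.length:
            raise ValueError("read length exceeds the reference length")
        if not 0.0 <= self.repeat_mutation_rate <= 1.0:
            raise ValueError("repeat_mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin_start: int  # 0-based inclusive
    origin_end: int  # 0-based inclusive
    planted_edits: int


def _random_string(rng: np.random.Generator, alphabet: str, n: int) -> str:
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(letters, size=n).tobytes().decode()


def generate_reference(spec: SyntheticSpec) -> Reference:
    """Uniform background with planted (optionally mutated) repeat copies.

    Copies are placed at mutually non-overlapping positions so that no copy
    overwrites another; with mutation rate 0 the repeat string therefore
    occurs at least ``repeat_copies`` times per family.  Placement fails
    with an error when the requested copies cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_string(rng, spec.alphabet, spec.length))
    occupied: list[tuple[int, int]] = []
    for _fam in range(spec.n_repeat_families):
        template = _random_string(rng, spec.alphabet, spec.repeat_length)
        for _copy in range(spec.repeat_copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, spec.length - spec.repeat_length + 1))
                end = start + spec.repeat_length
                if all(end <= a or start >= b for a, b in occupied):
                    break
            else:
                raise ValueError(
                    "could not place non-overlapping repeat copies; reduce "
                    "repeat_length, repeat_copies or n_repeat_families"
                )
            occupied.append((start, end))
            copy = list(template)
            if spec.repeat_mutation_rate > 0:
                hits = rng.random(spec.repeat_length) < spec.repeat_mutation_rate
                for i in np.nonzero(hits)[0]:
                    copy[i] = spec.alphabet[int(rng.integers(len(spec.alphabet)))]
            seq[start:end] = copy
    return Reference(name=f"synthetic_seed{spec.seed}", sequence="".join(seq))


def _plant_edits(
    seq: str, k: int, alphabet: str, rng: np.random.Generator
) -> str:
    out = list(seq)
    for _ in range(k):
        op = int(rng.integers(3))
        if op == 0 and out:  # substitution
            i = int(rng.integers(len(out)))
            out[i] = alphabet[int(rng.integers(len(alphabet)))]
        elif op == 1:  # insertion
            i = int(rng.integers(len(out) + 1))
            out.insert(i, alphabet[int(rng.integers(len(alphabet)))])
        elif out:  # deletion
            i = int(rng.integers(len(out)))
            del out[i]
    return "".join(out)


def generate_reads(
    reference: Reference, spec: SyntheticSpec
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Reads from uniform start positions with up to ``max_edits`` planted
    edits each (uniform mix of substitutions, insertions and deletions).

    The truth table records the origin interval and the planted edit count;
    since edits can cancel, the true edit distance to the origin is at most
    the planted count.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = len(reference)
    reads: list[SimulatedRead] = []
    for i in range(spec.read_count):
        start = int(rng.integers(0, n - spec.read_length + 1))
        end = start + spec.read_length - 1
        k = int(rng.integers(0, spec.max_edits + 1))
        seq = _plant_edits(
            reference.sequence[start : end + 1], k, spec.alphabet, rng
        )
        reads.append(
            SimulatedRead(
                read_id=f"read{i:05d}",
                sequence=seq,
                origin_start=start,
                origin_end=end,
                planted_edits=k,
            )
        )
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "origin_start": [r.origin_start for r in reads],
            "origin_end": [r.origin_end for r in reads],
            "planted_edits": [r.planted_edits for r in reads],
        }
    )
    return reads, truth


# -- plain-text I/O --------------------------------------------------------


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Constant-quality FASTQ ('I' throughout; the generator does not model
    base quality and all readers here ignore it)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs; qualities are ignored."""
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- profiling reports -----------------------------------------------------


@dataclass
class StatsReport:
    """Aggregate profiles of a built database and of seeding behaviour.

    ``depth_profile``: per trie depth, node count, mean children per node,
    mean neighbor count and mean non-immediate neighbor count.
    ``seeding``: per error tolerance and scheme, mean seed count, mean total
    seed frequency and the pigeonhole-fallback rate.
    ``storage``: table entry counts per sampling interval.
    """

    depth_profile: pd.DataFrame
    seeding: pd.DataFrame
    storage: pd.DataFrame

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.depth_profile.to_csv(
            directory / "depth_profile.tsv", sep="\t", index=False
        )
        self.seeding.to_csv(directory / "seeding.tsv", sep="\t", index=False)
        self.storage.to_csv(directory / "storage.tsv", sep="\t", index=False)

    def plot(self, directory: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
        dp = self.depth_profile
        axes[0].plot(dp["depth"], dp["mean_neighbors"], marker="o")
        axes[0].set_xlabel("trie depth")
        axes[0].set_ylabel("mean neighbors / node")
        axes[1].plot(dp["depth"], dp["mean_children"], marker="o")
        axes[1].set_xlabel("trie depth")
        axes[1].set_ylabel("mean children / node")
        axes[2].plot(dp["depth"], dp["mean_non_immediate"], marker="o")
        axes[2].set_xlabel("trie depth")
        axes[2].set_ylabel("mean non-immediate / node")
        fig.tight_layout()
        fig.savefig(directory / "depth_profile.png", dpi=120)
        plt.close(fig)


def run_stats(
    db: NeighborDB,
    table: CASTable,
    reads: list[str] | list[SimulatedRead],
    t_values: list[int],
    naive_k: int = 12,
) -> StatsReport:
    """Depth profiles of the trie/neighbor database and the CAS-vs-naive
    seeding comparison over the given reads and tolerances."""
    trie = db.trie
    depths = np.asarray(trie.depth)
    n_children = (np.asarray(trie.children) >= 0).sum(axis=1)
    neigh_counts = np.asarray([len(x) for x in db.X])
    nonimm_counts = np.asarray([int((z == 0).sum()) for z in db.Z])
    rows = []
    for depth in range(1, int(depths.max()) + 1):
        sel = depths == depth
        rows.append(
            {
                "depth": depth,
                "n_nodes": int(sel.sum()),
                "mean_children": float(n_children[sel].mean()),
                "mean_neighbors": float(neigh_counts[sel].mean()),
                "mean_non_immediate": float(nonimm_counts[sel].mean()),
            }
        )
    depth_profile = pd.DataFrame(rows)

    sequences = [
        r.sequence if isinstance(r, SimulatedRead) else r for r in reads
    ]
    index = OccurrenceIndex(trie.reference.sequence)
    seed_rows = []
    for t in t_values:
        for scheme in ("cas", f"naive{naive_k}"):
            counts, freqs, fallbacks = [], [], 0
            for seq in sequences:
                if scheme == "cas":
                    sel = seed_read(seq, t, table, index)
                    if sel.mode == "pigeonhole_fallback":
                        fallbacks += 1
                else:
                    sel = naive_pigeonhole_seeds(seq, t, index, k=naive_k)
                counts.append(len(sel.seeds))
                freqs.append(sel.total_frequency)
            seed_rows.append(
                {
                    "t": t,
                    "scheme": scheme,
                    "mean_seed_count": float(np.mean(counts)),
                    "mean_total_frequency": float(np.mean(freqs)),
                    "fallback_rate": fallbacks / max(1, len(sequences)),
                }
            )
    seeding = pd.DataFrame(seed_rows)

    storage_rows = []
    for interval in (1, 2, 4, 8):
        if interval > table.P:
            continue
        lengths = sampled_lengths(table.P, interval)
        entries = sum(
            max(0, table.length - y + 1) for y in lengths
        )
        storage_rows.append({"interval": interval, "entries": entries})
    storage = pd.DataFrame(storage_rows)
    logger.info(
        "stats: %d nodes, M=%d, %d reads, t=%s",
        trie.n_nodes,
        db.M,
        len(sequences),
        list(t_values),
    )
    return StatsReport(
        depth_profile=depth_profile, seeding=seeding, storage=storage
    )
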