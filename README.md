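# casmap — context-aware seeds for read mapping

`casmap` implements a weighted generalization of pigeonhole seeding for
seed-and-extend read mapping.  A reference interval `[l1, l2]` is a *valid
mapping* of a read `R` under tolerance `t` when `D(R, T[l1, l2]) < t`
(unit-cost edit distance).  Classical mappers split `R` into `t`
non-overlapping seeds to guarantee that no valid mapping is missed; as `t`
grows the seeds shrink and their occurrence frequency — and with it the
number of candidate alignments — explodes.

`casmap` instead profiles the reference offline: every seed `s` (substring
up to length `P`) gets a **confidence radius**

    c_s = min { D(s, s') : s' a nontrivial neighbor of s },  capped at θ,

where a *neighbor* is a reference substring with `D(s, s') < θ` and a
neighbor is *trivial* when all of its occurrences fall inside the
`D(s, s')`-extended window of an occurrence of `s`.  The **weighted
pigeonhole principle** then states: any non-overlapping seed set `S` of `R`
with `Σ_{s∈S} c_s ≥ t` finds every valid mapping — a mapping missed by all
seeds would cost at least `c_s` edits per seed, i.e. `≥ t` in total.
Ordinary pigeonhole seeding is the special case `c_s ≡ 1`.

The package provides:

- a bounded-depth suffix trie with BFS ranks (`casmap.suffix_trie`);
- an all-pairs bounded edit-distance neighbor database over the trie, with
  distances derived incrementally along trie edges and
  substring/superstring/overlap classification of every pair
  (`casmap.neighbor_db`);
- the per-position, per-length confidence-radius table with interval
  sampling and frequency-matched radius inference for unsampled lengths
  (`casmap.cas_table`);
- greedy context-aware seeding (maximal-exact-match extraction, frequency
  ranking, pigeonhole fallback) and exhaustive vicinity-window verification
  returning *all* valid mappings (`casmap.seeding`);
- definition-level brute-force oracles that validate every fast path
  (`casmap.brute_oracle`);
- a seeded synthetic reference/read generator with planted truth and
  profiling reports (`casmap.synthetic_io`), and a `cas` command-line
  interface.

## Worked example

```bash
cas simulate --length 2000 --repeat-families 2 --repeat-length 150 \
    --repeat-copies 3 --repeat-mutation-rate 0.02 \
    --read-count 8 --read-length 100 --max-edits 2 --seed 11 --out sim
cas build --ref sim/ref.fa --theta 3 --max-seed-len 12 --interval 2 --out db
# database written to db: 11964 entries, min radius 1
cas inspect db --position 100 --length 12
# c(T[100, 112)) = 3
```

The 12-mer at position 100 has radius 3: no reference substring within two
edits of it occurs anywhere its own occurrences would not reveal, so this
single seed absorbs tolerance 3 on its own.  Seeding the simulated reads at
`t = 3`:

```bash
cas seed --db db --ref sim/ref.fa --reads sim/reads.fq --t 3
# read_id    mode                 n_seeds  total_radius  total_frequency
# read00000  pigeonhole_fallback  3        3             5
# read00001  cas                  1        3             1
# read00004  cas                  3        5             5
# ...
cas compare --db db --ref sim/ref.fa --reads sim/reads.fq --t 3
# CAS:    mean seeds 2.25  mean total frequency 3.25
# naive12: mean seeds 3.00  mean total frequency 5.38
```

Several reads are secured by a single seed of radius 3 and frequency 1
where naive pigeonhole seeding would pay for three 12-mers; reads whose
surviving seeds cannot reach total radius 3 revert to the pigeonhole split
automatically.  Mapping reports every valid interval (1-based inclusive in
the TSV output):

```bash
cas map --db db --ref sim/ref.fa --reads sim/reads.fq --t 3 --out maps.tsv
# read00000  1163  1264  2
# read00000  1164  1264  1
# ...
```

Overlapping intervals around one locus are all reported because each one
satisfies `D < t`; pass `--best-per-locus` to keep only the
minimum-distance interval per cluster.

`cas verify --ref ... --theta ... --max-seed-len ...` cross-checks a small
reference against brute-force enumeration, and `cas stats` writes the
depth-profile and seeding-comparison tables.

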