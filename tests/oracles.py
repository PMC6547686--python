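"""Independent reference implementations used to cross-check the package.

Each oracle is deliberately naive (quadratic merges, exhaustive
enumeration, closed-form algebra) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations, groupby

import numpy as np


def brute_force_clusters(reads, min_reads, min_crosslinked, min_conversion_fraction):
    """O(n^2) transitive-overlap merge via union-find on read pairs.

    ``reads`` are (transcript_id, start, end, n_conversions) tuples.
    Returns a set of (transcript_id, start, end, n_reads, n_crosslinked)
    for groups passing all three thresholds.
    """
    parent = list(range(len(reads)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(reads)), 2):
        ti, si, ei, _ = reads[i]
        tj, sj, ej, _ = reads[j]
        if ti == tj and si < ej and sj < ei:
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(reads)):
        groups.setdefault(find(i), []).append(i)

    out = set()
    for members in groups.values():
        n = len(members)
        n_xl = sum(1 for i in members if reads[i][3] > 0)
        if (
            n >= min_reads
            and n_xl >= min_crosslinked
            and n_xl / n >= min_conversion_fraction
        ):
            out.add(
                (
                    reads[members[0]][0],
                    min(reads[i][1] for i in members),
                    max(reads[i][2] for i in members),
                    n,
                    n_xl,
                )
            )
    return out


def exhaustive_g4(sequence, min_tract=3, max_loop=7, min_tracts=4):
    """Leftmost-greedy G4 scan built from itertools.groupby runs.

    Returns a list of (start, end, tract_lengths, loop_lengths) tuples.
    """
    runs = []
    pos = 0
    for char, grp in groupby(sequence.upper().replace("U", "T")):
        n = len(list(grp))
        if char == "G" and n >= min_tract:
            runs.append((pos, n))
        pos += n

    motifs = []
    used_until = -1
    idx = 0
    while idx < len(runs):
        if runs[idx][0] <= used_until:
            idx += 1
            continue
        chain = [runs[idx]]
        nxt = idx + 1
        while nxt < len(runs):
            gap = runs[nxt][0] - (chain[-1][0] + chain[-1][1])
            if 1 <= gap <= max_loop:
                chain.append(runs[nxt])
                nxt += 1
            else:
                break
        if len(chain) >= min_tracts:
            start = chain[0][0]
            end = chain[-1][0] + chain[-1][1]
            loops = tuple(
                chain[k + 1][0] - (chain[k][0] + chain[k][1])
                for k in range(len(chain) - 1)
            )
            motifs.append((start, end, tuple(n for _, n in chain), loops))
            used_until = end - 1
        idx = nxt
    return motifs


def ks_two_sample_enumerated(x, y):
    """Two-sample KS: D plus exact two-sided p by full enumeration.

    Enumerates all C(n+m, n) assignments of the pooled (distinct) values
    to the two samples; p is the fraction of assignments with D at least
    as large as observed.  Feasible for n, m <= ~8.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires distinct values"

    def ks_d(a, b):
        grid = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    d_obs = ks_d(x, y)
    n = len(x)
    total = 0
    hits = 0
    idx_all = set(range(len(pooled)))
    for combo in combinations(range(len(pooled)), n):
        a = pooled[list(combo)]
        b = pooled[sorted(idx_all - set(combo))]
        total += 1
        if ks_d(a, b) >= d_obs - 1e-12:
            hits += 1
    return float(d_obs), hits / total


def halflife_normal_equations(t, y):
    """Closed-form least squares of ln(y) on t via the normal equations."""
    t = np.asarray(t, dtype=float)
    ly = np.log(np.asarray(y, dtype=float))
    n = len(t)
    sxx = n * np.sum(t * t) - np.sum(t) ** 2
    slope = (n * np.sum(t * ly) - np.sum(t) * np.sum(ly)) / sxx
    k = -slope
    return k, (np.log(2) / k if k > 0 else float("nan"))


def random_read_instance(rng, n_reads_max=200, tx_length=500, n_transcripts=2):
    """A random read set for cluster-caller cross-checks.

    Returns (reads tuples, AlignedRead-compatible dicts not included).
    """
    n = int(rng.integers(0, n_reads_max + 1))
    reads = []
    for _ in range(n):
        tx = f"tx{rng.integers(n_transcripts)}"
        start = int(rng.integers(0, tx_length - 30))
        length = int(rng.integers(15, 31))
        n_conv = int(rng.integers(0, 3))
        reads.append((tx, start, start + length, n_conv))
    return reads
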