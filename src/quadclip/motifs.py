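"""Sequence-motif analysis of binding sites.

k-mer Z-score enrichment against a composition-preserving shuffled
background, k-mer class labels (G-rich / AU-rich), an RNA G-quadruplex
(rG4) motif scanner, and overlap statistics between rG4 motifs and
PAR-CLIP clusters.

U and T are treated as equivalent throughout (sequences are normalized
to the DNA alphabet internally).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _encode(sequence: str, context: str = "sequence") -> np.ndarray:
    """Normalize to uppercase DNA and encode as 0..3 integer codes."""
    seq = sequence.upper().replace("U", "T")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(codes.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        out[codes == ord(base)] = code
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"invalid character {bad!r} in {context}")
    return out


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=k)]


def count_kmers(sequences: Iterable[str], k: int = 5) -> pd.Series:
    """Count overlapping k-mer occurrences summed across sequences.

    Returns the complete 4^k table (absent k-mers get count 0), indexed
    by k-mer in lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    for i, seq in enumerate(sequences):
        codes = _encode(seq, context=f"sequence #{i}")
        n = codes.size - k + 1
        if n <= 0:
            continue
        vals = np.zeros(n, dtype=np.int64)
        for j in range(k):
            vals = vals * 4 + codes[j : j + n]
        counts += np.bincount(vals, minlength=4**k)
    return pd.Series(counts, index=all_kmers(k), name="count")


def scramble_preserving_composition(sequence: str, rng: np.random.Generator) -> str:
    """Uniformly random permutation of the sequence's characters.

    Preserves the full nucleotide composition (hence GC content) while
    destroying all positional structure.
    """
    if len(sequence) == 0:
        raise ValueError("cannot scramble an empty sequence")
    chars = np.array(list(sequence))
    return "".join(rng.permutation(chars))


def classify_kmer(kmer: str) -> str:
    """Label a 5-mer: 'G-rich' (>=3 G), else 'AU-rich' (>=4 of A/U), else 'other'."""
    seq = kmer.upper().replace("U", "T")
    if len(seq) != 5 or any(c not in _BASE_CODE for c in seq):
        raise ValueError(f"expected a 5-mer over A/C/G/T/U, got {kmer!r}")
    if seq.count("G") >= 3:
        return "G-rich"
    if seq.count("A") + seq.count("T") >= 4:
        return "AU-rich"
    return "other"


def kmer_zscores(
    target_sequences: Sequence[str],
    k: int = 5,
    n_background: int = 50,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """k-mer enrichment Z-scores against a shuffled-composition background.

    For the target set, each k-mer's proportion X = count / total counts.
    The background is ``n_background`` independent draws, each scrambling
    every target sequence (full composition-preserving permutation) and
    recomputing the proportion vector; mu and sigma are the mean and
    (sample) standard deviation of the background proportions, and
    Z = (X - mu) / sigma.

    Degenerate cases: sigma = 0 with X = mu gives Z = 0; sigma = 0 with
    X != mu gives a signed infinite Z.  Both are marked in the
    ``degenerate`` column and should be excluded from rankings.

    Returns a DataFrame indexed by k-mer with columns ``count``, ``X``,
    ``mu``, ``sigma``, ``Z``, ``label`` (5-mers only), ``degenerate``.
    """
    rng = np.random.default_rng(rng)
    if n_background < 2:
        raise ValueError("n_background must be >= 2")
    target_counts = count_kmers(target_sequences, k)
    total = int(target_counts.sum())
    if total == 0:
        raise ValueError("no k-mers in target set (all sequences shorter than k?)")
    X = target_counts.to_numpy(dtype=float) / total

    props = np.empty((n_background, 4**k))
    for d in range(n_background):
        shuffled = [
            scramble_preserving_composition(s, rng) for s in target_sequences
        ]
        c = count_kmers(shuffled, k).to_numpy(dtype=float)
        props[d] = c / c.sum()
    mu = props.mean(axis=0)
    sigma = props.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / sigma
        degenerate = sigma == 0
        Z[degenerate & (X == mu)] = 0.0
        Z[degenerate & (X != mu)] = np.sign(X - mu)[degenerate & (X != mu)] * np.inf

    out = pd.DataFrame(
        {
            "count": target_counts.to_numpy(),
            "X": X,
            "mu": mu,
            "sigma": sigma,
            "Z": Z,
            "degenerate": degenerate,
        },
        index=pd.Index(all_kmers(k), name="kmer"),
    )
    out["label"] = [classify_kmer(km) for km in out.index] if k == 5 else ""
    return out


@dataclass(frozen=True)
class G4Motif:
    """A putative (r)G4 motif: >=4 G-tracts separated by short loops."""

    transcript_id: str
    start: int
    end: int
    tract_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]

    @property
    def n_tracts(self) -> int:
        return len(self.tract_lengths)


def _g_runs(codes: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of G as (start, length)."""
    is_g = codes == _BASE_CODE["G"]
    runs = []
    i = 0
    n = codes.size
    while i < n:
        if is_g[i]:
            j = i
            while j < n and is_g[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def scan_g4(
    sequence: str,
    min_tract: int = 3,
    max_loop: int = 7,
    min_tracts: int = 4,
    transcript_id: str = "",
) -> list[G4Motif]:
    """Scan for quadruplex-competent G-tract arrangements.

    A motif is at least ``min_tracts`` maximal G-runs of length
    >= ``min_tract`` in which consecutive tracts are separated by loops
    of 1..``max_loop`` nt.  The scan is leftmost-greedy with maximal
    extension: starting from the leftmost unused qualifying tract, further
    qualifying tracts are absorbed while the gap condition holds, and the
    chain is emitted if long enough.  Reported motifs are non-overlapping.

    Default criteria (tracts of >=3 G, loops up to 7 nt, 4 tracts) are the
    canonical rG4 pattern; rG4s with fewer guanines or longer loops can be
    captured by relaxing the parameters.
    """
    if min_tract < 1 or min_tracts < 2 or max_loop < 1:
        raise ValueError("min_tract >= 1, min_tracts >= 2, max_loop >= 1 required")
    codes = _encode(sequence, context=transcript_id or "sequence")
    tracts = [(s, l) for s, l in _g_runs(codes) if l >= min_tract]
    motifs: list[G4Motif] = []
    i = 0
    while i < len(tracts):
        chain = [tracts[i]]
        j = i
        while j + 1 < len(tracts):
            prev_end = tracts[j][0] + tracts[j][1]
            gap = tracts[j + 1][0] - prev_end
            if 1 <= gap <= max_loop:
                chain.append(tracts[j + 1])
                j += 1
            else:
                break
        if len(chain) >= min_tracts:
            start = chain[0][0]
            end = chain[-1][0] + chain[-1][1]
            loops = tuple(
                chain[m + 1][0] - (chain[m][0] + chain[m][1])
                for m in range(len(chain) - 1)
            )
            motifs.append(
                G4Motif(
                    transcript_id=transcript_id,
                    start=start,
                    end=end,
                    tract_lengths=tuple(l for _, l in chain),
                    loop_lengths=loops,
                )
            )
        i = j + 1
    return motifs


def scan_g4_sequences(
    sequences: Mapping[str, str],
    min_tract: int = 3,
    max_loop: int = 7,
    min_tracts: int = 4,
) -> list[G4Motif]:
    """Run :func:`scan_g4` over a {transcript_id: sequence} mapping."""
    motifs = []
    for tx_id in sorted(sequences):
        motifs.extend(
            scan_g4(sequences[tx_id], min_tract, max_loop, min_tracts, transcript_id=tx_id)
        )
    return motifs


def _as_interval(obj) -> tuple[str, int, int]:
    if hasattr(obj, "transcript_id") and hasattr(obj, "start"):
        return (obj.transcript_id, obj.start, obj.end)
    tx, start, end = obj[0], obj[1], obj[2]
    return (tx, int(start), int(end))


def overlap_with_sites(
    g4_sites: Sequence,
    clusters: Sequence,
    by_region: bool = False,
    regions: Sequence[str] | None = None,
) -> float | tuple[float, dict[str, float]]:
    """Fraction of rG4 sites recovered by binding clusters.

    A site counts as recovered when it overlaps any cluster on the same
    transcript by at least 1 nt.  Sites and clusters may be
    :class:`G4Motif` / :class:`~quadclip.clipcore.Cluster` objects or
    ``(transcript_id, start, end)`` tuples.

    With ``by_region=True``, ``regions`` must supply one region label per
    site; the return value is then ``(overall, {region: fraction})``.
    """
    if len(g4_sites) == 0:
        raise ValueError("no rG4 sites given")
    if by_region:
        if regions is None or len(regions) != len(g4_sites):
            raise ValueError("by_region requires one region label per site")
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        tx, s, e = _as_interval(c)
        by_tx.setdefault(tx, []).append((s, e))

    hits = np.zeros(len(g4_sites), dtype=bool)
    for i, site in enumerate(g4_sites):
        tx, s, e = _as_interval(site)
        hits[i] = any(s < ce and cs < e for cs, ce in by_tx.get(tx, ()))
    overall = float(hits.mean())
    if not by_region:
        return overall
    per_region: dict[str, float] = {}
    regions = np.asarray(regions)
    for region in sorted(set(regions)):
        mask = regions == region
        per_region[region] = float(hits[mask].mean())
    return overall, per_region
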