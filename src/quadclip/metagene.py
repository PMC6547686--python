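"""Metagene profiles of cluster density around start/stop codons.

Observed positional density of binding clusters in a fixed window
downstream of the start or stop codon, with an empirical null built by
repositioning every cluster uniformly at random within its own
transcript (length preserved).  The null randomizes only position while
keeping each transcript's cluster load and the cluster length
distribution, which is the minimal null for positional enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clipcore import Cluster, TranscriptModel

ANCHORS = ("start_codon", "stop_codon")


@dataclass
class MetageneProfile:
    anchor: str
    window_length: int
    bin_width: int
    observed: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_randomizations: int = 0
    normalized: bool = True  # False when no cluster touched the window

    @property
    def n_bins(self) -> int:
        return self.window_length // self.bin_width

    def enrichment(self) -> np.ndarray:
        """(observed - null_mean) / null_sd per bin (NaN where sd = 0)."""
        if self.null_mean is None or self.null_sd is None:
            raise ValueError("profile has no null")
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.observed - self.null_mean) / self.null_sd


def _anchor_position(model: TranscriptModel, anchor: str) -> int:
    if anchor == "start_codon":
        return model.cds_start
    if anchor == "stop_codon":
        return model.cds_end
    raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")


def _check_bins(window_length: int, bin_width: int) -> int:
    if window_length % bin_width != 0:
        raise ValueError(
            f"bin_width {bin_width} does not divide window_length {window_length}"
        )
    return window_length // bin_width


def _availability(
    transcripts: Mapping[str, TranscriptModel], anchor: str, window_length: int
) -> np.ndarray:
    """Number of transcripts whose sequence extends over each window position.

    Transcripts shorter than the window contribute up to their end
    (truncated, not dropped); dividing per-position coverage by this count
    keeps distal bins comparable despite 3'-short transcripts.
    """
    avail = np.zeros(window_length)
    for model in transcripts.values():
        a = _anchor_position(model, anchor)
        span = min(window_length, model.length - a)
        if span > 0:
            avail[:span] += 1
    return avail


def _coverage_to_density(
    cov: np.ndarray, avail: np.ndarray, n_bins: int, bin_width: int
) -> tuple[np.ndarray, bool]:
    with np.errstate(divide="ignore", invalid="ignore"):
        per_nt = np.where(avail > 0, cov / avail, 0.0)
    binned = per_nt.reshape(n_bins, bin_width).sum(axis=1)
    total = binned.sum()
    if total == 0:
        return binned, False
    return binned / total, True


def metagene_profile(
    clusters: Sequence[Cluster],
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "start_codon",
    window_length: int = 200,
    bin_width: int = 10,
) -> MetageneProfile:
    """Observed per-bin cluster density in a window downstream of the anchor.

    Per-nt cluster coverage is summed over transcripts, divided by the
    number of transcripts reaching each position, binned, and normalized
    to sum to 1.  If no cluster touches any window the all-zero profile is
    returned with ``normalized=False``.
    """
    n_bins = _check_bins(window_length, bin_width)
    avail = _availability(transcripts, anchor, window_length)
    cov = np.zeros(window_length)
    for c in clusters:
        model = transcripts[c.transcript_id]
        a = _anchor_position(model, anchor)
        lo = max(c.start - a, 0)
        hi = min(c.end - a, window_length)
        if hi > lo:
            cov[lo:hi] += 1
    density, has_signal = _coverage_to_density(cov, avail, n_bins, bin_width)
    return MetageneProfile(
        anchor=anchor,
        window_length=window_length,
        bin_width=bin_width,
        observed=density,
        normalized=has_signal,
    )


def metagene_null(
    clusters: Sequence[Cluster],
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "start_codon",
    window_length: int = 200,
    bin_width: int = 10,
    n: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomized-placement null for the metagene profile.

    Each of the ``n`` iterations repositions every cluster uniformly at
    random within its own transcript (any in-bounds start, length
    preserved) and recomputes the normalized profile.

    Returns ``(null_mean, null_sd, draws)`` where ``draws`` has shape
    (n, n_bins).
    """
    if n < 2:
        raise ValueError("need n >= 2 randomizations")
    rng = np.random.default_rng(rng)
    n_bins = _check_bins(window_length, bin_width)
    avail = _availability(transcripts, anchor, window_length)

    # per cluster: transcript anchor, max start, and n random starts
    cov = np.zeros((n, window_length))
    for c in clusters:
        model = transcripts[c.transcript_id]
        clen = c.end - c.start
        if clen > model.length:
            raise ValueError(
                f"cluster of length {clen} exceeds transcript "
                f"{c.transcript_id} (length {model.length})"
            )
        a = _anchor_position(model, anchor)
        starts = rng.integers(0, model.length - clen + 1, size=n)
        los = np.maximum(starts - a, 0)
        his = np.minimum(starts + clen - a, window_length)
        for it in range(n):
            if his[it] > los[it]:
                cov[it, los[it] : his[it]] += 1

    draws = np.zeros((n, n_bins))
    for it in range(n):
        draws[it], _ = _coverage_to_density(cov[it], avail, n_bins, bin_width)
    return draws.mean(axis=0), draws.std(axis=0, ddof=1), draws


def metagene(
    clusters: Sequence[Cluster],
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "start_codon",
    window_length: int = 200,
    bin_width: int = 10,
    n_randomizations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> MetageneProfile:
    """Observed metagene profile together with its randomized null."""
    profile = metagene_profile(clusters, transcripts, anchor, window_length, bin_width)
    null_mean, null_sd, _ = metagene_null(
        clusters, transcripts, anchor, window_length, bin_width, n_randomizations, rng
    )
    profile.null_mean = null_mean
    profile.null_sd = null_sd
    profile.n_randomizations = n_randomizations
    return profile
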