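"""Core PAR-CLIP objects and operations.

Transcript-space analysis of PAR-CLIP libraries: transcript models with
5'UTR/CDS/3'UTR segmentation, aligned reads carrying T-to-C conversion
marks, conversion-supported binding clusters, and per-gene occupancy
scores (NXPM, normalized crosslinked reads per million).

All coordinates are 0-based half-open in transcript space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("utr5", "cds", "utr3")

#: tie-break preference when a cluster overlaps two regions equally:
#: UTRs win over CDS, 5'UTR first.
_REGION_PRIORITY = {"utr5": 0, "utr3": 1, "cds": 2}


class CoordinateError(ValueError):
    """An interval falls outside its transcript."""


@dataclass(frozen=True)
class TranscriptModel:
    """A single (principal) transcript of a gene.

    The transcript is partitioned into 5'UTR ``[0, cds_start)``, CDS
    ``[cds_start, cds_end)`` and 3'UTR ``[cds_end, length)``.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: require 0 <= cds_start <= cds_end <= length, "
                f"got {self.cds_start}, {self.cds_end}, {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != {self.length}"
            )

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, self.length)

    def region_bounds(self, region: str) -> tuple[int, int]:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}[region]


@dataclass(frozen=True)
class AlignedRead:
    """A read aligned to transcript space.

    ``conversion_offsets`` are read-relative positions (0-based, within
    ``[0, end - start)``) that carry a T-to-C conversion, the diagnostic
    signature of a 4SU crosslink.
    """

    transcript_id: str
    start: int
    end: int
    conversion_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")
        for off in self.conversion_offsets:
            if not 0 <= off < self.end - self.start:
                raise ValueError(
                    f"conversion offset {off} outside read of length {self.end - self.start}"
                )

    @property
    def is_crosslinked(self) -> bool:
        return len(self.conversion_offsets) > 0


@dataclass
class Cluster:
    """A merged interval of overlapping reads with conversion support."""

    transcript_id: str
    gene_id: str
    start: int
    end: int
    n_reads: int
    n_crosslinked_reads: int
    category: str | None = None
    spans_boundary: bool = False

    @property
    def conversion_fraction(self) -> float:
        return self.n_crosslinked_reads / self.n_reads if self.n_reads else 0.0


def assign_annotation(
    start: int, end: int, model: TranscriptModel
) -> tuple[str, bool]:
    """Assign a cluster interval to the transcript region it mostly overlaps.

    Returns ``(category, spans_boundary)``.  The category is the region
    with maximal overlap; ties are broken UTR over CDS (5'UTR first).
    ``spans_boundary`` is True when the interval has recorded overlap in
    more than one region.

    Raises
    ------
    CoordinateError
        If the interval is not contained in ``[0, length)``.
    """
    if not (0 <= start < end <= model.length):
        raise CoordinateError(
            f"cluster [{start}, {end}) outside transcript "
            f"{model.transcript_id} of length {model.length}"
        )
    overlaps = {}
    for region in REGIONS:
        r0, r1 = model.region_bounds(region)
        overlaps[region] = max(0, min(end, r1) - max(start, r0))
    best = max(REGIONS, key=lambda r: (overlaps[r], -_REGION_PRIORITY[r]))
    spanning = sum(1 for v in overlaps.values() if v > 0) > 1
    return best, spanning


def call_clusters(
    reads: Iterable[AlignedRead],
    transcripts: Mapping[str, TranscriptModel],
    min_reads: int = 5,
    min_crosslinked: int = 2,
    min_conversion_fraction: float = 0.2,
) -> list[Cluster]:
    """Merge transitively overlapping reads into conversion-supported clusters.

    Reads on each transcript are merged into maximal sets of transitively
    overlapping intervals (the cluster interval is the union of read
    extents).  A cluster is kept iff it has at least ``min_reads`` reads,
    at least ``min_crosslinked`` reads carrying >=1 T-to-C conversion, and
    a crosslinked-read fraction of at least ``min_conversion_fraction``.

    This is a deliberately transparent merge-based caller; it implements
    the conversion-supported-cluster concept, not a kernel-density model.

    Output clusters are disjoint per transcript, sorted by (transcript,
    start), and annotated to the region of maximal overlap.
    """
    by_tx: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.transcript_id not in transcripts:
            raise ValueError(f"read references unknown transcript {read.transcript_id!r}")
        by_tx.setdefault(read.transcript_id, []).append(read)

    clusters: list[Cluster] = []
    for tx_id in sorted(by_tx):
        model = transcripts[tx_id]
        txreads = sorted(by_tx[tx_id], key=lambda r: (r.start, r.end))
        i = 0
        while i < len(txreads):
            j = i + 1
            cur_end = txreads[i].end
            while j < len(txreads) and txreads[j].start < cur_end:
                cur_end = max(cur_end, txreads[j].end)
                j += 1
            members = txreads[i:j]
            n_reads = len(members)
            n_xl = sum(1 for r in members if r.is_crosslinked)
            frac = n_xl / n_reads
            if (
                n_reads >= min_reads
                and n_xl >= min_crosslinked
                and frac >= min_conversion_fraction
            ):
                start = members[0].start
                category, spanning = assign_annotation(start, cur_end, model)
                clusters.append(
                    Cluster(
                        transcript_id=tx_id,
                        gene_id=model.gene_id,
                        start=start,
                        end=cur_end,
                        n_reads=n_reads,
                        n_crosslinked_reads=n_xl,
                        category=category,
                        spans_boundary=spanning,
                    )
                )
            i = j
    return clusters


def counts_to_tpm(
    counts: pd.DataFrame | pd.Series, lengths: pd.Series
) -> pd.Series:
    """Convert raw counts to TPM (transcripts per million).

    ``counts`` is genes x samples (or a single-sample Series); ``lengths``
    gives transcript length in nt per gene.  For a DataFrame, per-sample
    TPMs are averaged.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_frame()
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing transcript lengths for genes: {missing}")
    rate = counts.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return tpm.mean(axis=1)


def compute_nxpm(
    clusters: Sequence[Cluster],
    tpm: pd.Series | Mapping[str, float],
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene occupancy: normalized crosslinked reads per million (NXPM).

    XPM(g) = 1e6 * crosslinked reads on g / total crosslinked reads in the
    library; NXPM(g) = XPM(g) / TPM(g).  Per-region NXPM uses the
    crosslinked reads of clusters assigned to that region, with the same
    library total.  Genes below ``min_tpm`` are retained but flagged
    (``low_tpm``) with NXPM set to NaN.

    Returns a DataFrame indexed by gene_id with columns ``n_clusters``,
    ``crosslinked_reads``, ``xpm``, ``tpm``, ``nxpm``, ``nxpm_utr5``,
    ``nxpm_cds``, ``nxpm_utr3``, ``low_tpm``.
    """
    if not isinstance(tpm, pd.Series):
        tpm = pd.Series(dict(tpm), dtype=float)
    total_xl = sum(c.n_crosslinked_reads for c in clusters)
    if total_xl == 0:
        raise ValueError("no crosslinked reads in the library; NXPM undefined")

    rows: dict[str, dict[str, float]] = {}
    for c in clusters:
        row = rows.setdefault(
            c.gene_id,
            {"n_clusters": 0, "crosslinked_reads": 0}
            | {f"xl_{r}": 0 for r in REGIONS},
        )
        row["n_clusters"] += 1
        row["crosslinked_reads"] += c.n_crosslinked_reads
        if c.category is not None:
            row[f"xl_{c.category}"] += c.n_crosslinked_reads

    genes = sorted(rows)
    missing = [g for g in genes if g not in tpm.index]
    if missing:
        raise ValueError(f"abundance (TPM) missing for scored genes: {missing[:5]}")

    df = pd.DataFrame.from_dict(rows, orient="index").loc[genes]
    df.index.name = "gene_id"
    df["xpm"] = 1e6 * df["crosslinked_reads"] / total_xl
    df["tpm"] = tpm.reindex(df.index)
    df["low_tpm"] = df["tpm"] < min_tpm
    with np.errstate(divide="ignore", invalid="ignore"):
        df["nxpm"] = df["xpm"] / df["tpm"]
        for region in REGIONS:
            df[f"nxpm_{region}"] = (1e6 * df[f"xl_{region}"] / total_xl) / df["tpm"]
    df.loc[df["low_tpm"], ["nxpm"] + [f"nxpm_{r}" for r in REGIONS]] = np.nan
    return df[
        ["n_clusters", "crosslinked_reads", "xpm", "tpm", "nxpm"]
        + [f"nxpm_{r}" for r in REGIONS]
        + ["low_tpm"]
    ]


def replicate_r2(
    nxpm_rep1: pd.Series,
    nxpm_rep2: pd.Series,
    eps: float = 1e-3,
) -> float:
    """Replicate reproducibility: squared Pearson r of log10(NXPM + eps).

    Computed over genes present (and non-NaN) in both replicates; at
    least 3 shared genes are required.
    """
    shared = nxpm_rep1.dropna().index.intersection(nxpm_rep2.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared between replicates (need >=3)")
    x = np.log10(nxpm_rep1.loc[shared].to_numpy(dtype=float) + eps)
    y = np.log10(nxpm_rep2.loc[shared].to_numpy(dtype=float) + eps)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
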