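"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA for transcript sequences (via Biopython); TSV dialects for the
transcript annotation, transcript-space reads with conversion offsets,
clusters, occupancy profiles, ground truth and count matrices; BED6 for
clusters and G4 motifs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clipcore import AlignedRead, Cluster, TranscriptModel
from .motifs import G4Motif


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation(transcripts: Mapping[str, TranscriptModel], path) -> None:
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "len_5utr": m.cds_start,
            "len_cds": m.cds_end - m.cds_start,
            "len_3utr": m.length - m.cds_end,
        }
        for m in transcripts.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path, sequences: Mapping[str, str] | None = None) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        length = int(row.len_5utr + row.len_cds + row.len_3utr)
        seq = sequences.get(row.transcript_id) if sequences else None
        out[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            length=length,
            cds_start=int(row.len_5utr),
            cds_end=int(row.len_5utr + row.len_cds),
            sequence=seq,
        )
    return out


def write_reads(reads: Iterable[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\tconversion_offsets\n")
        for r in reads:
            offs = ",".join(str(o) for o in r.conversion_offsets)
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{offs}\n")


def read_reads(path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["transcript_id", "start", "end"]:
            raise ValueError(f"unexpected reads TSV header in {path}")
        for line in fh:
            tx, start, end, offs = (line.rstrip("\n").split("\t") + [""])[:4]
            conversion_offsets = (
                tuple(int(o) for o in offs.split(",")) if offs else ()
            )
            reads.append(
                AlignedRead(
                    transcript_id=tx,
                    start=int(start),
                    end=int(end),
                    conversion_offsets=conversion_offsets,
                )
            )
    return reads


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "gene_id": c.gene_id,
                "start": c.start,
                "end": c.end,
                "n_reads": c.n_reads,
                "n_crosslinked_reads": c.n_crosslinked_reads,
                "conversion_fraction": c.conversion_fraction,
                "category": c.category,
                "spans_boundary": c.spans_boundary,
            }
            for c in clusters
        ]
    )


def write_clusters(clusters: Sequence[Cluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list[Cluster]:
    df = pd.read_csv(path, sep="\t")
    return [
        Cluster(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            start=int(row.start),
            end=int(row.end),
            n_reads=int(row.n_reads),
            n_crosslinked_reads=int(row.n_crosslinked_reads),
            category=row.category if isinstance(row.category, str) else None,
            spans_boundary=bool(row.spans_boundary),
        )
        for row in df.itertuples(index=False)
    ]


def write_clusters_bed(clusters: Sequence[Cluster], path) -> None:
    """Clusters as BED6: name = gene_id:category, score = crosslinked reads."""
    with open(path, "w") as fh:
        for c in clusters:
            name = f"{c.gene_id}:{c.category or 'NA'}"
            fh.write(
                f"{c.transcript_id}\t{c.start}\t{c.end}\t{name}\t{c.n_crosslinked_reads}\t+\n"
            )


def write_g4_bed(motifs: Sequence[G4Motif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(
                f"{m.transcript_id}\t{m.start}\t{m.end}\tG4:{m.n_tracts}tracts\t{m.n_tracts}\t+\n"
            )


def g4_to_frame(motifs: Sequence[G4Motif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": m.transcript_id,
                "start": m.start,
                "end": m.end,
                "n_tracts": m.n_tracts,
                "tract_lengths": ",".join(map(str, m.tract_lengths)),
                "loop_lengths": ",".join(map(str, m.loop_lengths)),
            }
            for m in motifs
        ]
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)


def write_metagene_profile(profile, path) -> None:
    """Profile TSV: bin_start, bin_end, observed, null_mean, null_sd."""
    rows = []
    for j in range(profile.n_bins):
        rows.append(
            {
                "bin_start": j * profile.bin_width,
                "bin_end": (j + 1) * profile.bin_width,
                "observed": profile.observed[j],
                "null_mean": profile.null_mean[j] if profile.null_mean is not None else "",
                "null_sd": profile.null_sd[j] if profile.null_sd is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
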