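import numpy as np
import pandas as pd
import pytest

import quadclip as qc


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study for unit-level checks."""
    config = qc.SimConfig(
        n_genes=80,
        parclip_depth=30_000,
        rna_depth=300_000,
        rpf_depth=300_000,
        seed=11,
    )
    transcripts, truth = qc.simulate_transcriptome(config)
    reads = qc.simulate_parclip_reads(transcripts, truth, config)
    table = qc.simulate_counts(transcripts, truth, config)
    clusters = qc.call_clusters(reads, transcripts)
    return {
        "config": config,
        "transcripts": transcripts,
        "truth": truth,
        "reads": reads,
        "table": table,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def endtoend():
    """The full seeded study: 500 genes, 30% targets, beta_mrna=0.3,
    beta_rpf=0, NB dispersion 0.05, 3+3 replicates, occupancy scaled to 1."""
    config = qc.SimConfig(
        n_genes=500,
        target_fraction=0.3,
        beta_mrna=0.3,
        beta_rpf=0.0,
        nb_dispersion=0.05,
        n_replicates=3,
        occupancy_scale=0.0,
        seed=101,
    )
    transcripts, truth = qc.simulate_transcriptome(config)
    reads = qc.simulate_parclip_reads(transcripts, truth, config)
    table = qc.simulate_counts(transcripts, truth, config)
    clusters = qc.call_clusters(reads, transcripts)
    lengths = pd.Series({m.gene_id: m.length for m in transcripts.values()})
    tpm = qc.counts_to_tpm(table.subset("rna", "wt"), lengths)
    profiles = qc.compute_nxpm(clusters, tpm)
    # anchor normalization on genes without called clusters (non-targets)
    controls = [g for g in table.counts.index if g not in profiles.index]
    summary = qc.differential_summary(table, control_genes=controls)
    return {
        "config": config,
        "transcripts": transcripts,
        "truth": truth,
        "reads": reads,
        "table": table,
        "clusters": clusters,
        "profiles": profiles,
        "summary": summary,
    }


@pytest.fixture()
def three_region_model():
    return qc.TranscriptModel(
        transcript_id="tx1", gene_id="gene1", length=600, cds_start=100, cds_end=400
    )
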