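# quadclip

Downstream analysis of PAR-CLIP experiments for G-quadruplex-resolving RNA
helicases, in transcript space, together with the integration of RNA-seq and
Ribo-seq count data from knockout-vs-parental designs.

PAR-CLIP (photoactivatable-ribonucleoside-enhanced crosslinking and
immunoprecipitation) maps protein–RNA contacts: 4-thiouridine incorporated
into nascent RNA crosslinks to the bound protein under UV light, and
crosslinked positions read out as T-to-C conversions in the sequenced cDNA.
`quadclip` is for analysts working with helicases such as DHX36 that bind
G-rich elements: it answers where on mRNAs the protein sits, what sequence
element it prefers, and what losing the protein does to target mRNA
abundance, stability, and translation.

## What it computes

* **Conversion-supported clusters** — maximal sets of transitively
  overlapping reads merged into one interval, kept when they have enough
  reads, enough T-to-C-converted reads, and a high enough converted-read
  fraction; annotated to 5′UTR/CDS/3′UTR by maximal overlap.
* **NXPM occupancy** — normalized crosslinked reads per million:
  `XPM(g) = 10⁶ · xl(g) / Σ xl`, `NXPM(g) = XPM(g) / TPM(g)`, overall and
  per transcript region, plus replicate reproducibility as R² of
  log₁₀(NXPM + ε).
* **5-mer enrichment** — `Z = (X − μ)/σ`, where `X` is a 5-mer's proportion
  of all 5-mer counts in the binding-site sequences and `μ`, `σ` come from
  repeatedly scrambling every site sequence while preserving its
  composition; 5-mers are labeled G-rich (≥3 G) or A/U-rich (≥4 A/U).
* **rG4 motifs** — a leftmost-greedy scan for ≥4 G-tracts (≥3 G each,
  configurable) separated by 1–7 nt loops, and the fraction of rG4 sites
  recovered by binding clusters, per region.
* **Metagene profiles** — cluster density in windows downstream of the
  start codon (200 nt) and stop codon (500 nt) against an empirical null
  of 1000 random repositionings of every cluster within its transcript.
* **Occupancy-binned integration** — per-gene log₂ fold changes of mRNA
  and ribosome-protected fragments (RPF), translational efficiency
  TE = RPF/RNA and ΔTE = log₂(TE_KO/TE_WT), compared across NXPM bins
  against non-target genes by two-sided Kolmogorov–Smirnov tests on the
  empirical CDFs.
* **Decay fits and imaging** — first-order mRNA decay from
  transcription-block time courses (half-life = ln 2 / k from a log-linear
  least-squares fit) and corrected total cell fluorescence
  (CTCF = integrated density − area × mean background).
* **Synthetic data** — a generator producing transcriptomes with planted
  G4 sites, crosslink reads, and WT/KO count matrices with known ground
  truth, so every stage is testable at desk scale.

## Worked example

```python
import pandas as pd
import quadclip as qc

config = qc.SimConfig(n_genes=500, target_fraction=0.3, beta_mrna=0.3,
                      beta_rpf=0.0, occupancy_scale=0.0, seed=101)
transcripts, truth = qc.simulate_transcriptome(config)
reads = qc.simulate_parclip_reads(transcripts, truth, config)
table = qc.simulate_counts(transcripts, truth, config)

clusters = qc.call_clusters(reads, transcripts)          # 204 clusters
lengths = pd.Series({m.gene_id: m.length for m in transcripts.values()})
tpm = qc.counts_to_tpm(table.subset("rna", "wt"), lengths)
profiles = qc.compute_nxpm(clusters, tpm)

controls = [g for g in table.counts.index if g not in profiles.index]
summary = qc.differential_summary(table, control_genes=controls)
print(summary.loc[truth["is_target"], "lfc_rna"].median())   # 0.2955
print(summary.loc[truth["is_target"], "delta_te"].median())  # -0.3497
```

The generator planted a log₂ fold change of 0.3 on every bound mRNA in the
knockout with no change in ribosome footprints; the pipeline recovers a
median target mRNA log₂FC of 0.30 and, because footprints stay flat while
mRNA rises, a matching *drop* in translational efficiency (median ΔTE
−0.35). Binding-site 5-mer enrichment on the same run ranks exclusively
G-rich 5-mers at the top (`GGGGT`, `AGGGG`, `TGGGG`, … with Z ≈ 11–14), and
`scan_g4` recovers 100% of the planted rG4 sites.

A CLI mirrors the library (`quadclip simulate | clusters | nxpm |
kmer-enrich | g4scan | metagene | integrate | halflife`); every stochastic
subcommand takes an explicit `--seed`.

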