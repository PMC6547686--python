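# Methods

This note documents the models, defaults, and numerical choices behind
`quadclip`, and what the synthetic-data generator does and does not
emulate.

## Cluster calling

Binding sites are called as *conversion-supported clusters*: on each
transcript, reads are sorted by start and maximal sets of transitively
overlapping reads are merged; the cluster interval is the union of the
member read extents. A cluster is retained when it satisfies all of

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 5 | member reads |
| `min_crosslinked` | 2 | member reads with ≥1 T-to-C conversion |
| `min_conversion_fraction` | 0.2 | crosslinked fraction of member reads |

This is a deliberately transparent merge-based caller, not a kernel-density
segmentation: it keeps the defining property of PAR-CLIP binding sites —
overlapping reads with conversion support above what chance background
produces — while remaining exactly checkable against a quadratic
union-find oracle. Consequences of the simplification: adjacent true sites
closer than one read length merge into one cluster, and cluster boundaries
are read-extent boundaries rather than crosslink-density modes.

Clusters are annotated to the transcript region (5′UTR, CDS, 3′UTR) of
maximal overlap; exact ties go to the UTR (5′ before 3′), and a
`spans_boundary` flag records intervals with overlap in more than one
region. Single-label assignment makes the per-region read accounting a
deterministic partition.

## NXPM

Occupancy per gene is crosslinked reads normalized twice: to library depth
(`XPM = 10⁶ · xl(g)/Σ xl`) and to mRNA abundance (`NXPM = XPM/TPM`).
Abundance is TPM computed from the wild-type RNA-seq counts
(count/length, rescaled to 10⁶ per sample, averaged over replicates).
Genes with TPM below `min_tpm` (default 1) are flagged `low_tpm` with NXPM
set to NaN rather than dropped; their ratio denominators are too noisy to
rank. NXPM is a *relative* score: it is invariant under uniform scaling of
the read library, but its absolute magnitude depends on the abundance
unit, so NXPM thresholds are not portable across datasets. Replicate
agreement is reported as squared Pearson correlation of log₁₀(NXPM + ε),
ε = 10⁻³.

## 5-mer Z-scores

For the set of binding-site sequences, each 5-mer's proportion
`X = count/total` is compared against `n_background` (default 50)
independent draws in which *every* site sequence is replaced by a uniform
random permutation of its own characters. Permutation preserves the full
nucleotide composition of each sequence — a strictly stronger guarantee
than preserving GC content alone, and unambiguous. `μ` and `σ` are the
mean and sample standard deviation of the background proportion vectors
and `Z = (X − μ)/σ`.

Degenerate 5-mers (σ = 0) are flagged: Z is set to 0 when X = μ (e.g.
homopolymer targets) and to signed infinity otherwise; flagged entries are
excluded from rankings. Because each background draw scrambles the whole
target set, σ shrinks roughly as 1/√(total k-mer mass): Z magnitudes grow
with the size of the target set and should be compared only within one
analysis, not across datasets of different size.

Class labels follow the field's convention: G-rich = at least 3 G among
the 5 positions; A/U-rich = at least 4 of A/U (our choice; the threshold
is exposed), with G-rich taking precedence. U and T are equivalent
throughout.

## rG4 scanning

The scanner reports arrangements of ≥`min_tracts` (default 4) maximal
G-runs of length ≥`min_tract` (default 3) whose consecutive tracts are
separated by loops of 1–`max_loop` nt (default 7) — the canonical rG4
pattern. The scan is leftmost-greedy with maximal extension: the chain
absorbs every further qualifying tract while the loop condition holds, so
a five-tract region is one motif, not two overlapping four-tract calls,
and reported motifs are non-overlapping. rG4s with fewer guanines or
longer loops are reachable by relaxing the parameters. The scanner is
purely grammatical; it does not score thermodynamic stability.

rG4 recovery is the fraction of motif sites overlapping any cluster by
≥1 nt, overall and per region.

## Metagene profiles

Cluster coverage is accumulated per nucleotide over windows downstream of
the start codon (200 nt) or stop codon (500 nt), in 10-nt bins, and
normalized to sum to 1. Each position is first divided by the number of
transcripts whose sequence reaches it, so transcripts with short 3′UTRs
truncate their contribution without deflating distal bins.

The null repositions every cluster uniformly at random within its own
transcript (length preserved, any in-bounds start) and recomputes the
profile, 1000 times by default. This randomizes position only: it keeps
each transcript's cluster load and the cluster length distribution, which
is the minimal null for asking "is binding positionally biased?". An
across-transcript shuffle would also randomize the per-transcript load and
confound position with expression; we deliberately stay within
transcripts. Note one genuine property of this null rather than an
artifact: positions within one cluster length of a transcript end have
reduced coverage probability under uniform placement, so flatness holds
only for windows away from transcript ends — observed and null share the
effect, so enrichment calls are unaffected.

## Count integration

Normalization is DESeq-style median-of-ratios (per assay, both conditions
jointly) or CPM. When a substantial fraction of genes shifts in one
direction between conditions — precisely the situation a knockout of a
stabilizing/destabilizing factor creates — global size factors absorb part
of the shift and bias all fold changes toward zero. `normalize_counts`
therefore accepts `control_genes`; the pipeline passes the genes without
called clusters, anchoring the fold-change scale on presumed non-targets.

Fold changes are transparent normalized-mean log₂ ratios with a
pseudocount of 1 (the binned CDF comparisons consume per-gene fold
changes, not significance calls, so a dispersion-moderated test would add
machinery without changing the comparisons). TE = RPF/RNA abundance per
condition from replicate means; genes with mean abundance below 1 in any
required quantity are flagged and excluded from ΔTE, not silently dropped.
Genes are binned on NXPM (total, per region, or cluster count) over
right-open intervals; genes with no clusters form the non-target reference
bin. Each bin's fold-change distribution is compared to the reference with
a two-sided two-sample KS test (scipy; exact for small samples under its
auto mode, asymptotic otherwise, validated against full enumeration for
n,m ≤ 6). Per-panel p-values are reported without multiple-testing
correction across bins, matching how such binned CDF panels are
conventionally presented.

Half-lives come from ordinary least squares of ln(level) on time;
k = −slope, half-life = ln2/k for k > 0, and non-decaying series (k ≤ 0)
are flagged instead of reporting a negative half-life. Input is a
long-format table of relative levels (each gene normalized to its t = 0
value; rescaling changes only the intercept). CTCF is the standard imaging
statistic `integrated density − area × mean background`; negative values
are possible and flagged.

## Synthetic data

The generator produces the statistical structure the analysis assumes, at
desk scale, with every draw under one seeded generator per stage (child
seeds derived from `SimConfig.seed`, so stages are independently
reproducible and byte-identical across runs).

* **Transcriptome** — 500 genes by default, one transcript each, with
  5′UTR/CDS/3′UTR lengths uniform in 100–300/300–900/200–800 nt (CDS
  rounded to a codon multiple). Background sequence is uniform over
  A/C/G/T except that G-runs are capped below 3, so the planted motifs
  are provably the only canonical G4s. 30% of genes receive one site:
  four G-tracts of 3–4 nt with A/C/T loops of 1–7 nt, placed in the
  5′UTR/CDS/3′UTR with weights 0.2/0.3/0.5 (3′UTR-biased, as for
  DHX36-class binders), uniformly within the region (or at the region
  start, for positional-enrichment tests).
* **Occupancy and effects** — site strength is log-normal (median 1,
  σ = `occupancy_scale`, default 0.5, emulating a heavy-tailed NXPM
  distribution). The *scaled* occupancy — clipped at the 95th percentile
  and divided by it — multiplies the planted effects, keeping them
  bounded: mRNA log₂FC in the KO is `beta_mrna` × scaled occupancy
  (default 0.3), RPF log₂FC is `beta_rpf` (default 0), and the planted TE
  change is exactly their difference. Setting `occupancy_scale=0` makes
  every site equally strong (scaled occupancy 1), the configuration used
  for parameter-recovery checks where the planted effect must be a single
  known number.
* **PAR-CLIP reads** — 200,000 reads of 30 nt; 95% are site reads
  allocated across targets proportionally to occupancy × relative
  expression (more transcript copies crosslink more) and positioned to
  overlap the site by ≥10 nt; 5% are background reads spread over all
  transcripts proportionally to expression × length at uniform positions.
  Each reference-T in a read converts independently: 0.8 per T at sites,
  0.02 per T in background (sequencing-error scale). These defaults keep
  the library signal-dominated; much denser background percolates into
  long merged read chains that no conversion filter can reject, which is
  not how filtered PAR-CLIP libraries look.
* **Counts** — WT RNA means proportional to expression × length (2M reads
  per sample), RPF means proportional to expression × CDS length; KO means
  are WT × 2^(planted LFC). Counts are negative-binomial with
  Var = μ + 0.05 μ² (Poisson in the zero-dispersion limit), 3 replicates
  per assay/condition.

What the generator does **not** emulate: genome-space alignment and
splicing, multiple isoforms, sequencing errors and adapters, PCR
duplicates/UMIs, non-uniform crosslinking efficiency along a site,
multiple sites per gene, correlated replicate structure, or any
relationship between binding and basal expression. Passing tests
demonstrate that the analysis recovers planted structure under its own
model assumptions — they do not certify performance on real libraries,
where cluster boundaries, background structure, and normalization are all
harder.

## Problem sizes and expected recovery

The standard end-to-end check runs 500 genes / 30% targets /
`beta_mrna`=0.3 / dispersion 0.05 / 3+3 replicates, a size chosen so the
full pipeline runs in seconds while leaving the statistics well-powered.
At dispersion 0.05 a per-gene fold-change estimate has an sd of ≈0.26
log₂ units, so the median over ~150 targets carries an sd of ≈0.03; runs
with different seeds scatter accordingly around the planted 0.3.
Without control-gene normalization the same runs recover ≈0.21–0.26 — the
composition bias described above, worth remembering when a large target
fraction moves in one direction.
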