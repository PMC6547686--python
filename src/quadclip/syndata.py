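"""Synthetic data generator for PAR-CLIP downstream analysis.

Generates desk-scale data with the statistical structure the analysis
pipeline assumes:

* transcriptomes with contiguous 5'UTR/CDS/3'UTR segmentation in which a
  configurable fraction of genes carries one planted G-quadruplex-competent
  site (four G-tracts, short loops) while the background sequence contains
  no G-run of length >= 3, so planted motifs are the only canonical G4s;
* PAR-CLIP read sets in which site reads are drawn at a rate proportional
  to the planted occupancy (times transcript abundance) and carry T-to-C
  conversions at a high per-T rate, against a uniform low-conversion
  background;
* wild-type vs knockout RNA-seq and Ribo-seq count matrices in which bound
  mRNAs gain abundance (``beta_mrna``) without gaining ribosome-protected
  fragments (``beta_rpf``, default 0), so translational efficiency drops.

Every generator is fully deterministic given ``SimConfig.seed``; each of
the three stages derives its own child seed so stages can be rerun
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clipcore import AlignedRead, TranscriptModel
from .integrate import ExpressionTable

#: planted-motif grammar: tract lengths and loop lengths sampled uniformly
_TRACT_LEN = (3, 4)
_LOOP_LEN = (1, 7)
_N_TRACTS = 4
_MAX_MOTIF_LEN = _N_TRACTS * _TRACT_LEN[1] + (_N_TRACTS - 1) * _LOOP_LEN[1]

_NON_G = np.array(list("ACT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of a helicase PAR-CLIP study in
    a knockout-vs-parental design: ~30% of genes are bound, sites are
    G4-competent and biased to the 3'UTR, loss of the helicase stabilizes
    bound mRNAs (log2 FC ``beta_mrna`` per unit scaled occupancy) without
    a matching gain in ribosome footprints (``beta_rpf`` = 0).
    """

    n_genes: int = 500
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (200, 800)
    target_fraction: float = 0.3
    region_weights: dict[str, float] = field(
        default_factory=lambda: {"utr5": 0.2, "cds": 0.3, "utr3": 0.5}
    )
    site_position: str = "uniform"  # or "region_start"
    occupancy_scale: float = 0.5  # log-normal sigma; 0 => all sites equal
    expression_sigma: float = 1.0  # log-normal sigma of baseline abundance
    beta_mrna: float = 0.3  # planted log2 FC of target mRNA in KO per unit scaled occupancy
    beta_rpf: float = 0.0
    nb_dispersion: float = 0.05
    parclip_depth: int = 200_000
    background_read_fraction: float = 0.05
    read_length: int = 30
    rna_depth: int = 2_000_000
    rpf_depth: int = 2_000_000
    n_replicates: int = 3
    conv_prob_site: float = 0.8
    conv_prob_background: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SimConfigError("n_genes must be >= 0")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise SimConfigError("target_fraction must be in [0, 1]")
        for name in ("utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise SimConfigError(f"{name} must satisfy 0 < min <= max")
            if lo < _MAX_MOTIF_LEN + 2:
                raise SimConfigError(
                    f"{name} min {lo} too short for a planted motif "
                    f"(need >= {_MAX_MOTIF_LEN + 2})"
                )
        if set(self.region_weights) != {"utr5", "cds", "utr3"}:
            raise SimConfigError("region_weights needs keys utr5, cds, utr3")
        w = np.array([self.region_weights[r] for r in ("utr5", "cds", "utr3")])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise SimConfigError("region_weights must be non-negative and sum to 1")
        if self.site_position not in ("uniform", "region_start"):
            raise SimConfigError("site_position must be 'uniform' or 'region_start'")
        if self.occupancy_scale < 0 or self.expression_sigma < 0:
            raise SimConfigError("scale parameters must be >= 0")
        if not np.isfinite(self.beta_mrna) or not np.isfinite(self.beta_rpf):
            raise SimConfigError("beta values must be finite")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        for name in ("parclip_depth", "rna_depth", "rpf_depth", "n_replicates"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.background_read_fraction <= 1.0:
            raise SimConfigError("background_read_fraction must be in [0, 1]")
        if self.read_length < 15:
            raise SimConfigError("read_length must be >= 15")
        for name in ("conv_prob_site", "conv_prob_background"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimConfigError(f"{name} must be a probability")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["utr5_range"] = list(d["utr5_range"])
        d["cds_range"] = list(d["cds_range"])
        d["utr3_range"] = list(d["utr3_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for name in ("utr5_range", "cds_range", "utr3_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


def _background_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random sequence over A/C/G/T with every G-run shorter than 3."""
    chars = rng.choice(np.array(list("ACGT")), size=n)
    run = 0
    for i in range(n):
        if chars[i] == "G":
            run += 1
            if run >= 3:
                chars[i] = _NON_G[rng.integers(0, 3)]
                run = 0
        else:
            run = 0
    return chars


def _planted_motif(rng: np.random.Generator) -> str:
    """One G4 motif from the generator grammar: 4 tracts, A/C/T loops."""
    parts = []
    for t in range(_N_TRACTS):
        parts.append("G" * int(rng.integers(_TRACT_LEN[0], _TRACT_LEN[1] + 1)))
        if t < _N_TRACTS - 1:
            loop_len = int(rng.integers(_LOOP_LEN[0], _LOOP_LEN[1] + 1))
            parts.append("".join(rng.choice(_NON_G, size=loop_len)))
    return "".join(parts)


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, TranscriptModel], pd.DataFrame]:
    """Generate transcripts and the per-gene ground truth table.

    Returns ``(transcripts, truth)`` where ``truth`` is indexed by gene_id
    with columns ``transcript_id``, ``is_target``, ``region``,
    ``site_start``, ``site_end``, ``occupancy``, ``scaled_occupancy``,
    ``rel_expression``, ``lfc_mrna``, ``lfc_rpf``, ``lfc_te``.

    Planted log2 fold changes are ``beta * scaled_occupancy`` where the
    scaled occupancy is the log-normal occupancy clipped at its 95th
    percentile and divided by that percentile (bounded in (0, 1]); the
    planted TE change is exactly ``lfc_rpf - lfc_mrna``.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    n = config.n_genes
    transcripts: dict[str, TranscriptModel] = {}
    rows = []

    is_target = rng.random(n) < config.target_fraction
    occupancy = np.where(
        is_target, rng.lognormal(0.0, config.occupancy_scale, size=n), 0.0
    )
    rel_expr = rng.lognormal(0.0, config.expression_sigma, size=n)
    if is_target.any():
        p95 = np.percentile(occupancy[is_target], 95)
        scaled = np.where(is_target, np.minimum(occupancy, p95) / p95, 0.0)
    else:
        scaled = np.zeros(n)
    lfc_mrna = config.beta_mrna * scaled
    lfc_rpf = config.beta_rpf * scaled

    region_names = ("utr5", "cds", "utr3")
    region_p = np.array([config.region_weights[r] for r in region_names])

    for g in range(n):
        gene_id = f"g{g:05d}"
        tx_id = f"t{g:05d}"
        len5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        lenc = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        lenc -= lenc % 3
        len3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        length = len5 + lenc + len3
        chars = _background_sequence(rng, length)

        region = ""
        site_start = site_end = -1
        if is_target[g]:
            region = str(rng.choice(region_names, p=region_p))
            bounds = {
                "utr5": (0, len5),
                "cds": (len5, len5 + lenc),
                "utr3": (len5 + lenc, length),
            }[region]
            motif = _planted_motif(rng)
            if config.site_position == "region_start":
                site_start = bounds[0]
            else:
                site_start = int(rng.integers(bounds[0], bounds[1] - len(motif) + 1))
            site_end = site_start + len(motif)
            chars[site_start:site_end] = list(motif)

        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            length=length,
            cds_start=len5,
            cds_end=len5 + lenc,
            sequence="".join(chars),
        )
        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": tx_id,
                "is_target": bool(is_target[g]),
                "region": region,
                "site_start": site_start,
                "site_end": site_end,
                "occupancy": float(occupancy[g]),
                "scaled_occupancy": float(scaled[g]),
                "rel_expression": float(rel_expr[g]),
                "lfc_mrna": float(lfc_mrna[g]),
                "lfc_rpf": float(lfc_rpf[g]),
                "lfc_te": float(lfc_rpf[g] - lfc_mrna[g]),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "is_target", "region", "site_start",
            "site_end", "occupancy", "scaled_occupancy", "rel_expression",
            "lfc_mrna", "lfc_rpf", "lfc_te",
        ],
    ).set_index("gene_id")
    return transcripts, truth


def _draw_conversions(
    rng: np.random.Generator, is_t: np.ndarray, start: int, end: int, p: float
) -> tuple[int, ...]:
    offs = np.flatnonzero(is_t[start:end])
    if offs.size == 0 or p == 0.0:
        return ()
    keep = offs[rng.random(offs.size) < p]
    return tuple(int(o) for o in keep)


def simulate_parclip_reads(
    transcripts: dict[str, TranscriptModel],
    truth: pd.DataFrame,
    config: SimConfig,
    replicate: int = 0,
) -> list[AlignedRead]:
    """Generate transcript-space PAR-CLIP reads with T-to-C conversion marks.

    Site reads are allocated across target genes proportionally to
    occupancy x relative expression and placed so that they overlap the
    planted site; the remaining ``background_read_fraction`` of reads is
    spread across all transcripts proportionally to expression x length
    with uniform positions.  Each eligible reference-T position within a
    read converts independently (``conv_prob_site`` at sites,
    ``conv_prob_background`` elsewhere).

    Distinct ``replicate`` indices give independent but individually
    reproducible libraries.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 2, replicate))
    if config.parclip_depth == 0 or not transcripts:
        return []

    is_t = {
        tx: np.frombuffer(m.sequence.encode(), dtype=np.uint8) == ord("T")
        for tx, m in transcripts.items()
    }
    rl = config.read_length
    reads: list[AlignedRead] = []

    targets = truth[truth["is_target"]]
    n_site_total = int(round(config.parclip_depth * (1 - config.background_read_fraction)))
    if len(targets) == 0:
        n_site_total = 0
    n_bg_total = config.parclip_depth - n_site_total

    if n_site_total > 0:
        w = (targets["occupancy"] * targets["rel_expression"]).to_numpy()
        counts = rng.multinomial(n_site_total, w / w.sum())
        for (gene, row), n_reads in zip(targets.iterrows(), counts):
            if n_reads == 0:
                continue
            tx = row["transcript_id"]
            model = transcripts[tx]
            a, b = int(row["site_start"]), int(row["site_end"])
            ov = min(10, b - a)
            lo = max(0, a + ov - rl)
            hi = min(model.length - rl, b - ov)
            hi = max(hi, lo)
            starts = rng.integers(lo, hi + 1, size=n_reads)
            tmask = is_t[tx]
            for s in starts:
                s = int(s)
                reads.append(
                    AlignedRead(
                        transcript_id=tx,
                        start=s,
                        end=s + rl,
                        conversion_offsets=_draw_conversions(
                            rng, tmask, s, s + rl, config.conv_prob_site
                        ),
                    )
                )

    if n_bg_total > 0:
        tx_ids = sorted(transcripts)
        lengths = np.array([transcripts[t].length for t in tx_ids])
        expr = truth.set_index("transcript_id")["rel_expression"].reindex(tx_ids).to_numpy()
        w = expr * lengths
        counts = rng.multinomial(n_bg_total, w / w.sum())
        for tx, n_reads in zip(tx_ids, counts):
            if n_reads == 0:
                continue
            model = transcripts[tx]
            starts = rng.integers(0, max(model.length - rl, 0) + 1, size=n_reads)
            tmask = is_t[tx]
            for s in starts:
                s = int(s)
                e = min(s + rl, model.length)
                reads.append(
                    AlignedRead(
                        transcript_id=tx,
                        start=s,
                        end=e,
                        conversion_offsets=_draw_conversions(
                            rng, tmask, s, e, config.conv_prob_background
                        ),
                    )
                )
    return reads


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(
    transcripts: dict[str, TranscriptModel],
    truth: pd.DataFrame,
    config: SimConfig,
) -> ExpressionTable:
    """Generate WT/KO RNA-seq and Ribo-seq count matrices.

    Per gene, the WT RNA mean is proportional to relative expression x
    transcript length (scaled to ``rna_depth``); the KO RNA mean is the
    WT mean x 2^lfc_mrna.  RPF means are proportional to expression x CDS
    length with the analogous ``lfc_rpf`` effect.  Counts are
    negative-binomial with the configured dispersion (Poisson in the
    dispersion -> 0 limit).
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 3))
    genes = list(truth.index)
    lengths = np.array([transcripts[truth.at[g, "transcript_id"]].length for g in genes])
    cds_lengths = np.array(
        [
            transcripts[truth.at[g, "transcript_id"]].cds_end
            - transcripts[truth.at[g, "transcript_id"]].cds_start
            for g in genes
        ]
    )
    expr = truth["rel_expression"].to_numpy()
    lfc_mrna = truth["lfc_mrna"].to_numpy()
    lfc_rpf = truth["lfc_rpf"].to_numpy()

    w_rna = expr * lengths
    w_rpf = expr * cds_lengths
    mu_rna_wt = config.rna_depth * w_rna / w_rna.sum()
    mu_rpf_wt = config.rpf_depth * w_rpf / w_rpf.sum()
    mu_rna_ko = mu_rna_wt * np.exp2(lfc_mrna)
    mu_rpf_ko = mu_rpf_wt * np.exp2(lfc_rpf)

    data = {}
    for assay, cond, mu in (
        ("rna", "wt", mu_rna_wt),
        ("rna", "ko", mu_rna_ko),
        ("rpf", "wt", mu_rpf_wt),
        ("rpf", "ko", mu_rpf_ko),
    ):
        for rep in range(1, config.n_replicates + 1):
            data[f"{assay}_{cond}_{rep}"] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return ExpressionTable(counts)
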