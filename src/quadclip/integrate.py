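"""Integration of RNA-seq / Ribo-seq count matrices with binding occupancy.

Count normalization, per-gene log2 fold changes, translational efficiency
(TE = RPF abundance / RNA abundance), occupancy-binned CDF comparisons by
two-sided Kolmogorov-Smirnov test, exponential mRNA decay fits from
transcription-block (actinomycin D) time courses, and the corrected total
cell fluorescence (CTCF) imaging statistic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ASSAYS = ("rna", "rpf")
CONDITIONS = ("wt", "ko")

_SAMPLE_RE = re.compile(r"^(rna|rpf)_(wt|ko)_(\d+)$")


class ExpressionTable:
    """Gene x sample integer count matrix with sample metadata.

    Sample columns follow the ``{assay}_{condition}_{replicate}`` naming
    convention (e.g. ``rna_wt_1``), from which assay in {rna, rpf},
    condition in {wt, ko} and the replicate index are parsed.
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        samples = []
        for col in counts.columns:
            m = _SAMPLE_RE.match(col)
            if not m:
                raise ValueError(
                    f"sample column {col!r} does not match 'assay_condition_rep'"
                )
            samples.append((col, m.group(1), m.group(2), int(m.group(3))))
        self.counts = counts
        self.samples = pd.DataFrame(
            samples, columns=["sample", "assay", "condition", "replicate"]
        ).set_index("sample")

    def subset(self, assay: str, condition: str) -> pd.DataFrame:
        mask = (self.samples["assay"] == assay) & (self.samples["condition"] == condition)
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise ValueError(f"no samples for assay={assay!r}, condition={condition!r}")
        return self.counts[cols]

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def normalize_counts(
    counts: pd.DataFrame,
    method: str = "median_of_ratios",
    control_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalize a gene x sample count matrix.

    ``cpm``: counts per million per column.  ``median_of_ratios``:
    DESeq-style size factors — per sample the median, over genes with all
    counts nonzero, of count / geometric row mean; abundances are counts
    divided by the sample's size factor.

    ``control_genes`` (median_of_ratios only) restricts size-factor
    estimation to the given genes.  When a sizeable fraction of genes
    shifts in one direction between conditions, global size factors absorb
    part of the shift; estimating them on genes believed unaffected (e.g.
    genes without binding clusters) removes that composition bias.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    if method == "cpm":
        return counts.div(counts.sum(axis=0), axis=1) * 1e6
    if method == "median_of_ratios":
        estimation = counts
        if control_genes is not None:
            estimation = counts.loc[counts.index.intersection(control_genes)]
            if estimation.empty:
                raise ValueError("no control genes present in the count matrix")
        arr = estimation.to_numpy(dtype=float)
        nonzero = (arr > 0).all(axis=1)
        if not nonzero.any():
            raise ValueError("median_of_ratios requires >=1 gene nonzero in all samples")
        ref = arr[nonzero]
        log_geo_mean = np.log(ref).mean(axis=1)
        size_factors = np.exp(
            np.median(np.log(ref) - log_geo_mean[:, None], axis=0)
        )
        return counts / size_factors
    raise ValueError(f"unknown normalization method {method!r}")


def log2fc(
    abund_ko: pd.DataFrame | pd.Series,
    abund_wt: pd.DataFrame | pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_KO + pc) / (mean_WT + pc)) of normalized abundance."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_ko = abund_ko.mean(axis=1) if isinstance(abund_ko, pd.DataFrame) else abund_ko
    mean_wt = abund_wt.mean(axis=1) if isinstance(abund_wt, pd.DataFrame) else abund_wt
    return np.log2((mean_ko + pseudocount) / (mean_wt + pseudocount))


def translational_efficiency(
    rna_wt: pd.DataFrame,
    rna_ko: pd.DataFrame,
    rpf_wt: pd.DataFrame,
    rpf_ko: pd.DataFrame,
    min_abund: float = 1.0,
) -> pd.DataFrame:
    """Translational efficiency TE = RPF abundance / RNA abundance per condition.

    Inputs are normalized abundance matrices (genes x replicates) on a
    matched gene universe.  Replicate means are used.  Genes whose mean
    abundance falls below ``min_abund`` in any of the four quantities are
    flagged (``te_flagged``) and their TE / delta_te set to NaN rather
    than dropped.

    Returns columns ``te_wt``, ``te_ko``, ``delta_te`` (log2(TE_KO/TE_WT))
    and ``te_flagged``.
    """
    idx = rna_wt.index
    for other in (rna_ko, rpf_wt, rpf_ko):
        if not idx.equals(other.index):
            raise ValueError("gene universe must match across assays/conditions")
    means = {
        "rna_wt": rna_wt.mean(axis=1),
        "rna_ko": rna_ko.mean(axis=1),
        "rpf_wt": rpf_wt.mean(axis=1),
        "rpf_ko": rpf_ko.mean(axis=1),
    }
    flagged = pd.concat(means, axis=1).lt(min_abund).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        te_wt = means["rpf_wt"] / means["rna_wt"]
        te_ko = means["rpf_ko"] / means["rna_ko"]
        delta = np.log2(te_ko / te_wt)
    out = pd.DataFrame(
        {"te_wt": te_wt, "te_ko": te_ko, "delta_te": delta, "te_flagged": flagged}
    )
    out.loc[flagged, ["te_wt", "te_ko", "delta_te"]] = np.nan
    return out


def differential_summary(
    table: ExpressionTable,
    method: str = "median_of_ratios",
    pseudocount: float = 1.0,
    min_abund: float = 1.0,
    control_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: normalize per assay, then LFCs and TE.

    ``control_genes`` are passed to :func:`normalize_counts`; in a binding
    study the natural choice is the genes without called clusters, which
    anchors the fold-change scale on presumed non-targets.

    Returns per-gene ``lfc_rna``, ``lfc_rpf``, ``te_wt``, ``te_ko``,
    ``delta_te``, ``te_flagged``.
    """
    rna = normalize_counts(
        pd.concat([table.subset("rna", "wt"), table.subset("rna", "ko")], axis=1),
        method,
        control_genes=control_genes,
    )
    rpf = normalize_counts(
        pd.concat([table.subset("rpf", "wt"), table.subset("rpf", "ko")], axis=1),
        method,
        control_genes=control_genes,
    )
    rna_wt = rna[table.subset("rna", "wt").columns]
    rna_ko = rna[table.subset("rna", "ko").columns]
    rpf_wt = rpf[table.subset("rpf", "wt").columns]
    rpf_ko = rpf[table.subset("rpf", "ko").columns]
    out = translational_efficiency(rna_wt, rna_ko, rpf_wt, rpf_ko, min_abund)
    out.insert(0, "lfc_rpf", log2fc(rpf_ko, rpf_wt, pseudocount))
    out.insert(0, "lfc_rna", log2fc(rna_ko, rna_wt, pseudocount))
    return out


NONTARGET_BIN = "non-target"


def bin_targets(
    profiles: pd.DataFrame,
    metric: str,
    bounds: Sequence[float],
    universe: Sequence[str] | None = None,
) -> pd.Series:
    """Partition genes into occupancy bins plus a non-target reference bin.

    ``profiles`` is the output of :func:`quadclip.clipcore.compute_nxpm`
    (indexed by gene_id).  ``metric`` is one of its numeric columns
    (``nxpm``, ``nxpm_utr5``, ``nxpm_cds``, ``nxpm_utr3``, ``n_clusters``).
    ``bounds`` are strictly increasing edges of right-open intervals
    ``[b_i, b_{i+1})``; an implicit final edge of +inf is appended.

    Genes in ``universe`` (default: the profile index) with no clusters —
    including genes absent from ``profiles`` — form the ``non-target``
    reference bin regardless of metric.
    """
    bounds = [float(b) for b in bounds]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError(f"bin bounds must be strictly increasing: {bounds}")
    if metric not in profiles.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if universe is None:
        universe = list(profiles.index)
    edges = bounds + [np.inf]
    labels = {}
    for gene in universe:
        if gene not in profiles.index or profiles.at[gene, "n_clusters"] == 0:
            labels[gene] = NONTARGET_BIN
            continue
        value = profiles.at[gene, metric]
        if pd.isna(value):
            labels[gene] = NONTARGET_BIN
            continue
        label = NONTARGET_BIN
        for lo, hi in zip(edges, edges[1:]):
            if lo <= value < hi:
                label = f"[{lo:g}, {hi:g})"
                break
        labels[gene] = label
    return pd.Series(labels, name="bin")


@dataclass
class BinnedComparison:
    """KS comparison of one occupancy bin against the reference bin."""

    bin_label: str
    n: int
    n_ref: int
    D: float
    p: float
    median: float
    median_ref: float


def cdf_ks_compare(
    values_by_bin: Mapping[str, Sequence[float]],
    reference_bin: str = NONTARGET_BIN,
    min_size: int = 10,
) -> pd.DataFrame:
    """Compare each bin's value distribution to the reference bin.

    For every non-reference bin with at least ``min_size`` finite values,
    reports the two-sample Kolmogorov-Smirnov statistic
    D = sup |ECDF_bin - ECDF_ref| with a two-sided p-value (exact for
    small samples via scipy's auto mode, asymptotic otherwise) and the
    bin medians for effect direction.  Undersized or empty bins are
    skipped with a warning.
    """
    ref = np.asarray(values_by_bin[reference_bin], dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("reference bin is empty")
    rows = []
    for label, values in values_by_bin.items():
        if label == reference_bin:
            continue
        vals = np.asarray(values, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < min_size:
            warnings.warn(
                f"bin {label!r} has {vals.size} values (< {min_size}); skipped",
                stacklevel=2,
            )
            continue
        res = stats.ks_2samp(vals, ref, alternative="two-sided", method="auto")
        rows.append(
            BinnedComparison(
                bin_label=label,
                n=int(vals.size),
                n_ref=int(ref.size),
                D=float(res.statistic),
                p=float(res.pvalue),
                median=float(np.median(vals)),
                median_ref=float(np.median(ref)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class DecayFit:
    """Exponential decay fit of an mRNA level time course.

    ``k`` is the first-order decay constant (per hour) from a least-squares
    fit of ln(level) against time; ``half_life`` = ln 2 / k when k > 0,
    otherwise NaN with ``non_decaying`` set.
    """

    k: float
    half_life: float
    r_squared: float
    non_decaying: bool


def fit_halflife(timepoints: Sequence[float], levels: Sequence[float]) -> DecayFit:
    """Fit a first-order decay to relative mRNA levels after transcription block.

    Levels are typically qPCR values normalized to the t=0 sample; any
    uniform rescaling changes only the intercept, not k.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >=3 timepoints, got {t.size}")
    if t.size != y.size:
        raise ValueError("timepoints and levels differ in length")
    if (y <= 0).any():
        raise ValueError("levels must be positive (log-linear fit)")
    logy = np.log(y)
    slope, intercept = np.polyfit(t, logy, 1)
    resid = logy - (slope * t + intercept)
    ss_tot = np.sum((logy - logy.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(1 - np.sum(resid**2) / ss_tot)
    k = float(-slope)
    if k > 0:
        return DecayFit(k=k, half_life=float(np.log(2) / k), r_squared=r2, non_decaying=False)
    return DecayFit(k=k, half_life=float("nan"), r_squared=r2, non_decaying=True)


def fit_halflives(long_table: pd.DataFrame) -> pd.DataFrame:
    """Fit decay per gene from a long-format table (gene_id, time_h, level)."""
    required = {"gene_id", "time_h", "level"}
    if not required.issubset(long_table.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    rows = []
    for gene, grp in long_table.groupby("gene_id", sort=True):
        fit = fit_halflife(grp["time_h"].to_numpy(), grp["level"].to_numpy())
        rows.append(
            {
                "gene_id": gene,
                "k": fit.k,
                "half_life": fit.half_life,
                "r_squared": fit.r_squared,
                "non_decaying": fit.non_decaying,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


class CTCFResult(NamedTuple):
    value: float
    negative: bool


def ctcf(
    integrated_density: float, cell_area: float, background_mean: float
) -> CTCFResult:
    """Corrected total cell fluorescence.

    CTCF = integrated density - (cell area x mean background fluorescence).
    The value may come out negative for dim cells on bright background;
    such results are flagged rather than clipped.
    """
    if cell_area < 0:
        raise ValueError("cell_area must be >= 0")
    value = float(integrated_density - cell_area * background_mean)
    return CTCFResult(value=value, negative=value < 0)
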