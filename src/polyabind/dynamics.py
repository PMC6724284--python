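"""mRNA decay-rate fitting, translational efficiency, and derived rates.

The degradation rate of a gene is the slope of the ordinary least-squares
regression of y_t = ln(FPKM_0 / FPKM_t) on time after transcriptional
shutoff; the regression keeps an intercept (it absorbs the t = 0
normalisation offset), replicates are fitted separately and their slopes
averaged.  Translational efficiency (TE) is ribosome-footprint RPKM over
the CDS divided by mRNA FPKM, computed only for genes passing strict
expression floors (> 0.5 RPKM and > 1 FPKM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DecayFit:
    """Per-gene degradation-rate fit."""

    gene_id: str
    rate: float          # per hour; average of replicate slopes
    intercept: float     # average replicate intercept
    r_squared: float     # average replicate R^2
    n_points: int        # points used in the sparsest replicate fit
    replicate_rates: tuple[float, ...]
    reason: str | None = None  # set when no fit could be made

    @property
    def half_life(self) -> float:
        """ln 2 / rate, defined for positive rates only."""
        return np.log(2) / self.rate if self.rate > 0 else np.nan


def _fit_one_series(times: np.ndarray, fpkm: np.ndarray, min_points: int = 3):
    """OLS of ln(m0/mt) on t for one replicate; returns (slope, intercept, r2, n)."""
    times = np.asarray(times, float)
    fpkm = np.asarray(fpkm, float)
    if not np.any(times == 0) or fpkm[times == 0][0] <= 0:
        return None
    m0 = fpkm[times == 0][0]
    keep = fpkm > 0  # nonpositive observations carry no log signal
    t, m = times[keep], fpkm[keep]
    if len(t) < min_points:
        return None
    y = np.log(m0 / m)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2), int(len(t))


def fit_decay(gene_id: str, times, fpkm_by_replicate, min_points: int = 3) -> DecayFit:
    """Fit one gene's decay rate from replicate time series.

    ``fpkm_by_replicate`` is an iterable of FPKM vectors aligned to
    ``times``.  Replicates are fitted independently and their slopes
    averaged; replicates with fewer than ``min_points`` usable (positive)
    observations are skipped, and if none survive the fit is reported with
    a reason instead of numbers.
    """
    fits = []
    for series in fpkm_by_replicate:
        res = _fit_one_series(np.asarray(times), np.asarray(series), min_points)
        if res is not None:
            fits.append(res)
    if not fits:
        return DecayFit(gene_id, np.nan, np.nan, np.nan, 0, (), reason="too_few_points")
    slopes = [f[0] for f in fits]
    return DecayFit(
        gene_id=gene_id,
        rate=float(np.mean(slopes)),
        intercept=float(np.mean([f[1] for f in fits])),
        r_squared=float(np.mean([f[2] for f in fits])),
        n_points=min(f[3] for f in fits),
        replicate_rates=tuple(slopes),
    )


def fit_decay_table(course: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Fit every gene in a tidy (gene_id, replicate, time, fpkm) time course."""
    rows = []
    for gene_id, sub in course.groupby("gene_id", sort=True):
        series = []
        times_ref = None
        for _, rep in sub.groupby("replicate"):
            rep = rep.sort_values("time")
            times_ref = rep["time"].to_numpy()
            series.append(rep["fpkm"].to_numpy())
        fit = fit_decay(gene_id, times_ref, series, min_points=min_points)
        rows.append(dict(
            gene_id=gene_id, rate=fit.rate, intercept=fit.intercept,
            r_squared=fit.r_squared, n_points=fit.n_points,
            half_life=fit.half_life, reason=fit.reason,
        ))
    return pd.DataFrame(rows)


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series,
                 count_col: str = "count") -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads.

    RPKM = count * 1e9 / (length_nt * total counts); ``lengths`` maps
    gene_id to feature length in nt (the CDS for ribosome footprints).
    """
    total = counts[count_col].sum()
    if total <= 0:
        raise ValueError("no mapped reads")
    out = counts.copy()
    out["length"] = out["gene_id"].map(lengths)
    if out["length"].isna().any():
        missing = out.loc[out["length"].isna(), "gene_id"].tolist()[:3]
        raise KeyError(f"no feature length for gene(s) {missing}")
    out["rpkm"] = out[count_col] * 1e9 / (out["length"] * total)
    return out


def compute_te(ribo_rpkm: pd.DataFrame, mrna_fpkm: pd.DataFrame,
               floors: tuple[float, float] = (0.5, 1.0)) -> pd.DataFrame:
    """TE = ribo RPKM / mRNA FPKM for genes above both (strict) floors."""
    merged = ribo_rpkm[["gene_id", "rpkm"]].merge(
        mrna_fpkm[["gene_id", "fpkm"]], on="gene_id", how="outer"
    ).rename(columns={"rpkm": "ribo_rpkm", "fpkm": "mrna_fpkm"})
    merged["passes_filter"] = (
        (merged["ribo_rpkm"] > floors[0]) & (merged["mrna_fpkm"] > floors[1])
    ).fillna(False)
    merged["te"] = np.where(
        merged["passes_filter"], merged["ribo_rpkm"] / merged["mrna_fpkm"], np.nan
    )
    return merged


def periodicity_score(positions: pd.DataFrame, cds_starts: pd.Series) -> float:
    """Fraction of footprints whose 5' end sits in the modal reading frame.

    ``positions`` has columns gene_id, position; frames are
    (position - cds_start) mod 3.
    """
    starts = positions["gene_id"].map(cds_starts)
    frames = ((positions["position"] - starts) % 3).to_numpy()
    if len(frames) == 0:
        raise ValueError("no footprint positions")
    counts = np.bincount(frames.astype(int), minlength=3)
    return float(counts.max() / counts.sum())


def reduced_te_set(te_wild: pd.DataFrame, te_mut: pd.DataFrame) -> pd.DataFrame:
    """Genes with below-median TE fold change (mutant vs wild type).

    Fold changes are computed over genes passing the expression filters in
    both conditions; ``reduced_te`` flags log2 fold changes strictly below
    the median, so about half the genes are flagged by construction.
    """
    wt = te_wild[te_wild["passes_filter"]][["gene_id", "te"]]
    mut = te_mut[te_mut["passes_filter"]][["gene_id", "te"]]
    merged = wt.merge(mut, on="gene_id", suffixes=("_wild", "_mut"))
    merged["log2_fc_te"] = np.log2(merged["te_mut"] / merged["te_wild"])
    med = merged["log2_fc_te"].median()
    merged["reduced_te"] = merged["log2_fc_te"] < med
    return merged


def protein_synthesis_rate(protein: pd.DataFrame, mrna: pd.DataFrame,
                           min_mrna: float = 0.0) -> pd.DataFrame:
    """Per-gene protein synthesis rate = protein level / mRNA level.

    Genes with mRNA at or below ``min_mrna`` are omitted (never infinite).
    """
    merged = protein[["gene_id", "protein"]].merge(
        mrna[["gene_id", "fpkm"]], on="gene_id"
    ).rename(columns={"fpkm": "mrna"})
    merged = merged[merged["mrna"] > min_mrna].copy()
    merged["synthesis_rate"] = merged["protein"] / merged["mrna"]
    return merged
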