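"""Statistical layer: associations, paired tests, AIC model ladder,
enrichment, and Mendelian segregation.

All hypothesis tests report raw p values (no multiple-testing correction).
The "paired Mann-Whitney U" of the paralog comparison is realised as the
Wilcoxon signed-rank test, its standard paired analogue.  The AIC of an
ordinary-least-squares model is the Gaussian profile form
``n * ln(RSS/n) + 2 * (k + 1)`` with k coefficients including the
intercept, so only AIC differences between models on the same response are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# ---------------------------------------------------------------------------
# associations

@dataclass
class DecileAssociation:
    rho: float
    p_value: float
    bins: pd.DataFrame  # per-bin summary for display
    n: int


def decile_association(g_percent: Sequence[float], binding_eff: Sequence[float],
                       n_bins: int = 10) -> DecileAssociation:
    """Spearman association between per-gene G% and binding efficiency.

    The correlation and p value are computed on the unbinned gene-level
    values; equal-size rank bins (ties to the lower bin) are reported for
    visualisation only, with the per-bin median of both variables.
    """
    g = np.asarray(g_percent, float)
    b = np.asarray(binding_eff, float)
    keep = np.isfinite(g) & np.isfinite(b)
    g, b = g[keep], b[keep]
    n = len(g)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} genes with both values, got {n}")
    if np.all(g == g[0]):
        return DecileAssociation(np.nan, np.nan, pd.DataFrame(), n)
    rho, p = stats.spearmanr(g, b)
    order = np.argsort(g, kind="mergesort")  # stable: ties to the lower bin
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = (np.arange(n) * n_bins) // n
    bins = pd.DataFrame({"g_percent": g, "binding_efficiency": b, "bin": bin_of})
    summary = bins.groupby("bin").agg(
        n=("bin", "size"),
        median_g_percent=("g_percent", "median"),
        median_binding_efficiency=("binding_efficiency", "median"),
    ).reset_index()
    return DecileAssociation(float(rho), float(p), summary, n)


def paired_paralog_test(low_g_be: Sequence[float], high_g_be: Sequence[float],
                        min_informative: int = 6):
    """One-sided Wilcoxon signed-rank test on within-pair BE differences.

    Alternative: the low-G member binds better (differences > 0).  Tied
    (zero-difference) pairs are dropped; fewer than ``min_informative``
    informative pairs is an error.
    Returns (statistic, one-sided p, n informative pairs).
    """
    d = np.asarray(low_g_be, float) - np.asarray(high_g_be, float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) < min_informative:
        raise ValueError(
            f"only {len(d)} informative (non-tied) pairs; need >= {min_informative}"
        )
    res = stats.wilcoxon(d, alternative="greater")
    return float(res.statistic), float(res.pvalue), int(len(d))


# ---------------------------------------------------------------------------
# AIC model ladder

#: the eight nested predictor sets compared for translational efficiency
TE_MODELS: tuple[tuple[str, ...], ...] = (
    (),
    ("g_percent",),
    ("mrna_level",),
    ("mrna_level", "g_percent"),
    ("tail_length",),
    ("tail_length", "g_percent"),
    ("mrna_level", "tail_length"),
    ("mrna_level", "tail_length", "g_percent"),
)


def ols_aic(rss: float, n: int, k: int) -> float:
    """Gaussian-OLS AIC: n * ln(RSS/n) + 2 * (k + 1), k coefficients incl. intercept."""
    if rss <= 0 or n <= 0:
        raise ValueError("rss and n must be positive")
    return n * np.log(rss / n) + 2 * (k + 1)


def aic_ladder(data: pd.DataFrame, log_transform: bool = True,
               models: Sequence[Sequence[str]] = TE_MODELS) -> pd.DataFrame:
    """Compare OLS models of translational efficiency by AIC.

    ``data`` needs columns te, mrna_level, tail_length, g_percent.  TE and
    mRNA level are log10-transformed by default (their distributions span
    orders of magnitude; linear-scale fits are dominated by outliers);
    tail length and G% enter linearly.  All models are fitted on the same
    complete cases; rank-deficient designs are skipped with a reason.
    """
    needed = {"te", "mrna_level", "tail_length", "g_percent"}
    missing = needed - set(data.columns)
    if missing:
        raise KeyError(f"missing columns {sorted(missing)}")
    df = data[list(needed)].replace([np.inf, -np.inf], np.nan).dropna()
    if log_transform:
        df = df[(df["te"] > 0) & (df["mrna_level"] > 0)].copy()
        df["te"] = np.log10(df["te"])
        df["mrna_level"] = np.log10(df["mrna_level"])
    y = df["te"].to_numpy()
    n = len(df)
    rows = []
    for i, predictors in enumerate(models, start=1):
        X = sm.add_constant(df[list(predictors)].to_numpy()) if predictors \
            else np.ones((n, 1))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(dict(model_id=i, predictors="+".join(predictors) or "null",
                             n_obs=n, k_params=X.shape[1], rss=np.nan, aic=np.nan,
                             skipped_reason="rank_deficient"))
            continue
        fit = sm.OLS(y, X).fit()
        rss = float(fit.ssr)
        rows.append(dict(model_id=i, predictors="+".join(predictors) or "null",
                         n_obs=n, k_params=X.shape[1], rss=rss,
                         aic=ols_aic(rss, n, X.shape[1]), skipped_reason=None))
    table = pd.DataFrame(rows)
    best = table["aic"].min()
    table["delta_aic"] = table["aic"] - best
    return table


# ---------------------------------------------------------------------------
# group and enrichment tests

def group_comparison(values_a: Sequence[float], values_b: Sequence[float],
                     alternative: str = "two-sided") -> float:
    """Mann-Whitney U p value; exact when both groups have <= 8 observations,
    otherwise the tie-corrected normal approximation."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def enrichment_test(table: Sequence[Sequence[int]]):
    """Fisher's exact test (two-sided, point-probability rule) on a 2x2 table.

    Returns (odds ratio, p value); the odds ratio uses the Haldane
    correction (+0.5 everywhere) when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Mendelian segregation

@dataclass
class CrossSpec:
    """A self-cross of a plant heterozygous at one locus.

    ``lethal_classes`` lists genotype classes ('AA', 'Aa', 'aa') that abort
    before scoring; by default the homozygous-mutant class.
    """

    lethal_classes: tuple[str, ...] = ("aa",)


@dataclass
class MendelianExpectation:
    pre_lethality: dict
    viable: dict
    aborted_fraction: float


def mendelian_expectations(cross: CrossSpec = CrossSpec()) -> MendelianExpectation:
    """Expected genotype fractions for a selfed heterozygote.

    Pre-lethality segregation is 1/4 AA : 1/2 Aa : 1/4 aa.  Conditioning on
    the lethal classes gives the viable fractions (with the homozygous
    mutant lethal: viable WT:het = 1:2) and the aborted-seed fraction.
    """
    pre = {"AA": 0.25, "Aa": 0.5, "aa": 0.25}
    unknown = set(cross.lethal_classes) - set(pre)
    if unknown:
        raise ValueError(f"unknown genotype class(es) {sorted(unknown)}")
    aborted = sum(pre[c] for c in cross.lethal_classes)
    if aborted >= 1.0:
        raise ValueError("all classes lethal")
    viable = {c: f / (1.0 - aborted) for c, f in pre.items()
              if c not in cross.lethal_classes}
    return MendelianExpectation(pre_lethality=pre, viable=viable,
                                aborted_fraction=aborted)


def segregation_binomial_test(n_observed: int, n_total: int,
                              expected_fraction: float = 2.0 / 3.0) -> float:
    """Two-sided exact binomial test of an observed class count."""
    return float(stats.binomtest(n_observed, n_total, expected_fraction,
                                 alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# sequencing-quality arithmetic

def phred_error_rate(q: float) -> float:
    """Expected sequencing errors per 10,000 bases at Phred quality q."""
    return 1e4 * 10 ** (-q / 10.0)
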