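"""Negative-binomial differential expression between stages.

The model family is the standard one for RNA-seq counts: per-sample
median-of-ratios size factors, a per-feature negative-binomial dispersion
(variance = mu + alpha * mu^2) estimated by the method of moments, and a
Wald test on the log2 fold change of normalized condition means. Small
pseudo-counts stabilize zero means. Raw p-values are combined with
Benjamini-Hochberg adjusted values, and a feature is called up or down only
when |log2FC| >= 1, p < 0.05 AND the adjusted p < 0.1 (both thresholds are
applied, and both are configurable).

This is a from-scratch implementation of the model family, not a wrapper:
exact numerical agreement with any particular DE package is not a goal;
distributional correctness (type-I error, FDR, effect recovery) is.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SampleSheet

LFC_PSEUDOCOUNT = 0.5


def size_factors(values: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over features i (restricted to rows with no zero) of
    count_ij / geometric_mean_i. Raises when no all-nonzero row exists.
    """
    mat = values.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no feature with nonzero counts in every sample; "
            "use a pseudo-reference fallback or filter samples"
        )
    sub = mat[nonzero]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return pd.Series(factors, index=values.columns, name="size_factor")


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_test(
    values: pd.DataFrame,
    sheet: SampleSheet,
    contrast: Tuple[str, str],
    factors: Optional[pd.Series] = None,
    eps: float = LFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature NB Wald test of stage B over stage A.

    Counts are normalized by size factors (computed over the full matrix
    when not supplied). Per feature, the dispersion alpha is the moment
    estimate max(0, (s^2 - mu) / mu^2) from the pooled within-condition
    variance of normalized counts; alpha = 0 degenerates to Poisson. The
    Wald statistic log2FC / SE(log2FC) is referred to a t distribution with
    nA + nB - 2 degrees of freedom (moment variance estimate from few
    replicates). Features with all-zero counts in both conditions are
    reported untested (NaN statistics).
    """
    stage_a, stage_b = contrast
    cols_a = [s.sample_id for s in sheet.samples_for_stage(stage_a)]
    cols_b = [s.sample_id for s in sheet.samples_for_stage(stage_b)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("nb_test requires >= 2 replicates per condition")
    if factors is None:
        factors = size_factors(values)
    norm = values / factors

    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    tested = (values[cols_a + cols_b].sum(axis=1) > 0).to_numpy()

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    grand_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            grand_mean > 0, (pooled_var - grand_mean) / grand_mean**2, 0.0
        )
    alpha = np.clip(alpha, 0.0, None)

    log2fc = np.log2((mean_b + eps) / (mean_a + eps))
    ln2_sq = np.log(2.0) ** 2
    ma = np.maximum(mean_a, eps)
    mb = np.maximum(mean_b, eps)
    var_mean_a = (ma + alpha * ma**2) / n_a
    var_mean_b = (mb + alpha * mb**2) / n_b
    se = np.sqrt(
        var_mean_a / ((mean_a + eps) ** 2 * ln2_sq)
        + var_mean_b / ((mean_b + eps) ** 2 * ln2_sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)

    out = pd.DataFrame(
        {
            "feature_id": values.index,
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2FC": log2fc,
            "p": p,
            "padj": np.nan,
            "tested": tested,
        }
    )
    out.loc[~out["tested"], ["log2FC", "p"]] = np.nan
    mask = out["tested"].to_numpy()
    if mask.any():
        out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"])
    return out


def classify_de(
    results: pd.DataFrame,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    fdr_cut: float = 0.1,
) -> pd.DataFrame:
    """Add up/down/ns calls using both the raw-p and the FDR threshold."""
    res = results.copy()
    sig = (res["p"] < p_cut) & (res["padj"] < fdr_cut)
    call = np.where(
        sig & (res["log2FC"] >= lfc_cut),
        "up",
        np.where(sig & (res["log2FC"] <= -lfc_cut), "down", "ns"),
    )
    call = np.where(res["tested"].fillna(False), call, "ns")
    res["call"] = call
    return res


def de_summary(results: pd.DataFrame) -> Tuple[int, int, int]:
    """(n_up, n_down, n_ns) for one classified contrast."""
    calls = results["call"].value_counts()
    return (
        int(calls.get("up", 0)),
        int(calls.get("down", 0)),
        int(calls.get("ns", 0)),
    )


def stage_correlation(
    cpm: pd.DataFrame,
    sheet: SampleSheet,
    pair: Tuple[str, str],
    features: Optional[Sequence[str]] = None,
) -> dict:
    """Pearson correlation of mean log2(CPM+1) between two stages.

    Computed over the supplied feature set (e.g. the union expressed
    catalog). Zero variance in either stage flags R as undefined.
    """
    stage_a, stage_b = pair
    sub = cpm.loc[list(features)] if features is not None else cpm
    if len(sub) < 3:
        raise ValueError("stage_correlation requires >= 3 features")
    cols_a = [s.sample_id for s in sheet.samples_for_stage(stage_a)]
    cols_b = [s.sample_id for s in sheet.samples_for_stage(stage_b)]
    x = np.log2(sub[cols_a] + 1).mean(axis=1).to_numpy()
    y = np.log2(sub[cols_b] + 1).mean(axis=1).to_numpy()
    if x.std() == 0 or y.std() == 0:
        return {"pair": f"{stage_a}-{stage_b}", "R": np.nan, "p": np.nan,
                "n": len(x), "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"pair": f"{stage_a}-{stage_b}", "R": float(r), "p": float(p),
            "n": len(x), "defined": True}
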