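"""Negative-binomial differential-activity engine.

A transparent NB engine providing pairwise Wald contrasts and an
across-stage likelihood-ratio test over raw count matrices, with
median-of-ratios sample normalization and Benjamini-Hochberg correction.

Deliberate simplifications relative to full GLM machinery: no dispersion
trend or empirical-Bayes shrinkage, no LFC shrinkage, no independent
filtering, no outlier refitting.  Gene-wise dispersion is estimated by
method of moments on normalized counts within groups and floored at the
cohort median of those estimates — the minimal moderation that keeps the
Wald test calibrated at three replicates per group (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_FLOOR = 1e-8
RESULT_COLUMNS = [
    "feature_id", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj",
]


class DesignError(ValueError):
    """Raised for contrasts the sample design cannot support."""


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios sample normalization factors.

    factor_s = median over features of count_{g,s} / geometric-mean_g(count),
    over features with all-positive counts.  With ``pseudo_reference`` the
    geometric mean is taken over nonzero entries only (sparse-count fallback).
    """
    mat = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(mat > 0, np.log(np.where(mat > 0, mat, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        usable = ~np.isnan(ref)
    else:
        usable = (mat > 0).all(axis=1)
        if not usable.any():
            raise DesignError(
                "no feature has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        ref = np.exp(np.mean(np.log(mat[usable]), axis=1))
        ratios = mat[usable] / ref[:, None]
        return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")
    ratios = np.where(mat[usable] > 0, mat[usable] / ref[usable, None], np.nan)
    sf = np.nanmedian(ratios, axis=0)
    if np.isnan(sf).any() or (sf <= 0).any():
        raise DesignError("size factors undefined for at least one sample")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] / (np.arange(1, m + 1) / m)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _dispersion_mom(
    norm: np.ndarray, groups: list[np.ndarray], floor_at_median: bool = True
) -> np.ndarray:
    """Gene-wise method-of-moments NB dispersion from within-group moments.

    For each group with >=2 samples: alpha_hat = (var - mean) / mean^2;
    estimates are df-weighted across groups, clipped at zero, and floored at
    the cohort median (then at ALPHA_FLOOR).
    """
    n_feat = norm.shape[0]
    num = np.zeros(n_feat)
    den = np.zeros(n_feat)
    for idx in groups:
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num[ok] += (v[ok] - m[ok]) / m[ok] ** 2 * (idx.size - 1)
        den[ok] += idx.size - 1
    alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    alpha = np.clip(alpha, 0.0, None)
    if floor_at_median and n_feat > 1:
        alpha = np.maximum(alpha, np.median(alpha))
    return np.maximum(alpha, ALPHA_FLOOR)


def wald_test(
    counts: pd.DataFrame,
    stages: pd.Series,
    stage: str,
    other: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature NB Wald contrast of ``stage`` over ``other``.

    log2 fold change is the ratio of group means of size-factor-normalized
    counts with a +0.5 pseudocount (pseudocount affects the fold change only,
    not the variance model); the standard error follows from the NB
    information, Var[log mean] ~= (1/mu + alpha)/n per group.
    """
    for s in (stage, other):
        if (stages == s).sum() < 2:
            raise DesignError(f"stage {s!r} needs >=2 samples for a Wald contrast")
    samples = list(stages.index[stages.isin([stage, other])])
    sub = counts[samples]
    sf = size_factors(sub)
    norm = (sub / sf).to_numpy(dtype=float)
    lab = stages.loc[samples].to_numpy()
    ia = np.flatnonzero(lab == stage)
    ib = np.flatnonzero(lab == other)
    mu_a = norm[:, ia].mean(axis=1)
    mu_b = norm[:, ib].mean(axis=1)
    alpha = _dispersion_mom(norm, [ia, ib])
    l2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    with np.errstate(divide="ignore"):
        var_ln = (
            (np.where(mu_a > 0, 1.0 / np.where(mu_a > 0, mu_a, 1.0), np.inf) + alpha)
            / ia.size
            + (np.where(mu_b > 0, 1.0 / np.where(mu_b > 0, mu_b, 1.0), np.inf) + alpha)
            / ib.size
        )
    se = np.sqrt(var_ln) / np.log(2)
    z = np.where(np.isfinite(se) & (se > 0), l2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))
    res = pd.DataFrame({
        "feature_id": counts.index,
        "baseMean": norm.mean(axis=1),
        "log2FoldChange": l2fc,
        "lfcSE": se,
        "stat": z,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
    }).set_index("feature_id", drop=False)
    res["zero_group"] = (mu_a == 0) | (mu_b == 0)
    res.attrs["test"] = "wald"
    res.attrs["contrast"] = (stage, other)
    return res


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB log-likelihood; k integer counts, mu broadcastable."""
    r = 1.0 / alpha[:, None]
    mu = np.maximum(mu, 1e-12)
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p).sum(axis=1)


def lrt_test(counts: pd.DataFrame, stages: pd.Series) -> pd.DataFrame:
    """Across-stage likelihood-ratio test per feature.

    Full model: one NB mean per stage; reduced: a single mean.  The same
    gene-wise dispersion (from full-model within-stage moments) is used for
    both fits; the deviance difference is referred to chi^2 with
    (n_stages - 1) degrees of freedom.
    """
    stage_names = list(dict.fromkeys(stages))
    if len(stage_names) < 2:
        raise DesignError("LRT needs at least 2 stages")
    sf = size_factors(counts)
    norm = (counts / sf).to_numpy(dtype=float)
    raw = counts.to_numpy(dtype=np.int64)
    sf_v = sf.to_numpy()
    lab = stages.loc[counts.columns].to_numpy()
    groups = [np.flatnonzero(lab == s) for s in stage_names]
    alpha = _dispersion_mom(norm, groups)
    # stage-mean fit: MLE of the NB mean at fixed dispersion is the group mean
    mu_full = np.empty_like(norm)
    for idx in groups:
        mu_full[:, idx] = norm[:, idx].mean(axis=1)[:, None]
    mu_red = norm.mean(axis=1)[:, None] * np.ones_like(norm)
    ll_full = _nb_loglik(raw, mu_full * sf_v[None, :], alpha)
    ll_red = _nb_loglik(raw, mu_red * sf_v[None, :], alpha)
    stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    df = len(stage_names) - 1
    pvalue = stats.chi2.sf(stat, df)
    res = pd.DataFrame({
        "feature_id": counts.index,
        "baseMean": norm.mean(axis=1),
        "log2FoldChange": np.log2(
            (np.max([norm[:, g].mean(axis=1) for g in groups], axis=0) + 0.5)
            / (np.min([norm[:, g].mean(axis=1) for g in groups], axis=0) + 0.5)
        ),
        "lfcSE": np.nan,
        "stat": stat,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
    }).set_index("feature_id", drop=False)
    res.attrs["test"] = "lrt"
    res.attrs["stages"] = stage_names
    return res


def base_means(counts: pd.DataFrame, stages: pd.Series,
               pseudo_reference: bool = False) -> pd.DataFrame:
    """Per-stage means of size-factor-normalized counts (plus overall)."""
    sf = size_factors(counts, pseudo_reference=pseudo_reference)
    norm = counts / sf
    out = pd.DataFrame(index=counts.index)
    for stage in dict.fromkeys(stages):
        out[stage] = norm[stages.index[stages == stage]].mean(axis=1)
    out["overall"] = norm.mean(axis=1)
    return out
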