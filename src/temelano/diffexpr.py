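"""Negative-binomial differential expression, from first principles.

The model is the standard two-group RNA-seq workhorse: counts K_fs for
family f in sample s are NB with mean sf_s * mu_{f,cond(s)} and variance
mu + alpha * mu^2. Size factors come from the median-of-ratios estimator;
per-family dispersions from a method-of-moments fit on normalized counts
(no empirical-Bayes shrinkage — a documented simplification); the log2 fold
change tg vs wildtype is tested with a Wald statistic whose standard error
follows from the delta method on the NB variances. p-values are referred to
a t distribution with n_a + n_b - 2 degrees of freedom: with plug-in
method-of-moments dispersions the plain normal reference is anticonservative
at typical group sizes, and the t reference restores finite-sample
calibration while converging to the normal for large designs.

Selection of differentially expressed families follows the study's rule:
|log2FC| > 1, raw p < 0.05 and baseMean > 100 (all strict); BH-adjusted
p-values are reported alongside.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix
from .qpcr import mann_whitney_exact

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame | CountMatrix,
                 pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over families of count[f][s] / geomean_f, where the
    geometric mean runs over samples and families containing any zero are
    excluded. With `pseudo_reference=True` the geometric mean is taken over
    positive entries only, a fallback for sparse matrices.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(mat > 0, np.log(np.where(mat > 0, mat, 1.0)), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        usable = ~np.isnan(log_gm)
    else:
        usable = (mat > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no family with all-positive counts; re-run with "
                "pseudo_reference=True to use a positive-entry reference")
        log_gm = np.full(mat.shape[0], np.nan)
        log_gm[usable] = np.log(mat[usable]).mean(axis=1)
    ratios = mat[usable] / np.exp(log_gm[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(cm: CountMatrix, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(cm)
    return cm.counts / factors


def dispersion_mom(cm: CountMatrix, factors: Optional[pd.Series] = None) -> pd.Series:
    """Method-of-moments NB dispersion per family.

    alpha = max(0, (pooled within-condition variance of normalized counts
    - mean) / mean^2), floored at 1e-8. All-zero families are NaN
    (untestable).
    """
    q = normalized_counts(cm, factors)
    conds = sorted(set(cm.conditions.values()))
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    group_cols = [cm.samples_of(c) for c in conds]
    if any(len(g) < 2 for g in group_cols):
        raise ValueError("need >= 2 samples per condition")
    qn = q.to_numpy()
    idx = [np.array([q.columns.get_loc(s) for s in g]) for g in group_cols]
    # pooled within-condition variance (ddof=1 per group, df-weighted)
    dfs = np.array([len(g) - 1 for g in group_cols], dtype=float)
    variances = np.stack([qn[:, i].var(axis=1, ddof=1) for i in idx])
    pooled_var = (variances * dfs[:, None]).sum(axis=0) / dfs.sum()
    mean = qn.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum(0.0, (pooled_var - mean) / mean ** 2)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    alpha[mean == 0] = np.nan
    return pd.Series(alpha, index=q.index, name="dispersion")


def wald_de_test(cm: CountMatrix,
                 conditions: tuple[str, str] = ("wildtype", "tg"),
                 factors: Optional[pd.Series] = None,
                 dispersions: Optional[pd.Series] = None,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-family NB Wald test of log2FC (condition B vs condition A).

    Returns a DataFrame with baseMean, log2FC, se, p, padj (BH over tested
    families). Untestable families (all-zero) get NaN p and padj.
    `pseudocount` is added to a condition mean only when that mean is zero.
    """
    cond_a, cond_b = conditions
    if factors is None:
        factors = size_factors(cm)
    if dispersions is None:
        dispersions = dispersion_mom(cm, factors)
    q = normalized_counts(cm, factors)
    cols_a, cols_b = cm.samples_of(cond_a), cm.samples_of(cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per condition")
    sf = factors.to_numpy()
    sf_a = factors[cols_a].to_numpy()
    sf_b = factors[cols_b].to_numpy()
    qa, qb = q[cols_a].to_numpy(), q[cols_b].to_numpy()
    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)
    base_mean = q.to_numpy().mean(axis=1)
    alpha = dispersions.reindex(q.index).to_numpy()

    ma = np.where(mean_a == 0, pseudocount, mean_a)
    mb = np.where(mean_b == 0, pseudocount, mean_b)
    lfc = np.log2(mb / ma)
    n_a, n_b = len(cols_a), len(cols_b)
    # delta method: Var(mean_c) = (1/n^2) sum_s (mu_c / sf_s + alpha mu_c^2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = (ma[:, None] / sf_a[None, :] + alpha[:, None] * ma[:, None] ** 2
                 ).sum(axis=1) / n_a ** 2
        var_b = (mb[:, None] / sf_b[None, :] + alpha[:, None] * mb[:, None] ** 2
                 ).sum(axis=1) / n_b ** 2
        se = np.sqrt(var_a / ma ** 2 + var_b / mb ** 2) / np.log(2.0)
        z = lfc / se
    p = 2.0 * stats.t.sf(np.abs(z), df=n_a + n_b - 2)
    testable = ~np.isnan(p)
    padj = np.full_like(p, np.nan)
    if testable.any():
        padj[testable] = multipletests(p[testable], method="fdr_bh")[1]
    res = pd.DataFrame({
        "baseMean": base_mean,
        "log2FC": np.where(testable, lfc, np.nan),
        "se": se,
        "p": p,
        "padj": padj,
    }, index=q.index)
    res.index.name = "family_id"
    res.loc[~testable, "baseMean"] = base_mean[~testable]  # 0 for all-zero rows
    return res


def select_de(results: pd.DataFrame,
              min_abs_lfc: float = 1.0,
              max_p: float = 0.05,
              min_basemean: float = 100.0) -> pd.DataFrame:
    """The study's selection rule, all inequalities strict:
    |log2FC| > 1, p < 0.05, baseMean > 100; adds a direction column."""
    mask = ((results["log2FC"].abs() > min_abs_lfc)
            & (results["p"] < max_p)
            & (results["baseMean"] > min_basemean))
    sel = results[mask.fillna(False)].copy()
    sel["direction"] = np.where(sel["log2FC"] > 0, "up", "down")
    return sel


def expressed_census(cm: CountMatrix, class_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-class counts of expressed families (>= 1 raw read over all
    samples) and their percentage of the expressed total."""
    totals = cm.counts.sum(axis=1)
    expressed = totals[totals >= 1].index
    classes = pd.Series({f: class_of.get(f, "Unknown") for f in expressed})
    if len(expressed) == 0:
        return pd.DataFrame(columns=["n_expressed", "pct"])
    tab = classes.value_counts().to_frame("n_expressed")
    tab["pct"] = tab["n_expressed"] / tab["n_expressed"].sum() * 100.0
    tab.index.name = "class"
    return tab


def class_aggregate_test(cm: CountMatrix,
                         class_of: Mapping[str, str],
                         conditions: tuple[str, str] = ("wildtype", "tg"),
                         factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-class sums of normalized counts compared between conditions with
    the exact two-sided Mann-Whitney U test."""
    cond_a, cond_b = conditions
    cols_a, cols_b = cm.samples_of(cond_a), cm.samples_of(cond_b)
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("need >= 3 samples per condition for the exact test")
    q = normalized_counts(cm, factors)
    cls = pd.Series({f: class_of.get(f, "Unknown") for f in q.index})
    rows = []
    for c in sorted(cls.unique()):
        fams = cls[cls == c].index
        sums_a = q.loc[fams, cols_a].sum(axis=0).to_numpy()
        sums_b = q.loc[fams, cols_b].sum(axis=0).to_numpy()
        u, p = mann_whitney_exact(sums_a, sums_b)
        rows.append({"class": c,
                     "mean_sum_a": float(sums_a.mean()),
                     "mean_sum_b": float(sums_b.mean()),
                     "U": u, "p": p})
    return pd.DataFrame(rows).set_index("class")
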