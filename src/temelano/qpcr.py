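"""qPCR validation statistics.

Relative expression by the 2^-dCt method (target Ct normalized to a
reference gene, efa1 in the medaka experiments) and exact Mann-Whitney U
tests between groups. The exact two-sided p-value is obtained by full
enumeration of group assignments for small samples and by a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

_EPS = 1e-9


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference)."""
    return float(2.0 ** -(ct_target - ct_reference))


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney_exact(group_a: Sequence[float], group_b: Sequence[float],
                       exact_limit: int = 16) -> tuple[float, float]:
    """Mann-Whitney U with exact two-sided p for small samples.

    U is computed from midrank sums. For n_a + n_b <= `exact_limit` the null
    distribution of U is enumerated over all C(n, n_a) equally likely group
    assignments (valid under ties because midranks are fixed); the two-sided
    p doubles the smaller tail, capped at 1. Larger samples use the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray([x for x in group_a if not np.isnan(x)], dtype=float)
    b = np.asarray([x for x in group_b if not np.isnan(x)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain values")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)  # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)

    if n <= exact_limit:
        offset = n_a * (n_a + 1) / 2
        lower = higher = 0
        total = comb(n, n_a)
        for idx in combinations(range(n), n_a):
            u = ranks[list(idx)].sum() - offset
            if u <= u_obs + _EPS:
                lower += 1
            if u >= u_obs - _EPS:
                higher += 1
        p = 2.0 * min(lower, higher) / total
        return u_obs, min(1.0, p)

    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mean_u) - 0.5) / sqrt(var_u)
    p = 2.0 * norm.sf(max(z, 0.0))
    return u_obs, min(1.0, p)


def analyze_ct_table(ct: pd.DataFrame,
                     reference_gene: str = "efa1",
                     target_genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-gene group comparison of 2^-dCt relative expression.

    Input columns: sample, group, gene, ct. Technical duplicates (several Ct
    records per sample/gene) are averaged to one Ct before analysis; samples
    lacking a reference-gene Ct are excluded. Returns one row per target
    gene and group pair with group medians, U and the exact two-sided p.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    mean_ct = (ct.groupby(["sample", "group", "gene"])["ct"].mean().reset_index())
    ref = (mean_ct[mean_ct["gene"] == reference_gene]
           .set_index("sample")["ct"])
    genes = (list(target_genes) if target_genes is not None
             else sorted(set(mean_ct["gene"]) - {reference_gene}))
    rows = []
    for gene in genes:
        sub = mean_ct[mean_ct["gene"] == gene].copy()
        sub = sub[sub["sample"].isin(ref.index)]
        sub["rel_expr"] = [relative_expression(t, ref[s])
                           for s, t in zip(sub["sample"], sub["ct"])]
        groups = sorted(sub["group"].unique())
        for g1, g2 in combinations(groups, 2):
            va = sub.loc[sub["group"] == g1, "rel_expr"].to_numpy()
            vb = sub.loc[sub["group"] == g2, "rel_expr"].to_numpy()
            u, p = mann_whitney_exact(va, vb)
            rows.append({"gene": gene, "group_a": g1, "group_b": g2,
                         "n_a": len(va), "n_b": len(vb),
                         "median_a": float(np.median(va)),
                         "median_b": float(np.median(vb)),
                         "U": u, "p": p})
    return pd.DataFrame(rows)
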