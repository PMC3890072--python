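"""Sex-stratified network comparison.

Partial correlations are re-estimated separately within each stratum of a
binary covariate (males/females in the motivating analysis), conditioning on
age and all other metabolites but deliberately not on the SNP block — the
halved sample sizes make the large joint variable set unreliable — and of
course not on the stratum variable itself, which is constant within a
stratum.  Each pair's stratum coefficients are then compared with the Fisher
z-test for partial correlations:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1 - k - 3) + 1/(n2 - k - 3))

with k the conditioning-set size, and a two-sided normal p-value.  Two
Bonferroni families are supported: the edges of the pooled network
(alpha / #edges) and all p(p-1)/2 metabolite pairs (alpha / #pairs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, CovariateTable
from .pcor import PcorResult, partial_correlation_matrix


def stratified_pcor(data: AbundanceMatrix, covariates: CovariateTable,
                    stratum_column: str = "sex",
                    conditioning: tuple[str, ...] = ("age",),
                    adjust_df: bool = True) -> dict[int, PcorResult]:
    """Full-conditional partial correlations within each level of a binary
    stratum column; SNP columns and the stratum variable are excluded from
    the conditioning set."""
    cov = covariates.aligned_to(data.sample_ids)
    strata = cov.table[stratum_column].to_numpy()
    levels = np.unique(strata)
    if levels.size != 2:
        raise ValueError(f"stratum column {stratum_column!r} must be binary, "
                         f"found levels {levels.tolist()}")
    results: dict[int, PcorResult] = {}
    for level in levels:
        rows = np.flatnonzero(strata == level)
        sub = data.subset(row_idx=rows)
        sub_cov = cov.aligned_to(sub.sample_ids).conditioning_frame(
            include=conditioning, include_snps=False, exclude=(stratum_column,))
        need = data.n_metabolites + sub_cov.shape[1] + 3
        if len(rows) < need:
            raise ValueError(
                f"stratum {stratum_column}={level} has n={len(rows)}; "
                f"need at least n={need} for inversion")
        results[int(level)] = partial_correlation_matrix(
            sub, sub_cov, adjust_df=adjust_df)
    return results


def fisher_compare(r1: float, n1: int, r2: float, n2: int,
                   k: int = 0, adjust_df: bool = True) -> tuple[float, float]:
    """Fisher z-test for the difference of two independent (partial)
    correlations; returns (z, two-sided p)."""
    for name, r in (("r1", r1), ("r2", r2)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    kk = k if adjust_df else 0
    d1, d2 = n1 - kk - 3, n2 - kk - 3
    if d1 < 1 or d2 < 1:
        raise ValueError(f"insufficient stratum sizes n1={n1}, n2={n2} "
                         f"for conditioning-set size k={k}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / d1 + 1.0 / d2)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return float(z), p


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / m


def compare_all_pairs(strata_results: dict[int, PcorResult],
                      family: str = "all_pairs",
                      alpha: float = 0.05,
                      network_edges: list[tuple[str, str]] | None = None,
                      adjust_df: bool = True) -> pd.DataFrame:
    """Fisher comparison of stratum-specific partial correlations.

    ``family='all_pairs'`` tests every unordered metabolite pair at
    alpha / (p(p-1)/2); ``family='network_edges'`` tests only the supplied
    pooled-network edges at alpha / #edges.  Columns r_1/r_2, z, p and a
    ``significant`` flag; stratum order follows sorted stratum levels.
    """
    if len(strata_results) != 2:
        raise ValueError("exactly two strata required")
    (lev1, res1), (lev2, res2) = sorted(strata_results.items())
    if res1.metabolite_ids != res2.metabolite_ids:
        raise ValueError("strata estimated on different metabolite sets")
    ids = res1.metabolite_ids
    index = {mid: i for i, mid in enumerate(ids)}

    if family == "all_pairs":
        pairs = [(ids[i], ids[j]) for i in range(len(ids))
                 for j in range(i + 1, len(ids))]
        m = len(pairs)
    elif family == "network_edges":
        if not network_edges:
            raise ValueError("family='network_edges' requires the pooled "
                             "network edge list")
        pairs = [tuple(sorted(e)) for e in network_edges]
        unknown = [e for e in pairs if e[0] not in index or e[1] not in index]
        if unknown:
            raise KeyError(f"network edges outside the metabolite set: {unknown[:5]}")
        m = len(pairs)
    else:
        raise ValueError(f"unknown family {family!r}")

    threshold = bonferroni_threshold(alpha, m)
    k = res1.k
    rows = []
    for a, b in pairs:
        i, j = index[a], index[b]
        z, p = fisher_compare(res1.r[i, j], res1.n, res2.r[i, j], res2.n,
                              k=k, adjust_df=adjust_df)
        rows.append((a, b, res1.r[i, j], res2.r[i, j], z, p, p < threshold))
    out = pd.DataFrame(rows, columns=["metabolite_1", "metabolite_2",
                                      f"r_{lev1}", f"r_{lev2}",
                                      "z", "p", "significant"])
    out.attrs.update({"family": family, "alpha": alpha, "m": m,
                      "threshold": threshold, "strata": (lev1, lev2), "k": k})
    return out
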