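"""Full-conditional partial correlations and FDR edge calling.

The estimator is the classical Gaussian-graphical-model one: form the joint
variable set (all metabolites plus the conditioning covariates), invert its
correlation matrix, and read each metabolite pair's partial correlation off
the precision matrix as rho_ij = -omega_ij / sqrt(omega_ii * omega_jj).
Inverting the correlation rather than the covariance matrix makes the result
invariant to per-variable rescaling and improves numerical conditioning.

Significance uses the Student-t statistic t = r * sqrt(df / (1 - r^2)) with
df = n - 2 - k, where k is the size of the conditioning set (all other
metabolites plus covariate columns).  With hundreds of conditioned variables
the df adjustment is material; it can be disabled to get the naive n - 2
convention.  Edge calling applies Benjamini-Hochberg (or optionally
Benjamini-Yekutieli) step-up control over the p(p-1)/2 unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

_TINY = np.finfo(float).tiny


class SingularityError(np.linalg.LinAlgError):
    """Joint correlation matrix is numerically singular."""


@dataclass
class PcorResult:
    r: np.ndarray                 # p x p partial correlations, diag 1
    pvals: np.ndarray             # p x p two-sided p-values, diag NaN
    n: int                        # samples
    k: int                        # conditioning-set size per pair
    metabolite_ids: list[str]

    @property
    def p(self) -> int:
        return self.r.shape[0]

    def pair_index(self) -> list[tuple[int, int]]:
        p = self.p
        return [(i, j) for i in range(p) for j in range(i + 1, p)]

    def upper_values(self) -> tuple[np.ndarray, np.ndarray]:
        iu = np.triu_indices(self.p, 1)
        return self.r[iu], self.pvals[iu]


@dataclass
class FdrDecision:
    q: float
    m: int
    data_driven_cutoff: float | None
    significant_mask: np.ndarray      # symmetric boolean p x p, diag False
    method: str = "bh"


def pcor_pvalues(r, n: int, k: int, adjust_df: bool = True):
    """Two-sided p-value for a (partial) correlation under Gaussianity.

    Accepts scalars or arrays.  ``|r| = 1`` is reported as the smallest
    positive float with a warning rather than zero.
    """
    r = np.asarray(r, dtype=float)
    df = (n - 2 - k) if adjust_df else (n - 2)
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom: n={n}, k={k}")
    at_unit = np.abs(r) >= 1.0
    if np.any(at_unit):
        warnings.warn("|partial correlation| = 1 encountered; p-value clipped "
                      "to the smallest positive float", RuntimeWarning,
                      stacklevel=2)
    safe = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    t = safe * np.sqrt(df / (1.0 - safe ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _TINY, 1.0)
    p = np.where(at_unit, _TINY, p)
    return p if p.ndim else float(p)


def partial_correlation_matrix(data: AbundanceMatrix,
                               covariates: pd.DataFrame | None = None,
                               ridge: float = 0.0,
                               adjust_df: bool = True) -> PcorResult:
    """Estimate the full-conditional partial-correlation matrix.

    ``covariates`` holds exactly the columns to condition on (e.g. age, sex
    and SNP dosages for the pooled network; age only within sex strata).
    Covariate rows/columns of the inverted matrix are used solely for
    conditioning and never reported.  ``ridge`` adds ridge * I to the joint
    correlation matrix before inversion; the default 0 fails loudly on a
    singular matrix rather than regularizing silently.
    """
    if data.missing_mask.any():
        raise ValueError("partial correlations require a complete (imputed) matrix")
    x = data.values
    names = list(data.metabolite_ids)
    if covariates is not None and covariates.shape[1] > 0:
        if list(covariates.index) != list(data.sample_ids):
            covariates = covariates.loc[data.sample_ids]
        x = np.column_stack([x, covariates.to_numpy(dtype=float)])
        names = names + list(covariates.columns)
    n, total = x.shape
    p = data.n_metabolites
    q = total - p

    spread = np.ptp(x, axis=0)
    constant = [names[j] for j in np.flatnonzero(spread == 0)]
    if constant:
        raise ValueError(f"constant columns cannot be conditioned on: {constant}")
    if n <= total + 2 and ridge <= 0:
        raise ValueError(
            f"n={n} too small for {total} joint variables (need n > p+q+2); "
            "pass ridge > 0 or reduce the variable set")

    corr = np.corrcoef(x, rowvar=False)
    if ridge > 0:
        corr = corr + ridge * np.eye(total)
    eigmin = np.linalg.eigvalsh(corr)[0]
    if eigmin < 1e-12:
        raise SingularityError(
            f"joint correlation matrix singular (lambda_min={eigmin:.3g}); "
            "set ridge > 0 or remove collinear variables")
    omega = np.linalg.inv(corr)

    om = omega[:p, :p]
    d = np.sqrt(np.diag(om))
    r = -om / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    k = p - 2 + q
    off_diag = r.copy()
    np.fill_diagonal(off_diag, 0.0)     # diagonal carries no test
    pv = np.asarray(pcor_pvalues(off_diag, n, k, adjust_df=adjust_df))
    np.fill_diagonal(pv, np.nan)
    return PcorResult(r=r, pvals=pv, n=n, k=k, metabolite_ids=data.metabolite_ids)


def fdr_cutoff(pvals, q: float = 0.05, method: str = "bh") -> float | None:
    """Data-driven step-up cutoff for a flat p-value collection: the largest
    p-value declared significant, or None if nothing is."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(~((pvals > 0) & (pvals <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown fdr method {method!r} (use 'bh' or 'by')")
    reject = multipletests(pvals, alpha=q, method=key)[0]
    return float(pvals[reject].max()) if reject.any() else None


def bh_fdr(pcor: PcorResult, q: float = 0.05, method: str = "bh") -> FdrDecision:
    """Call significant edges by step-up FDR over all unordered pairs.

    ``method`` is ``"bh"`` (Benjamini-Hochberg, independence/PRDS) or
    ``"by"`` (Benjamini-Yekutieli, arbitrary dependence).  The returned
    decision records the data-driven cutoff: the largest p-value among
    declared-significant pairs (None if nothing is significant).
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0,1), got {q}")
    p = pcor.p
    iu = np.triu_indices(p, 1)
    pvals = pcor.pvals[iu]
    if pvals.size == 0:
        raise ValueError("no metabolite pairs to test")
    cutoff = fdr_cutoff(pvals, q=q, method=method)
    mask = np.zeros((p, p), dtype=bool)
    if cutoff is not None:
        sig = pvals <= cutoff
        mask[iu] = sig
        mask |= mask.T
    return FdrDecision(q=q, m=int(pvals.size), data_driven_cutoff=cutoff,
                       significant_mask=mask, method=method.lower())
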