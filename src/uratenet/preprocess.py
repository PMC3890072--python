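"""Data-reduction chain for metabolite abundance matrices.

Order of operations: run-day median normalization on raw ion counts, then
missingness filtering (metabolites before samples), natural-log transform,
chained-equations imputation, and finally removal of duplicate analytes.
Each step consumes a matrix at one stage tag and emits the next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AbundanceMatrix, StageError

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Record of the two-pass missingness filter (metabolites first)."""

    dropped_metabolites: list[tuple[str, float]] = field(default_factory=list)
    dropped_samples: list[tuple[str, float]] = field(default_factory=list)
    n_before: int = 0
    p_before: int = 0
    n_after: int = 0
    p_after: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_metabolites": [{"id": m, "missing_fraction": f}
                                    for m, f in self.dropped_metabolites],
            "dropped_samples": [{"id": s, "missing_fraction": f}
                                for s, f in self.dropped_samples],
            "n_before": self.n_before, "p_before": self.p_before,
            "n_after": self.n_after, "p_after": self.p_after,
        }


def runday_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each observed value by the median of observed values of the
    same metabolite within the same run day.

    Raw ion counts must be strictly positive (they are logged later).  A
    run-day x metabolite group with no observed value keeps its cells
    missing; the missing mask is never altered.
    """
    if m.stage != "raw":
        raise StageError(f"runday_normalize expects stage 'raw', got {m.stage!r}")
    obs = ~m.missing_mask
    if np.any(m.values[obs] <= 0):
        n_bad = int(np.sum(m.values[obs] <= 0))
        raise ValueError(f"{n_bad} non-positive observed ion counts; "
                         "cannot normalize/log")
    out = m.values.copy()
    for day in np.unique(m.runday):
        rows = m.runday == day
        block = out[rows]
        observed_any = ~np.isnan(block).all(axis=0)
        med = np.full(block.shape[1], np.nan)
        med[observed_any] = np.nanmedian(block[:, observed_any], axis=0)
        out[rows] = block / med[None, :]    # all-missing groups stay missing
    return m.advance(out, "normalized")


def filter_missingness(m: AbundanceMatrix,
                       metabolite_threshold: float = 0.20,
                       sample_threshold: float = 0.10) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop metabolites with missing fraction strictly above
    ``metabolite_threshold``, then — on the reduced matrix — samples strictly
    above ``sample_threshold``.  The order matters and is fixed.
    """
    if m.stage not in ("normalized", "filtered"):
        raise StageError("filter_missingness expects stage 'normalized' "
                         f"(or 'filtered' for a re-run), got {m.stage!r}")
    for name, t in (("metabolite_threshold", metabolite_threshold),
                    ("sample_threshold", sample_threshold)):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must be in [0,1], got {t}")
    report = FilterReport(n_before=m.n_samples, p_before=m.n_metabolites)

    col_frac = m.missing_mask.mean(axis=0)
    keep_cols = np.flatnonzero(col_frac <= metabolite_threshold)
    report.dropped_metabolites = [(m.metabolite_ids[j], float(col_frac[j]))
                                  for j in np.flatnonzero(col_frac > metabolite_threshold)]
    if keep_cols.size == 0:
        raise ValueError("missingness filter dropped every metabolite")
    reduced = m.subset(col_idx=keep_cols)

    row_frac = reduced.missing_mask.mean(axis=1)
    keep_rows = np.flatnonzero(row_frac <= sample_threshold)
    report.dropped_samples = [(reduced.sample_ids[i], float(row_frac[i]))
                              for i in np.flatnonzero(row_frac > sample_threshold)]
    if keep_rows.size == 0:
        raise ValueError("missingness filter dropped every sample")
    reduced = reduced.subset(row_idx=keep_rows)

    report.n_after, report.p_after = reduced.n_samples, reduced.n_metabolites
    logger.info("missingness filter: %d -> %d metabolites, %d -> %d samples",
                report.p_before, report.p_after, report.n_before, report.n_after)
    if m.stage == "normalized":
        reduced = reduced.advance(reduced.values, "filtered")
    return reduced, report


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Natural log of every observed value; missing cells untouched."""
    if m.stage != "filtered":
        raise StageError(f"log_transform expects stage 'filtered', got {m.stage!r}")
    obs = ~m.missing_mask
    bad = obs & (m.values <= 0)
    if np.any(bad):
        cells = list(zip(*np.nonzero(bad)))[:10]
        named = [(m.sample_ids[i], m.metabolite_ids[j]) for i, j in cells]
        raise ValueError(f"non-positive observed values at {named}")
    with np.errstate(invalid="ignore"):
        return m.advance(np.log(m.values), "logged")


def impute(m: AbundanceMatrix, n_iterations: int = 10, seed: int = 0,
           deterministic: bool = False, max_predictors: int | None = 10,
           min_abs_corr: float = 0.1) -> AbundanceMatrix:
    """Single-imputation chained equations on the logged matrix.

    Missing cells start at their metabolite's observed mean; then, in fixed
    input column order, each metabolite with missing cells is regressed on
    other metabolites over its observed samples and its missing cells are
    replaced by the predictions plus residual-scaled Gaussian noise
    (``deterministic=True`` drops the noise).  Observed values are never
    altered.  A singular chained regression falls back to mean imputation
    for that metabolite with a logged warning.

    Imputation models use a screened predictor set — the ``max_predictors``
    metabolites most correlated with the target, among those with absolute
    correlation at least ``min_abs_corr`` (recomputed from the completed
    matrix each iteration; ``max_predictors=None`` uses all metabolites).
    Beyond being standard practice for wide matrices, the restriction keeps
    imputation error from leaking every metabolite into every imputed cell,
    which would otherwise distort the downstream full-conditional network.
    """
    if m.stage != "logged":
        raise StageError(f"impute expects stage 'logged', got {m.stage!r}")
    mask = m.missing_mask
    n_obs = (~mask).sum(axis=0)
    thin = np.flatnonzero(n_obs < 2)
    if thin.size:
        names = [m.metabolite_ids[j] for j in thin]
        raise ValueError(f"metabolites with fewer than 2 observed values: {names}")

    x = m.values.copy()
    if not mask.any():
        return m.advance(x, "imputed")

    rng = np.random.default_rng(seed)
    col_means = np.nansum(np.where(mask, 0.0, x), axis=0) / n_obs
    x[mask] = np.take(col_means, np.nonzero(mask)[1])

    targets = [j for j in range(m.n_metabolites) if mask[:, j].any()]
    p = m.n_metabolites
    for _ in range(n_iterations):
        if max_predictors is not None and p > 2:
            with np.errstate(invalid="ignore"):
                corr = np.abs(np.corrcoef(x, rowvar=False))
            np.fill_diagonal(corr, 0.0)
            corr = np.nan_to_num(corr)
        for j in targets:
            if max_predictors is None or p <= 2:
                others = [c for c in range(p) if c != j]
            else:
                ranked = np.argsort(corr[:, j])[::-1]
                others = [int(c) for c in ranked[:max_predictors]
                          if corr[c, j] >= min_abs_corr]
                if not others:
                    x[mask[:, j], j] = col_means[j]
                    continue
            obs = ~mask[:, j]
            design = np.column_stack([np.ones(obs.sum()), x[obs][:, others]])
            beta, _, rank, _ = np.linalg.lstsq(design, x[obs, j], rcond=None)
            if rank < design.shape[1]:
                logger.warning("singular chained regression for %s; "
                               "falling back to mean imputation",
                               m.metabolite_ids[j])
                x[mask[:, j], j] = col_means[j]
                continue
            pred_design = np.column_stack([np.ones(mask[:, j].sum()),
                                           x[mask[:, j]][:, others]])
            pred = pred_design @ beta
            if not deterministic:
                resid = x[obs, j] - design @ beta
                dof = max(1, obs.sum() - design.shape[1])
                pred = pred + rng.normal(0.0, np.sqrt(resid @ resid / dof),
                                         pred.shape)
            x[mask[:, j], j] = pred
    return m.advance(x, "imputed")


def drop_duplicates(m: AbundanceMatrix, duplicate_ids: list[str]) -> AbundanceMatrix:
    """Remove duplicate-analyte columns; every other column and all rows
    are untouched (stage is preserved)."""
    unknown = [d for d in duplicate_ids if d not in m.metabolite_ids]
    if unknown:
        raise KeyError(f"unknown metabolite ids: {unknown}")
    if not duplicate_ids:
        return m
    keep = [j for j, mid in enumerate(m.metabolite_ids) if mid not in set(duplicate_ids)]
    return m.subset(col_idx=np.array(keep))
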