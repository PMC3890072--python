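"""Per-metabolite covariate effect models.

Each network metabolite's log abundance is regressed on sex and
urate-lowering medication with age adjustment, by ordinary least squares.
Sex is coded 0 = male / 1 = female and medication 0 = untreated /
1 = treated, so a beta is the additive shift in natural-log abundance for
females vs males, or treated vs untreated.  The default fits one joint
model (abundance ~ sex + medication + age); a 'separate' form fits the two
predictors in independent age-adjusted models.  Significance uses a
Bonferroni family of (#metabolites x #predictors) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AbundanceMatrix, CovariateTable


@dataclass(frozen=True)
class EffectEstimate:
    metabolite: str
    predictor: str
    beta: float
    se: float
    p: float
    significant: bool | None = None


def fit_effects(data: AbundanceMatrix, covariates: CovariateTable,
                metabolite_set: list[str] | None = None,
                model_form: str = "joint",
                predictors: tuple[str, ...] = ("sex", "medication"),
                adjust_for: tuple[str, ...] = ("age",)) -> list[EffectEstimate]:
    """OLS effect estimates per metabolite and predictor on the log scale."""
    if model_form not in ("joint", "separate"):
        raise ValueError(f"model_form must be 'joint' or 'separate', got {model_form!r}")
    if data.missing_mask.any():
        raise ValueError("effect models require a complete (imputed) matrix")
    cov = covariates.aligned_to(data.sample_ids).table
    for col in (*predictors, *adjust_for):
        if col not in cov.columns:
            raise KeyError(f"covariate column {col!r} not found")
        if cov[col].nunique() < 2:
            raise ValueError(f"predictor {col!r} is constant; model is collinear")

    ids = metabolite_set if metabolite_set is not None else list(data.metabolite_ids)
    unknown = [m for m in ids if m not in data.metabolite_ids]
    if unknown:
        raise KeyError(f"metabolites not in matrix: {unknown}")

    def design(cols: tuple[str, ...]) -> pd.DataFrame:
        return sm.add_constant(cov[list(cols)].astype(float), has_constant="add")

    estimates: list[EffectEstimate] = []
    if model_form == "joint":
        x = design((*predictors, *adjust_for))
        for mid in ids:
            fit = sm.OLS(data.column(mid), x).fit()
            for pred in predictors:
                estimates.append(EffectEstimate(mid, pred,
                                                float(fit.params[pred]),
                                                float(fit.bse[pred]),
                                                float(fit.pvalues[pred])))
    else:
        for pred in predictors:
            x = design((pred, *adjust_for))
            for mid in ids:
                fit = sm.OLS(data.column(mid), x).fit()
                estimates.append(EffectEstimate(mid, pred,
                                                float(fit.params[pred]),
                                                float(fit.bse[pred]),
                                                float(fit.pvalues[pred])))
        # stable output order: by metabolite, then predictor
        order = {m: i for i, m in enumerate(ids)}
        estimates.sort(key=lambda e: (order[e.metabolite],
                                      predictors.index(e.predictor)))
    return estimates


def family_threshold(n_metabolites: int, n_predictors: int = 2,
                     alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / (n_metabolites * n_predictors)."""
    if n_metabolites < 1 or n_predictors < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / (n_metabolites * n_predictors)


def flag_significance(estimates: list[EffectEstimate],
                      threshold: float) -> list[EffectEstimate]:
    return [EffectEstimate(e.metabolite, e.predictor, e.beta, e.se, e.p,
                           e.p < threshold) for e in estimates]


def effects_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Wide table with one row per metabolite: beta/p per predictor plus
    significance flags (mirrors the usual reporting layout)."""
    long = pd.DataFrame([e.__dict__ for e in estimates])
    wide = long.pivot(index="metabolite", columns="predictor")
    cols = {}
    for pred in long["predictor"].unique():
        cols[f"beta_{pred}"] = wide[("beta", pred)]
        cols[f"p_{pred}"] = wide[("p", pred)]
        if wide[("significant", pred)].notna().any():
            cols[f"significant_{pred}"] = wide[("significant", pred)]
    out = pd.DataFrame(cols)
    out.index.name = "metabolite"
    return out.sort_index()
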