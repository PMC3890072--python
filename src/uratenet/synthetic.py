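"""Synthetic cohort generation with a planted Gaussian graphical model.

The restricted-access cohort the method was designed for cannot be shipped,
so this module generates cohorts with the same statistical anatomy: latent
log-abundances drawn from a multivariate normal whose precision matrix has a
known sparse off-diagonal support (the planted edges), additive covariate
effects on the log scale (age, sex, urate-lowering medication, SNP dosages),
multiplicative run-day batch factors, missing cells, and one duplicate
analyte measured twice with a controlled Pearson correlation to its source
(the xanthine / alternate-xanthine situation).  The planted truth is kept
alongside the cohort so network recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, CovariateTable

_PD_MARGIN = 5e-2          # smallest eigenvalue enforced on the precision matrix
_MAX_PD_ROUNDS = 64

Edge = tuple[int, int]


class InfeasibleTruthError(ValueError):
    """Planted density/magnitude combination cannot be made positive definite."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: precision matrix, edge support, realized partial
    correlations, covariate effect sizes (natural-log scale per unit of the
    covariate) and the duplicate-analyte specification."""

    precision: np.ndarray
    planted_edges: frozenset[Edge]
    planted_pcor: dict[Edge, float]
    covariate_effects: dict[tuple[int, str], float]
    duplicate_spec: tuple[int, float] | None
    seed: int

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def validate(self) -> None:
        omega = self.precision
        if not np.allclose(omega, omega.T):
            raise ValueError("precision not symmetric")
        lam = np.linalg.eigvalsh(omega)[0]
        if lam <= 0:
            raise ValueError(f"precision not positive definite (lambda_min={lam:g})")
        d = np.sqrt(np.diag(omega))
        for (i, j), rho in self.planted_pcor.items():
            if abs(-omega[i, j] / (d[i] * d[j]) - rho) > 1e-10:
                raise ValueError(f"planted pcor inconsistent at edge {(i, j)}")
        support = {(i, j) for i in range(self.p) for j in range(i + 1, self.p)
                   if omega[i, j] != 0.0}
        if support != set(self.planted_edges):
            raise ValueError("off-diagonal support does not match planted edge set")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distributions of the cohort covariates.

    Defaults follow the cohort the pipeline emulates: ages 32-81 years with
    mean ~60.9, slight female majority, urate-lowering medication in ~4.7 %
    of participants and strongly male-skewed, plus a handful of biallelic
    SNPs with additive dosage coding.
    """

    age_mean: float = 60.9
    age_sd: float = 11.0
    age_range: tuple[float, float] = (32.0, 81.0)
    female_fraction: float = 908 / 1764
    medication_prev_female: float = 17 / 908
    medication_prev_male: float = 66 / 856
    n_snps: int = 3
    snp_maf: float = 0.3


@dataclass(frozen=True)
class SyntheticCohort:
    abundance: AbundanceMatrix
    covariates: CovariateTable
    truth: SyntheticTruth
    metabolite_index: dict[str, int] = field(default_factory=dict)
    duplicate_id: str | None = None


@dataclass(frozen=True)
class RecoveryReport:
    tpr: float
    fdp: float
    n_planted: int
    n_recovered: int
    n_true_positive: int
    edge_errors: dict[Edge, float]   # estimated - planted, per planted recovered edge


def generate_truth(p: int,
                   edge_density: float,
                   pcor_magnitude_range: tuple[float, float],
                   seed: int,
                   covariate_effects: dict[tuple[int, str], float] | None = None,
                   duplicate_spec: tuple[int, float] | None = None) -> SyntheticTruth:
    """Plant a sparse precision matrix with known partial correlations.

    Each unordered pair carries an edge independently with probability
    ``edge_density``; edge partial-correlation magnitudes are uniform on the
    given range with random sign.  Positive definiteness is enforced by
    inflating the diagonal in bounded rounds, and the realized partial
    correlations are then re-read from the final matrix, so the recorded
    ``planted_pcor`` is exact by construction.
    """
    low, high = pcor_magnitude_range
    if p < 3:
        raise ValueError(f"need p >= 3 metabolites, got {p}")
    if not (0.0 < edge_density < 1.0):
        raise ValueError(f"edge_density must be in (0,1), got {edge_density}")
    if not (0.0 < low <= high < 1.0):
        raise ValueError(f"invalid magnitude range {pcor_magnitude_range}")
    n_pairs = p * (p - 1) // 2
    if edge_density * n_pairs < 1.0:
        raise ValueError("expected edge count below 1; raise density or p")

    rng = np.random.default_rng(seed)
    omega = np.eye(p)
    edges: list[Edge] = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_density:
                rho = rng.uniform(low, high) * (1.0 if rng.random() < 0.5 else -1.0)
                # with unit diagonal, pcor_ij = -omega_ij
                omega[i, j] = omega[j, i] = -rho
                edges.append((i, j))

    for _ in range(_MAX_PD_ROUNDS):
        lam_min = np.linalg.eigvalsh(omega)[0]
        if lam_min >= _PD_MARGIN * (1.0 - 1e-9):
            break
        omega[np.diag_indices(p)] += _PD_MARGIN - lam_min + 1e-12
    else:
        raise InfeasibleTruthError(
            f"could not make precision positive definite at p={p}, "
            f"density={edge_density}, range={pcor_magnitude_range}")

    # standardize so the implied covariance has unit variances: a diagonal
    # congruence D^(1/2) Omega D^(1/2) leaves every partial correlation and
    # the edge support unchanged but pins each metabolite's latent variance
    # at 1, keeping covariate effect sizes on a fixed scale
    s = np.sqrt(np.diag(np.linalg.inv(omega)))
    omega = omega * np.outer(s, s)

    d = np.sqrt(np.diag(omega))
    planted_pcor = {(i, j): float(-omega[i, j] / (d[i] * d[j])) for i, j in edges}
    truth = SyntheticTruth(precision=omega,
                           planted_edges=frozenset(edges),
                           planted_pcor=planted_pcor,
                           covariate_effects=dict(covariate_effects or {}),
                           duplicate_spec=duplicate_spec,
                           seed=seed)
    truth.validate()
    return truth


def _draw_covariates(n: int, spec: CovariateSpec, rng: np.random.Generator,
                     sample_ids: list[str]) -> CovariateTable:
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range)
    sex = (rng.random(n) < spec.female_fraction).astype(int)
    prev = np.where(sex == 1, spec.medication_prev_female, spec.medication_prev_male)
    medication = (rng.random(n) < prev).astype(int)
    cols = {"age": np.round(age, 1), "sex": sex, "medication": medication}
    snp_names = [f"snp{i + 1}" for i in range(spec.n_snps)]
    for name in snp_names:
        cols[name] = rng.binomial(2, spec.snp_maf, n)
    table = pd.DataFrame(cols, index=sample_ids)
    return CovariateTable(table, snp_names)


def generate_cohort(truth: SyntheticTruth,
                    n: int,
                    covariate_spec: CovariateSpec | None = None,
                    n_rundays: int = 20,
                    runday_effect_sd: float = 0.1,
                    missing_rate: float = 0.1,
                    seed: int = 0,
                    missing_mechanism: str = "mcar",
                    metabolite_ids: list[str] | None = None) -> SyntheticCohort:
    """Draw a cohort from the planted model.

    Latent log-abundances are multivariate normal with covariance equal to
    the inverse planted precision, shifted per sample by the covariate
    effects.  The duplicate analyte is the source column plus independent
    noise calibrated so its Pearson correlation with the source hits the
    requested target.  Abundances are exponentiated to a raw ion-count
    scale, multiplied by per-(run day, metabolite) batch factors, and
    missing cells are injected either completely at random (``mcar``) or by
    left-censoring the lowest intensities (``censor``).
    """
    if n < 10:
        raise ValueError(f"need n >= 10 samples, got {n}")
    if missing_mechanism not in ("mcar", "censor"):
        raise ValueError(f"unknown missing mechanism {missing_mechanism!r}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing rate must be in [0,1), got {missing_rate}")
    truth.validate()
    spec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(seed)
    p = truth.p

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    if metabolite_ids is None:
        metabolite_ids = [f"met{j:03d}" for j in range(p)]
    if len(metabolite_ids) != p:
        raise ValueError("metabolite_ids length does not match truth dimension")

    covariates = _draw_covariates(n, spec, rng, sample_ids)

    sigma = np.linalg.inv(truth.precision)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:   # pragma: no cover - truth invariant
        raise RuntimeError("internal inconsistency: planted covariance "
                           "not positive definite") from exc
    log_x = rng.standard_normal((n, p)) @ chol.T

    baseline = rng.uniform(6.0, 12.0, p)    # baseline log ion counts
    log_x += baseline
    for (j, cov_name), effect in truth.covariate_effects.items():
        log_x[:, j] += effect * covariates.table[cov_name].to_numpy(dtype=float)

    ids = list(metabolite_ids)
    duplicate_id = None
    if truth.duplicate_spec is not None:
        src, target_r = truth.duplicate_spec
        if not (0.0 < target_r < 1.0):
            raise ValueError(f"duplicate target correlation must be in (0,1), got {target_r}")
        source = log_x[:, src]
        sd_src = float(np.std(source))
        noise_sd = sd_src * np.sqrt(1.0 / target_r ** 2 - 1.0)
        dup = source + rng.normal(0.0, noise_sd, n)
        log_x = np.column_stack([log_x, dup])
        duplicate_id = f"{ids[src]}_dup"
        ids = ids + [duplicate_id]

    raw = np.exp(log_x)

    # contiguous measurement-day blocks, multiplicative per-day drift per analyte
    runday_idx = (np.arange(n) * n_rundays) // n
    runday = np.array([f"day{d + 1:02d}" for d in runday_idx])
    factors = np.exp(rng.normal(0.0, runday_effect_sd, (n_rundays, raw.shape[1])))
    raw *= factors[runday_idx, :]

    if missing_rate > 0:
        if missing_mechanism == "mcar":
            raw[rng.random(raw.shape) < missing_rate] = np.nan
        else:
            # below-detection-limit: lowest missing_rate quantile per analyte
            cut = np.nanquantile(raw, missing_rate, axis=0)
            raw[raw < cut[None, :]] = np.nan

    abundance = AbundanceMatrix(sample_ids, ids, raw, runday, stage="raw")
    return SyntheticCohort(abundance=abundance,
                           covariates=covariates,
                           truth=truth,
                           metabolite_index={mid: j for j, mid in enumerate(ids)},
                           duplicate_id=duplicate_id)


def edge_recovery_metrics(estimated, truth: SyntheticTruth,
                          index_of: dict[str, int]) -> RecoveryReport:
    """Score a recovered network against the planted edge set.

    ``estimated`` is a networkx graph whose edges carry a ``pcor`` attribute;
    ``index_of`` maps its node names onto truth metabolite indices (the
    duplicate column, which has no truth index, must not appear).
    """
    unmapped = [v for v in estimated.nodes if v not in index_of]
    if unmapped:
        raise KeyError(f"graph nodes missing from index mapping: {unmapped[:5]}")
    recovered: dict[Edge, float] = {}
    for u, v, attrs in estimated.edges(data=True):
        i, j = sorted((index_of[u], index_of[v]))
        recovered[(i, j)] = float(attrs.get("pcor", np.nan))
    planted = set(truth.planted_edges)
    hits = set(recovered) & planted
    tpr = len(hits) / len(planted) if planted else 1.0
    fdp = len(set(recovered) - planted) / max(1, len(recovered))
    errors = {e: recovered[e] - truth.planted_pcor[e] for e in sorted(hits)}
    return RecoveryReport(tpr=tpr, fdp=fdp, n_planted=len(planted),
                          n_recovered=len(recovered), n_true_positive=len(hits),
                          edge_errors=errors)
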