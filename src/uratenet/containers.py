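"""Core in-memory containers for the pipeline.

An :class:`AbundanceMatrix` holds a samples x metabolites table of relative
ion intensities with missing cells encoded as NaN and a per-sample run-day
label.  Matrices carry a ``stage`` tag that advances monotonically through
the preprocessing chain (raw -> normalized -> filtered -> logged -> imputed)
so that each operation can assert it receives data at the right point of the
chain.

A :class:`CovariateTable` holds per-sample age (years), sex (0 = male,
1 = female), urate-lowering medication (0/1) and optional additive SNP
dosage columns in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "normalized", "filtered", "logged", "imputed")


class StageError(ValueError):
    """Raised when an operation receives a matrix at the wrong pipeline stage."""


@dataclass
class AbundanceMatrix:
    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray          # n x p floats, NaN = missing
    runday: np.ndarray          # n labels (strings)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.metabolite_ids = list(self.metabolite_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.runday = np.asarray(self.runday)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.metabolite_ids) != p:
            raise ValueError(f"{len(self.metabolite_ids)} metabolite ids for {p} columns")
        if len(self.runday) != n:
            raise ValueError(f"{len(self.runday)} run-day labels for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.metabolite_ids)) != p:
            raise ValueError("duplicate metabolite ids")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        observed = ~np.isnan(self.values)
        if not np.all(np.isfinite(self.values[observed])):
            raise ValueError("non-finite observed values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def advance(self, new_values: np.ndarray, new_stage: str) -> "AbundanceMatrix":
        """Return a copy at the next stage; transitions must follow STAGES order."""
        if STAGES.index(new_stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"illegal stage transition {self.stage!r} -> {new_stage!r}")
        return replace(self, values=np.asarray(new_values, dtype=float), stage=new_stage)

    def subset(self, row_idx: np.ndarray | None = None,
               col_idx: np.ndarray | None = None) -> "AbundanceMatrix":
        """Row/column subset preserving order; stage is kept unchanged."""
        out = self
        if row_idx is not None:
            row_idx = np.asarray(row_idx)
            out = replace(out,
                          sample_ids=[out.sample_ids[i] for i in row_idx],
                          values=out.values[row_idx],
                          runday=out.runday[row_idx])
        if col_idx is not None:
            col_idx = np.asarray(col_idx)
            out = replace(out,
                          metabolite_ids=[out.metabolite_ids[j] for j in col_idx],
                          values=out.values[:, col_idx])
        return out

    def column(self, metabolite_id: str) -> np.ndarray:
        try:
            j = self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.metabolite_ids)


@dataclass
class CovariateTable:
    """Per-sample covariates indexed by sample id.

    ``snp_columns`` names the additive-dosage columns so downstream steps can
    include or exclude the SNP block from a conditioning set.
    """

    table: pd.DataFrame
    snp_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in covariate table")
        missing = [c for c in self.snp_columns if c not in self.table.columns]
        if missing:
            raise ValueError(f"snp columns absent from table: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, sample_ids: list[str]) -> "CovariateTable":
        """Reindex to the given samples (e.g. after sample filtering)."""
        absent = set(sample_ids) - set(self.table.index)
        if absent:
            raise KeyError(f"samples missing from covariate table: {sorted(absent)[:5]}")
        return CovariateTable(self.table.loc[sample_ids], list(self.snp_columns))

    def conditioning_frame(self, include: tuple[str, ...] = ("age", "sex"),
                           include_snps: bool = True,
                           exclude: tuple[str, ...] = ()) -> pd.DataFrame:
        """Covariate columns to condition on, in a stable order."""
        cols = [c for c in include if c not in exclude]
        if include_snps:
            cols += [c for c in self.snp_columns if c not in exclude]
        absent = [c for c in cols if c not in self.table.columns]
        if absent:
            raise KeyError(f"covariate columns not found: {absent}")
        return self.table[cols]
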