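"""Plain-text readers and writers for every pipeline artifact.

Abundance matrices travel as TSV with samples in rows: a ``sample_id``
column, a ``runday`` column, then one column per metabolite.  Missing cells
are empty strings ("0" is the number zero, never missing).  Floats are
written with Python's shortest round-trip repr, so write -> read restores
values, missing mask and ordering exactly — which is what makes byte-level
rerun determinism checkable.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, CovariateTable
from .pcor import FdrDecision, PcorResult
from .synthetic import SyntheticTruth


class ParseError(ValueError):
    """Malformed tabular input; message carries the offending line number."""


def _fmt(x: float) -> str:
    return "" if np.isnan(x) else repr(float(x))


def write_abundance_tsv(m: AbundanceMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "runday", *m.metabolite_ids])
        for i, sid in enumerate(m.sample_ids):
            w.writerow([sid, str(m.runday[i]), *(_fmt(v) for v in m.values[i])])


def read_abundance_tsv(path, stage: str = "raw") -> AbundanceMatrix:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header[:2] != ["sample_id", "runday"]:
            raise ParseError(f"{path}: line 1: header must start with "
                             "'sample_id\\trunday'")
        met_ids = header[2:]
        if len(set(met_ids)) != len(met_ids):
            raise ParseError(f"{path}: line 1: duplicate metabolite ids")
        sample_ids, rundays, rows = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(header)} fields, got {len(row)}")
            sample_ids.append(row[0])
            rundays.append(row[1])
            vals = []
            for col, cell in zip(met_ids, row[2:]):
                if cell == "":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ParseError(f"{path}: line {lineno}: non-numeric "
                                         f"value {cell!r} in column {col!r}") from None
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return AbundanceMatrix(sample_ids, met_ids, np.array(rows, dtype=float),
                           np.array(rundays), stage=stage)


def write_covariates_tsv(c: CovariateTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *c.table.columns])
        for sid, row in c.table.iterrows():
            w.writerow([sid, *(repr(float(v)) if isinstance(v, float)
                               else str(v) for v in row)])


def read_covariates_tsv(path) -> CovariateTable:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or header[0] != "sample_id":
            raise ParseError(f"{path}: line 1: first column must be 'sample_id'")
        cols = header[1:]
        sample_ids, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(header)} fields, got {len(row)}")
            sample_ids.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    table = pd.DataFrame(rows, index=sample_ids, columns=cols)
    for col in table.columns:
        as_int = table[col].astype(int)
        if (as_int == table[col]).all():
            table[col] = as_int
    snps = [c for c in cols if c.startswith("snp")]
    return CovariateTable(table, snps)


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "precision": truth.precision.tolist(),
        "edges": sorted(map(list, truth.planted_edges)),
        "planted_pcor": {f"{i},{j}": v for (i, j), v in
                         sorted(truth.planted_pcor.items())},
        "covariate_effects": {f"{j},{c}": v for (j, c), v in
                              sorted(truth.covariate_effects.items())},
        "duplicate_spec": list(truth.duplicate_spec) if truth.duplicate_spec else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth_json(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        precision=np.array(d["precision"], dtype=float),
        planted_edges=frozenset(tuple(e) for e in d["edges"]),
        planted_pcor={tuple(map(int, k.split(","))): v
                      for k, v in d["planted_pcor"].items()},
        covariate_effects={(int(k.split(",")[0]), k.split(",")[1]): v
                           for k, v in d["covariate_effects"].items()},
        duplicate_spec=tuple(d["duplicate_spec"]) if d["duplicate_spec"] else None,
        seed=d["seed"],
    )


def write_pcor_result(res: PcorResult, decision: FdrDecision | None,
                      outdir, prefix: str = "ggm") -> None:
    """Square r and p-value matrices as TSV plus a JSON sidecar with the
    sample size, conditioning-set size and FDR settings."""
    outdir = Path(outdir)
    for name, mat in (("r", res.r), ("pvals", res.pvals)):
        df = pd.DataFrame(mat, index=res.metabolite_ids,
                          columns=res.metabolite_ids)
        df.to_csv(outdir / f"{prefix}_{name}.tsv", sep="\t",
                  index_label="metabolite")
    sidecar = {"n": res.n, "k": res.k, "p": res.p}
    if decision is not None:
        sidecar["fdr"] = {"q": decision.q, "method": decision.method,
                          "m": decision.m,
                          "cutoff": decision.data_driven_cutoff}
    (outdir / f"{prefix}_meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
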