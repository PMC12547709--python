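"""Patient records, cohort tables, and delimited-text readers/writers.

A cohort is two tables: a static table with one row per patient (baseline
covariates plus optional ``gastrostomy_day`` / ``censor_day`` columns) and
a longitudinal table of weight measurements on a days-from-diagnosis axis
(diagnosis = day 0). Missing values are carried as ``None`` in records and
as NaN in frames — never as an in-band sentinel number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ttegast.schema import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    CovariateSpec,
    baseline_names,
    check_schema,
)

logger = logging.getLogger(__name__)

ID_COL = "id"
TDAYS_COL = "t_days"
WEIGHT_COL = "weight_kg"


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


@dataclass
class PatientRecord:
    """Static covariates plus the longitudinal weight series of one subject.

    ``weights`` is a list of ``(t_days, kg)`` pairs sorted by time;
    ``gastrostomy_day`` and ``censor_day`` are days from diagnosis.
    """

    id: str
    covariates: dict = field(default_factory=dict)
    weights: list = field(default_factory=list)
    gastrostomy_day: int | None = None
    censor_day: int | None = None

    def sorted_weights(self) -> list:
        return sorted(self.weights, key=lambda p: p[0])

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            self.id,
            dict(self.covariates),
            list(self.weights),
            self.gastrostomy_day,
            self.censor_day,
        )


@dataclass
class CohortTable:
    """A schema, a list of patient records, and a provenance tag.

    ``meta`` carries processing state (e.g. the frozen outlier-rate
    cutoff after cleaning); it is not part of the on-disk format.
    """

    schema: list
    records: list
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        check_schema(self.schema)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list:
        return [r.id for r in self.records]

    def record(self, pid: str) -> PatientRecord:
        for r in self.records:
            if r.id == pid:
                return r
        raise KeyError(pid)

    def static_frame(self) -> pd.DataFrame:
        """Baseline covariates as a DataFrame indexed by patient id."""
        cols = baseline_names(self.schema)
        data = {c: [r.covariates.get(c) for r in self.records] for c in cols}
        df = pd.DataFrame(data, index=pd.Index(self.ids(), name=ID_COL))
        for spec in self.schema:
            if spec.name in df.columns and spec.kind == CONTINUOUS:
                df[spec.name] = pd.to_numeric(df[spec.name], errors="coerce")
        return df

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for t, kg in r.sorted_weights():
                rows.append((r.id, t, kg))
        return pd.DataFrame(rows, columns=[ID_COL, TDAYS_COL, WEIGHT_COL])

    def copy(self) -> "CohortTable":
        return CohortTable(list(self.schema), [r.copy() for r in self.records],
                           self.provenance, dict(self.meta))


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(static_path, longitudinal_path, schema: list) -> CohortTable:
    """Read a cohort from a static and a longitudinal delimited-text file.

    Unparseable numeric cells become missing with a logged warning;
    longitudinal rows whose id is absent from the static table are skipped
    with a warning; a duplicated id in the static table is a hard error.
    """
    check_schema(schema)
    static = pd.read_csv(static_path, sep=_sep_for(static_path), dtype=str)
    long = pd.read_csv(longitudinal_path, sep=_sep_for(longitudinal_path), dtype=str)

    for col, frame, label in ((ID_COL, static, "static"), (ID_COL, long, "longitudinal")):
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column {col!r} in {label} file")
    for col in (TDAYS_COL, WEIGHT_COL):
        if col not in long.columns:
            raise ValueError(f"missing mandatory column {col!r} in longitudinal file")

    dupes = static[ID_COL][static[ID_COL].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate id in static file: {sorted(set(dupes))}")

    by_kind = {s.name: s for s in schema}
    records = {}
    n_bad_cells = 0
    for _, row in static.iterrows():
        pid = row[ID_COL]
        cov = {}
        for name in baseline_names(schema):
            if name not in static.columns:
                continue
            raw = row[name]
            if _is_missing(raw) or raw == "":
                cov[name] = None
                continue
            spec = by_kind[name]
            if spec.kind == CONTINUOUS:
                try:
                    cov[name] = float(raw)
                except (TypeError, ValueError):
                    logger.warning("unparseable value %r for %s (patient %s): set missing", raw, name, pid)
                    n_bad_cells += 1
                    cov[name] = None
            else:
                cov[name] = raw
        rec = PatientRecord(pid, cov)
        for meta, attr in (("gastrostomy_day", "gastrostomy_day"), ("censor_day", "censor_day")):
            if meta in static.columns and not (_is_missing(row[meta]) or row[meta] == ""):
                try:
                    setattr(rec, attr, int(float(row[meta])))
                except (TypeError, ValueError):
                    logger.warning("unparseable %s %r for patient %s: set missing", meta, row[meta], pid)
        records[pid] = rec

    n_dropped_rows = 0
    for _, row in long.iterrows():
        pid = row[ID_COL]
        if pid not in records:
            logger.warning("longitudinal id %s absent from static file: row skipped", pid)
            n_dropped_rows += 1
            continue
        try:
            t = int(float(row[TDAYS_COL]))
            kg = float(row[WEIGHT_COL])
        except (TypeError, ValueError):
            logger.warning("unparseable weight row for patient %s (%r, %r): dropped",
                           pid, row[TDAYS_COL], row[WEIGHT_COL])
            n_dropped_rows += 1
            continue
        records[pid].weights.append((t, kg))

    for rec in records.values():
        rec.weights = rec.sorted_weights()

    logger.info("read_cohort: %d patients, %d weight points, %d bad cells, %d dropped rows",
                len(records), sum(len(r.weights) for r in records.values()),
                n_bad_cells, n_dropped_rows)
    return CohortTable(list(schema), list(records.values()), provenance=str(static_path))


def write_cohort(tbl: CohortTable, static_path, longitudinal_path) -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    rows = []
    for r in tbl.records:
        row = {ID_COL: r.id}
        for name in baseline_names(tbl.schema):
            v = r.covariates.get(name)
            row[name] = "" if _is_missing(v) else (repr(float(v)) if isinstance(v, (int, float)) else v)
        row["gastrostomy_day"] = "" if r.gastrostomy_day is None else r.gastrostomy_day
        row["censor_day"] = "" if r.censor_day is None else r.censor_day
        rows.append(row)
    pd.DataFrame(rows).to_csv(static_path, sep=_sep_for(static_path), index=False)
    long = tbl.long_frame()
    long[WEIGHT_COL] = long[WEIGHT_COL].map(lambda x: repr(float(x)))
    long.to_csv(longitudinal_path, sep=_sep_for(longitudinal_path), index=False)


def validate_cohort(tbl: CohortTable) -> list:
    """Check every record against the schema; return violation messages.

    An empty list means the cohort satisfies all invariants.
    """
    report = []
    by_name = {s.name: s for s in tbl.schema}
    for r in tbl.records:
        ts = [t for t, _ in r.weights]
        if ts != sorted(ts):
            report.append(f"{r.id}: weight times not sorted")
        for t, kg in r.weights:
            if not kg > 0:
                report.append(f"{r.id}: non-positive weight {kg} at day {t}")
        if r.gastrostomy_day is not None and r.gastrostomy_day < 0:
            report.append(f"{r.id}: negative gastrostomy_day {r.gastrostomy_day}")
        if r.censor_day is not None and r.censor_day < 0:
            report.append(f"{r.id}: negative censor_day {r.censor_day}")
        for name, v in r.covariates.items():
            if name not in by_name:
                report.append(f"{r.id}: covariate {name!r} not in schema")
                continue
            if _is_missing(v):
                continue
            spec = by_name[name]
            if spec.kind in (BINARY, CATEGORICAL) and v not in spec.levels:
                report.append(f"{r.id}: unknown level {v!r} for {name!r} (levels {list(spec.levels)})")
    return report
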