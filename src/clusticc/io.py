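"""Reading and writing long-format subject tables and results tables.

Input data are long-format CSVs: one row per subject, one column holding
the cluster label and one numeric column per outcome.  Missing outcome
values are dropped per variable (listwise within each outcome column), so
different variables from the same file may have different totals.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ClusterDataset,
    DegenerateDataError,
    FixtureCorruptionError,
    ICCEstimate,
    ICCTable,
    InputError,
    VariableResult,
)

__all__ = [
    "read_long_csv",
    "load_emip_fixture",
    "render_results_csv",
    "write_results_csv",
    "read_results_csv",
    "EMIP_TABLE_ROW_COUNTS",
]

# Row counts of the reference multicenter preterm-birth study tables,
# used as the fixture integrity check.
EMIP_TABLE_ROW_COUNTS = {
    "T1": 24,
    "T2": 14,
    "T3": 12,
    "T4": 44,
    "T5": 43,
    "T6": 35,
    "T7": 27,
    "T8": 15,
    "T9": 18,
    "T10": 29,
}


def read_long_csv(
    path: Union[str, Path],
    cluster_col: str,
    outcome_cols: Optional[Sequence[str]] = None,
    type_map: Optional[Mapping[str, str]] = None,
) -> list[ClusterDataset]:
    """Read a long-format subject CSV into one :class:`ClusterDataset` per outcome.

    Parameters
    ----------
    path
        CSV with a header row; comma-separated, UTF-8, decimal point.
    cluster_col
        Column holding the cluster (centre) label.
    outcome_cols
        Outcome columns to extract; default: every column except ``cluster_col``.
    type_map
        Optional per-column ``{"binary", "continuous", "auto"}``.  ``auto``
        (the default) classifies a column as binary iff its non-missing
        values are a subset of {0, 1}.

    Rows with a missing value in a given outcome column are dropped for
    that outcome only.
    """
    frame = pd.read_csv(path)
    if cluster_col not in frame.columns:
        raise InputError(f"cluster column {cluster_col!r} not found in {path}")
    if outcome_cols is None:
        outcome_cols = [c for c in frame.columns if c != cluster_col]
    missing = [c for c in outcome_cols if c not in frame.columns]
    if missing:
        raise InputError(f"outcome columns not found: {missing}")
    type_map = dict(type_map or {})

    datasets = []
    for col in outcome_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        keep = values.notna()
        vals = values[keep].to_numpy(dtype=float)
        clusters = frame.loc[keep, cluster_col].to_numpy()
        declared = type_map.get(col, "auto")
        if declared not in ("binary", "continuous", "auto"):
            raise InputError(f"unknown type {declared!r} for column {col!r}")
        if declared == "auto":
            declared = "binary" if vals.size and np.isin(vals, (0.0, 1.0)).all() else "continuous"
        if np.unique(clusters).size < 2:
            raise DegenerateDataError(
                f"column {col!r} has fewer than 2 clusters after missing-data removal"
            )
        datasets.append(
            ClusterDataset(variable_name=col, var_type=declared, clusters=clusters, values=vals)
        )
    return datasets


def _fixture_path() -> Path:
    return Path(str(resources.files("clusticc").joinpath("data/emip_tables.csv")))


def load_emip_fixture() -> ICCTable:
    """Load the bundled per-variable results of the Brazilian multicenter
    preterm-birth study (261 variables across tables T1-T10).

    ICCs printed as "<0.001" are stored as 0 with ``censored_icc`` set.
    """
    table = read_results_csv(_fixture_path())
    table.provenance = "fixture"
    counts = {}
    for row in table.rows:
        counts[row.table_id] = counts.get(row.table_id, 0) + 1
    if len(table) != 261 or counts != EMIP_TABLE_ROW_COUNTS:
        raise FixtureCorruptionError(
            f"fixture integrity check failed: {len(table)} rows, per-table counts {counts}"
        )
    return table


def _render(value: float, digits: int, floor_label: bool = False) -> str:
    if math.isnan(value):
        return ""
    if floor_label and value < 0.001:
        return "<0.001"
    return f"{value:.{digits}f}"


def render_results_csv(table: ICCTable) -> str:
    """Render a results table as CSV text using the study's display
    conventions: ICC and CI bounds to 3 decimals, Deff to 1 decimal,
    prevalence/mean to 1 decimal, mean cluster size as an integer; ICCs
    and lower CI bounds below 0.001 are rendered ``<0.001``.  The output
    round-trips through :func:`read_results_csv` at this precision.
    """
    if len(table) == 0:
        raise InputError("refusing to write an empty results table")
    lines = ["table_id,variable,var_type,estimate,icc,ci_low,ci_high,deff,n_a,censored,error"]
    for r in table.rows:
        icc = r.icc.rho if r.icc else math.nan
        lo = r.icc.ci_low if r.icc and r.icc.ci_low is not None else math.nan
        hi = r.icc.ci_high if r.icc and r.icc.ci_high is not None else math.nan
        name = r.variable_name
        if "," in name or '"' in name:
            name = '"' + name.replace('"', '""') + '"'
        censored = r.censored_icc or (not math.isnan(icc) and icc < 0.001)
        fields = [
            r.table_id,
            name,
            r.var_type,
            _render(r.estimate, 1),
            _render(icc, 3, floor_label=True),
            _render(lo, 3, floor_label=True),
            _render(hi, 3),
            _render(r.deff, 1),
            "" if math.isnan(r.n_a) else str(int(round(r.n_a))),
            str(int(censored)),
            r.error or "",
        ]
        lines.append(",".join(fields))
    return "\n".join(lines) + "\n"


def write_results_csv(table: ICCTable, path: Union[str, Path]) -> None:
    """Write :func:`render_results_csv` output to ``path``."""
    try:
        Path(path).write_text(render_results_csv(table), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def _parse_floor(raw, default=math.nan) -> tuple[float, bool]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return default, False
    s = str(raw).strip()
    if s.startswith("<"):
        return 0.0, True
    return float(s), False


def read_results_csv(path: Union[str, Path]) -> ICCTable:
    """Read a results table written by :func:`write_results_csv` (or the
    packaged fixture, which uses the same schema with numeric zeros and an
    explicit ``censored`` flag)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"table_id", "variable", "var_type", "estimate", "icc", "ci_low", "ci_high", "deff", "n_a"}
    if not required.issubset(frame.columns):
        raise InputError(f"results file missing columns: {sorted(required - set(frame.columns))}")
    rows = []
    for rec in frame.to_dict("records"):
        icc, icc_floor = _parse_floor(rec["icc"])
        lo, _ = _parse_floor(rec["ci_low"])
        hi, _ = _parse_floor(rec["ci_high"])
        est, _ = _parse_floor(rec["estimate"])
        deff, _ = _parse_floor(rec["deff"])
        n_a, _ = _parse_floor(rec["n_a"])
        censored = icc_floor or bool(int(rec.get("censored", "0") or 0))
        icc_est = None
        if not math.isnan(icc):
            icc_est = ICCEstimate(
                rho=icc,
                rho_raw=icc,
                method="fixture",
                ci_low=None if math.isnan(lo) else lo,
                ci_high=None if math.isnan(hi) else hi,
                alpha=0.05,
            )
        rows.append(
            VariableResult(
                variable_name=rec["variable"],
                table_id=rec["table_id"],
                var_type=rec["var_type"],
                estimate=est,
                icc=icc_est,
                deff=deff,
                n_a=n_a,
                censored_icc=censored,
                error=rec.get("error", "") or None,
            )
        )
    return ICCTable(rows=rows, provenance="computed")
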