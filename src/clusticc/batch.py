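"""Batch estimation over many variables and aggregate reporting.

``estimate_all`` runs the full pipeline (prevalence/mean, ANOVA ICC with
confidence interval, exact design effect, mean cluster size) over a
collection of variables; ``summarize`` reduces a results table to the
aggregates a study report prints: median/range of ICC and Deff, the
percentage of variables with ICC below chosen thresholds, and per-group
medians.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .anova import estimate_icc
from .design import deff_ratio
from .types import (
    ClusterDataset,
    DegenerateDataError,
    ICCTable,
    InputError,
    SummaryStats,
    VariableResult,
)

__all__ = ["estimate_all", "summarize", "compare_to_fixture", "ComparisonReport"]


def estimate_all(
    datasets: Iterable[ClusterDataset],
    alpha: float = 0.05,
    table_id: str = "",
) -> ICCTable:
    """Estimate every variable; failures become explicit rows, never drops.

    Each result row carries the prevalence (in %, binary) or mean
    (continuous), the Kish-formula ICC with its asymptotic confidence
    interval, the exact variance-ratio Deff, and the mean cluster size
    ``n_a`` (non-missing N over contributing clusters).  A variable whose
    estimation fails (e.g. zero variance) is reported with the failure
    reason in its ``error`` field.
    """
    datasets = list(datasets)
    if not datasets:
        raise InputError("estimate_all needs at least one dataset")
    rows = []
    for data in datasets:
        try:
            _, est = estimate_icc(data, alpha=alpha)
            deff = deff_ratio(data)
            estimate = data.values.mean() * (100.0 if data.var_type == "binary" else 1.0)
            rows.append(
                VariableResult(
                    variable_name=data.variable_name,
                    table_id=table_id,
                    var_type=data.var_type,
                    estimate=float(estimate),
                    icc=est,
                    deff=deff.deff_ratio,
                    n_a=data.mean_cluster_size,
                    censored_icc=est.rho < 0.001,
                )
            )
        except (DegenerateDataError, InputError) as exc:
            rows.append(
                VariableResult(
                    variable_name=data.variable_name,
                    table_id=table_id,
                    var_type=data.var_type,
                    error=str(exc),
                )
            )
    return ICCTable(rows=rows, provenance="computed")


def _round_half_up(x: float, digits: int = 1) -> float:
    factor = 10.0**digits
    return math.floor(x * factor + 0.5) / factor


def summarize(
    table: ICCTable,
    thresholds: Sequence[float] = (0.1, 0.3),
    groups: Optional[Mapping[str, str]] = None,
) -> SummaryStats:
    """Aggregate a results table.

    Censored ICCs (printed "<0.001") enter as 0.  The median of an even
    count is the midpoint of the two central values; threshold
    proportions use a strict "<" comparison and are rounded half-up to
    one decimal.  ``groups`` maps variable name to a group label for the
    per-group medians; by default rows group by their ``table_id``.
    """
    rows = [r for r in table.rows if r.error is None]
    if not rows:
        raise InputError("nothing to summarize: table is empty or all rows failed")
    iccs = [r.icc_value for r in rows]
    deffs = [r.deff for r in rows if not math.isnan(r.deff)]
    prop_below = {
        t: _round_half_up(100.0 * sum(1 for v in iccs if v < t) / len(iccs)) for t in thresholds
    }

    if groups is not None:
        names = {r.variable_name for r in rows}
        unknown = sorted(set(groups) - names)
        if unknown:
            raise InputError(f"group map names unknown variables: {unknown}")
        membership = {r.variable_name: groups.get(r.variable_name) for r in rows}
        keyed: dict[str, list[float]] = {}
        for r in rows:
            g = membership[r.variable_name]
            if g is not None:
                keyed.setdefault(g, []).append(r.icc_value)
    else:
        keyed = {}
        for r in rows:
            if r.table_id:
                keyed.setdefault(r.table_id, []).append(r.icc_value)
    def natural(label: str):
        return [int(part) if part.isdigit() else part for part in re.split(r"(\d+)", label)]

    group_medians = {g: float(median(keyed[g])) for g in sorted(keyed, key=natural)}

    n_a = [r.n_a for r in rows if not math.isnan(r.n_a)]
    return SummaryStats(
        n_variables=len(rows),
        icc_median=float(median(iccs)),
        icc_min=float(min(iccs)),
        icc_max=float(max(iccs)),
        prop_below=prop_below,
        deff_median=float(median(deffs)) if deffs else math.nan,
        deff_min=float(min(deffs)) if deffs else math.nan,
        deff_max=float(max(deffs)) if deffs else math.nan,
        group_medians=group_medians,
        mean_cluster_size=float(sum(n_a) / len(n_a)) if n_a else math.nan,
    )


@dataclass
class ComparisonReport:
    """Per-variable differences between a computed table and a reference."""

    diffs: pd.DataFrame  # variable, icc_diff, deff_diff
    flagged: list[str]  # variables whose |diff| exceeds the tolerance
    tolerance: float

    @property
    def ok(self) -> bool:
        return not self.flagged


def compare_to_fixture(
    computed: ICCTable, fixture: ICCTable, tolerance: float = 0.005
) -> ComparisonReport:
    """Compare per-variable ICC and Deff against a reference table.

    Variables are matched by name; a mismatch in the name sets is an
    error listing the offenders.  Rows whose absolute ICC or Deff
    difference exceeds ``tolerance`` are flagged.
    """
    left = {(r.table_id, r.variable_name): r for r in computed.rows}
    right = {(r.table_id, r.variable_name): r for r in fixture.rows}
    only_left = sorted(set(left) - set(right))
    only_right = sorted(set(right) - set(left))
    if only_left or only_right:
        raise InputError(
            f"variable names do not match; computed-only: {only_left}, reference-only: {only_right}"
        )
    records, flagged = [], []
    for key in left:
        icc_diff = abs(left[key].icc_value - right[key].icc_value)
        deff_diff = abs(left[key].deff - right[key].deff)
        records.append({"variable": key[1], "icc_diff": icc_diff, "deff_diff": deff_diff})
        if icc_diff > tolerance or deff_diff > tolerance:
            flagged.append(key[1])
    return ComparisonReport(
        diffs=pd.DataFrame.from_records(records), flagged=flagged, tolerance=tolerance
    )
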