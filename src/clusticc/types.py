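"""Core data model for cluster-sampled, subject-level data.

The unit of analysis is a single subject; subjects are grouped into
clusters (primary sampling units such as hospitals).  All estimators in
this package consume a :class:`ClusterDataset` — one outcome variable's
non-missing observations together with their cluster labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "DegenerateDataError",
    "DegenerateVarianceError",
    "FixtureCorruptionError",
    "ClusterDataset",
    "VarianceComponents",
    "ICCEstimate",
    "VariableResult",
    "ICCTable",
    "SummaryStats",
]


class InputError(ValueError):
    """Malformed user input (missing columns, out-of-range parameters)."""


class DegenerateDataError(ValueError):
    """Data cannot support estimation (fewer than 2 clusters, all singletons)."""


class DegenerateVarianceError(DegenerateDataError):
    """Total variance is zero: every observed value is identical."""


class FixtureCorruptionError(RuntimeError):
    """The packaged reference-results table failed its integrity check."""


@dataclass(frozen=True)
class ClusterDataset:
    """Observations of one outcome variable, grouped by cluster.

    Parameters
    ----------
    variable_name
        Label for the outcome column.
    var_type
        ``"binary"`` (values restricted to {0, 1}) or ``"continuous"``.
    clusters
        Cluster label per observation (any hashable labels).
    values
        Observed value per observation; must be finite.
    """

    variable_name: str
    var_type: str
    clusters: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        clusters = np.asarray(self.clusters)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "values", values)
        if self.var_type not in ("binary", "continuous"):
            raise InputError(f"unknown var_type {self.var_type!r}")
        if clusters.shape != values.shape or values.ndim != 1:
            raise InputError("clusters and values must be 1-D and equal length")
        if values.size and not np.all(np.isfinite(values)):
            raise InputError(f"{self.variable_name!r}: non-finite values present")
        if self.var_type == "binary" and values.size and not np.isin(values, (0.0, 1.0)).all():
            raise InputError(f"{self.variable_name!r}: binary variable has values outside {{0,1}}")
        codes, counts = _factorize(clusters)
        if counts.size < 2:
            raise DegenerateDataError(
                f"{self.variable_name!r}: at least 2 clusters are required, got {counts.size}"
            )
        object.__setattr__(self, "_codes", codes)
        object.__setattr__(self, "_counts", counts)

    # cached grouping -------------------------------------------------
    @property
    def cluster_codes(self) -> np.ndarray:
        """Integer cluster code per observation (0 .. a-1)."""
        return self._codes  # type: ignore[attr-defined]

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Number of observations per cluster (length ``a``)."""
        return self._counts  # type: ignore[attr-defined]

    @property
    def a(self) -> int:
        """Number of distinct clusters."""
        return int(self.cluster_sizes.size)

    @property
    def n(self) -> int:
        """Total number of (non-missing) observations."""
        return int(self.values.size)

    @property
    def mean_cluster_size(self) -> float:
        return self.n / self.a


def _factorize(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if labels.dtype.kind in "iu":
        uniq, codes, counts = np.unique(labels, return_inverse=True, return_counts=True)
        return codes, counts
    codes, uniq = pd.factorize(labels, sort=True)
    counts = np.bincount(codes, minlength=len(uniq))
    return codes, counts


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA decomposition of a :class:`ClusterDataset`.

    ``msb`` and ``msw`` are the between- and within-cluster mean squares;
    ``n0`` is the adjusted average cluster size
    ``(N - sum(n_i^2)/N) / (a - 1)`` used in place of a common cluster
    size when the design is unbalanced.  ``s2_total`` is the element-level
    variance estimate ``s2_between + (n0-1)/n0 * msw`` where
    ``s2_between = msb / n0`` is the variance among cluster means on the
    element scale.
    """

    a: int
    n: int
    n0: float
    ssb: float
    ssw: float
    msb: float
    msw: float
    f: float
    grand_mean: float
    s2_total: float
    cluster_sizes: np.ndarray

    @property
    def s2_between(self) -> float:
        """Between-cluster variance component on the element scale (MSB/n0)."""
        return self.msb / self.n0


@dataclass(frozen=True)
class ICCEstimate:
    """ANOVA intracluster correlation estimate with its normal-theory CI.

    ``rho`` is truncated to [0, 1]; the raw (possibly negative) estimate
    is kept in ``rho_raw`` for diagnostics.  ``ci_low``/``ci_high`` are
    ``None`` until a confidence interval has been attached.
    """

    rho: float
    rho_raw: float
    method: str
    se: float = math.nan
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1] after truncation")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.rho <= self.ci_high + 1e-12):
                raise ValueError("confidence interval must bracket rho")


@dataclass
class VariableResult:
    """One reported row: prevalence/mean, ICC with CI, Deff, mean cluster size."""

    variable_name: str
    table_id: str = ""
    var_type: str = "binary"
    estimate: float = math.nan  # prevalence in % (binary) or mean (continuous)
    icc: Optional[ICCEstimate] = None
    deff: float = math.nan
    n_a: float = math.nan  # mean cluster size (displayed rounded to integer)
    censored_icc: bool = False
    error: Optional[str] = None

    @property
    def icc_value(self) -> float:
        return self.icc.rho if self.icc is not None else math.nan


@dataclass
class ICCTable:
    """Ordered collection of per-variable results (one study table or many)."""

    rows: list[VariableResult] = field(default_factory=list)
    provenance: str = "computed"  # or "fixture"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = (row.table_id, row.variable_name)
            if key in seen:
                raise InputError(f"duplicate variable {row.variable_name!r} in {row.table_id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def subset(self, table_id: str) -> "ICCTable":
        return ICCTable([r for r in self.rows if r.table_id == table_id], self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "table_id": r.table_id,
                    "variable": r.variable_name,
                    "var_type": r.var_type,
                    "estimate": r.estimate,
                    "icc": r.icc.rho if r.icc else math.nan,
                    "ci_low": r.icc.ci_low if r.icc else math.nan,
                    "ci_high": r.icc.ci_high if r.icc else math.nan,
                    "deff": r.deff,
                    "n_a": r.n_a,
                    "censored": int(r.censored_icc),
                    "error": r.error or "",
                }
            )
        return pd.DataFrame.from_records(records)


@dataclass
class SummaryStats:
    """Aggregate statistics over an :class:`ICCTable`."""

    n_variables: int
    icc_median: float
    icc_min: float
    icc_max: float
    prop_below: Mapping[float, float]  # threshold -> % of variables strictly below
    deff_median: float
    deff_min: float
    deff_max: float
    group_medians: Mapping[str, float]
    mean_cluster_size: float
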