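"""Design effects and design-effect-based sample-size calculations.

The design effect (Deff) is the ratio of an estimator's variance under
the actual single-stage cluster design to its variance under simple
random sampling (SRS) of the same size,

    Deff = var_actual(r) / var_SRS(r),

approximated for a mean cluster size m by 1 + (m - 1) * ICC.  Deff is the
factor by which an SRS sample size must be inflated to retain the same
precision under cluster sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .types import ClusterDataset, DegenerateVarianceError, InputError

__all__ = [
    "DeffResult",
    "SampleSizeSpec",
    "deff_ratio",
    "deff_approx",
    "srs_sample_size_proportion",
    "inflate_sample_size",
]


@dataclass(frozen=True)
class DeffResult:
    """Exact variance-ratio design effect alongside its ICC approximation."""

    deff_ratio: float
    deff_approx: Optional[float]
    var_actual: float
    var_srs: float
    m: float  # mean cluster size N / a


@dataclass(frozen=True)
class SampleSizeSpec:
    """Sample-size requirement, before and after design-effect inflation."""

    n_srs: int
    n_cluster: int
    deff: float
    icc: float
    m: float
    n_clusters: int  # clusters of mean size m needed to reach n_cluster
    p: Optional[float] = None
    d: Optional[float] = None
    alpha: Optional[float] = None


def deff_ratio(data: ClusterDataset, icc: Optional[float] = None, weighted: bool = False) -> DeffResult:
    """Exact design effect of the sample mean for one variable.

    ``var_actual`` treats clusters as primary sampling units drawn with
    replacement: the variance among cluster means divided by the number
    of clusters (``s2_a / a``).  ``var_srs`` is the element variance
    (N-1 denominator) divided by N.  With ``weighted=True`` the actual
    variance is the with-replacement linearisation of the ratio estimator
    ``sum(y) / N``, which weights clusters by their size.

    ``icc``, when given, also reports the 1 + (m-1)*ICC approximation.
    """
    values = data.values
    n = data.n
    a = data.a
    var_srs = float(np.var(values, ddof=1)) / n
    if var_srs == 0.0:
        raise DegenerateVarianceError(
            f"{data.variable_name!r}: zero element variance; design effect undefined"
        )
    sizes = data.cluster_sizes.astype(float)
    sums = np.bincount(data.cluster_codes, weights=values, minlength=a)
    if weighted:
        r = values.sum() / n
        z = sums - r * sizes
        var_actual = a / (a - 1.0) * float(np.sum(z**2)) / n**2
    else:
        means = sums / sizes
        var_actual = float(np.var(means, ddof=1)) / a
    m = n / a
    approx = deff_approx(icc, m) if icc is not None else None
    return DeffResult(
        deff_ratio=var_actual / var_srs,
        deff_approx=approx,
        var_actual=var_actual,
        var_srs=var_srs,
        m=m,
    )


def deff_approx(icc: float, m: float) -> float:
    """Kish approximation ``1 + (m - 1) * ICC`` for mean cluster size ``m``."""
    if not (math.isfinite(icc) and math.isfinite(m)):
        raise InputError("icc and m must be finite")
    if m < 1:
        raise InputError("mean cluster size m must be >= 1")
    return 1.0 + (m - 1.0) * icc


def srs_sample_size_proportion(p: float, d: float, alpha: float = 0.05) -> int:
    """Simple-random-sampling size to estimate a proportion ``p`` to within
    an absolute precision ``d`` at two-sided level ``alpha``:

        n = ceil( z_{1-alpha/2}^2 * p (1 - p) / d^2 ).
    """
    if not 0.0 < p < 1.0:
        raise InputError("p must lie in (0, 1)")
    if not 0.0 < d < p:
        raise InputError("precision d must lie in (0, p)")
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")
    z = norm.ppf(1.0 - alpha / 2.0)
    return math.ceil(z**2 * p * (1.0 - p) / d**2)


def inflate_sample_size(
    n_srs: int,
    icc: float,
    m: float = 1.0,
    p: Optional[float] = None,
    d: Optional[float] = None,
    alpha: Optional[float] = None,
) -> SampleSizeSpec:
    """Inflate an SRS sample size for cluster sampling via ``1 + (m-1)*ICC``.

    Returns both the inflated subject count (``ceil(n_srs * deff)``) and
    the number of clusters of mean size ``m`` needed to reach it.  The
    ceiling convention is conservative: required sizes are never rounded
    down.
    """
    if n_srs < 1:
        raise InputError("n_srs must be >= 1")
    deff = deff_approx(icc, m)
    n_cluster = math.ceil(n_srs * deff)
    return SampleSizeSpec(
        n_srs=int(n_srs),
        n_cluster=n_cluster,
        deff=deff,
        icc=icc,
        m=m,
        n_clusters=math.ceil(n_cluster / m),
        p=p,
        d=d,
        alpha=alpha,
    )
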