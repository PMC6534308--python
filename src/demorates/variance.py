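"""Complex-survey sampling-error machinery.

Two variance estimators are provided, matching standard household-survey
practice for two-stage cluster designs:

* Taylor linearization for ratio estimators r = y/x (age-specific and
  general fertility rates), with clusters nested in explicit strata;
* a non-stratified delete-one-cluster jackknife for indicators that are not
  simple ratios (the total fertility rate and the synthetic-cohort
  childhood mortality rates), where each replicate drops one primary
  sampling unit and the variance is formed from pseudo-values.

On top of either standard error the module derives the design effect
(DEFT = design SE / simple-random-sample SE), the relative standard error,
and normal-theory confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class LonelyPSUError(ValueError):
    """A stratum contains a single cluster, so its variance is undefined."""


@dataclass
class VarianceResult:
    se: float
    deft: float | None = None
    rse: float | None = None
    lci: float | None = None
    uci: float | None = None
    iterations: int | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)


def collapse_singleton_strata(strata: np.ndarray) -> np.ndarray:
    """Merge each stratum holding one cluster with the next stratum in sort order.

    The last stratum, if singleton, merges backwards.  Returns a relabelled
    copy; point estimates are unaffected, only variance strata change.
    """
    strata = np.asarray(strata)
    out = strata.copy()
    while True:
        frame = pd.DataFrame({"h": out})
        # number of distinct clusters is not known here; singleton means the
        # stratum has a single distinct value of anything grouped later, so
        # callers pass cluster-level arrays (one row per cluster)
        counts = frame.groupby("h").size()
        lonely = counts[counts < 2].index.tolist()
        if not lonely:
            return out
        order = sorted(counts.index.tolist())
        for h in lonely:
            i = order.index(h)
            target = order[i + 1] if i + 1 < len(order) else order[i - 1]
            out[out == h] = target
            break  # re-derive counts after each merge


def taylor_ratio_se(
    y: np.ndarray,
    x: np.ndarray,
    strata: np.ndarray,
    clusters: np.ndarray,
    collapse_strata: bool = False,
) -> float:
    """Standard error of the ratio r = sum(y)/sum(x) by Taylor linearization.

    ``y`` and ``x`` are weighted per-record numerator/denominator
    contributions; records are first aggregated to (stratum, cluster) totals
    y_hi, x_hi.  With m_h clusters in stratum h, stratum totals y_h, x_h and
    residuals z_hi = y_hi - r x_hi,

        se^2 = (1/x^2) * sum_h [ m_h/(m_h-1) * ( sum_i z_hi^2 - z_h^2/m_h ) ].

    Strata holding a single cluster raise :class:`LonelyPSUError` unless
    ``collapse_strata`` merges them with their sort-order neighbour.
    """
    frame = pd.DataFrame(
        {
            "h": np.asarray(strata),
            "i": np.asarray(clusters),
            "y": np.asarray(y, float),
            "x": np.asarray(x, float),
        }
    )
    agg = frame.groupby(["h", "i"], sort=True, observed=True)[["y", "x"]].sum().reset_index()
    if collapse_strata:
        agg["h"] = collapse_singleton_strata(agg["h"].to_numpy())
    sizes = agg.groupby("h", observed=True).size()
    lonely = sizes[sizes < 2]
    if len(lonely):
        raise LonelyPSUError(
            f"strata with a single cluster (lonely PSU): {list(lonely.index)}; "
            "merge or collapse strata before estimating the variance"
        )
    x_total = agg["x"].sum()
    if x_total <= 0:
        raise ValueError("ratio denominator must be positive")
    r = agg["y"].sum() / x_total
    agg["z"] = agg["y"] - r * agg["x"]

    var = 0.0
    for _, g in agg.groupby("h", observed=True):
        m_h = len(g)
        z = g["z"].to_numpy()
        var += m_h / (m_h - 1) * (np.sum(z**2) - np.sum(z) ** 2 / m_h)
    var /= x_total**2
    return float(np.sqrt(max(var, 0.0)))


def srs_ratio_se(y: np.ndarray, x: np.ndarray) -> float:
    """Taylor SE of r = y/x with every elementary unit its own cluster.

    This is the simple-random-sample baseline used in the denominator of the
    design effect: one stratum, each record a PSU.
    """
    n = len(y)
    return taylor_ratio_se(
        np.asarray(y, float),
        np.asarray(x, float),
        strata=np.zeros(n, dtype=int),
        clusters=np.arange(n),
    )


def srs_residual_se(residuals: np.ndarray) -> float:
    """SRS baseline SE from per-unit linearized contributions u_i.

    Used for indicators (the TFR) whose per-unit influence is a linear
    combination of ratio residuals rather than a single y/x pair:
    se^2 = m/(m-1) * ( sum u_i^2 - (sum u_i)^2 / m ).
    """
    u = np.asarray(residuals, float)
    m = len(u)
    if m < 2:
        return 0.0
    var = m / (m - 1) * (np.sum(u**2) - np.sum(u) ** 2 / m)
    return float(np.sqrt(max(var, 0.0)))


def srs_proportion_se(rate_per_1000: float, n: float) -> float:
    """Binomial SRS baseline for a per-1000 probability-type rate.

    se = sqrt(r * (1000 - r) / n) on the per-1000 scale, with n the
    unweighted number of contributing units.
    """
    if n <= 0:
        return 0.0
    return float(np.sqrt(max(rate_per_1000 * (1000.0 - rate_per_1000), 0.0) / n))


def jackknife_se(
    cluster_ids: Sequence,
    estimator: Callable[[object | None], float],
) -> VarianceResult:
    """Non-stratified delete-one-cluster jackknife standard error.

    ``estimator(None)`` must return the full-sample rate r; ``estimator(c)``
    the rate r_(i) with cluster ``c`` excluded — recomputed from scratch on
    the reduced sample.  With k clusters and pseudo-values
    k r - (k-1) r_(i),

        se^2 = sum_i ( k r - (k-1) r_(i) - r )^2 / ( k (k-1) ).

    The replicate count equals the number of distinct clusters.
    """
    distinct = pd.unique(np.asarray(cluster_ids))
    k = len(distinct)
    if k < 2:
        raise ValueError(f"jackknife needs >= 2 clusters, got {k}")
    r = float(estimator(None))
    reps = np.empty(k, float)
    for j, c in enumerate(distinct):
        try:
            reps[j] = float(estimator(c))
        except Exception as exc:
            raise RuntimeError(f"estimator failed on replicate without cluster {c!r}") from exc
    pseudo = k * r - (k - 1) * reps
    var = float(np.sum((pseudo - r) ** 2) / (k * (k - 1)))
    return VarianceResult(se=float(np.sqrt(max(var, 0.0))), iterations=k, replicates=reps)


def confidence_interval(r: float, se: float, cl: float = 95.0) -> tuple[float, float]:
    """Normal-theory CI r +/- z_{alpha/2} se at confidence level ``cl`` percent.

    The lower bound is deliberately not floored at zero: a small rate with a
    large SE legitimately reports a bound near (or below) zero.
    """
    if not 0 < cl < 100:
        raise ValueError(f"confidence level must be in (0, 100), got {cl}")
    z = stats.norm.ppf(1 - (1 - cl / 100.0) / 2)
    return float(r - z * se), float(r + z * se)


def finalize(
    r: float,
    se: float,
    se_srs: float | None,
    cl: float,
    iterations: int | None = None,
    replicates: np.ndarray | None = None,
) -> VarianceResult:
    """Assemble DEFT, RSE and the CI around a computed design-based SE."""
    deft = None
    if se_srs is not None and se_srs > 0:
        deft = float(se / se_srs)
    rse = float(se / r) if r > 0 else None
    lci, uci = confidence_interval(r, se, cl)
    return VarianceResult(
        se=float(se), deft=deft, rse=rse, lci=lci, uci=uci,
        iterations=iterations, replicates=replicates,
    )
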