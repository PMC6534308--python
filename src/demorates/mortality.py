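"""Synthetic-cohort childhood mortality estimation from birth records.

The five rates (NNMR, PNMR, IMR, CMR, U5MR) are built from component death
probabilities p_i for eight age segments (0, 1-2, 3-5, 6-11, 12-23, 24-35,
36-47, 48-59 completed months).  For a reference window of calendar months
and a segment with age bounds [a_l, a_u), children split into three birth
cohorts by date of birth:

* cohort 2 lives through the whole segment inside the window and counts
  fully in both deaths and exposure;
* cohorts 1 and 3 (born just early/late enough that only part of their
  segment falls in the window) count half the exposure and half the deaths
  — except that when the window ends at the survey date, cohort-3 deaths
  count fully, since deaths this cohort will still suffer inside the
  segment after the interview go unobserved and the reported deaths are
  taken to be half of the cohort's eventual total.

p_i is the ratio of the weighted death sum to the weighted exposure sum;
the rates then combine segments multiplicatively, e.g.
U5MR = 1000 * (1 - prod_i (1 - p_i)).

Deaths are placed in a segment by completed-month age at death; period
attribution comes entirely from the cohort construction.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variance
from .fertility import fieldwork_warning
from .survey_io import (
    DEFAULT_WEIGHT_DIVISOR,
    _resolve_column,
    cmc_to_decimal_year,
    cmc_to_label,
    parse_period_end,
    resolve_design,
)

logger = logging.getLogger("demorates")


@dataclass(frozen=True)
class AgeSegment:
    """One of the eight completed-month age segments [a_l, a_u)."""

    index: int  # 1-based
    label: str
    a_l: int
    a_u: int


AGE_SEGMENTS: tuple[AgeSegment, ...] = (
    AgeSegment(1, "0", 0, 1),
    AgeSegment(2, "1-2", 1, 3),
    AgeSegment(3, "3-5", 3, 6),
    AgeSegment(4, "6-11", 6, 12),
    AgeSegment(5, "12-23", 12, 24),
    AgeSegment(6, "24-35", 24, 36),
    AgeSegment(7, "36-47", 36, 48),
    AgeSegment(8, "48-59", 48, 60),
)

RATE_LABELS = ["NNMR", "PNMR", "IMR", "CMR", "U5MR"]

#: 1-based segment indices each rate is composed from (also used for N/WN)
RATE_SEGMENTS = {
    "NNMR": (1,),
    "PNMR": (2, 3, 4),
    "IMR": (1, 2, 3, 4),
    "CMR": (5, 6, 7, 8),
    "U5MR": (1, 2, 3, 4, 5, 6, 7, 8),
}


def assign_cohort(child_dob: int, segment: AgeSegment, start_cmc: int, end_cmc: int) -> int:
    """Cohort (1, 2 or 3) of a child for one segment, or 0 for none.

    ``start_cmc``/``end_cmc`` are the first and last months of the window,
    both included.  With s = start, L = end, a child born in month b is in

    * cohort 1 iff s - a_u <= b <= s - a_l - 1 (enters the segment before
      the window opens, leaves it inside);
    * cohort 2 iff s - a_l <= b <= L - a_u (the whole segment inside);
    * cohort 3 iff L - a_u + 1 <= b <= L - a_l + 1 (still inside the
      segment when the window closes).

    The three intervals partition [s - a_u, L - a_l + 1]; cohort 3 is one
    month wider than cohort 1 because a child born in the month after the
    window still has segment-months overlapping the window's last month.
    """
    b, s, L = int(child_dob), int(start_cmc), int(end_cmc)
    if s - segment.a_u <= b <= s - segment.a_l - 1:
        return 1
    if s - segment.a_l <= b <= L - segment.a_u:
        return 2
    if L - segment.a_u + 1 <= b <= L - segment.a_l + 1:
        return 3
    return 0


def cohort_weights(cohort: int, ends_at_survey: bool) -> tuple[float, float]:
    """(exposure_weight, death_weight) for a cohort assignment."""
    if cohort == 2:
        return 1.0, 1.0
    if cohort == 1:
        return 0.5, 0.5
    if cohort == 3:
        return 0.5, 1.0 if ends_at_survey else 0.5
    return 0.0, 0.0


def death_in_segment(age_at_death_months: int, segment: AgeSegment) -> bool:
    """True iff a death at the given completed-month age falls in the segment."""
    if age_at_death_months < 0:
        raise ValueError("age at death must be non-negative")
    return segment.a_l <= age_at_death_months < segment.a_u


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

@dataclass
class MortalityTallies:
    """Per-child per-segment death/exposure contributions plus design labels."""

    death: np.ndarray  # (n, 8) death-weight contributions (unweighted)
    exposure: np.ndarray  # (n, 8) exposure-weight contributions (unweighted)
    weight: np.ndarray  # (n,)
    strata: np.ndarray
    clusters: np.ndarray
    interview_cmc: np.ndarray

    @property
    def death_w(self) -> np.ndarray:
        return self.death * self.weight[:, None]

    @property
    def exposure_w(self) -> np.ndarray:
        return self.exposure * self.weight[:, None]

    def mask(self, keep: np.ndarray) -> "MortalityTallies":
        return MortalityTallies(
            self.death[keep], self.exposure[keep], self.weight[keep],
            self.strata[keep], self.clusters[keep], self.interview_cmc[keep],
        )


def tally_mortality(
    dob_cmc: np.ndarray,
    age_at_death: np.ndarray,  # NaN for surviving children
    interview_cmc: np.ndarray,
    weight: np.ndarray,
    strata: np.ndarray,
    clusters: np.ndarray,
    period_months: int = 60,
    period_end: str | None = None,
) -> MortalityTallies:
    """Vectorized cohort assignment and death/exposure contributions.

    Without ``period_end`` each child's window ends the month before its
    mother's interview (and cohort-3 deaths are counted fully); a fixed
    period end is shared by all children and cohort-3 deaths count half.
    """
    dob = np.asarray(dob_cmc, np.int64)
    itv = np.asarray(interview_cmc, np.int64)
    b7 = np.asarray(age_at_death, float)
    if period_end is None:
        end = itv - 1
        ends_at_survey = True
    else:
        end = np.full(len(dob), parse_period_end(period_end), np.int64)
        ends_at_survey = False
    start = end - period_months + 1

    died = np.isfinite(b7)
    if np.any(b7[died] < 0):
        raise ValueError("age at death must be non-negative")
    if np.any(died & (b7 > itv - dob)):
        raise ValueError("age at death exceeds the child's age at interview")

    n = len(dob)
    death = np.zeros((n, len(AGE_SEGMENTS)))
    exposure = np.zeros((n, len(AGE_SEGMENTS)))
    c3_death_w = 1.0 if ends_at_survey else 0.5
    for j, seg in enumerate(AGE_SEGMENTS):
        c1 = (dob >= start - seg.a_u) & (dob <= start - seg.a_l - 1)
        c2 = (dob >= start - seg.a_l) & (dob <= end - seg.a_u)
        c3 = (dob >= end - seg.a_u + 1) & (dob <= end - seg.a_l + 1)
        e_w = 1.0 * c2 + 0.5 * (c1 | c3)
        d_w = 1.0 * c2 + 0.5 * c1 + c3_death_w * c3
        in_seg = died & (b7 >= seg.a_l) & (b7 < seg.a_u)
        exposure[:, j] = e_w
        death[:, j] = d_w * in_seg

    return MortalityTallies(
        death=death, exposure=exposure, weight=np.asarray(weight, float),
        strata=np.asarray(strata), clusters=np.asarray(clusters), interview_cmc=itv,
    )


def component_probabilities(tallies: MortalityTallies) -> pd.DataFrame:
    """The eight component death probabilities with their tallies.

    Columns mirror the standard report: PROBABILITY, W.DEATHS, W.EXPOSURE,
    DEATHS, EXPOSURE — the unweighted sums keep the half-unit cohort
    weights, hence the half-integer death counts.
    """
    d_w = tallies.death_w.sum(axis=0)
    e_w = tallies.exposure_w.sum(axis=0)
    d_u = tallies.death.sum(axis=0)
    e_u = tallies.exposure.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(e_w > 0, d_w / e_w, np.nan)
    if np.any(e_w <= 0):
        _warnings.warn(
            "zero exposure in age segment(s) "
            f"{[AGE_SEGMENTS[j].label for j in np.flatnonzero(e_w <= 0)]}; "
            "probability reported as missing there",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "PROBABILITY": p,
            "W.DEATHS": d_w,
            "W.EXPOSURE": e_w,
            "DEATHS": d_u,
            "EXPOSURE": e_u,
        },
        index=[seg.label for seg in AGE_SEGMENTS],
    )


def compose_rates(p: np.ndarray) -> dict[str, float]:
    """Combine the eight component probabilities into the five rates.

    NNMR = 1000 p_1; IMR and CMR chain survival over segments 1-4 and 5-8;
    PNMR = IMR - NNMR; U5MR chains all eight.
    """
    p = np.asarray(p, float)
    if p.shape != (8,):
        raise ValueError("expected eight component probabilities")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("component probabilities must lie in [0, 1]")
    surv = 1.0 - p
    nnmr = 1000.0 * p[0]
    imr = 1000.0 * (1.0 - np.prod(surv[:4]))
    cmr = 1000.0 * (1.0 - np.prod(surv[4:]))
    u5mr = 1000.0 * (1.0 - np.prod(surv))
    return {
        "NNMR": nnmr,
        "PNMR": imr - nnmr,
        "IMR": imr,
        "CMR": cmr,
        "U5MR": u5mr,
    }


def _rates_from_tallies(tallies: MortalityTallies) -> dict[str, float]:
    d_w = tallies.death_w.sum(axis=0)
    e_w = tallies.exposure_w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(e_w > 0, d_w / e_w, 0.0)
    return compose_rates(np.clip(p, 0.0, 1.0))


def _rate_n_wn(tallies: MortalityTallies, segments: tuple[int, ...]) -> tuple[float, float]:
    """Distinct-children totals over the rate's constituent segments.

    Each child counts once, with its largest cohort exposure weight among
    the segments (1 for a full cohort-2 membership, 0.5 for edge cohorts),
    so single-segment rates reproduce that segment's exposure totals.
    """
    cols = [s - 1 for s in segments]
    contrib = tallies.exposure[:, cols].max(axis=1)
    return float(contrib.sum()), float((contrib * tallies.weight).sum())


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

@dataclass
class ChmortReport:
    """One childhood-mortality run: header facts plus the estimate table."""

    indicator: str
    period_months: int
    ends_at_survey: bool
    reference_end_decimal: float
    reference_end_label: str
    average_reference_period: float
    estimates: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)


def _prepare_children(
    data, cluster, strata, weight, date_of_interview, date_of_birth,
    age_at_death, weight_divisor, class_var,
):
    data = data.copy()
    data.columns = [str(c).lower() for c in data.columns]
    _, weights = resolve_design(data, cluster, strata, weight, weight_divisor)
    itv = pd.to_numeric(data[_resolve_column(data, date_of_interview)], errors="coerce")
    dob = pd.to_numeric(data[_resolve_column(data, date_of_birth)], errors="coerce")
    b7 = pd.to_numeric(data[_resolve_column(data, age_at_death)], errors="coerce")

    usable = itv.notna().to_numpy() & dob.notna().to_numpy()
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.info("%d birth records missing dates excluded", n_dropped)
    data = data.loc[usable].reset_index(drop=True)
    class_labels = data[_resolve_column(data, class_var)] if class_var else None
    return (
        dob.to_numpy(float)[usable].astype(np.int64),
        b7.to_numpy(float)[usable],
        itv.to_numpy(float)[usable].astype(np.int64),
        weights[usable],
        data[_resolve_column(data, strata)].to_numpy(),
        data[_resolve_column(data, cluster)].to_numpy(),
        class_labels, n_dropped,
    )


def _chmort_table(tallies: MortalityTallies, jk: bool, cl: float) -> pd.DataFrame:
    rates = _rates_from_tallies(tallies)
    replicate_rates: dict[str, np.ndarray] = {}
    if jk:
        # one delete-one-cluster pass; every replicate recomputes the full
        # tally reduction and yields all five rates at once
        distinct = pd.unique(tallies.clusters)
        if len(distinct) < 2:
            raise ValueError("jackknife needs >= 2 clusters")
        reps = [
            _rates_from_tallies(tallies.mask(tallies.clusters != c))
            for c in distinct
        ]
        replicate_rates = {
            name: np.array([r[name] for r in reps]) for name in RATE_LABELS
        }
    rows = []
    for name in RATE_LABELS:
        n_u, n_w = _rate_n_wn(tallies, RATE_SEGMENTS[name])
        row = {"Rate": name, "R": rates[name], "N": round(n_u), "WN": round(n_w)}
        if jk:
            reps_i = replicate_rates[name]
            k = len(reps_i)
            pseudo = k * rates[name] - (k - 1) * reps_i
            se = float(np.sqrt(np.sum((pseudo - rates[name]) ** 2) / (k * (k - 1))))
            res = variance.finalize(
                rates[name], se,
                variance.srs_proportion_se(rates[name], n_u), cl,
                iterations=k, replicates=reps_i,
            )
            row.update({
                "SE": res.se, "DEFT": res.deft, "RSE": res.rse,
                "LCI": res.lci, "UCI": res.uci, "iterations": res.iterations,
            })
        rows.append(row)
    cols = ["Rate", "R", "SE", "N", "WN", "DEFT", "RSE", "LCI", "UCI", "iterations"]
    frame = pd.DataFrame(rows)
    return frame[[c for c in cols if c in frame.columns]]


def _window_header(itv: np.ndarray, period: int, period_end: str | None):
    if period_end is None:
        end_dec = cmc_to_decimal_year(float(np.mean(itv)))
        label = f"{cmc_to_label(int(itv.min()))[:3]}—{cmc_to_label(int(itv.max()))}"
        ends_at_survey = True
    else:
        end_cmc = parse_period_end(period_end)
        end_dec = cmc_to_decimal_year(end_cmc)
        label = cmc_to_label(end_cmc)
        ends_at_survey = False
    avg = cmc_to_decimal_year(
        float(parse_period_end(period_end)) if period_end else float(np.mean(itv))
    ) - period / 24.0
    return end_dec, label, ends_at_survey, avg


def chmort(
    data: pd.DataFrame,
    jk: bool = False,
    cl: float = 95.0,
    cluster: str = "v021",
    strata: str = "v022",
    weight: str = "v005",
    date_of_interview: str = "v008",
    date_of_birth: str = "b3",
    age_at_death: str = "b7",
    period: int = 60,
    period_end: str | None = None,
    class_var: str | None = None,
    weight_divisor: float = DEFAULT_WEIGHT_DIVISOR,
) -> ChmortReport:
    """The five childhood mortality rates from a BR-shaped births table.

    Jackknife SEs, DEFT, RSE and CIs are attached when ``jk`` is set; with
    ``class_var`` each class is estimated independently (the jackknife then
    iterates over the clusters present in that class).
    """
    (dob, b7, itv, weights, strata_arr, cluster_arr,
     class_labels, n_dropped) = _prepare_children(
        data, cluster, strata, weight, date_of_interview, date_of_birth,
        age_at_death, weight_divisor, class_var,
    )
    if len(dob) == 0:
        raise ValueError("no usable birth records")

    run_warnings: list[str] = []
    if period_end is not None:
        note = fieldwork_warning(parse_period_end(period_end), itv)
        if note:
            run_warnings.append(note)
            logger.warning(note)

    def one_run(keep):
        tallies = tally_mortality(
            dob[keep], b7[keep], itv[keep], weights[keep],
            strata_arr[keep], cluster_arr[keep], period, period_end,
        )
        return _chmort_table(tallies, jk, cl)

    if class_labels is None:
        estimates = one_run(np.ones(len(dob), bool))
    else:
        labels = class_labels.astype(str).to_numpy()
        pieces = []
        for value in pd.unique(labels):
            tab = one_run(labels == value)
            tab.insert(0, "Class", value)
            pieces.append(tab)
        estimates = pd.concat(pieces, ignore_index=True)

    end_dec, label, ends_at_survey, avg = _window_header(itv, period, period_end)
    return ChmortReport(
        indicator="chmort", period_months=period, ends_at_survey=ends_at_survey,
        reference_end_decimal=end_dec, reference_end_label=label,
        average_reference_period=avg, estimates=estimates,
        warnings=run_warnings, dropped={"children": n_dropped},
    )


def chmortp(
    data: pd.DataFrame,
    cluster: str = "v021",
    strata: str = "v022",
    weight: str = "v005",
    date_of_interview: str = "v008",
    date_of_birth: str = "b3",
    age_at_death: str = "b7",
    period: int = 60,
    period_end: str | None = None,
    class_var: str | None = None,
    weight_divisor: float = DEFAULT_WEIGHT_DIVISOR,
) -> ChmortReport:
    """Component death probabilities per age segment (the chmortp surface)."""
    (dob, b7, itv, weights, strata_arr, cluster_arr,
     class_labels, n_dropped) = _prepare_children(
        data, cluster, strata, weight, date_of_interview, date_of_birth,
        age_at_death, weight_divisor, class_var,
    )
    if len(dob) == 0:
        raise ValueError("no usable birth records")

    run_warnings: list[str] = []
    if period_end is not None:
        note = fieldwork_warning(parse_period_end(period_end), itv)
        if note:
            run_warnings.append(note)
            logger.warning(note)

    def one_run(keep):
        tallies = tally_mortality(
            dob[keep], b7[keep], itv[keep], weights[keep],
            strata_arr[keep], cluster_arr[keep], period, period_end,
        )
        return component_probabilities(tallies)

    if class_labels is None:
        estimates = one_run(np.ones(len(dob), bool))
    else:
        labels = class_labels.astype(str).to_numpy()
        pieces = []
        for value in pd.unique(labels):
            tab = one_run(labels == value)
            tab.insert(0, "Class", value)
            pieces.append(tab)
        estimates = pd.concat(pieces)

    end_dec, label, ends_at_survey, avg = _window_header(itv, period, period_end)
    return ChmortReport(
        indicator="chmortp", period_months=period, ends_at_survey=ends_at_survey,
        reference_end_decimal=end_dec, reference_end_label=label,
        average_reference_period=avg, estimates=estimates,
        warnings=run_warnings, dropped={"children": n_dropped},
    )
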