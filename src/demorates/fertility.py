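"""Direct fertility estimation from woman-level birth histories.

Rates are occurrence/exposure rates over a reference window of calendar
months: for each five-year age group a (15-19 ... 45-49), the age-specific
fertility rate is

    ASFR_a = 1000 * B_a / E_a,

with B_a the (weighted) births to women while in group a during the window
and E_a the (weighted) woman-years those women lived in group a during the
window.  The total fertility rate is TFR = 5 * sum_a ASFR_a / 1000 and the
general fertility rate divides all births by the exposure of women 15-44.

A woman enters age group a in the month her age in completed months reaches
180 + 60 a and leaves it 60 months later, so one woman can spread her
window exposure over two adjacent groups.  By default the window is the
``period`` months ending the month before each woman's interview; a fixed
calendar end ("YYYY-MM", the last included month) can be set instead.

Ever-married samples are supported through the DHS all-women factors: a
percentage that inflates each woman's exposure (never her births) so that
rates refer to all women.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variance
from .survey_io import (
    DEFAULT_WEIGHT_DIVISOR,
    _resolve_column,
    cmc_to_decimal_year,
    cmc_to_label,
    parse_period_end,
    present_birth_columns,
    resolve_design,
)

logger = logging.getLogger("demorates")

AGE_GROUP_LABELS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]
N_AGE_GROUPS = 7

#: age in completed months at which group a = 0 begins
_FIRST_GROUP_START = 180
_GROUP_SPAN = 60


@dataclass(frozen=True)
class ReferenceWindow:
    """Inclusive CMC month interval [start_cmc, end_cmc] of exposure."""

    start_cmc: int
    end_cmc: int
    ends_at_survey: bool = True

    def __post_init__(self):
        if self.start_cmc > self.end_cmc:
            raise ValueError("window start must not exceed its end")

    @property
    def length_months(self) -> int:
        return self.end_cmc - self.start_cmc + 1


def resolve_window(
    interview_cmc: int, period_months: int = 36, period_end: str | None = None
) -> ReferenceWindow:
    """Reference window for one woman (or child).

    Without ``period_end`` the window is the ``period_months`` months ending
    the month before the interview (the interview month itself is excluded).
    With ``period_end`` ("YYYY-MM"), that month is the last included month,
    shared by all respondents.
    """
    if period_months < 1:
        raise ValueError("period_months must be >= 1")
    if period_end is None:
        end = int(interview_cmc) - 1
        ends_at_survey = True
    else:
        end = parse_period_end(period_end)
        ends_at_survey = False
    return ReferenceWindow(end - period_months + 1, end, ends_at_survey)


def average_reference_period(
    interview_cmcs: np.ndarray, period_months: int, period_end: str | None = None
) -> float:
    """Midpoint of the reference period as a decimal year.

    The reference end is the fixed period end when given, else the
    (unweighted) mean interview CMC; the midpoint sits period/24 years
    before it.
    """
    if period_end is not None:
        end = float(parse_period_end(period_end))
    else:
        end = float(np.mean(np.asarray(interview_cmcs, float)))
    return cmc_to_decimal_year(end) - period_months / 24.0


# ---------------------------------------------------------------------------
# Per-woman tallies (the unit operations; vectorized versions below)
# ---------------------------------------------------------------------------

def exposure_months_by_age_group(dob_cmc: int, window: ReferenceWindow) -> np.ndarray:
    """Months of exposure in each of the seven age groups during the window.

    In month m the woman has completed age m - dob months; she contributes
    to group a iff 180 + 60a <= m - dob <= 239 + 60a.  Months outside ages
    15-49 contribute nothing.
    """
    return _exposure_months(
        np.array([dob_cmc]), np.array([window.start_cmc]), np.array([window.end_cmc])
    )[0]


def births_by_age_group(
    dob_cmc: int, birth_cmcs, window: ReferenceWindow
) -> tuple[np.ndarray, int]:
    """Count window births per age group; returns (counts[7], n_dropped).

    A birth in month b falls in group floor((b - dob)/60) - 3; births with
    the mother outside 15-49 at birth are dropped (and counted), births
    before the mother's own birth are a contract violation.
    """
    counts = np.zeros(N_AGE_GROUPS, dtype=int)
    dropped = 0
    for b in birth_cmcs:
        b = int(b)
        if b < dob_cmc:
            raise ValueError(f"birth CMC {b} precedes mother's DOB {dob_cmc}")
        if not window.start_cmc <= b <= window.end_cmc:
            continue
        a = (b - dob_cmc) // _GROUP_SPAN - 3
        if 0 <= a < N_AGE_GROUPS:
            counts[a] += 1
        else:
            dropped += 1
    return counts, dropped


def _exposure_months(dob: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """(n, 7) months each woman spends in each age group within her window."""
    n = len(dob)
    out = np.zeros((n, N_AGE_GROUPS), dtype=np.int64)
    for a in range(N_AGE_GROUPS):
        lo = np.maximum(start, dob + _FIRST_GROUP_START + _GROUP_SPAN * a)
        hi = np.minimum(end, dob + _FIRST_GROUP_START + _GROUP_SPAN * a + _GROUP_SPAN - 1)
        out[:, a] = np.maximum(hi - lo + 1, 0)
    return out


# ---------------------------------------------------------------------------
# Dataset-level tally container
# ---------------------------------------------------------------------------

@dataclass
class FertilityTallies:
    """Woman-level exposure/birth matrices plus design labels.

    Everything downstream — point estimates, Taylor and jackknife variances,
    SRS baselines — reduces these arrays, so a jackknife replicate simply
    re-reduces them with one cluster masked out.
    """

    exposure_months: np.ndarray  # (n, 7) int months
    births: np.ndarray  # (n, 7) int counts
    weight: np.ndarray  # (n,)
    awfactor: np.ndarray  # (n,) percent
    strata: np.ndarray  # (n,) labels
    clusters: np.ndarray  # (n,) labels
    interview_cmc: np.ndarray  # (n,)
    dropped_births: int = 0

    @property
    def exposure_years_u(self) -> np.ndarray:
        return self.exposure_months / 12.0

    @property
    def exposure_years_w(self) -> np.ndarray:
        return self.exposure_months / 12.0 * (self.weight * self.awfactor / 100.0)[:, None]

    @property
    def births_w(self) -> np.ndarray:
        return self.births * self.weight[:, None]

    def mask(self, keep: np.ndarray) -> "FertilityTallies":
        return FertilityTallies(
            self.exposure_months[keep], self.births[keep], self.weight[keep],
            self.awfactor[keep], self.strata[keep], self.clusters[keep],
            self.interview_cmc[keep], self.dropped_births,
        )


def tally_fertility(
    dob_cmc: np.ndarray,
    interview_cmc: np.ndarray,
    birth_mother_idx: np.ndarray,
    birth_cmc: np.ndarray,
    weight: np.ndarray,
    awfactor: np.ndarray,
    strata: np.ndarray,
    clusters: np.ndarray,
    period_months: int = 36,
    period_end: str | None = None,
) -> FertilityTallies:
    """Vectorized exposure and birth tally over all women.

    ``birth_mother_idx``/``birth_cmc`` hold one entry per recorded birth,
    indexing into the woman arrays.
    """
    dob = np.asarray(dob_cmc, np.int64)
    itv = np.asarray(interview_cmc, np.int64)
    if period_end is None:
        end = itv - 1
    else:
        end = np.full(len(dob), parse_period_end(period_end), np.int64)
    start = end - period_months + 1

    exp_months = _exposure_months(dob, start, end)

    births = np.zeros((len(dob), N_AGE_GROUPS), dtype=np.int64)
    dropped = 0
    if len(birth_cmc):
        widx = np.asarray(birth_mother_idx, np.int64)
        bcmc = np.asarray(birth_cmc, np.int64)
        if np.any(bcmc < dob[widx]):
            raise ValueError("a recorded birth precedes its mother's date of birth")
        in_window = (bcmc >= start[widx]) & (bcmc <= end[widx])
        age_groups = (bcmc - dob[widx]) // _GROUP_SPAN - 3
        valid = in_window & (age_groups >= 0) & (age_groups < N_AGE_GROUPS)
        dropped = int(np.sum(in_window & ~valid))
        if dropped:
            logger.info(
                "%d births to mothers outside ages 15-49 at delivery dropped", dropped
            )
        np.add.at(births, (widx[valid], age_groups[valid]), 1)

    return FertilityTallies(
        exposure_months=exp_months,
        births=births,
        weight=np.asarray(weight, float),
        awfactor=np.asarray(awfactor, float),
        strata=np.asarray(strata),
        clusters=np.asarray(clusters),
        interview_cmc=itv,
        dropped_births=dropped,
    )


# ---------------------------------------------------------------------------
# Point estimators
# ---------------------------------------------------------------------------

def asfr_point(tallies: FertilityTallies) -> np.ndarray:
    """Seven ASFRs per 1000 woman-years (unrounded)."""
    b = tallies.births_w.sum(axis=0)
    e = tallies.exposure_years_w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(e > 0, 1000.0 * b / e, np.nan)
    if np.any(e <= 0):
        _warnings.warn(
            "zero exposure in age group(s) "
            f"{[AGE_GROUP_LABELS[a] for a in np.flatnonzero(e <= 0)]}; "
            "ASFR reported as missing there",
            stacklevel=2,
        )
    return rates


def tfr_point(tallies: FertilityTallies) -> float:
    """TFR = 5 * sum_a ASFR_a / 1000, from unrounded ASFRs."""
    b = tallies.births_w.sum(axis=0)
    e = tallies.exposure_years_w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        asfr = np.where(e > 0, 1000.0 * b / e, 0.0)
    return float(5.0 * np.sum(asfr) / 1000.0)


def gfr_point(tallies: FertilityTallies) -> float:
    """GFR per 1000: all births over exposure of women 15-44."""
    b = tallies.births_w.sum()
    e = tallies.exposure_years_w[:, :-1].sum()
    if e <= 0:
        raise ValueError("zero woman-years of exposure at ages 15-44")
    return float(1000.0 * b / e)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class FertReport:
    """One fertility run: header facts plus the estimate table."""

    indicator: str
    period_months: int
    ends_at_survey: bool
    reference_end_decimal: float
    reference_end_label: str
    average_reference_period: float
    estimates: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)


def _prepare_women(
    data: pd.DataFrame,
    cluster: str,
    strata: str,
    weight: str,
    date_of_interview: str,
    woman_dob: str,
    evermw: bool,
    awfact: str | None,
    weight_divisor: float,
    class_var: str | None,
):
    """Resolve columns, drop unusable rows, and return plain arrays."""
    data = data.copy()
    data.columns = [str(c).lower() for c in data.columns]
    _, weights = resolve_design(data, cluster, strata, weight, weight_divisor)
    itv_col = _resolve_column(data, date_of_interview)
    dob_col = _resolve_column(data, woman_dob)

    if awfact is not None and not evermw:
        raise ValueError("an all-women factor only applies to ever-married samples; "
                         "set evermw=True to use awfact")
    if evermw:
        awf_col = _resolve_column(data, awfact if awfact is not None else "awfactt")
        awf = pd.to_numeric(data[awf_col], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(awf)) or np.any(awf <= 0):
            raise ValueError(f"all-women factor {awf_col!r} must be positive")
    else:
        awf = np.full(len(data), 100.0)

    itv = pd.to_numeric(data[itv_col], errors="coerce").to_numpy(float)
    dob = pd.to_numeric(data[dob_col], errors="coerce").to_numpy(float)
    usable = np.isfinite(itv) & np.isfinite(dob)
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.info("%d women missing interview or birth-date CMC excluded", n_dropped)
    data = data.loc[usable].reset_index(drop=True)
    weights, awf, itv, dob = weights[usable], awf[usable], itv[usable], dob[usable]

    dob_cols = present_birth_columns(data, "b3_")
    rows, cmcs = [], []
    for col in dob_cols:
        vals = pd.to_numeric(data[col], errors="coerce").to_numpy(float)
        hit = np.isfinite(vals)
        rows.append(np.flatnonzero(hit))
        cmcs.append(vals[hit])
    birth_idx = np.concatenate(rows) if rows else np.empty(0, np.int64)
    birth_cmc = np.concatenate(cmcs) if cmcs else np.empty(0)

    class_labels = data[_resolve_column(data, class_var)] if class_var else None
    return (
        data, dob.astype(np.int64), itv.astype(np.int64), weights, awf,
        data[_resolve_column(data, strata)].to_numpy(),
        data[_resolve_column(data, cluster)].to_numpy(),
        birth_idx.astype(np.int64), birth_cmc.astype(np.int64),
        class_labels, n_dropped,
    )


def _group_n_wn(tallies) -> tuple[np.ndarray, np.ndarray]:
    """Per-group unweighted/weighted woman-years rounded to integers.

    Multi-group totals (TFR, GFR) sum these rounded group values, so the
    reported GFR N equals the TFR N minus the 45-49 group's N exactly.
    """
    n = np.round(tallies.exposure_years_u.sum(axis=0)).astype(int)
    wn = np.round(tallies.exposure_years_w.sum(axis=0)).astype(int)
    return n, wn


def _asfr_table(tallies, cl, collapse_strata):
    rates = asfr_point(tallies)
    b_w, e_w = tallies.births_w, tallies.exposure_years_w
    n_groups, wn_groups = _group_n_wn(tallies)
    rows = []
    for a, label in enumerate(AGE_GROUP_LABELS):
        se = variance.taylor_ratio_se(
            1000.0 * b_w[:, a], e_w[:, a], tallies.strata, tallies.clusters,
            collapse_strata=collapse_strata,
        )
        se_srs = variance.srs_ratio_se(1000.0 * b_w[:, a], e_w[:, a])
        res = variance.finalize(rates[a], se, se_srs, cl)
        rows.append({
            "AGE": label, "ASFR": rates[a], "SE": res.se,
            "N": int(n_groups[a]), "WN": int(wn_groups[a]),
            "DEFT": res.deft, "RSE": res.rse, "LCI": res.lci, "UCI": res.uci,
        })
    return pd.DataFrame(rows)


def _gfr_table(tallies, cl, collapse_strata):
    rate = gfr_point(tallies)
    y = 1000.0 * tallies.births_w.sum(axis=1)
    x = tallies.exposure_years_w[:, :-1].sum(axis=1)
    se = variance.taylor_ratio_se(
        y, x, tallies.strata, tallies.clusters, collapse_strata=collapse_strata
    )
    res = variance.finalize(rate, se, variance.srs_ratio_se(y, x), cl)
    n_groups, wn_groups = _group_n_wn(tallies)
    return pd.DataFrame([{
        "GFR": rate, "SE": res.se,
        "N": int(n_groups[:-1].sum()), "WN": int(wn_groups[:-1].sum()),
        "DEFT": res.deft, "RSE": res.rse, "LCI": res.lci, "UCI": res.uci,
    }])


def _tfr_table(tallies, jk, cl):
    rate = tfr_point(tallies)
    n_groups, wn_groups = _group_n_wn(tallies)
    row = {"TFR": rate, "N": int(n_groups.sum()), "WN": int(wn_groups.sum())}
    if jk:
        def estimator(excluded):
            sub = tallies if excluded is None else tallies.mask(
                tallies.clusters != excluded
            )
            return tfr_point(sub)

        jk_res = variance.jackknife_se(tallies.clusters, estimator)
        # SRS baseline: per-woman linearized TFR contribution
        b_w, e_w = tallies.births_w, tallies.exposure_years_w
        E = e_w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            asfr_frac = np.where(E > 0, b_w.sum(axis=0) / E, 0.0)
            u = 5.0 * np.sum(
                np.where(E > 0, (b_w - asfr_frac[None, :] * e_w) / E[None, :], 0.0),
                axis=1,
            )
        res = variance.finalize(
            rate, jk_res.se, variance.srs_residual_se(u), cl,
            iterations=jk_res.iterations, replicates=jk_res.replicates,
        )
        row.update({
            "SE": res.se, "DEFT": res.deft, "RSE": res.rse,
            "LCI": res.lci, "UCI": res.uci, "iterations": res.iterations,
        })
        order = ["TFR", "SE", "N", "WN", "DEFT", "RSE", "LCI", "UCI", "iterations"]
        return pd.DataFrame([row])[order]
    return pd.DataFrame([row])


def fieldwork_warning(end_cmc: int, interview_cmcs: np.ndarray) -> str | None:
    """Warn when a fixed period end overlaps or postdates the fieldwork."""
    itv = np.asarray(interview_cmcs)
    if end_cmc > itv.max():
        return (
            "You specified a reference period that ends after the survey "
            "fieldwork dates. Make sure the dates in the survey are coded "
            "according to the Gregorian calendar; otherwise use a PeriodEnd "
            "expressed in the survey's own calendar."
        )
    if end_cmc >= itv.min():
        return (
            "The specified reference period ends inside the survey fieldwork "
            "span; respondents interviewed before the period end contribute "
            "no information after their interview."
        )
    return None


def fert(
    data: pd.DataFrame,
    indicator: str = "tfr",
    jk: bool = False,
    cl: float = 95.0,
    cluster: str = "v021",
    strata: str = "v022",
    weight: str = "v005",
    date_of_interview: str = "v008",
    woman_dob: str = "v011",
    evermw: bool = False,
    awfact: str | None = None,
    period: int = 36,
    period_end: str | None = None,
    class_var: str | None = None,
    weight_divisor: float = DEFAULT_WEIGHT_DIVISOR,
    collapse_strata: bool = False,
) -> FertReport:
    """Fertility rates (ASFR, TFR or GFR) from an IR-shaped women table.

    Taylor-linearized standard errors are always attached to ASFR and GFR;
    the TFR gets a delete-one-cluster jackknife SE when ``jk`` is set.
    With ``class_var`` the estimation runs independently within each class.
    """
    indicator = indicator.lower()
    if indicator not in {"asfr", "tfr", "gfr"}:
        raise ValueError(f"indicator must be 'asfr', 'tfr' or 'gfr', got {indicator!r}")

    (_, dob, itv, weights, awf, strata_arr, cluster_arr,
     birth_idx, birth_cmc, class_labels, n_dropped_women) = _prepare_women(
        data, cluster, strata, weight, date_of_interview, woman_dob,
        evermw, awfact, weight_divisor, class_var,
    )
    if len(dob) == 0:
        raise ValueError("no usable women records")

    run_warnings: list[str] = []
    if period_end is not None:
        note = fieldwork_warning(parse_period_end(period_end), itv)
        if note:
            run_warnings.append(note)
            logger.warning(note)

    def one_run(keep: np.ndarray) -> tuple[pd.DataFrame, int]:
        kept_birth = keep[birth_idx]
        # reindex mothers into the subset
        new_pos = np.cumsum(keep) - 1
        tallies = tally_fertility(
            dob[keep], itv[keep], new_pos[birth_idx[kept_birth]],
            birth_cmc[kept_birth], weights[keep], awf[keep],
            strata_arr[keep], cluster_arr[keep], period, period_end,
        )
        if indicator == "asfr":
            return _asfr_table(tallies, cl, collapse_strata), tallies.dropped_births
        if indicator == "gfr":
            return _gfr_table(tallies, cl, collapse_strata), tallies.dropped_births
        return _tfr_table(tallies, jk, cl), tallies.dropped_births

    dropped_births = 0
    if class_labels is None:
        estimates, dropped_births = one_run(np.ones(len(dob), bool))
    else:
        labels = class_labels.astype(str).to_numpy()
        pieces = []
        for value in pd.unique(labels):
            tab, d = one_run(labels == value)
            tab.insert(0, "Class", value)
            pieces.append(tab)
            dropped_births += d
        estimates = pd.concat(pieces, ignore_index=True)

    if period_end is None:
        end_dec = cmc_to_decimal_year(float(np.mean(itv)))
        label = f"{cmc_to_label(int(itv.min()))[:3]}—{cmc_to_label(int(itv.max()))}"
        ends_at_survey = True
    else:
        end_cmc = parse_period_end(period_end)
        end_dec = cmc_to_decimal_year(end_cmc)
        label = cmc_to_label(end_cmc)
        ends_at_survey = False

    return FertReport(
        indicator=indicator,
        period_months=period,
        ends_at_survey=ends_at_survey,
        reference_end_decimal=end_dec,
        reference_end_label=label,
        average_reference_period=average_reference_period(itv, period, period_end),
        estimates=estimates,
        warnings=run_warnings,
        dropped={"women": n_dropped_women, "births_outside_15_49": dropped_births},
    )
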