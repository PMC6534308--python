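"""Synthetic DHS-format surveys with known true rates.

The generator emits a matched pair of tables in the DHS recode layout — a
women (IR-style) table with wide birth-history columns ``b3_01..b3_20`` /
``b7_01..b7_20`` and a births (BR-style) table with one row per live birth
— so every estimator and variance routine in the package can be exercised
end to end against known parameters.

The demographic model is deliberately minimal:

* fertility is a monthly Bernoulli process: while a woman is in age group
  a she bears a child each month with probability f_a, independent of
  parity and birth spacing, so the true age-specific rate is
  ASFR*_a = 12000 f_a and TFR* = 5 * sum_a 12 f_a;
* child survival follows stationary conditional segment hazards p*_i: a
  child alive at the start of segment i dies within it with probability
  p*_i, at an age uniform over the segment's months.  Deaths that would
  fall after the mother's interview are unobserved (the child is recorded
  as surviving), reproducing the right-censoring the synthetic-cohort
  estimator is built to handle.

Weights are constant or cluster-varying; the two-stage design is strata x
clusters x women with equal cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import AGE_SEGMENTS, compose_rates

#: monthly birth probabilities per age group; a moderately high-fertility
#: schedule peaking at ages 20-29, TFR* just under 4
DEFAULT_BIRTH_PROBS = (0.009, 0.017, 0.0165, 0.012, 0.0085, 0.003, 0.0005)

#: conditional death probabilities per age segment; NNMR* ~ 29, U5MR* ~ 69,
#: the level of a contemporary southern-African survey
DEFAULT_DEATH_PROBS = (0.0286, 0.0055, 0.0060, 0.0109,
                       0.0112, 0.0039, 0.0023, 0.0026)


@dataclass
class SimulationConfig:
    """Design and demographic parameters of one synthetic survey."""

    n_strata: int = 4
    clusters_per_stratum: int = 10
    women_per_cluster: int = 25
    #: inclusive CMC range of interview months (default Jul-Dec 2015)
    interview_cmc_range: tuple[int, int] = (1387, 1392)
    #: woman's age at interview drawn uniformly over these completed months
    age_months_range: tuple[int, int] = (180, 599)
    monthly_birth_prob: tuple[float, ...] = DEFAULT_BIRTH_PROBS
    segment_death_prob: tuple[float, ...] = DEFAULT_DEATH_PROBS
    #: "constant" or "cluster" (weights uniform on [0.5, 1.5] per cluster)
    weight_model: str = "cluster"
    #: probability a woman is ever-married; None = all-women survey
    ever_married_fraction: float | None = None
    class_values: tuple[str, str] = ("urban", "rural")

    def __post_init__(self):
        f = np.asarray(self.monthly_birth_prob, float)
        p = np.asarray(self.segment_death_prob, float)
        if len(f) != 7 or np.any((f < 0) | (f > 1)):
            raise ValueError("monthly_birth_prob must be 7 probabilities in [0, 1]")
        if len(p) != len(AGE_SEGMENTS) or np.any((p < 0) | (p > 1)):
            raise ValueError("segment_death_prob must be 8 probabilities in [0, 1]")
        if self.n_strata * self.clusters_per_stratum * self.women_per_cluster == 0:
            raise ValueError("empty survey design")
        if self.weight_model not in {"constant", "cluster"}:
            raise ValueError("weight_model must be 'constant' or 'cluster'")
        if self.ever_married_fraction is not None and not (
            0 < self.ever_married_fraction <= 1
        ):
            raise ValueError("ever_married_fraction must be in (0, 1]")


def true_rates(config: SimulationConfig) -> dict[str, float]:
    """Expected rates implied by the configuration.

    Fertility: ASFR*_a = 12000 f_a (scaled by the ever-married fraction when
    only married women bear children); mortality: the five rates composed
    from the configured segment probabilities.
    """
    f = np.asarray(config.monthly_birth_prob, float)
    em = config.ever_married_fraction if config.ever_married_fraction else 1.0
    asfr = 12000.0 * f * em
    out = {f"ASFR_{lab}": v for lab, v in zip(
        ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"], asfr
    )}
    out["TFR"] = float(5.0 * np.sum(asfr) / 1000.0)
    out.update(compose_rates(np.asarray(config.segment_death_prob, float)))
    return out


def _simulate_deaths(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent age at death in completed months per child (-1 = survives to 5+).

    Sequential conditional hazards: a child alive at a_l of segment i dies
    within the segment with probability p_i, at a uniform month in
    [a_l, a_u).
    """
    age = np.full(n, -1, dtype=np.int64)
    alive = np.ones(n, bool)
    for j, seg in enumerate(AGE_SEGMENTS):
        dies = alive & (rng.random(n) < probs[j])
        if dies.any():
            age[dies] = rng.integers(seg.a_l, seg.a_u, size=int(dies.sum()))
        alive &= ~dies
    return age


def generate_survey(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one survey; returns the (IR-style, BR-style) table pair.

    Deterministic under ``seed``; the two layouts are mutually consistent
    (exploding the IR wide columns reproduces the BR rows).
    """
    rng = np.random.default_rng(seed)
    n_clusters = config.n_strata * config.clusters_per_stratum
    n_women = n_clusters * config.women_per_cluster

    v022 = np.repeat(np.arange(1, config.n_strata + 1),
                     config.clusters_per_stratum * config.women_per_cluster)
    v021 = np.repeat(np.arange(1, n_clusters + 1), config.women_per_cluster)
    if config.weight_model == "constant":
        cluster_w = np.ones(n_clusters)
    else:
        cluster_w = rng.uniform(0.5, 1.5, n_clusters)
    v005 = np.round(cluster_w[v021 - 1] * 1_000_000).astype(np.int64)
    v025 = np.asarray(config.class_values)[
        rng.integers(0, len(config.class_values), n_clusters)
    ][v021 - 1]

    lo, hi = config.interview_cmc_range
    v008 = rng.integers(lo, hi + 1, n_women)
    age_lo, age_hi = config.age_months_range
    age_months = rng.integers(age_lo, age_hi + 1, n_women)
    v011 = v008 - age_months

    married = np.ones(n_women, bool)
    if config.ever_married_fraction is not None:
        married = rng.random(n_women) < config.ever_married_fraction

    # monthly Bernoulli births over each woman's fecund months before interview
    f = np.asarray(config.monthly_birth_prob, float)
    max_span = age_hi - 180 + 1
    offsets = np.arange(max_span)
    month = (v011[:, None] + 180) + offsets[None, :]  # calendar month per slot
    valid = month < v008[:, None]  # exposure strictly before the interview month
    group = offsets // 60  # age group index per slot
    prob = f[np.minimum(group, 6)]
    draws = rng.random((n_women, max_span))
    births_mask = valid & (draws < prob[None, :]) & married[:, None]

    w_idx, slot = np.nonzero(births_mask)
    b3 = month[w_idx, slot]

    # child survival: latent death age, censored at the interview
    latent = _simulate_deaths(len(b3), np.asarray(config.segment_death_prob), rng)
    observed_death = (latent >= 0) & (b3 + latent <= v008[w_idx])
    b7 = np.where(observed_death, latent, np.nan)

    women = pd.DataFrame({
        "caseid": np.arange(1, n_women + 1),
        "v005": v005, "v008": v008, "v011": v011,
        "v021": v021, "v022": v022, "v025": v025,
    })

    # all-women factors per age group from the simulated population
    if config.ever_married_fraction is not None:
        grp = np.minimum((v008 - v011 - 180) // 60, 6)
        factors = np.full(7, 100.0)
        for a in range(7):
            total = np.sum(grp == a)
            em = np.sum((grp == a) & married)
            if em:
                factors[a] = 100.0 * total / em
        women["awfactt"] = factors[grp]
        women = women.loc[married].reset_index(drop=True)
        keep_birth = married[w_idx]
        w_idx = np.cumsum(married)[w_idx[keep_birth]] - 1  # reindex into kept women
        b3, b7 = b3[keep_birth], b7[keep_birth]

    # wide birth-history columns, chronological order, capped at 20 slots
    n_kept = len(women)
    order = np.lexsort((b3, w_idx))
    w_sorted, b3_s, b7_s = w_idx[order], b3[order], b7[order]
    line = np.ones(len(w_sorted), np.int64)
    if len(w_sorted):
        same = np.concatenate([[False], w_sorted[1:] == w_sorted[:-1]])
        for i in range(1, len(line)):
            if same[i]:
                line[i] = line[i - 1] + 1
    in_slots = line <= 20
    wide_b3 = np.full((n_kept, 20), np.nan)
    wide_b7 = np.full((n_kept, 20), np.nan)
    wide_b3[w_sorted[in_slots], line[in_slots] - 1] = b3_s[in_slots]
    wide_b7[w_sorted[in_slots], line[in_slots] - 1] = b7_s[in_slots]
    for i in range(20):
        women[f"b3_{i + 1:02d}"] = wide_b3[:, i]
        women[f"b7_{i + 1:02d}"] = wide_b7[:, i]

    mothers = women.iloc[w_sorted[in_slots]].reset_index(drop=True)
    births = pd.DataFrame({
        "caseid": mothers["caseid"],
        "bidx": line[in_slots],
        "v005": mothers["v005"], "v008": mothers["v008"], "v011": mothers["v011"],
        "v021": mothers["v021"], "v022": mothers["v022"], "v025": mothers["v025"],
        "b3": b3_s[in_slots].astype(np.int64),
        "b7": b7_s[in_slots],
    })
    if "awfactt" in women.columns:
        births["awfactt"] = mothers["awfactt"].to_numpy()
    return women, births
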