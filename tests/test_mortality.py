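import numpy as np
import pandas as pd
import pytest

from demorates import chmort, chmortp
from demorates.mortality import (
    AGE_SEGMENTS,
    RATE_LABELS,
    assign_cohort,
    component_probabilities,
    compose_rates,
    death_in_segment,
    tally_mortality,
)

from oracles import brute_force_mortality, random_children

SEG = {s.label: s for s in AGE_SEGMENTS}


def _tallies_from_dicts(children, period, fixed_end=None):
    period_end = None
    if fixed_end is not None:
        year = 1900 + (fixed_end - 1) // 12
        month = (fixed_end - 1) % 12 + 1
        period_end = f"{year:04d}-{month:02d}"
    return tally_mortality(
        np.array([c["dob"] for c in children]),
        np.array([np.nan if c["b7"] is None else c["b7"] for c in children]),
        np.array([c["itv"] for c in children]),
        np.array([c["weight"] for c in children]),
        strata=np.ones(len(children), int),
        clusters=np.arange(len(children)),
        period_months=period, period_end=period_end,
    )


class TestCohortAssignment:
    def test_five_year_window_segment_3_5(self):
        """Windows ending at a survey in Sep 2018: cohort month ranges for 3-5m."""
        # 60 months ending the month before a September 2018 interview
        start, end = 1365, 1424  # Sep 2013 .. Aug 2018
        seg = SEG["3-5"]
        for dob in range(1359, 1362):  # Mar-May 2013
            assert assign_cohort(dob, seg, start, end) == 1
        for dob in range(1362, 1419):  # Jun 2013-Feb 2018
            assert assign_cohort(dob, seg, start, end) == 2
        for dob in range(1419, 1423):  # Mar-Jun 2018
            assert assign_cohort(dob, seg, start, end) == 3
        for dob in range(1423, 1426):  # Jul-Sep 2018: no cohort
            assert assign_cohort(dob, seg, start, end) == 0

    def test_one_year_window_child_memberships(self):
        """A Dec 2015-Nov 2016 window: membership of children born around it."""
        start, end = 1392, 1403
        expected = {
            1388: {"0": 0, "1-2": 0, "3-5": 1, "6-11": 2},  # child A, Aug 2015
            1389: {"0": 0, "1-2": 1, "3-5": 2, "6-11": 2},  # child B, Sep 2015
            1390: {"0": 0, "1-2": 1, "3-5": 2, "6-11": 2},  # child C, Oct 2015
            1392: {"0": 2, "1-2": 2, "3-5": 2, "6-11": 3},  # child D, Dec 2015
            1394: {"0": 2, "1-2": 2, "3-5": 2, "6-11": 3},  # child E, Feb 2016
            1396: {"0": 2, "1-2": 2, "3-5": 2, "6-11": 3},  # child F, Apr 2016
            1397: {"0": 2, "1-2": 2, "3-5": 2, "6-11": 3},  # child G, May 2016
        }
        for dob, memberships in expected.items():
            for label, cohort in memberships.items():
                assert assign_cohort(dob, SEG[label], start, end) == cohort, (dob, label)

    def test_cohorts_partition_without_gap_or_overlap(self):
        """For every segment and window, cohorts 1/2/3 tile the feasible DOBs."""
        for seg in AGE_SEGMENTS:
            for start, period in [(1365, 60), (1392, 12), (1300, 120)]:
                end = start + period - 1
                lo, hi = start - seg.a_u, end - seg.a_l + 1
                for dob in range(lo - 3, hi + 4):
                    cohort = assign_cohort(dob, seg, start, end)
                    inside = lo <= dob <= hi
                    assert (cohort > 0) == inside, (seg.label, dob)

    def test_cohort_three_is_one_month_wider(self):
        for seg in AGE_SEGMENTS:
            start, end = 1365, 1424
            c1 = [d for d in range(1200, 1500) if assign_cohort(d, seg, start, end) == 1]
            c3 = [d for d in range(1200, 1500) if assign_cohort(d, seg, start, end) == 3]
            assert len(c3) == len(c1) + 1 == seg.a_u - seg.a_l + 1


class TestDeathInSegment:
    @pytest.mark.parametrize(
        "age,label,expected",
        [
            (0, "0", True), (1, "0", False),
            (5, "3-5", True), (6, "3-5", False), (3, "3-5", True),
            (59, "48-59", True),
        ],
    )
    def test_half_open_bounds(self, age, label, expected):
        assert death_in_segment(age, SEG[label]) is expected

    def test_age_60_belongs_to_no_segment(self):
        assert not any(death_in_segment(60, seg) for seg in AGE_SEGMENTS)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            death_in_segment(-1, SEG["0"])


class TestComponentProbabilities:
    def test_no_deaths_gives_zero_probabilities(self):
        children = [
            {"dob": 1400, "itv": 1420, "weight": 1.0, "b7": None} for _ in range(10)
        ]
        table = component_probabilities(_tallies_from_dicts(children, 60))
        assert (table["PROBABILITY"].fillna(0) == 0).all()

    def test_single_full_cohort_death(self):
        # child well inside the window, died in its first month
        children = [{"dob": 1380, "itv": 1420, "weight": 1.0, "b7": 0}]
        table = component_probabilities(_tallies_from_dicts(children, 60))
        assert table.loc["0", "PROBABILITY"] == pytest.approx(1.0)

    def test_half_weighted_edge_cohort_death(self):
        """One cohort-1 death plus one surviving cohort-2 child: p = 1/3."""
        # fixed window Jan 2013..Dec 2017; segment 12-23 months
        fixed_end = 1415  # Dec 2017 window start 1356
        children = [
            # born 14 months before window start: in cohort 1 of 12-23m
            {"dob": 1356 - 14, "itv": 1420, "weight": 1.0, "b7": 13},
            {"dob": 1380, "itv": 1420, "weight": 1.0, "b7": None},
        ]
        table = component_probabilities(_tallies_from_dicts(children, 60, fixed_end))
        assert table.loc["12-23", "PROBABILITY"] == pytest.approx(1 / 3)
        assert table.loc["12-23", "DEATHS"] == pytest.approx(0.5)
        assert table.loc["12-23", "EXPOSURE"] == pytest.approx(1.5)

    def test_cohort_three_deaths_full_weight_only_at_survey(self):
        """The same late-born dead child counts 1.0 deaths when the window
        ends at the survey but 0.5 under a fixed calendar end."""
        child = {"dob": 1423, "itv": 1425, "weight": 1.0, "b7": 1}
        at_survey = _tallies_from_dicts([child], 60)  # end = 1424
        fixed = _tallies_from_dicts([child], 60, fixed_end=1424)
        j = 1  # segment 1-2 months: dob 1423 is cohort 3 for end 1424
        assert at_survey.death[0, j] == 1.0
        assert fixed.death[0, j] == 0.5
        assert at_survey.exposure[0, j] == fixed.exposure[0, j] == 0.5

    def test_unweighted_sums_are_half_integers(self, survey_pair):
        _, br = survey_pair
        table = chmortp(br).estimates
        for col in ("DEATHS", "EXPOSURE"):
            np.testing.assert_allclose(
                (2 * table[col].to_numpy()) % 1.0, 0.0, atol=1e-9
            )


class TestComposeRates:
    def test_all_zero(self):
        rates = compose_rates(np.zeros(8))
        assert all(v == 0 for v in rates.values())

    def test_neonatal_only(self):
        rates = compose_rates(np.array([0.05, 0, 0, 0, 0, 0, 0, 0]))
        for name in ("NNMR", "IMR", "U5MR"):
            assert rates[name] == pytest.approx(50.0)
        assert rates["PNMR"] == pytest.approx(0.0, abs=1e-9)
        assert rates["CMR"] == 0.0

    def test_infant_rate_from_published_probabilities(self):
        p = np.array([0.0286, 0.0055, 0.0060, 0.0109, 0, 0, 0, 0])
        assert compose_rates(p)["IMR"] == pytest.approx(50.14, abs=0.1)

    def test_identities(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.05, 8)
        rates = compose_rates(p)
        assert rates["PNMR"] == rates["IMR"] - rates["NNMR"]
        lhs = 1 - rates["U5MR"] / 1000
        rhs = (1 - rates["IMR"] / 1000) * (1 - rates["CMR"] / 1000)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            compose_rates(np.array([1.2, 0, 0, 0, 0, 0, 0, 0]))
        with pytest.raises(ValueError):
            compose_rates(np.zeros(7))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("fixed_end", [None, 1400])
    def test_per_child_evaluation_matches(self, seed, fixed_end):
        """Scalar per-child cohort/death sums reproduce every D_i and E_i."""
        rng = np.random.default_rng(seed)
        children = random_children(rng, 50)
        d_u, d_w, e_u, e_w = brute_force_mortality(children, 60, fixed_end)
        t = _tallies_from_dicts(children, 60, fixed_end)
        np.testing.assert_allclose(t.death.sum(axis=0), d_u, rtol=1e-12)
        np.testing.assert_allclose(t.death_w.sum(axis=0), d_w, rtol=1e-12)
        np.testing.assert_allclose(t.exposure.sum(axis=0), e_u, rtol=1e-12)
        np.testing.assert_allclose(t.exposure_w.sum(axis=0), e_w, rtol=1e-12)


class TestChmortDriver:
    def test_zero_deaths_zero_rates_and_ses(self, survey_pair):
        _, br = survey_pair
        alive = br.assign(b7=np.nan)
        report = chmort(alive, jk=True)
        assert (report.estimates["R"] == 0).all()
        assert (report.estimates["SE"] == 0).all()

    def test_rate_row_order(self, survey_pair):
        _, br = survey_pair
        assert list(chmort(br).estimates["Rate"]) == RATE_LABELS

    def test_class_run_equals_subset_runs(self, survey_pair):
        _, br = survey_pair
        by_class = chmort(br, class_var="v025").estimates
        for value in br["v025"].unique():
            sub = chmort(br[br["v025"] == value]).estimates.set_index("Rate")
            rows = by_class[by_class["Class"] == value].set_index("Rate")
            for name in RATE_LABELS:
                assert rows.loc[name, "R"] == pytest.approx(
                    sub.loc[name, "R"], rel=1e-12
                )

    def test_point_estimates_invariant_to_weight_scale(self, survey_pair):
        _, br = survey_pair
        base = chmort(br).estimates["R"].to_numpy()
        scaled = chmort(br.assign(v005=br["v005"] * 3)).estimates["R"].to_numpy()
        np.testing.assert_allclose(base, scaled, rtol=1e-12)

    def test_age_at_death_beyond_interview_rejected(self):
        bad = pd.DataFrame(
            {
                "v005": [1_000_000], "v008": [1420], "v021": [1], "v022": [1],
                "b3": [1415], "b7": [24.0],
            }
        )
        with pytest.raises(ValueError, match="age at death"):
            chmort(bad)

    def test_missing_required_column(self, survey_pair):
        _, br = survey_pair
        with pytest.raises(KeyError):
            chmort(br.drop(columns=["b3"]))
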