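"""Independent brute-force oracles used by the test suite.

These evaluators loop woman-by-woman and month-by-month (fertility) or
child-by-child and segment-by-segment (mortality) with scalar arithmetic,
sharing no code with the vectorized implementations they check.
"""

import numpy as np

SEGMENT_BOUNDS = [(0, 1), (1, 3), (3, 6), (6, 12), (12, 24), (24, 36), (36, 48), (48, 60)]


def brute_force_fertility(women, period, fixed_end=None):
    """Month-enumeration tally of births and exposure by age group.

    ``women``: iterable of dicts with keys dob, itv, weight, awf (percent),
    births (list of CMCs).  Returns (B_u, B_w, E_months_u, E_w_years) as
    length-7 arrays.
    """
    b_u = np.zeros(7)
    b_w = np.zeros(7)
    e_months = np.zeros(7)
    e_w = np.zeros(7)
    for w in women:
        end = (w["itv"] - 1) if fixed_end is None else fixed_end
        start = end - period + 1
        for m in range(start, end + 1):
            age = m - w["dob"]
            if 180 <= age < 600:
                a = (age - 180) // 60
                e_months[a] += 1
                e_w[a] += w["weight"] * w.get("awf", 100.0) / 100.0 / 12.0
        for b in w["births"]:
            if start <= b <= end:
                age = b - w["dob"]
                a = age // 60 - 3
                if 0 <= a <= 6:
                    b_u[a] += 1
                    b_w[a] += w["weight"]
    return b_u, b_w, e_months, e_w


def classify_cohort(dob, a_l, a_u, start, end):
    """Scalar cohort classification (1/2/3/0) for one child and segment."""
    if start - a_u <= dob <= start - a_l - 1:
        return 1
    if start - a_l <= dob <= end - a_u:
        return 2
    if end - a_u + 1 <= dob <= end - a_l + 1:
        return 3
    return 0


def brute_force_mortality(children, period, fixed_end=None):
    """Per-child evaluation of segment death/exposure sums.

    ``children``: iterable of dicts with keys dob, itv, weight and b7
    (None for survivors).  Returns (D_u, D_w, E_u, E_w) length-8 arrays;
    the unweighted sums carry the half-unit cohort weights.
    """
    d_u = np.zeros(8)
    d_w = np.zeros(8)
    e_u = np.zeros(8)
    e_w = np.zeros(8)
    ends_at_survey = fixed_end is None
    for ch in children:
        end = (ch["itv"] - 1) if ends_at_survey else fixed_end
        start = end - period + 1
        for j, (a_l, a_u) in enumerate(SEGMENT_BOUNDS):
            cohort = classify_cohort(ch["dob"], a_l, a_u, start, end)
            if cohort == 0:
                continue
            exp_w = 1.0 if cohort == 2 else 0.5
            if cohort == 2:
                death_w = 1.0
            elif cohort == 1:
                death_w = 0.5
            else:
                death_w = 1.0 if ends_at_survey else 0.5
            e_u[j] += exp_w
            e_w[j] += exp_w * ch["weight"]
            if ch["b7"] is not None and a_l <= ch["b7"] < a_u:
                d_u[j] += death_w
                d_w[j] += death_w * ch["weight"]
    return d_u, d_w, e_u, e_w


def random_women(rng, n):
    """Random small fertility fixture for oracle comparisons."""
    women = []
    for _ in range(n):
        itv = int(rng.integers(1380, 1420))
        dob = itv - int(rng.integers(150, 650))
        n_births = int(rng.integers(0, 5))
        births = sorted(
            int(b) for b in rng.integers(max(dob + 150, 1000), itv, size=n_births)
        )
        women.append(
            {
                "dob": dob,
                "itv": itv,
                "weight": float(rng.uniform(0.5, 2.0)),
                "awf": float(rng.choice([100.0, 125.0])),
                "births": births,
            }
        )
    return women


def random_children(rng, n):
    """Random small mortality fixture for oracle comparisons."""
    children = []
    for _ in range(n):
        itv = int(rng.integers(1380, 1420))
        dob = itv - int(rng.integers(0, 90))
        age_at_itv = itv - dob
        b7 = None
        if rng.random() < 0.3 and age_at_itv > 0:
            b7 = int(rng.integers(0, min(age_at_itv, 60)))
        children.append(
            {"dob": dob, "itv": itv, "weight": float(rng.uniform(0.5, 2.0)), "b7": b7}
        )
    return children
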