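"""Open fractions, cohort stepping, adult survival, and the population projection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import saimaa_bycatch as sb
from saimaa_bycatch.errors import EstimationError
from saimaa_bycatch.mortality import AgeFrequencyTable


def _schedule(coverage=0.95, years=(2018,)):
    return sb.ClosureSchedule(coverage={y: coverage for y in years})


# ---------------------------------------------------------------------------
# Open fraction
# ---------------------------------------------------------------------------


def test_open_fraction_inside_spring_window():
    sched = _schedule(0.95, years=(2018, 2019))
    assert sched.open_fraction(2018, 5) == pytest.approx(0.05)


def test_open_fraction_outside_window_is_one():
    sched = _schedule(0.95, years=(2018, 2019))
    assert sched.open_fraction(2018, 10) == 1.0


def test_year_round_ban_closes_everything():
    sched = sb.ClosureSchedule(coverage={2018: 0.5}, scenario="year_round_ban")
    assert all(sched.open_fraction(2018, b) == 0.0 for b in range(30))


def test_second_spring_uses_next_years_coverage():
    sched = sb.ClosureSchedule(coverage={2000: 0.2, 2001: 0.8})
    assert sched.open_fraction(2000, 27) == pytest.approx(0.2)  # 1 - 0.8
    assert sched.open_fraction(2000, 5) == pytest.approx(0.8)  # 1 - 0.2


def test_bin_out_of_range_rejected():
    with pytest.raises(ValueError):
        _schedule().open_fraction(2018, 30)


# ---------------------------------------------------------------------------
# Cohort initialisation and stepping
# ---------------------------------------------------------------------------


def _pups(rows):
    return pd.DataFrame(rows, columns=["year", "pups_born", "observed_age0_deaths"])


def test_init_cohort_subtraction():
    pups = _pups([(2000, 50, 5), (2021, 90, 0)])
    assert sb.init_cohort(pups, 2000) == 45
    assert sb.init_cohort(pups, 2021) == 90
    with pytest.raises(KeyError):
        sb.init_cohort(pups, 1999)
    with pytest.raises(ValueError):
        sb.init_cohort(_pups([(2000, 10, 11)]), 2000)


def test_step_cohort_no_mortality():
    traj = sb.step_cohort(80.0, 0.4, np.zeros(30), np.zeros(30), np.ones(30))
    assert traj.survivors_15m == 80.0
    assert traj.deaths_total.sum() == 0.0


def test_step_cohort_hand_example():
    """One active bin with N=100, m=0.9, Pr=0.1, P(C)=0.5, O=0.5."""
    b = -2.0 * math.log(0.9)  # so exp(-b/2) = 0.9
    pr = np.zeros(30)
    pr[1] = 0.1
    conf = np.zeros(30)
    conf[1] = 0.5
    open_frac = np.ones(30)
    open_frac[1] = 0.5
    traj = sb.step_cohort(100.0, b, pr, conf, open_frac)
    potential = traj.deaths_total[1] + traj.averted[1]
    assert potential == pytest.approx(9.0)
    assert traj.bycatch[1] == pytest.approx(2.25)
    assert traj.deaths_other[1] == pytest.approx(4.5)
    assert traj.averted[1] == pytest.approx(2.25)
    assert traj.n[2] == pytest.approx(93.25)


def test_full_closure_zeroes_bycatch_and_maximises_survivors(rng):
    pr = rng.dirichlet(np.ones(30))
    conf = np.concatenate([[0.0], rng.uniform(0, 1, 29)])
    open_frac = rng.uniform(0, 1, 30)
    closed = sb.step_cohort(100.0, 0.3, pr, conf, np.zeros(30))
    partial = sb.step_cohort(100.0, 0.3, pr, conf, open_frac)
    assert np.all(closed.bycatch == 0.0)
    assert closed.survivors_15m >= partial.survivors_15m


def test_bin0_confidence_must_be_zero():
    conf = np.full(30, 0.2)
    with pytest.raises(ValueError, match="bin 0"):
        sb.step_cohort(10.0, 0.3, np.full(30, 1 / 30), conf, np.ones(30))


def test_implausible_death_fraction_rejected():
    pr = np.zeros(30)
    pr[3] = 1.5  # m * Pr > 1
    with pytest.raises(EstimationError):
        sb.step_cohort(10.0, 0.0, pr, np.zeros(30), np.ones(30))


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_cohort_conservation_property(seed):
    """N_age0 equals survivors plus realized deaths, to 1e-9."""
    r = np.random.default_rng(seed)
    pr = r.dirichlet(np.ones(30))
    conf = np.concatenate([[0.0], r.uniform(0, 1, 29)])
    open_frac = r.uniform(0, 1, 30)
    n0 = r.uniform(10, 1000)
    traj = sb.step_cohort(n0, r.uniform(0.05, 1.5), pr, conf, open_frac)
    balance = traj.survivors_15m + traj.deaths_total.sum() - n0
    assert abs(balance) < 1e-9
    assert (traj.n >= 0).all()
    assert (traj.bycatch >= 0).all() and (traj.deaths_other >= 0).all()


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bycatch_monotone_in_open_fraction(seed):
    """Element-wise smaller O never increases bycatch nor decreases survivors."""
    r = np.random.default_rng(seed)
    pr = r.dirichlet(np.ones(30))
    conf = np.concatenate([[0.0], r.uniform(0, 1, 29)])
    open_a = r.uniform(0, 1, 30)
    open_b = open_a * r.uniform(0, 1, 30)  # element-wise smaller
    t_a = sb.step_cohort(500.0, 0.4, pr, conf, open_a)
    t_b = sb.step_cohort(500.0, 0.4, pr, conf, open_b)
    assert t_b.bycatch.sum() <= t_a.bycatch.sum() + 1e-12
    assert t_b.survivors_15m >= t_a.survivors_15m - 1e-12


def test_zero_confidence_reduces_to_pure_survival(rng):
    """With P(C) = 0 the survivors are N0 * prod(1 - m*Pr_i)."""
    pr = rng.dirichlet(np.ones(30))
    b = 0.6
    m = math.exp(-b / 2)
    traj = sb.step_cohort(321.0, b, pr, np.zeros(30), rng.uniform(0, 1, 30))
    assert traj.survivors_15m == pytest.approx(321.0 * np.prod(1 - m * pr), rel=1e-12)


def test_run_cohorts_one_trajectory_per_year(small_dataset):
    pups = small_dataset["pups"]
    schedule = small_dataset["closures"]
    pr = np.full(30, 1 / 30)
    conf = np.concatenate([[0.0], np.full(29, 0.4)])
    trajs = sb.run_cohorts(pups, 0.25, pr, conf, schedule)
    assert len(trajs) == len(pups)
    assert [t.year for t in trajs] == sorted(pups["year"])


def test_run_cohorts_matches_brute_force_recursion(small_dataset):
    """Per-year bycatch equals a plain-python re-evaluation of the recursion."""
    pups = small_dataset["pups"]
    schedule = small_dataset["closures"]
    pr = np.full(30, 1 / 30)
    conf = np.concatenate([[0.0], np.full(29, 0.4)])
    b = 0.25
    trajs = sb.run_cohorts(pups, b, pr, conf, schedule)
    m = math.exp(-b / 2)
    for traj in trajs:
        n = sb.init_cohort(pups, traj.year)
        total_c = 0.0
        for i in range(30):
            o = schedule.open_fraction(traj.year, i)
            dead = n * m * pr[i]
            c = dead * conf[i] * o
            other = dead * (1 - conf[i])
            total_c += c
            n = n - c - other
        assert traj.total_bycatch == pytest.approx(total_c, rel=1e-12)
        assert traj.survivors_15m == pytest.approx(n, rel=1e-12)


def test_missing_schedule_year_raises(small_dataset):
    pups = small_dataset["pups"]
    schedule = sb.ClosureSchedule(coverage={1991: 0.5})
    pr = np.full(30, 1 / 30)
    conf = np.concatenate([[0.0], np.full(29, 0.4)])
    with pytest.raises(KeyError):
        sb.run_cohorts(pups, 0.25, pr, conf, schedule)


# ---------------------------------------------------------------------------
# Adults
# ---------------------------------------------------------------------------


def test_flat_adult_frequencies_give_survival_one():
    df = pd.DataFrame(
        {"stage": "adult", "age_years": np.repeat(np.arange(1, 31) + 0.5, 4)}
    )
    surv = sb.estimate_adult_survival(df)
    assert surv.annual_survival == 1.0


def test_adult_survival_from_exponential_frequencies():
    ages = np.arange(1, 31).astype(float)
    counts = np.round(500 * np.exp(-0.15 * ages)).astype(int)
    df = pd.DataFrame(
        {
            "stage": "adult",
            "age_years": np.repeat(ages + 0.2, counts),
        }
    )
    surv = sb.estimate_adult_survival(df)
    assert surv.annual_survival == pytest.approx(math.exp(-0.15), abs=0.01)


def test_empty_adult_data_raise():
    df = pd.DataFrame({"stage": "adult", "age_years": []})
    with pytest.raises(EstimationError):
        sb.estimate_adult_survival(df)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def _cohort_stub(year, survivors):
    pr = np.zeros(30)
    traj = sb.step_cohort(survivors, 0.0, pr, np.zeros(30), np.ones(30), year=year)
    return traj


def test_projection_starts_at_default_total():
    cohorts = [_cohort_stub(1991 + i, 0.0) for i in range(5)]
    pop = sb.project_population(cohorts, 1.0)
    assert pop.totals.loc[1990] == pytest.approx(189.0)


def test_projection_matches_age_ledger_oracle():
    """Totals equal an explicit per-class ledger: ageing, exit at 30, recruits."""
    survivors = {1991 + i: 10.0 + 3.0 * i for i in range(6)}
    cohorts = [_cohort_stub(y, s) for y, s in survivors.items()]
    s = 0.9
    pop = sb.project_population(cohorts, s, start_total=200.0)

    ledger = list(sb.stable_age_distribution(s) * 200.0)
    for year in range(1991, 1997):
        recruit = survivors.get(year - 1, survivors[year])  # first-year stand-in
        ledger = [recruit] + [x * s for x in ledger[:-1]]  # class 30 exits
        assert pop.totals.loc[year] == pytest.approx(sum(ledger), rel=1e-12)


def test_zero_recruitment_decline_tracks_exiting_mass():
    cohorts = [_cohort_stub(2001 + i, 0.0) for i in range(4)]
    s = 1.0
    pop = sb.project_population(cohorts, s, start_total=189.0)
    # with survival 1 the only loss is the uniform class-30 mass exiting
    per_class = 189.0 / 30
    for i, year in enumerate(range(2001, 2005), start=1):
        assert pop.totals.loc[year] == pytest.approx(189.0 - per_class * i, rel=1e-12)


def test_projection_missing_cohort_year_raises():
    cohorts = [_cohort_stub(1991, 5.0), _cohort_stub(1993, 5.0)]
    with pytest.raises(KeyError):
        sb.project_population(cohorts, 0.9)
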