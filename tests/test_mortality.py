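"""Catch-curve and k-NN death-proportion estimators against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import saimaa_bycatch as sb
from saimaa_bycatch.errors import EstimationError
from saimaa_bycatch.mortality import AgeFrequencyTable


def _juv_table(ages_months):
    return pd.DataFrame({"stage": "juvenile", "age_months": ages_months})


def _freq(stage, counts):
    counts = np.asarray(counts, dtype=int)
    if stage == "juvenile":
        bins = np.arange(30)
        ages = bins * 0.5
    else:
        bins = np.arange(1, 31)
        ages = bins.astype(float)
    return AgeFrequencyTable(stage=stage, bins=bins, ages=ages, counts=counts)


def _ols_oracle(ages, counts):
    """Closed-form OLS of ln(count+1) on age over the limb from the modal bin."""
    counts = np.asarray(counts, dtype=float)
    modal = int(np.argmax(counts))
    x = np.asarray(ages, dtype=float)[modal:]
    y = np.log(counts[modal:] + 1.0)
    x_mean, y_mean = x.mean(), y.mean()
    slope = np.sum((x - x_mean) * (y - y_mean)) / np.sum((x - x_mean) ** 2)
    return slope, y_mean - slope * x_mean


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def test_empty_table_gives_zero_counts():
    freq = sb.bin_carcass_ages(_juv_table([]), "juvenile")
    assert (freq.counts == 0).all()
    assert (freq.log_counts == 0.0).all()
    assert len(freq.bins) == 30


def test_half_open_binning():
    freq = sb.bin_carcass_ages(_juv_table([0.2, 0.7, 0.7]), "juvenile")
    assert freq.counts[0] == 1
    assert freq.counts[1] == 2
    assert freq.counts[2:].sum() == 0


def test_negative_ages_rejected_with_warning(caplog):
    with caplog.at_level("WARNING"):
        freq = sb.bin_carcass_ages(_juv_table([-1.0, 0.2]), "juvenile")
    assert freq.counts.sum() == 1
    assert "negative" in caplog.text


def test_binning_preserves_cause_marginal(small_dataset):
    """Total juvenile records equal the sum over bins, so cause tallies survive."""
    carcasses = small_dataset["carcasses"]
    juv = carcasses[carcasses["stage"] == "juvenile"]
    freq = sb.bin_carcass_ages(carcasses, "juvenile")
    assert freq.counts.sum() == len(juv)
    fishing = int((juv["cause_group"] == "fishing").sum())
    fishing_binned = sum(
        int(((juv["bin"] == b) & (juv["cause_group"] == "fishing")).sum())
        for b in range(30)
    )
    assert fishing == fishing_binned


# ---------------------------------------------------------------------------
# Catch curve
# ---------------------------------------------------------------------------


def test_flat_counts_give_zero_slope():
    fit = sb.fit_catch_curve(_freq("juvenile", np.full(30, 17)))
    assert fit.b == 0.0
    assert fit.half_month_factor == 1.0


def test_catch_curve_matches_ols_oracle_juvenile():
    ages = np.arange(30) * 0.5
    counts = np.round(1000 * np.exp(-0.5 * ages)).astype(int)
    fit = sb.fit_catch_curve(_freq("juvenile", counts))
    slope, intercept = _ols_oracle(ages, counts)
    assert fit.b == pytest.approx(-slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)


def test_catch_curve_recovers_slope_at_large_amplitude():
    """With large counts the ln(count+1) offset vanishes and b ≈ the true slope."""
    ages = np.arange(30) * 0.5
    counts = np.round(1e6 * np.exp(-0.5 * ages)).astype(int)
    fit = sb.fit_catch_curve(_freq("juvenile", counts))
    assert fit.b == pytest.approx(0.5, abs=0.01)
    ages_y = np.arange(1, 31).astype(float)
    counts_y = np.round(5e5 * np.exp(-0.2 * ages_y)).astype(int)
    fit_y = sb.fit_catch_curve(_freq("adult", counts_y))
    assert fit_y.b == pytest.approx(0.2, abs=0.01)


def test_too_few_positive_bins_raise():
    counts = np.zeros(30, dtype=int)
    counts[[3, 9]] = 5
    with pytest.raises(EstimationError):
        sb.fit_catch_curve(_freq("juvenile", counts))


def test_non_negative_limb_slope_clamps_to_zero():
    # modal bin first, a dip, then a long high plateau: the limb's OLS slope
    # is positive, which the fit clamps to b = 0 with a warning
    counts = np.concatenate([[148, 0, 0, 0], np.full(26, 133)])
    with pytest.warns(UserWarning, match="clamping"):
        fit = sb.fit_catch_curve(_freq("juvenile", counts))
    assert fit.b == 0.0
    assert fit.half_month_factor == 1.0


@given(
    st.lists(st.integers(min_value=0, max_value=5000), min_size=30, max_size=30).filter(
        lambda c: sum(x > 0 for x in c) >= 3
    )
)
def test_catch_curve_equals_oracle_on_any_input(counts):
    """The fitted slope and intercept equal closed-form OLS on the limb."""
    freq = _freq("juvenile", counts)
    arr = np.asarray(counts, dtype=float)
    modal = int(np.argmax(arr))
    y = np.log(arr[modal:] + 1.0)
    if np.allclose(y, y[0]):
        fit = sb.fit_catch_curve(freq)
        assert fit.b == 0.0
        return
    slope, intercept = _ols_oracle(freq.ages, arr)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sb.fit_catch_curve(freq)
    assert fit.b == pytest.approx(max(0.0, -slope), abs=1e-10)
    assert np.exp(-fit.b / 2) == pytest.approx(fit.half_month_factor, abs=1e-12)


# ---------------------------------------------------------------------------
# k-NN death proportions
# ---------------------------------------------------------------------------


def test_point_mass_is_exact_at_k1():
    table = _juv_table(np.full(50, 0.1))
    model = sb.fit_death_proportions(table, [1])
    assert model.pr[0] == pytest.approx(1.0)
    assert model.pr[1:].max() == pytest.approx(0.0)


def test_uniform_deaths_give_uniform_proportions(rng):
    bins = rng.integers(0, 30, 3000)
    table = _juv_table(bins * 0.5 + 0.2)
    model = sb.fit_death_proportions(table, [1, 5, 30], seed=0)
    assert np.abs(model.pr - 1 / 30).max() < 0.01


@given(st.integers(min_value=30, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
def test_smoothing_with_k_at_least_nbins_gives_global_mean(k, seed):
    props = np.random.default_rng(seed).dirichlet(np.ones(30))
    smoothed = sb.knn_smooth_proportions(props, k)
    assert np.allclose(smoothed, 1 / 30, atol=1e-12)


@given(st.integers(min_value=1, max_value=29), st.integers(min_value=0, max_value=2**31 - 1))
def test_smoothed_proportions_form_a_simplex(k, seed):
    props = np.random.default_rng(seed).dirichlet(np.ones(30))
    smoothed = sb.knn_smooth_proportions(props, k)
    assert smoothed.sum() == pytest.approx(1.0, abs=1e-9)
    assert (smoothed >= 0).all() and (smoothed <= 1).all()


def test_cv_selection_matches_brute_force_oracle(rng):
    """k chosen by the estimator equals an exhaustive fold-by-fold recomputation."""
    from sklearn.model_selection import KFold

    bins = np.concatenate([rng.integers(0, 10, 300), rng.integers(0, 30, 200)])
    table = _juv_table(bins * 0.5 + 0.1)
    k_grid = [2, 7]
    seed = 4
    model = sb.fit_death_proportions(table, k_grid, seed=seed)

    def props_of(idx):
        out = np.zeros(30)
        for b in bins[idx]:
            out[b] += 1
        return out / out.sum()

    def smooth(props, k):
        out = np.zeros(30)
        for i in range(30):
            order = sorted(range(30), key=lambda j: (abs(i - j), j))[:k]
            out[i] = np.mean([props[j] for j in order])
        return out / out.sum()

    losses = {}
    for k in k_grid:
        fold_losses = []
        for train, test in KFold(10, shuffle=True, random_state=seed).split(bins):
            fold_losses.append(
                float(np.sum((smooth(props_of(train), k) - props_of(test)) ** 2))
            )
        losses[k] = np.mean(fold_losses)
    oracle_k = min(losses, key=lambda k: (losses[k], k))
    assert model.k == oracle_k
    assert model.cv_error_by_k[oracle_k] == pytest.approx(losses[oracle_k], abs=1e-12)


def test_oversized_k_skipped_then_all_skipped_raises(rng):
    table = _juv_table(rng.integers(0, 30, 12) * 0.5)
    with pytest.warns(UserWarning, match="skipping k"):
        model = sb.fit_death_proportions(table, [3, 50], seed=0)
    assert model.k == 3
    with pytest.raises(EstimationError):
        with pytest.warns(UserWarning, match="skipping k"):
            sb.fit_death_proportions(table, [50], seed=0)


def test_too_few_records_raise():
    with pytest.raises(EstimationError):
        sb.fit_death_proportions(_juv_table([0.2] * 5), [1])
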