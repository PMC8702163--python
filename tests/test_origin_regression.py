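import math

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence
from hypothesis import given, settings
from hypothesis import strategies as st

from detectcomp.errors import (
    DegenerateDesignError,
    DegenerateResidualsError,
    DomainError,
    InsufficientDataError,
)
from detectcomp.origin_regression import (
    fit_through_origin,
    log_counts,
    standardize_residuals,
)


def test_log_counts_matches_natural_log():
    out = log_counts([1.0, math.e, math.e**2])
    assert out == pytest.approx([0.0, 1.0, 2.0], abs=1e-12)
    assert log_counts([10.0])[0] == pytest.approx(2.302585092994046, abs=1e-12)
    assert log_counts([100.0], base=10)[0] == pytest.approx(2.0, abs=1e-12)


def test_log_counts_names_offending_population():
    with pytest.raises(DomainError, match="badger_site"):
        log_counts([5.0, 0.0], population_ids=["marten_site", "badger_site"])


def test_exact_proportional_data_gives_unit_r2():
    fit = fit_through_origin([1, 2, 3], [2, 4, 6])
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.r2_uncentered == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(fit.residuals, 0.0, atol=1e-12)


def test_hand_computed_minimal_fit():
    # points (1,1), (2,3) plus the informationless (0,0):
    # slope = (1*1 + 2*3)/(1 + 4) = 1.4; residuals (-0.4, 0.2, 0); RSS = 0.2;
    # R2 = 1 - 0.2/10 = 0.98; df = 2; sigma2 = 0.1; F = 9.8/0.1 = 98;
    # se = sqrt(0.1/5)
    fit = fit_through_origin([1.0, 2.0, 0.0], [1.0, 3.0, 0.0])
    assert fit.slope == pytest.approx(1.4, abs=1e-12)
    rss = float(fit.residuals @ fit.residuals)
    assert rss == pytest.approx(0.2, abs=1e-12)
    assert fit.r2_uncentered == pytest.approx(0.98, abs=1e-12)
    assert fit.f_stat == pytest.approx(98.0, rel=1e-12)
    assert fit.slope_se == pytest.approx(math.sqrt(0.1 / 5), rel=1e-12)
    assert fit.df_resid == 2


def test_fit_matches_statsmodels_no_intercept_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 40))
        x = rng.normal(2.0, 1.0, size=n)
        y = rng.normal(1.0, 0.5) * x + rng.normal(0, 0.4, size=n)
        fit = fit_through_origin(x, y)
        sm_fit = sm.OLS(y, x[:, None]).fit()
        assert fit.slope == pytest.approx(sm_fit.params[0], abs=1e-10)
        assert fit.slope_se == pytest.approx(sm_fit.bse[0], abs=1e-10)
        assert fit.r2_uncentered == pytest.approx(sm_fit.rsquared, abs=1e-10)
        assert fit.f_stat == pytest.approx(sm_fit.fvalue, rel=1e-9)
        assert fit.df_resid == sm_fit.df_resid
        assert fit.p_value == pytest.approx(sm_fit.f_pvalue, abs=1e-12)
        assert np.allclose(fit.residuals, sm_fit.resid, atol=1e-10)
        stud = OLSInfluence(sm_fit).resid_studentized_internal
        assert np.allclose(fit.studentized_residuals, stud, atol=1e-8)


def test_type_invariants_hold_on_random_data():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(3, 30))
        x = rng.normal(1, 1, n)
        y = rng.normal(0, 1, n)
        fit = fit_through_origin(x, y)
        rss = float(fit.residuals @ fit.residuals)
        syy = float(np.dot(y, y))
        assert fit.r2_uncentered == pytest.approx(1 - rss / syy, abs=1e-12)
        assert fit.f_stat == pytest.approx(
            (syy - rss) / (rss / fit.df_resid), rel=1e-9
        )
        assert 0.0 <= fit.r2_uncentered <= 1.0
        assert fit.df_resid == n - 1


def test_r2_invariant_to_joint_rescaling():
    rng = np.random.default_rng(11)
    x = rng.normal(2, 1, 20)
    y = 0.9 * x + rng.normal(0, 0.3, 20)
    base = fit_through_origin(x, y)
    scaled = fit_through_origin(3.7 * x, 3.7 * y)
    assert scaled.r2_uncentered == pytest.approx(base.r2_uncentered, rel=1e-12)
    assert scaled.slope == pytest.approx(base.slope, rel=1e-12)


def test_slope_recovered_within_three_se():
    """y = beta*x + noise: |slope - beta| < 3 SE in >= 99% of replicates."""
    rng = np.random.default_rng(2024)
    beta, n, reps = 1.0, 27, 1000
    hits = 0
    for _ in range(reps):
        x = rng.normal(3.0, 1.2, n)
        y = beta * x + rng.normal(0, 0.42, n)
        fit = fit_through_origin(x, y)
        hits += abs(fit.slope - beta) < 3 * fit.slope_se
    assert hits / reps >= 0.99


def test_standardize_residuals_formula_and_options():
    rng = np.random.default_rng(5)
    x = rng.normal(2, 1, 15)
    y = x + rng.normal(0, 0.3, 15)
    fit = fit_through_origin(x, y)
    expected = fit.residuals / (fit.sigma * np.sqrt(1 - fit.leverages))
    assert np.allclose(standardize_residuals(fit), expected, atol=1e-12)
    plain = standardize_residuals(fit, kind="plain")
    assert np.allclose(plain, fit.residuals / np.std(fit.residuals, ddof=1), atol=1e-12)
    with pytest.raises(DomainError):
        standardize_residuals(fit, kind="bogus")


def test_symmetric_residuals_studentize_symmetrically():
    # equal leverage within each x-pair and residuals +-0.2, +-0.3:
    # studentized values must be symmetric about zero pairwise
    x = np.array([1.0, 1.0, 2.0, 2.0])
    y = x + np.array([0.2, -0.2, 0.3, -0.3])
    fit = fit_through_origin(x, y)
    stud = standardize_residuals(fit)
    assert stud[0] == pytest.approx(-stud[1], rel=1e-12)
    assert stud[2] == pytest.approx(-stud[3], rel=1e-12)
    assert np.all(np.isfinite(stud))


def test_degenerate_inputs_raise():
    with pytest.raises(InsufficientDataError):
        fit_through_origin([1, 2], [1, 3])
    with pytest.raises(DegenerateDesignError):
        fit_through_origin([0, 0, 0], [1, 2, 3])
    perfect = fit_through_origin([1, 2, 3], [2, 4, 6])
    with pytest.raises(DegenerateResidualsError):
        standardize_residuals(perfect)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.1, max_value=50), min_size=3, max_size=25),
    st.integers(min_value=0, max_value=2**16),
)
def test_r2_bounded_for_arbitrary_positive_counts(xs, noise_seed):
    rng = np.random.default_rng(noise_seed)
    x = np.log(np.asarray(xs))
    if float(x @ x) == 0.0:
        x = x + 0.1
    y = x + rng.normal(0, 0.5, x.size)
    fit = fit_through_origin(x, y)
    assert 0.0 <= fit.r2_uncentered <= 1.0
    assert fit.slope_se >= 0.0
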