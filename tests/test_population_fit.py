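from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tumornlme import (
    EstimationError,
    FitResult,
    FitSettings,
    GrowthDataset,
    PopulationParams,
    StudyDesign,
    log_likelihood,
    lrt,
    predict_intervals,
    predict_volume,
    saem_fit,
    simulate_cohort,
    two_stage_fit,
)
from tumornlme.growth_model import TreatmentSchedule

FAST = dict(n_burnin=40, n_sa=30, loglik_samples=0)


def _bare_fit(pop, arms=("vehicle",)):
    """FitResult wrapper around given population values (no estimation)."""
    return FitResult(
        estimates=pop, covariate_effects={}, arms=tuple(arms),
        loglik=None, loglik_se=None, trace=pd.DataFrame(), converged=True,
        seed=0, covariate_model={}, n_animals=0, n_obs=0,
    )


# ---------------------------------------------------------------------------
# two-stage oracle
# ---------------------------------------------------------------------------


def test_two_stage_single_noiseless_animal_recovers_truth():
    pop = PopulationParams(omega_k=0.0, omega_vmax=0.0, omega_eff=0.0,
                           sigma_prop=0.0, sigma_add=0.0)
    design = StudyDesign(arms=("vehicle",), n_per_arm=1,
                         obs_times=tuple(np.arange(0.0, 10.1, 1.0)), seed=3)
    dataset, _ = simulate_cohort(design, pop)
    est = two_stage_fit(dataset)
    assert est.k_growth_mean == pytest.approx(0.64, rel=0.01)
    assert est.v_max_mean == pytest.approx(1620.0, rel=0.01)
    assert est.gamma == pytest.approx(0.17, abs=0.01)
    assert est.omega_k == 0.0
    assert est.omega_vmax == 0.0


def test_two_stage_duplicated_animal_has_zero_spread():
    pop = PopulationParams(omega_k=0.0, omega_vmax=0.0, omega_eff=0.0,
                           sigma_prop=0.0, sigma_add=0.0)
    design = StudyDesign(arms=("vehicle",), n_per_arm=1,
                         obs_times=tuple(np.arange(0.0, 10.1, 1.0)), seed=3)
    dataset, _ = simulate_cohort(design, pop)
    dup = dataset.data.copy()
    dup["animal_id"] = "clone"
    both = GrowthDataset(pd.concat([dataset.data, dup], ignore_index=True))
    est = two_stage_fit(both)
    assert est.omega_k == pytest.approx(0.0, abs=1e-9)
    assert est.omega_vmax == pytest.approx(0.0, abs=1e-9)


def test_two_stage_recovers_rate_spread_in_heterogeneous_cohort():
    pop = PopulationParams(omega_k=0.39, omega_vmax=0.2, omega_eff=0.0,
                           sigma_prop=0.02, sigma_add=0.5)
    design = StudyDesign(arms=("vehicle",), n_per_arm=50,
                         obs_times=tuple(np.arange(0.0, 10.1, 1.0)), seed=13)
    dataset, _ = simulate_cohort(design, pop)
    est = two_stage_fit(dataset)
    assert est.omega_k == pytest.approx(0.39, rel=0.25)


def test_two_stage_needs_four_observations_per_animal():
    pop = PopulationParams()
    design = StudyDesign(arms=("vehicle",), n_per_arm=3,
                         obs_times=(0.0, 3.5, 7.0), seed=1)
    dataset, _ = simulate_cohort(design, pop)
    with pytest.raises(EstimationError, match="4 observations"):
        two_stage_fit(dataset)


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------


def test_saem_degenerate_noiseless_limit_recovers_truth():
    # no inter-individual variability and near-zero residual error:
    # effectively nonlinear least squares on a shared curve
    pop = PopulationParams(omega_k=0.0, omega_vmax=0.0, omega_eff=0.0,
                           sigma_prop=0.002, sigma_add=0.05)
    design = StudyDesign(arms=("vehicle",), n_per_arm=6,
                         obs_times=tuple(np.arange(0.0, 10.1, 1.0)), seed=5)
    dataset, _ = simulate_cohort(design, pop)
    fit = saem_fit(dataset, FitSettings(seed=2, n_burnin=120, n_sa=80,
                                        loglik_samples=0))
    assert fit.estimates.k_growth_mean == pytest.approx(0.64, rel=0.01)
    assert fit.estimates.v_max_mean == pytest.approx(1620.0, rel=0.01)
    assert fit.estimates.gamma == pytest.approx(0.17, abs=0.01)


def test_saem_estimates_invariant_to_row_order_and_relabeling(
        dense_vehicle_cohort):
    dataset, _ = dense_vehicle_cohort
    fit = saem_fit(dataset, FitSettings(seed=6, **FAST))
    shuffled = GrowthDataset(
        dataset.data.sample(frac=1.0, random_state=0).reset_index(drop=True))
    fit_shuffled = saem_fit(shuffled, FitSettings(seed=6, **FAST))
    assert fit.estimates == fit_shuffled.estimates
    # order-preserving relabeling of the animal ids
    relabeled = dataset.data.copy()
    relabeled["animal_id"] = relabeled["animal_id"].str.replace(
        "vehicle", "mouse", regex=False)
    fit_relabeled = saem_fit(GrowthDataset(relabeled),
                             FitSettings(seed=6, **FAST))
    assert fit.estimates == fit_relabeled.estimates


def test_saem_requires_two_animals():
    pop = PopulationParams()
    design = StudyDesign(arms=("vehicle",), n_per_arm=1, seed=1)
    dataset, _ = simulate_cohort(design, pop)
    with pytest.raises(EstimationError, match="2 animals"):
        saem_fit(dataset, FitSettings(**FAST))


def test_fit_settings_validation():
    with pytest.raises(ValueError, match="step_exponent"):
        FitSettings(step_exponent=0.3)
    with pytest.raises(ValueError, match="covariate"):
        FitSettings(covariate_model={"slope": ["A438079"]})


# ---------------------------------------------------------------------------
# observed-data log-likelihood & LRT
# ---------------------------------------------------------------------------


def test_loglik_matches_analytic_sum_when_variability_vanishes():
    # data generated without inter-individual variability, evaluated under
    # the matching zero-omega model: the random-effect integral degenerates
    tight = PopulationParams(omega_k=1e-6, omega_vmax=1e-6, omega_eff=1e-6)
    design = StudyDesign(arms=("vehicle",), n_per_arm=8,
                         obs_times=(0.0, 2.0, 4.0, 7.0, 10.0),
                         study_end=10.0, seed=19)
    dataset, _ = simulate_cohort(design, tight)
    fit = _bare_fit(tight)
    ll, se = log_likelihood(dataset, fit, n_samples=2000, seed=8)
    # with omegas ~ 0 the integral degenerates to the residual density at
    # the population parameters (skipping each animal's anchor point)
    expected = 0.0
    sched = TreatmentSchedule(treated=False)
    for _, g in dataset.data.groupby("animal_id"):
        g = g.sort_values("time_day")
        p = predict_volume(
            __import__("tumornlme").GompertzParams(
                k_growth=tight.k_growth_mean, v_max=tight.v_max_mean,
                gamma=tight.gamma, v0=g["volume_mm3"].iloc[0]),
            sched, g["time_day"].to_numpy())
        sd = tight.sigma_add + tight.sigma_prop * p[1:]
        expected += norm.logpdf(g["volume_mm3"].to_numpy()[1:], p[1:],
                                sd).sum()
    assert ll == pytest.approx(expected, abs=0.2)


def test_loglik_invariant_to_animal_relabeling(dense_vehicle_cohort):
    dataset, pop = dense_vehicle_cohort
    fit = _bare_fit(pop)
    ll_a = log_likelihood(dataset, fit, n_samples=500, seed=3)[0]
    relabeled = dataset.data.copy()
    relabeled["animal_id"] = relabeled["animal_id"].str.replace(
        "vehicle", "mouse", regex=False)
    ll_b = log_likelihood(GrowthDataset(relabeled), fit, n_samples=500,
                          seed=3)[0]
    assert ll_a == pytest.approx(ll_b, abs=1e-9)


def test_saem_estimates_beat_perturbed_initial_values(dense_vehicle_cohort):
    dataset, pop = dense_vehicle_cohort
    fit = saem_fit(dataset, FitSettings(seed=1, n_burnin=80, n_sa=60,
                                        loglik_samples=0))
    ll_fit = log_likelihood(dataset, fit, n_samples=1500, seed=5)[0]
    worse = replace(pop, k_growth_mean=pop.k_growth_mean * 1.6,
                    v_max_mean=pop.v_max_mean * 0.6)
    ll_worse = log_likelihood(dataset, _bare_fit(worse), n_samples=1500,
                              seed=5)[0]
    assert ll_fit > ll_worse


def test_lrt_basic_identities():
    a = _bare_fit(PopulationParams())
    b = _bare_fit(PopulationParams())
    a.loglik, a.loglik_se = -100.0, 0.1
    b.loglik, b.loglik_se = -100.0, 0.1
    res = lrt(a, b, 1)
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    # chi-square(1) tail at the classic 5% critical value
    b.loglik = -100.0 + 3.841 / 2.0
    assert lrt(a, b, 1).p_value == pytest.approx(0.05, abs=5e-4)


def test_lrt_clamps_negative_statistics_with_warning():
    a = _bare_fit(PopulationParams())
    b = _bare_fit(PopulationParams())
    a.loglik, a.loglik_se = -100.0, 0.2
    b.loglik, b.loglik_se = -103.0, 0.2
    with pytest.warns(RuntimeWarning, match="clamped"):
        res = lrt(a, b, 1)
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    with pytest.raises(ValueError):
        lrt(a, b, 0)


# ---------------------------------------------------------------------------
# prediction intervals
# ---------------------------------------------------------------------------


def test_band_collapses_without_variability():
    pop = PopulationParams(omega_k=0.0, omega_vmax=0.0, omega_eff=0.0,
                           sigma_prop=0.0, sigma_add=0.0)
    design = StudyDesign(n_per_arm=1, seed=0)
    bands = predict_intervals(_bare_fit(pop, design.arms), design,
                              n_sim=200, seed=1)
    veh = bands["vehicle"]
    np.testing.assert_allclose(veh["q5"], veh["q95"], rtol=1e-12)
    expected = predict_volume(
        __import__("tumornlme").GompertzParams(
            k_growth=0.64, v_max=1620.0, gamma=0.17, v0=80.0),
        TreatmentSchedule(treated=False), design.obs_times)
    np.testing.assert_allclose(veh["q50"], expected, rtol=1e-9)


def test_band_quantiles_are_ordered(printed_pop):
    design = StudyDesign(n_per_arm=1, seed=0)
    bands = predict_intervals(_bare_fit(printed_pop, design.arms), design,
                              n_sim=400, seed=2)
    for frame in bands.values():
        assert (frame["q5"] <= frame["q50"]).all()
        assert (frame["q50"] <= frame["q95"]).all()


def test_small_simulation_count_warns(printed_pop):
    design = StudyDesign(n_per_arm=1, seed=0)
    with pytest.warns(RuntimeWarning, match="n_sim"):
        predict_intervals(_bare_fit(printed_pop, design.arms), design,
                          n_sim=50, seed=3)
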