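import itertools
import json

import numpy as np
import pytest

from tumornlme import (
    PipelineError,
    Report,
    SurvivalRecord,
    gehan_breslow_wilcoxon,
    run_pipeline,
)


def _records(times_a, times_b, events_a=None, events_b=None):
    events_a = events_a or [1] * len(times_a)
    events_b = events_b or [1] * len(times_b)
    recs = [SurvivalRecord(f"a{i}", t, e, "A")
            for i, (t, e) in enumerate(zip(times_a, events_a))]
    recs += [SurvivalRecord(f"b{i}", t, e, "B")
             for i, (t, e) in enumerate(zip(times_b, events_b))]
    return recs


def test_identical_groups_give_null_result():
    recs = _records([3.0, 5.0, 8.0], [3.0, 5.0, 8.0])
    res = gehan_breslow_wilcoxon(recs, "A", "B")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0
    assert res.n_per_group == (3, 3)


def test_no_events_is_undefined():
    recs = _records([3.0, 5.0], [4.0, 6.0], [0, 0], [0, 0])
    with pytest.raises(ValueError, match="no events"):
        gehan_breslow_wilcoxon(recs, "A", "B")
    with pytest.raises(ValueError, match="non-empty"):
        gehan_breslow_wilcoxon(recs, "A", "C")


def test_rank_preserving_time_transform_leaves_statistic_unchanged():
    rng = np.random.default_rng(3)
    ta = list(rng.exponential(10.0, 9).round(2) + 0.5)
    tb = list(rng.exponential(14.0, 9).round(2) + 0.5)
    ev_a = [1, 1, 0, 1, 1, 1, 0, 1, 1]
    ev_b = [1, 0, 1, 1, 1, 0, 1, 1, 1]
    base = gehan_breslow_wilcoxon(_records(ta, tb, ev_a, ev_b), "A", "B")
    warped = gehan_breslow_wilcoxon(
        _records([t**2 for t in ta], [t**2 for t in tb], ev_a, ev_b),
        "A", "B")
    assert warped.statistic == pytest.approx(base.statistic, rel=1e-12)


def test_exhaustive_permutation_matches_brute_force_oracle():
    """4 + 4 uncensored samples: the permutation p-value must equal the
    exhaustive distribution over all 70 group assignments, computed here
    with an independent implementation of the risk-set-weighted statistic
    (lifelines' Gehan-Breslow-Wilcoxon variant)."""
    lifelines_stats = pytest.importorskip("lifelines.statistics")
    times = np.array([2.0, 3.0, 5.0, 7.0, 4.0, 8.0, 9.0, 12.0])
    events = np.ones(8, dtype=int)
    groups = ["A"] * 4 + ["B"] * 4
    recs = [SurvivalRecord(f"m{i}", t, 1, g)
            for i, (t, g) in enumerate(zip(times, groups))]
    res = gehan_breslow_wilcoxon(recs, "A", "B", method="permutation")

    def oracle_stat(mask):
        out = lifelines_stats.logrank_test(
            times[mask], times[~mask], events[mask], events[~mask],
            weightings="wilcoxon")
        return float(out.test_statistic)

    obs = oracle_stat(np.array([True] * 4 + [False] * 4))
    stats = []
    for combo in itertools.combinations(range(8), 4):
        mask = np.zeros(8, dtype=bool)
        mask[list(combo)] = True
        stats.append(oracle_stat(mask))
    expected_p = np.mean(np.array(stats) >= obs - 1e-12)
    assert res.p_value == pytest.approx(expected_p, abs=1e-12)


def test_asymptotic_statistic_matches_lifelines():
    lifelines_stats = pytest.importorskip("lifelines.statistics")
    rng = np.random.default_rng(8)
    ta = rng.exponential(8.0, 20) + 0.2
    tb = rng.exponential(13.0, 20) + 0.2
    ea = (rng.random(20) < 0.8).astype(int)
    eb = (rng.random(20) < 0.8).astype(int)
    res = gehan_breslow_wilcoxon(
        _records(list(ta), list(tb), list(ea), list(eb)), "A", "B")
    ref = lifelines_stats.logrank_test(ta, tb, ea, eb,
                                       weightings="wilcoxon")
    assert res.statistic == pytest.approx(float(ref.test_statistic),
                                          rel=1e-9)
    assert res.p_value == pytest.approx(float(ref.p_value), rel=1e-9)


def test_permutation_and_asymptotic_pvalues_agree_at_moderate_n():
    rng = np.random.default_rng(5)
    ta = list(rng.exponential(8.0, 16) + 0.2)
    tb = list(rng.exponential(12.0, 16) + 0.2)
    recs = _records(ta, tb)
    asym = gehan_breslow_wilcoxon(recs, "A", "B").p_value
    perm = gehan_breslow_wilcoxon(
        recs, "A", "B", method="permutation", max_exact=1000,
        n_permutations=4000, seed=0).p_value
    assert perm == pytest.approx(asym, abs=0.02)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

FAST_PIPELINE = {
    "scenario": "simulate_then_fit",
    "seed": 4,
    "design": {"n_per_arm": 5, "obs_times": [0, 2, 4, 7, 10, 14, 18, 22,
                                             26]},
    "fit": {"n_burnin": 40, "n_sa": 30, "loglik_samples": 0},
    "survival_tests": True,
}


def test_pipeline_simulate_then_fit_produces_full_report(tmp_path):
    out = tmp_path / "run"
    report = run_pipeline(dict(FAST_PIPELINE), out_dir=out)
    assert report["fit"]["k_growth_mean"] > 0
    assert len(report["survival"]) == 2
    for name in ("growth.csv", "survival.csv", "fit.json", "trace.csv",
                 "report.json"):
        assert (out / name).exists()
    # the written report validates against the published schema
    on_disk = json.loads((out / "report.json").read_text())
    Report.model_validate(on_disk)


def test_published_schema_file_matches_report_model():
    from importlib import resources

    stored = json.loads(
        resources.files("tumornlme").joinpath(
            "schemas/report.schema.json").read_text())
    assert stored == Report.model_json_schema()


def test_pipeline_is_deterministic_byte_for_byte(tmp_path):
    cfg = dict(FAST_PIPELINE)
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    run_pipeline(dict(cfg), out_dir=out_a)
    run_pipeline(dict(cfg), out_dir=out_b)
    for name in ("report.json", "fit.json", "growth.csv", "survival.csv"):
        assert (out_a / name).read_bytes() == (out_b / name).read_bytes()


def test_pipeline_rejects_empty_or_invalid_inputs(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("animal_id,arm,time_day,volume_mm3\n")
    with pytest.raises(PipelineError, match="empty"):
        run_pipeline({"scenario": "fit_only", "seed": 0,
                      "data": str(empty)})
    bad = tmp_path / "bad.csv"
    bad.write_text("animal_id,arm,time_day,volume_mm3\n"
                   "a,vehicle,0,80\na,vehicle,2,-5\n")
    with pytest.raises(PipelineError, match="invalid growth data"):
        run_pipeline({"scenario": "fit_only", "seed": 0, "data": str(bad)})
    with pytest.raises(PipelineError, match="unknown scenario"):
        run_pipeline({"scenario": "meta-analysis", "seed": 0})


def test_pipeline_hill_scenario_recovers_simulated_ec50(tmp_path):
    report = run_pipeline({
        "scenario": "hill", "seed": 0,
        "dose_response": {"ec50": 4.3, "hill_n": 1.5, "noise_sd": 0.0,
                          "n_cells": 3},
    }, out_dir=tmp_path / "hill")
    assert report["hill"]["ec50"] == pytest.approx(4.3, rel=1e-6)


def test_cli_smoke(tmp_path):
    from click.testing import CliRunner

    from tumornlme.cli import main

    runner = CliRunner()
    res = runner.invoke(main, ["hill", "--seed", "0", "--out",
                               str(tmp_path / "h")])
    assert res.exit_code == 0
    assert "ec50" in res.output
    res = runner.invoke(main, ["survival", "--data", "missing.csv"])
    assert res.exit_code != 0
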