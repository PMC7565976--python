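"""Survival comparison and the end-to-end analysis pipeline.

The survival comparison is the Gehan-Breslow-Wilcoxon test: a two-group
weighted log-rank statistic whose weight at each event time is the pooled
number at risk, which emphasizes early survival differences.  Ties are
handled by simultaneous risk-set reduction (Breslow convention) and the
p-value comes from the chi-square(1) approximation, with an exact
permutation option for small samples.

``run_pipeline`` ties the modules together: simulate a cohort (or load
one), fit the population model, run covariate likelihood-ratio tests,
export prediction bands, and compare survival between arms, writing a
JSON report that validates against the published schema.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel
from scipy.special import comb
from scipy.stats import chi2

from . import __version__
from .dose_response import fit_hill
from .population_fit import (
    FitResult,
    FitSettings,
    covariate_lrt,
    predict_intervals,
    saem_fit,
)
from .study_simulator import (
    VEHICLE_ARM,
    ConfigError,
    GrowthDataset,
    PopulationParams,
    StudyDesign,
    read_survival_csv,
    simulate_cohort,
    simulate_dose_response,
    write_survival_csv,
)

__all__ = [
    "SurvivalTestResult",
    "gehan_breslow_wilcoxon",
    "Report",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Invalid pipeline configuration or inputs."""


@dataclass(frozen=True)
class SurvivalTestResult:
    statistic: float
    p_value: float
    groups: tuple
    n_per_group: tuple
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


def _gehan_statistic(times, events, a_mask):
    """Weighted log-rank score U, its hypergeometric variance V and the
    chi-square statistic U^2/V, with weight = pooled number at risk."""
    ev_times = np.unique(times[events == 1])
    U = 0.0
    V = 0.0
    for t in ev_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & a_mask).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d1 = (dying & a_mask).sum()
        U += n * (d1 - d * n1 / n)
        if n > 1:
            V += n**2 * d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    stat = U * U / V if V > 0 else 0.0
    return U, V, stat


def gehan_breslow_wilcoxon(
    records,
    group_a: str,
    group_b: str,
    method: str = "asymptotic",
    max_exact: int = 200_000,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> SurvivalTestResult:
    """Gehan-Breslow-Wilcoxon comparison of two survival groups.

    ``method="asymptotic"`` refers U^2/V to chi-square(1);
    ``method="permutation"`` permutes the group assignment, exhaustively
    when the number of assignments is at most ``max_exact`` (exact test),
    otherwise by ``n_permutations`` Monte-Carlo draws.
    """
    recs = [r for r in records if r.group in (group_a, group_b)]
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=int)
    a_mask = np.array([r.group == group_a for r in recs], dtype=bool)
    n_a = int(a_mask.sum())
    n_b = int((~a_mask).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    if events.sum() == 0:
        raise ValueError(
            "no events in either group; the test is undefined"
        )
    _, _, stat = _gehan_statistic(times, events, a_mask)

    if method == "asymptotic":
        p = float(chi2.sf(stat, 1))
    elif method == "permutation":
        n = n_a + n_b
        if comb(n, n_a, exact=True) <= max_exact:
            count = 0
            total = 0
            for combo in itertools.combinations(range(n), n_a):
                mask = np.zeros(n, dtype=bool)
                mask[list(combo)] = True
                _, _, s = _gehan_statistic(times, events, mask)
                count += s >= stat - 1e-12
                total += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 1  # include the observed assignment
            for _ in range(n_permutations):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, n_a, replace=False)] = True
                _, _, s = _gehan_statistic(times, events, mask)
                count += s >= stat - 1e-12
            p = count / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SurvivalTestResult(
        statistic=float(stat),
        p_value=float(p),
        groups=(group_a, group_b),
        n_per_group=(n_a, n_b),
        method=method,
    )


# ---------------------------------------------------------------------------
# report models (the published JSON schema is generated from these)
# ---------------------------------------------------------------------------


class FitReport(BaseModel):
    k_growth_mean: float
    omega_k: float
    v_max_mean: float
    omega_vmax: float
    eff_mean: float
    omega_eff: float
    gamma: float
    sigma_prop: float
    sigma_add: float
    covariate_effects: dict[str, float]
    loglik: Optional[float] = None
    loglik_se: Optional[float] = None
    converged: bool
    n_animals: int
    n_obs: int


class LRTReport(BaseModel):
    parameter: str
    arms: list[str]
    statistic: float
    df: int
    p_value: float


class HillReport(BaseModel):
    ec50: float
    hill_n: float
    top: float
    residual_sse: float
    n_points: int


class SurvivalReport(BaseModel):
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


class Report(BaseModel):
    """Top-level pipeline report; serialized as sorted-key JSON."""

    scenario: str
    seed: int
    version: str
    fit: Optional[FitReport] = None
    lrt: Optional[list[LRTReport]] = None
    hill: Optional[HillReport] = None
    survival: Optional[list[SurvivalReport]] = None
    outputs: dict[str, str] = {}


def _fit_report(fit: FitResult) -> FitReport:
    d = fit.to_dict()
    est = d["estimates"]
    return FitReport(
        **est,
        covariate_effects=d["covariate_effects"],
        loglik=fit.loglik,
        loglik_se=fit.loglik_se,
        converged=fit.converged,
        n_animals=fit.n_animals,
        n_obs=fit.n_obs,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _build(cls, config_section, **extra):
    try:
        return cls(**{**(config_section or {}), **extra})
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"invalid {cls.__name__} config: {exc}") from exc


def _coerce_design(section, seed) -> StudyDesign:
    section = dict(section or {})
    if "arms" in section:
        section["arms"] = tuple(section["arms"])
    if "obs_times" in section:
        section["obs_times"] = tuple(float(t) for t in section["obs_times"])
    return _build(StudyDesign, section, seed=seed)


def _fit_stage(dataset: GrowthDataset, config, seed, report, written,
               out_dir):
    fit_cfg = dict(config.get("fit") or {})
    fit_cfg.setdefault("seed", seed)
    base_settings = _build(FitSettings, fit_cfg)
    logger.info("fitting base population model (seed=%d)", base_settings.seed)
    fit = saem_fit(dataset, base_settings)
    report["fit"] = _fit_report(fit)

    tests = []
    for entry in config.get("covariate_tests") or []:
        parameter = entry["parameter"]
        arms = list(entry["arms"])
        df = int(entry.get("df", len(arms)))
        logger.info("covariate test: %s on arms %s (df=%d)", parameter,
                    arms, df)
        res, _, _ = covariate_lrt(dataset, base_settings, parameter, arms,
                                  df=df)
        tests.append(LRTReport(parameter=parameter, arms=arms,
                               statistic=res.statistic, df=res.df,
                               p_value=res.p_value))
    if tests:
        report["lrt"] = tests

    if config.get("intervals") and out_dir is not None:
        icfg = dict(config["intervals"])
        design = _coerce_design(config.get("design"), seed)
        bands = predict_intervals(
            fit, design,
            n_sim=int(icfg.get("n_sim", 1000)),
            seed=seed + 2,
        )
        frames = []
        for arm, frame in bands.items():
            frame = frame.copy()
            frame.insert(0, "arm", arm)
            frames.append(frame)
        import pandas as pd

        path = out_dir / "intervals.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written["intervals"] = path.name

    if out_dir is not None:
        fit_path = out_dir / "fit.json"
        fit_path.write_text(
            json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        written["fit"] = fit_path.name
        trace_path = out_dir / "trace.csv"
        fit.trace.to_csv(trace_path, index=False)
        written["trace"] = trace_path.name
    return fit


def _survival_stage(records, config, report):
    pairs = config.get("survival_pairs")
    if pairs is None:
        groups = sorted({r.group for r in records})
        pairs = [(VEHICLE_ARM, g) for g in groups if g != VEHICLE_ARM
                 ] if VEHICLE_ARM in groups else []
        if not pairs and len(groups) == 2:
            pairs = [tuple(groups)]
    method = config.get("survival_method", "asymptotic")
    out = []
    for a, b in pairs:
        res = gehan_breslow_wilcoxon(records, a, b, method=method)
        out.append(SurvivalReport(
            group_a=a, group_b=b, statistic=res.statistic,
            p_value=res.p_value, n_a=res.n_per_group[0],
            n_b=res.n_per_group[1], method=res.method,
        ))
    if out:
        report["survival"] = out


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute a named analysis scenario and return the report bundle.

    Scenarios: ``simulate`` (write a synthetic cohort), ``simulate_then_fit``
    (cohort + population fit + optional covariate LRTs, prediction bands and
    survival tests), ``fit_only`` (fit a growth CSV), ``hill`` (EC50 fit),
    ``survival`` (group comparison on a survival CSV).  Identical config and
    seed give byte-identical JSON outputs.
    """
    scenario = config.get("scenario")
    seed = int(config.get("seed", 0))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"scenario": scenario, "seed": seed,
                    "version": __version__}
    written: dict = {}
    logger.info("pipeline scenario=%s seed=%d version=%s", scenario, seed,
                __version__)

    if scenario in ("simulate", "simulate_then_fit"):
        design = _coerce_design(config.get("design"), seed)
        pop = _build(PopulationParams, config.get("population"))
        dataset, survival = simulate_cohort(design, pop)
        if not len(dataset.data):
            raise PipelineError("simulated dataset is empty "
                                "(n_per_arm = 0 or no arms)")
        if out_dir is not None:
            dataset.to_csv(out_dir / "growth.csv")
            write_survival_csv(survival, out_dir / "survival.csv")
            written["growth"] = "growth.csv"
            written["survival_data"] = "survival.csv"
        if scenario == "simulate_then_fit":
            _fit_stage(dataset, config, seed, report, written, out_dir)
            if config.get("survival_tests", True):
                _survival_stage(survival, config, report)
    elif scenario == "fit_only":
        path = config.get("data")
        if not path:
            raise PipelineError("fit_only scenario needs a 'data' CSV path")
        try:
            dataset = GrowthDataset.from_csv(path)
        except ConfigError as exc:
            raise PipelineError(f"invalid growth data: {exc}") from exc
        if not len(dataset.data):
            raise PipelineError("growth dataset is empty")
        _fit_stage(dataset, config, seed, report, written, out_dir)
    elif scenario == "hill":
        if config.get("data"):
            import pandas as pd

            table = pd.read_csv(config["data"])
            for col in ("concentration_mM", "response"):
                if col not in table.columns:
                    raise PipelineError(
                        f"dose-response CSV missing column {col!r}"
                    )
        else:
            sim = dict(config.get("dose_response") or {})
            table = simulate_dose_response(
                ec50=float(sim.get("ec50", 4.3)),
                hill_n=float(sim.get("hill_n", 1.5)),
                concentrations=sim.get("concentrations",
                                       (0.3, 1.0, 3.0, 5.0, 10.0)),
                n_cells=int(sim.get("n_cells", 6)),
                noise_sd=float(sim.get("noise_sd", 0.05)),
                seed=seed,
            )
            if out_dir is not None:
                table.to_csv(out_dir / "dose_response.csv", index=False)
                written["dose_response"] = "dose_response.csv"
        hf = fit_hill(table["concentration_mM"], table["response"])
        report["hill"] = HillReport(
            ec50=hf.ec50, hill_n=hf.hill_n, top=hf.top,
            residual_sse=hf.residual_sse, n_points=len(table),
        )
    elif scenario == "survival":
        path = config.get("data")
        if not path:
            raise PipelineError("survival scenario needs a 'data' CSV path")
        try:
            records = read_survival_csv(path)
        except ConfigError as exc:
            raise PipelineError(f"invalid survival data: {exc}") from exc
        if not records:
            raise PipelineError("survival dataset is empty")
        _survival_stage(records, config, report)
    else:
        raise PipelineError(f"unknown scenario {scenario!r}")

    report["outputs"] = written
    model = Report(**report)
    bundle = model.model_dump()
    if out_dir is not None:
        (out_dir / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n"
        )
    return bundle
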