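"""Synthetic preclinical cohort generator.

Emulates the in vivo study design the population analysis assumes: an
orthotopic 4T1 mammary tumour model in which animals are enrolled once the
tumour reaches 80 mm^3, randomized to vehicle or one of two P2X7-antagonist
arms (A438079, AZ10606120), and measured by caliper twice a week.  Volumes
follow generalized Gompertz kinetics with log-normal inter-individual
variability around the published population values, observed with a
combined proportional + additive measurement error.  Humane-endpoint
survival times are derived from the noise-free trajectory crossing an
endpoint volume.

What the generator does NOT emulate: pharmacokinetics of the antagonists
(treatment is continuously on), bioluminescence signal, metastasis counts,
and body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_model import (
    GompertzParams,
    TreatmentSchedule,
    predict_volume,
    time_to_volume,
)

__all__ = [
    "VEHICLE_ARM",
    "TREATED_ARMS",
    "ConfigError",
    "PopulationParams",
    "StudyDesign",
    "GrowthDataset",
    "SurvivalRecord",
    "is_treated_arm",
    "sample_individual_params",
    "simulate_cohort",
    "simulate_dose_response",
    "survival_to_frame",
    "survival_from_frame",
    "write_survival_csv",
    "read_survival_csv",
]

VEHICLE_ARM = "vehicle"
#: antagonist arm labels of the emulated study
TREATED_ARMS = ("A438079", "AZ10606120")

#: simulated volumes are clipped below at this floor (mm^3) so that
#: log-scale machinery stays defined
VOLUME_FLOOR = 1.0

GROWTH_COLUMNS = ("animal_id", "arm", "time_day", "volume_mm3")
SURVIVAL_COLUMNS = ("animal_id", "group", "time_day", "event")


class ConfigError(ValueError):
    """Invalid study configuration (unknown arm, bad schema, ...)."""


def is_treated_arm(arm: str) -> bool:
    if arm == VEHICLE_ARM:
        return False
    if arm in TREATED_ARMS:
        return True
    raise ConfigError(
        f"unknown arm label {arm!r}; expected {VEHICLE_ARM!r} or one of "
        f"{TREATED_ARMS}"
    )


@dataclass(frozen=True)
class PopulationParams:
    """Population law of the Gompertz/treatment parameters.

    ``*_mean`` are the population typical values (the log-normal random
    effects are centred on log(mean)); ``omega_*`` are the standard
    deviations of the log-scale random effects, i.e. the inter-individual
    variabilities reported as percentages (39% -> omega 0.39).  ``gamma``
    is a fixed effect with no inter-individual variability.  The residual
    error is combined: sd(y | V) = sigma_add + sigma_prop * V.

    Defaults are the published population estimates of the emulated study:
    k_growth 0.64/day (39%), V_max 1620 mm^3 (64%), EFF 0.52 (82%),
    gamma 0.17; the residual magnitudes are the generator's own choice
    (the source analysis does not state its residual model).
    """

    k_growth_mean: float = 0.64
    omega_k: float = 0.39
    v_max_mean: float = 1620.0
    omega_vmax: float = 0.64
    eff_mean: float = 0.52
    omega_eff: float = 0.82
    gamma: float = 0.17
    sigma_prop: float = 0.15
    sigma_add: float = 5.0

    def __post_init__(self) -> None:
        for name in ("k_growth_mean", "v_max_mean", "eff_mean", "gamma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("omega_k", "omega_vmax", "omega_eff", "sigma_prop",
                     "sigma_add"):
            if not (getattr(self, name) >= 0):
                raise ValueError(f"{name} must be >= 0")


def _default_obs_times() -> tuple:
    # twice-weekly caliper measurements over four weeks, day 0 = treatment
    # start (enrollment at the 80 mm^3 threshold)
    return tuple(np.arange(0.0, 28.0 + 1e-9, 3.5))


@dataclass(frozen=True)
class StudyDesign:
    """Design of a simulated antagonist trial."""

    arms: tuple = (VEHICLE_ARM,) + TREATED_ARMS
    n_per_arm: int = 10
    enrollment_threshold: float = 80.0
    obs_times: tuple = field(default_factory=_default_obs_times)
    endpoint_volume: float = 1500.0
    study_end: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be >= 0")
        if not (self.enrollment_threshold > 0):
            raise ValueError("enrollment_threshold must be > 0")
        if not (self.endpoint_volume > 0):
            raise ValueError("endpoint_volume must be > 0")
        obs = np.asarray(self.obs_times, dtype=float)
        if obs.size == 0 or np.any(obs < 0) or np.any(np.diff(obs) <= 0):
            raise ValueError("obs_times must be non-empty, non-negative, "
                             "strictly increasing")
        for arm in self.arms:
            is_treated_arm(arm)  # raises ConfigError on unknown labels


@dataclass
class GrowthDataset:
    """Long-format longitudinal tumour volumes.

    ``data`` columns: animal_id, arm, time_day, volume_mm3.  Validated on
    construction: positive volumes, unique (animal_id, time_day), and at
    least two observations per animal (needed for fitting).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"growth data missing columns {missing}")
        df = df.loc[:, list(GROWTH_COLUMNS)].reset_index(drop=True)
        df["time_day"] = df["time_day"].astype(float)
        df["volume_mm3"] = df["volume_mm3"].astype(float)
        if len(df):
            bad = df.index[~(df["volume_mm3"] > 0) | ~np.isfinite(df["volume_mm3"])]
            if len(bad):
                raise ConfigError(
                    f"non-positive or non-finite volumes at rows {list(bad)}"
                )
            bad = df.index[df["time_day"] < 0]
            if len(bad):
                raise ConfigError(f"negative times at rows {list(bad)}")
            dup = df.duplicated(subset=["animal_id", "time_day"])
            if dup.any():
                raise ConfigError(
                    "duplicate (animal_id, time_day) at rows "
                    f"{list(df.index[dup])}"
                )
            counts = df.groupby("animal_id").size()
            short = counts[counts < 2]
            if len(short):
                raise ConfigError(
                    f"animals with fewer than 2 observations: "
                    f"{list(short.index)}"
                )
        self.data = df

    @property
    def n_animals(self) -> int:
        return self.data["animal_id"].nunique()

    def meta(self) -> pd.DataFrame:
        """Per-animal metadata: arm, treatment flag and baseline volume v0
        (the first observed volume, taken as the trajectory's anchor)."""
        if not len(self.data):
            return pd.DataFrame(
                columns=["animal_id", "arm", "treated", "v0"]
            )
        df = self.data.sort_values(["animal_id", "time_day"])
        first = df.groupby("animal_id", sort=True).first().reset_index()
        first["treated"] = [is_treated_arm(a) for a in first["arm"]]
        return first.rename(columns={"volume_mm3": "v0"})[
            ["animal_id", "arm", "treated", "v0"]
        ]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthDataset":
        # round_trip parsing keeps write/read lossless to the last ulp
        return cls(pd.read_csv(path, float_precision="round_trip"))


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-animal survival outcome: event = 1 when the humane endpoint was
    reached, 0 when censored at study end."""

    animal_id: str
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


def survival_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.animal_id, r.group, r.time, r.event) for r in records],
        columns=list(SURVIVAL_COLUMNS),
    )


def survival_from_frame(df: pd.DataFrame):
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"survival data missing columns {missing}")
    return [
        SurvivalRecord(str(r.animal_id), float(r.time_day), int(r.event),
                       str(r.group))
        for r in df.itertuples()
    ]


def write_survival_csv(records, path) -> None:
    survival_to_frame(records).to_csv(path, index=False)


def read_survival_csv(path):
    return survival_from_frame(
        pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_individual_params(
    pop: PopulationParams,
    arm: str,
    n: int,
    seed: int,
    v0: float = 80.0,
):
    """Draw per-animal Gompertz parameters from the population law.

    log k_growth ~ N(log k_mean, omega_k), same for v_max; treated arms
    additionally draw log eff ~ N(log eff_mean, omega_eff) (vehicle animals
    have eff = 0).  gamma is copied unchanged.  Reproducible given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    treated = is_treated_arm(arm)
    rng = np.random.default_rng(seed)
    lk = rng.normal(np.log(pop.k_growth_mean), pop.omega_k, n)
    lv = rng.normal(np.log(pop.v_max_mean), pop.omega_vmax, n)
    if treated:
        le = rng.normal(np.log(pop.eff_mean), pop.omega_eff, n)
        effs = np.exp(le)
    else:
        effs = np.zeros(n)
    out = []
    for i in range(n):
        v_max = float(np.exp(lv[i]))
        v_max = max(v_max, v0 * 1.01)  # keep v0 <= v_max valid
        out.append(
            GompertzParams(
                k_growth=float(np.exp(lk[i])),
                v_max=v_max,
                gamma=pop.gamma,
                eff=float(effs[i]),
                v0=v0,
            )
        )
    return out


def simulate_cohort(design: StudyDesign, pop: PopulationParams):
    """Simulate one trial: returns (GrowthDataset, list[SurvivalRecord]).

    Per animal: draw individual parameters; set v0 to the enrollment
    threshold perturbed by one measurement error; generate the noise-free
    trajectory; observe it at ``design.obs_times`` with combined residual
    error y = V (1 + eps_prop) + eps_add, clipped below at 1 mm^3 (the
    first observation is the enrollment measurement v0 itself).  The
    survival time is the first crossing of ``endpoint_volume`` by the
    noise-free trajectory, censored at ``study_end`` otherwise.
    """
    times = np.asarray(design.obs_times, dtype=float)
    rng = np.random.default_rng(design.seed)
    rows = []
    survival = []
    for a_idx, arm in enumerate(design.arms):
        sub_seed = (design.seed * 1000003 + 7919 * a_idx + 1) % (2**31)
        base_params = sample_individual_params(
            pop, arm, design.n_per_arm, sub_seed,
            v0=design.enrollment_threshold,
        )
        sched = TreatmentSchedule(treated=is_treated_arm(arm), start_time=0.0)
        for j, p0 in enumerate(base_params):
            v0 = (
                design.enrollment_threshold
                * (1.0 + rng.normal(0.0, pop.sigma_prop))
                + rng.normal(0.0, pop.sigma_add)
            )
            v0 = max(v0, VOLUME_FLOOR)
            p = replace(p0, v0=v0, v_max=max(p0.v_max, v0 * 1.01))
            f = predict_volume(p, sched, times, allow_shrinkage=True)
            y = (
                f * (1.0 + rng.normal(0.0, pop.sigma_prop, times.size))
                + rng.normal(0.0, pop.sigma_add, times.size)
            )
            y[0] = v0
            y = np.maximum(y, VOLUME_FLOOR)
            animal_id = f"{arm}_{j:03d}"
            for t, v in zip(times, y):
                rows.append((animal_id, arm, float(t), float(v)))
            t_cross = time_to_volume(p, sched, design.endpoint_volume)
            if t_cross is not None and 0 < t_cross <= design.study_end:
                survival.append(
                    SurvivalRecord(animal_id, float(t_cross), 1, arm)
                )
            else:
                survival.append(
                    SurvivalRecord(animal_id, float(design.study_end), 0, arm)
                )
    dataset = GrowthDataset(pd.DataFrame(rows, columns=list(GROWTH_COLUMNS)))
    return dataset, survival


def simulate_dose_response(
    ec50: float,
    hill_n: float,
    concentrations,
    n_cells: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate per-cell normalized concentration-response measurements.

    The underlying Hill response r(c) = c^n / (c^n + ec50^n) is rescaled so
    the reference (maximum) concentration maps to 1 -- mimicking currents
    expressed as a ratio of the response at the top concentration -- and
    Normal(0, noise_sd) noise is added per cell.  Returns a long table with
    columns concentration_mM, cell_id, response.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ConfigError("concentration list must be non-empty")
    if np.any(conc <= 0):
        raise ConfigError("concentrations must be > 0")
    if not (ec50 > 0 and hill_n > 0):
        raise ValueError("ec50 and hill_n must be > 0")
    ref = conc.max()
    r = conc**hill_n / (conc**hill_n + ec50**hill_n)
    r_ref = ref**hill_n / (ref**hill_n + ec50**hill_n)
    scaled = r / r_ref
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        noise = rng.normal(0.0, noise_sd, conc.size) if noise_sd > 0 else 0.0
        resp = scaled + noise
        for c, v in zip(conc, np.atleast_1d(resp + np.zeros(conc.size))):
            rows.append((float(c), f"cell_{cell:02d}", float(v)))
    return pd.DataFrame(rows, columns=["concentration_mM", "cell_id", "response"])
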