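"""Hill-equation fitting of concentration-response data.

Estimates the half-maximal effective concentration (EC50) of ATP-evoked
currents, with responses normalized to the current at a reference (maximum)
concentration.  The model is

    r(c) = top * c**n / (c**n + EC50**n)

with the Hill coefficient n and the maximal response ``top`` estimated
alongside EC50.  Optimization is deterministic: a fixed multi-start grid of
initial values is polished by trust-region least squares and the best
optimum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["HillFit", "hill_response", "normalize_currents", "fit_hill"]

#: deterministic multi-start grid: log-spaced EC50 (mM) and Hill slopes
EC50_STARTS = tuple(np.geomspace(0.1, 30.0, 6))
HILL_N_STARTS = (0.5, 1.0, 1.5, 2.0, 3.0)
TOP_MAX = 1.5


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-equation fit to normalized responses."""

    ec50: float
    hill_n: float
    top: float
    residual_sse: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError("ec50 must be > 0")
        if not (self.hill_n > 0):
            raise ValueError("hill_n must be > 0")
        if not (0 < self.top <= TOP_MAX):
            raise ValueError(f"top must be in (0, {TOP_MAX}]")
        if not (self.residual_sse >= 0):
            raise ValueError("residual_sse must be >= 0")


def hill_response(c, ec50: float, hill_n: float, top: float = 1.0):
    c = np.asarray(c, dtype=float)
    cn = c**hill_n
    return top * cn / (cn + ec50**hill_n)


def normalize_currents(concentrations, currents, reference_concentration):
    """Express currents as a ratio of the response at the reference
    concentration (e.g. the maximum agonist concentration applied).

    With replicates at the reference concentration, their mean defines the
    normalizing response.  A zero reference response is an error.
    """
    conc = np.asarray(concentrations, dtype=float)
    cur = np.asarray(currents, dtype=float)
    if conc.shape != cur.shape:
        raise ValueError("concentrations and currents must align")
    at_ref = np.isclose(conc, reference_concentration)
    if not at_ref.any():
        raise ValueError(
            f"reference concentration {reference_concentration} not present"
        )
    ref = cur[at_ref].mean()
    if ref == 0:
        raise ValueError("zero current at the reference concentration")
    return cur / ref


def fit_hill(concentrations, responses) -> HillFit:
    """Least-squares Hill fit of normalized responses; replicates allowed.

    Requires at least 3 distinct concentrations.  ``top`` is bounded in
    (0, 1.5] since normalization pins the reference response near 1.  The
    returned optimum has a residual SSE no larger than at any grid start.
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    resp = np.asarray(responses, dtype=float).ravel()
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentrations")

    lc = np.log(conc)

    def resid(x):
        log_ec50, log_n, top = x
        # work on log-concentration to keep powers well-conditioned
        z = np.exp(log_n) * (lc - log_ec50)
        frac = 1.0 / (1.0 + np.exp(-z))
        return top * frac - resp

    lb = (np.log(1e-3), np.log(0.05), 1e-6)
    ub = (np.log(1e3), np.log(10.0), TOP_MAX)
    best = None
    for ec0 in EC50_STARTS:
        for n0 in HILL_N_STARTS:
            x0 = (np.log(ec0), np.log(n0), 1.0)
            try:
                res = least_squares(resid, x0, bounds=(lb, ub), method="trf")
            except Exception:  # pragma: no cover - defensive
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("Hill fit failed from every multi-start point")
    log_ec50, log_n, top = best.x
    sse = float(2.0 * best.cost)
    return HillFit(
        ec50=float(np.exp(log_ec50)),
        hill_n=float(np.exp(log_n)),
        top=float(top),
        residual_sse=sse,
    )
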