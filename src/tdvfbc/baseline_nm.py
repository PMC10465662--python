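"""Nelder-Mead baseline for three-element Windkessel estimation.

Cross-validation fitter: minimizes the squared 2-norm of the residual between
the measured pressure and the Windkessel response written with recursive
exponential convolutions,

    cost(R1, R2, C, Pd) = sum_k [ p(t_k) - R1 q(t_k)
                                  - (1/C) (e^{a t} * q)(t_k) - Pd ]^2,

with a = -1/(R2 C) and theta(0) = 1, i.e. the step-source (approximate)
Windkessel response — the same response family the vector-fitting route
models — so that the cost vanishes on data generated by the very parameters
being sought.  The four parameters are normalized by the magnitudes of a
Thevenin-style initial guess before handing them to the simplex search,
which otherwise crawls across the ~18 orders of magnitude separating C from
R2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .rational_models import HemoWaveforms, InvalidParameterError, WindkesselParams, _exp_conv

__all__ = ["NmConfig", "NmResult", "wk_objective", "initial_guess",
           "fit_nelder_mead"]


@dataclass(frozen=True)
class NmConfig:
    """Simplex-search settings.

    x0 is the initial parameter point; scales are the per-parameter
    normalization magnitudes (default: |x0| components).  The search is
    restarted once from its own optimum, which lets Nelder-Mead escape the
    occasional premature simplex collapse.
    """

    x0: WindkesselParams | None = None
    scales: tuple | None = None
    max_fev: int = 4000
    tol: float = 1e-12
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.scales is not None and any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class NmResult:
    params: WindkesselParams
    converged: bool
    cost: float
    nfev: int


def wk_objective(params: WindkesselParams, w: HemoWaveforms) -> float:
    """Squared 2-norm (sum over all samples) of the pressure residual."""
    if params.R2 * params.C <= 0:
        raise InvalidParameterError("R2*C must be positive")
    a = -1.0 / (params.R2 * params.C)
    conv = _exp_conv(w.flow.values, w.dt, a)
    p_model = params.R1 * w.flow.values + conv / params.C + params.Pd
    r = w.pressure.values - p_model
    return float(r @ r)


def initial_guess(w: HemoWaveforms) -> WindkesselParams:
    """Thevenin-style starting point from gross waveform features.

    Pd from a deflated pressure minimum, R1+R2 from the mean pressure/flow
    ratio (DC impedance), R1 as a tenth of the total, and the time constant
    R2*C from a log-linear fit of the diastolic pressure decay (falling back
    to one second when no usable diastolic stretch exists).
    """
    p = w.pressure.values
    q = w.flow.values
    pd0 = 0.8 * float(np.min(p))
    qbar = float(np.mean(q))
    if qbar <= 0:
        raise InvalidParameterError("mean flow must be positive for the guess")
    rtot = max((float(np.mean(p)) - pd0) / qbar, 1e-300)
    r1 = 0.1 * rtot
    r2 = rtot - r1

    tau = _diastolic_tau(p, q, pd0, w.dt)
    return WindkesselParams(R1=r1, R2=r2, C=tau / r2, Pd=pd0)


def _diastolic_tau(p: np.ndarray, q: np.ndarray, pd0: float, dt: float) -> float:
    # fit the decay inside a single diastole: the longest contiguous
    # flowless stretch in the second half of the record (fitting across
    # several cycles would see the periodic pattern, not the decay)
    half = len(q) // 2
    idle = q[half:] < 0.05 * np.max(np.abs(q))
    best, run, start = (0, 0), 0, 0
    for i, flag in enumerate(idle):
        run = run + 1 if flag else 0
        if flag and run > best[1]:
            start = i - run + 1
            best = (start, run)
    i0, length = best
    y = p[half + i0: half + i0 + length] - pd0
    if length > 10 and np.all(y > 0):
        t = np.arange(length) * dt
        slope = np.polyfit(t, np.log(y), 1)[0]
        if slope < 0:
            return float(np.clip(-1.0 / slope, 1e-3, 1e2))
    return 1.0


def fit_nelder_mead(w: HemoWaveforms, cfg: NmConfig | None = None) -> NmResult:
    """Minimize :func:`wk_objective` over normalized (R1, R2, C, Pd).

    Parameters are optimized as multiples of the per-parameter scales;
    non-positive R2 or C trial points are rejected with an infinite cost.
    Returns the best point found with a convergence flag — never raises on
    non-convergence.
    """
    cfg = cfg or NmConfig()
    x0p = cfg.x0 or initial_guess(w)
    x0 = np.array([x0p.R1, x0p.R2, x0p.C, x0p.Pd], dtype=float)
    scales = np.asarray(cfg.scales, dtype=float) if cfg.scales is not None \
        else np.maximum(np.abs(x0), 1e-300)

    def cost(z: np.ndarray) -> float:
        r1, r2, c, pd = z * scales
        if r2 <= 0 or c <= 0 or r1 < 0:
            return np.inf
        return wk_objective(WindkesselParams(r1, r2, c, pd), w)

    z = x0 / scales
    nfev = 0
    converged = True
    for _ in range(cfg.restarts + 1):
        res = minimize(cost, z, method="Nelder-Mead",
                       options={"maxfev": cfg.max_fev, "xatol": 1e-10,
                                "fatol": cfg.tol * (1.0 + cost(z))})
        z = res.x
        nfev += res.nfev
        converged = bool(res.success)
    r1, r2, c, pd = z * scales
    return NmResult(params=WindkesselParams(r1, r2, c, pd),
                    converged=converged, cost=float(res.fun), nfev=nfev)
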