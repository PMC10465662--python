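"""Lumped outlet models: three-element Windkessel and pole-residue rational forms.

The three-element Windkessel (RCR) terminates a vessel outlet with a proximal
resistance ``R1``, a distal resistance ``R2``, a compliance ``C`` and a
constant distal pressure ``Pd`` (the pressure at which flow to the
microcirculation ceases).  In the Laplace domain the outlet impedance is

    H(s) = R1 + R2 / (s R2 C + 1),

an order-1 rational function.  The general order-n termination handled by this
package is the partial-fraction (pole-residue) form

    H(s) = c0 + sum_i c_i / (s - a_i),        P(s) ~= H(s) Q(s) + Pd / s,

i.e. the distal source is applied as a step from t = 0 (Heaviside convention
theta(0) = 1).  The step-source form is an approximation of the Windkessel
circuit that differs from it only during the start-up transient of duration
~R2*C; once the pulsatile periodic state is reached the two coincide.

All quantities are strict SI: Pa, m^3/s, s, Pa*s/m^3, m^3/Pa.  Unit
conversion for mmHg / cm^3/s / l/min lives in :mod:`tdvfbc.cli_io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.signal import lfilter

__all__ = [
    "TimeSeries",
    "HemoWaveforms",
    "WindkesselParams",
    "PoleResidueModel",
    "InvalidParameterError",
    "NotRepresentableError",
    "PoleEvaluationError",
    "IllConditionedFilterWarning",
    "pole_blocks",
    "wk_to_pole_residue",
    "pole_residue_to_wk",
    "eval_H",
    "wk_exact_response",
    "approx_response",
    "equivalent_source",
]


class InvalidParameterError(ValueError):
    """Physically inadmissible model parameters (e.g. R2 <= 0, C <= 0)."""


class NotRepresentableError(ValueError):
    """Pole-residue model has no three-element Windkessel equivalent."""


class PoleEvaluationError(ValueError):
    """Transfer function evaluated at (or numerically on top of) a pole."""


class IllConditionedFilterWarning(UserWarning):
    """Exponential filter kernel decays essentially to zero within one step."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar signal: sample k lives at t0 + k*dt."""

    t0: float
    dt: float
    values: np.ndarray
    unit_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values contain NaN or Inf")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.values) - 1)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, unit_label: str | None = None) -> "TimeSeries":
        return TimeSeries(self.t0, self.dt, values,
                          self.unit_label if unit_label is None else unit_label)


@dataclass(frozen=True)
class HemoWaveforms:
    """Co-located pressure (Pa) and flow-rate (m^3/s) records on one grid."""

    pressure: TimeSeries
    flow: TimeSeries

    def __post_init__(self) -> None:
        p, q = self.pressure, self.flow
        if len(p) != len(q):
            raise ValueError("pressure and flow must have the same length")
        if abs(p.dt - q.dt) > 1e-12 * max(p.dt, q.dt):
            raise ValueError("pressure and flow must share the sampling interval")
        if abs(p.t0 - q.t0) > 1e-9 * max(p.dt, q.dt):
            raise ValueError("pressure and flow must share the start time")

    @property
    def dt(self) -> float:
        return self.pressure.dt

    @property
    def t0(self) -> float:
        return self.pressure.t0

    def __len__(self) -> int:
        return len(self.pressure)


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: R1, R2 (Pa*s/m^3), C (m^3/Pa), Pd (Pa)."""

    R1: float
    R2: float
    C: float
    Pd: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 < 0:
            raise InvalidParameterError(f"R1 must be >= 0, got {self.R1}")
        if not self.R2 > 0:
            raise InvalidParameterError(f"R2 must be > 0, got {self.R2}")
        if not self.C > 0:
            raise InvalidParameterError(f"C must be > 0, got {self.C}")

    @property
    def tau(self) -> float:
        """Exponential time constant R2*C of the distal block (s)."""
        return self.R2 * self.C


def _check_conjugate_closure(poles: np.ndarray, residues: np.ndarray,
                             tol: float = 1e-8) -> None:
    used = np.zeros(len(poles), dtype=bool)
    for i, (a, c) in enumerate(zip(poles, residues)):
        if used[i] or a.imag == 0:
            continue
        scale = max(abs(a), 1e-300)
        for j in range(len(poles)):
            if j == i or used[j]:
                continue
            if (abs(poles[j] - np.conj(a)) <= tol * scale
                    and abs(residues[j] - np.conj(c)) <= tol * max(abs(c), 1e-300) + 1e-300):
                used[i] = used[j] = True
                break
        else:
            raise ValueError(
                f"pole {a} has no conjugate partner with conjugate residue")


@dataclass(frozen=True)
class PoleResidueModel:
    """Order-n termination H(s) = c0 + sum c_i/(s - a_i) with distal source Pd.

    Complex poles/residues must appear in conjugate pairs so that the
    time-domain response is real.
    """

    c0: float
    poles: tuple = ()
    residues: tuple = ()
    Pd: float = 0.0

    def __post_init__(self) -> None:
        poles = tuple(complex(a) for a in self.poles)
        residues = tuple(complex(c) for c in self.residues)
        object.__setattr__(self, "poles", poles)
        object.__setattr__(self, "residues", residues)
        if len(poles) != len(residues):
            raise ValueError("poles and residues must have matching lengths")
        pa = np.asarray(poles, dtype=complex)
        if len(poles):
            if np.any(np.abs(pa) == 0):
                raise ValueError("poles must have nonzero magnitude")
            # coincident poles would need a Jordan-block extension; reject
            for i in range(len(pa)):
                for j in range(i + 1, len(pa)):
                    if abs(pa[i] - pa[j]) <= 1e-12 * max(abs(pa[i]), 1):
                        raise ValueError(f"repeated pole {pa[i]} is not supported")
            _check_conjugate_closure(pa, np.asarray(residues, dtype=complex))

    @property
    def order(self) -> int:
        return len(self.poles)

    def is_stable(self) -> bool:
        return all(a.real < 0 for a in self.poles)

    def with_Pd(self, Pd: float) -> "PoleResidueModel":
        return replace(self, Pd=Pd)


def pole_blocks(poles: Sequence[complex],
                residues: Sequence[complex] | None = None,
                tol: float = 1e-8):
    """Group a conjugate-closed pole list into real poles and pair leaders.

    Returns a list of ``(kind, a, c)`` with ``kind`` either ``"r"`` (real
    pole) or ``"c"`` (complex pair, represented by its Im > 0 member).  When
    *residues* is None the residue slot is None.
    """
    poles = [complex(a) for a in poles]
    res = list(residues) if residues is not None else [None] * len(poles)
    used = [False] * len(poles)
    blocks = []
    for i, a in enumerate(poles):
        if used[i]:
            continue
        if abs(a.imag) <= tol * max(abs(a), 1e-300):
            blocks.append(("r", a.real, None if res[i] is None else complex(res[i]).real))
            used[i] = True
            continue
        partner = None
        for j in range(i + 1, len(poles)):
            if not used[j] and abs(poles[j] - np.conj(a)) <= tol * abs(a):
                partner = j
                break
        if partner is None:
            raise ValueError(f"pole {a} has no conjugate partner")
        used[i] = used[partner] = True
        lead = a if a.imag > 0 else poles[partner]
        c = None
        if residues is not None:
            c = res[i] if a.imag > 0 else res[partner]
        blocks.append(("c", lead, c))
    return blocks


# --------------------------------------------------------------------------
# Windkessel <-> pole-residue conversion
# --------------------------------------------------------------------------


def wk_to_pole_residue(wk: WindkesselParams) -> PoleResidueModel:
    """Express a three-element Windkessel as an order-1 pole-residue model.

    The unique mapping is a = -1/(R2 C), c1 = 1/C, c0 = R1; Pd is carried
    over unchanged.
    """
    a = -1.0 / (wk.R2 * wk.C)
    c1 = 1.0 / wk.C
    return PoleResidueModel(c0=wk.R1, poles=(a,), residues=(c1,), Pd=wk.Pd)


def pole_residue_to_wk(m: PoleResidueModel) -> WindkesselParams:
    """Invert :func:`wk_to_pole_residue`: R1 = c0, R2 = -c1/a, C = 1/c1.

    Only order-1 models with a real negative pole and a real positive residue
    admit a Windkessel equivalent; anything else raises
    :class:`NotRepresentableError`.
    """
    if m.order != 1:
        raise NotRepresentableError(
            f"only order-1 models map to a 3WK, got order {m.order}")
    a, c1 = m.poles[0], m.residues[0]
    if abs(a.imag) > 1e-12 * abs(a) or abs(c1.imag) > 1e-12 * abs(c1):
        raise NotRepresentableError("pole and residue must be real")
    a, c1 = a.real, c1.real
    if a >= 0:
        raise NotRepresentableError(f"pole must be negative, got {a}")
    if c1 <= 0:
        raise NotRepresentableError(f"residue must be positive, got {c1}")
    if m.c0 < 0:
        raise NotRepresentableError(f"direct term must be >= 0, got {m.c0}")
    return WindkesselParams(R1=m.c0, R2=-c1 / a, C=1.0 / c1, Pd=m.Pd)


def eval_H(m: PoleResidueModel, s: complex):
    """Evaluate the impedance H(s) = c0 + sum c_i/(s - a_i).

    Returns a float when the imaginary part is negligible (conjugate-closed
    model at real s), otherwise a complex value.
    """
    s = complex(s)
    val = complex(m.c0)
    for a, c in zip(m.poles, m.residues):
        d = s - a
        if abs(d) <= 1e-12 * max(abs(a), 1.0):
            raise PoleEvaluationError(f"s = {s} coincides with pole {a}")
        val += c / d
    if abs(val.imag) <= 1e-10 * max(abs(val.real), 1e-300):
        return val.real
    return val


# --------------------------------------------------------------------------
# exponential recursive convolution (shared kernel primitive)
# --------------------------------------------------------------------------


def _exp_conv(values: np.ndarray, dt: float, a: complex) -> np.ndarray:
    """y(t_k) = int_0^{t_k} e^{a (t_k - tau)} z(tau) dtau on a uniform grid.

    The input is reconstructed piecewise-linearly between samples, for which
    the one-step update y_k = E y_{k-1} + alpha z_{k-1} + beta z_k is exact
    (E = e^{a dt}).  y_0 = 0.  Works for real and complex a; a = 0 degrades
    to the cumulative trapezoidal integral.
    """
    z = np.asarray(values, dtype=float)
    if a == 0:
        return cumulative_trapezoid(z, dx=dt, initial=0.0)
    a = complex(a)
    if abs(a.real) * dt > 50:
        warnings.warn(
            f"|Re(a)|*dt = {abs(a.real) * dt:.3g} > 50: kernel decays within "
            "one step, filter output is quadrature-dominated",
            IllConditionedFilterWarning, stacklevel=2)
    x = a * dt
    E = np.exp(x)
    if abs(x) < 1e-4:
        # series for the quadrature weights; direct formulas cancel badly
        e1_over_x = 1 + x / 2 + x**2 / 6 + x**3 / 24 + x**4 / 120
        beta_over_dt = 0.5 + x / 6 + x**2 / 24 + x**3 / 120 + x**4 / 720
    else:
        e1 = E - 1
        e1_over_x = e1 / x
        beta_over_dt = (e1 - x) / x**2
    beta = dt * beta_over_dt
    alpha = dt * e1_over_x - beta
    zin = z.astype(complex) if a.imag != 0 or isinstance(E, complex) else z
    y = lfilter([beta, alpha], [1.0, -E], zin)
    if z[0] != 0.0:
        # lfilter's zero-state start injects beta*z0 at k=0; the definition
        # has y_0 = 0, so remove that term and its exponential propagation
        k = np.arange(len(z))
        with np.errstate(over="ignore"):
            y = y - beta * z[0] * np.exp(k * x)
    else:
        y[0] = 0.0
    if a.imag == 0:
        return y.real if np.iscomplexobj(y) else y
    return y


# --------------------------------------------------------------------------
# reference (oracle-grade) time-domain responses
# --------------------------------------------------------------------------


def wk_exact_response(wk: WindkesselParams, q: TimeSeries) -> TimeSeries:
    """Pressure of the exact Windkessel circuit (zero initial state).

    Solves the circuit ODE with p = R1 q + v,
    v' = (Pd - v)/(R2 C) + q/C, v(0) = 0, using an adaptive 8th-order
    integrator at tolerance 1e-10; the flow is interpolated linearly between
    samples and the step size is capped at dt so integration never straddles
    an interpolation kink.  Serves as the oracle for every fitter: the distal
    source enters through its exponential Thevenin transient, not as a step.
    """
    t = q.times
    qv = q.values
    tau = wk.tau

    def rhs(ti, y):
        qi = np.interp(ti, t, qv)
        return [(wk.Pd - y[0]) / tau + qi / wk.C]

    scale = max(abs(wk.Pd), (wk.R1 + wk.R2) * np.max(np.abs(qv)), 1.0)
    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, method="DOP853",
                    rtol=1e-10, atol=1e-12 * scale, max_step=q.dt)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    p = wk.R1 * qv + sol.y[0]
    return TimeSeries(q.t0, q.dt, p, unit_label="Pa")


def approx_response(m: PoleResidueModel | WindkesselParams,
                    q: TimeSeries, *, Pd: float | None = None) -> TimeSeries:
    """Pressure of the step-source (approximate) model.

    p(t) = c0 q(t) + sum_i c_i * (e^{a_i t} * q)(t) + Pd * theta(t), with
    theta(0) = 1, computed by exact-for-piecewise-linear-input recursive
    exponential convolution.  *Pd* overrides the model's distal pressure
    (used by the periodic-state bias estimator, which needs the Pd = 0
    response).
    """
    if isinstance(m, WindkesselParams):
        m = wk_to_pole_residue(m)
    pd = m.Pd if Pd is None else Pd
    horizon = q.duration
    for a in m.poles:
        if a.real > 0 and a.real * horizon > 50:
            raise OverflowError(
                f"unstable pole {a} over horizon {horizon:.3g}s would overflow")
    p = m.c0 * q.values + pd
    for kind, a, c in pole_blocks(m.poles, m.residues):
        y = _exp_conv(q.values, q.dt, a)
        if kind == "r":
            p = p + c * y
        else:
            p = p + 2.0 * (c * y).real
    return TimeSeries(q.t0, q.dt, p, unit_label="Pa")


def equivalent_source(wk: WindkesselParams, t):
    """Thevenin equivalent distal source Pd (1 - e^{a t}) theta(t), a = -1/(R2 C).

    This is what the step source Pd*theta(t) of the approximate model replaces;
    the two differ only over the transient of time constant tau = R2*C.
    Accepts scalar or array t.
    """
    t = np.asarray(t, dtype=float)
    a = -1.0 / wk.tau
    out = np.where(t >= 0, wk.Pd * -np.expm1(a * np.maximum(t, 0.0)), 0.0)
    return float(out) if out.ndim == 0 else out
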