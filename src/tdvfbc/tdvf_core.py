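"""Time-domain vector fitting (TDVF) with an unknown constant distal source.

Given co-located pressure/flow samples, the termination impedance is sought as
H(s) = N(s)/D(s) with numerator and denominator sharing an instrumental pole
set {a_i}:

    N(s) = c0 + sum c_i/(s - a_i),    D(s) = d0 + sum d_i/(s - a_i).

Multiplying the model relation P ~= H Q + Pd/s by D(s) and transforming back
to the time domain turns each term into the original signal plus its
exponentially filtered versions z_i(t) = int_0^t e^{a_i (t-tau)} z(tau) dtau.
Collecting every time sample yields the homogeneous least-squares system
A x ~= 0 with A = [-Phi  Gamma  Theta] and x = [d; c; b], where b_i = Pd d_i
absorbs the (bilinear) distal-pressure unknowns, and Theta holds the filtered
Heaviside step.  x is the right singular vector of the smallest singular
value.  The zeros of D(s) — eigenvalues of diag(a) - 1 d0^{-1} [d_1..d_n] —
become the next iteration's poles ("pole relocation"); at the fixed point
D(s) is constant and H(s) = N(s).

Non-zero initial conditions (records starting mid-beat) add a natural
response G(s) = B(s)/(s D(s)) sharing the same poles; it only changes the
meaning of b (b_i = Pd d_i + r_i), so the identification of c and d is
unchanged and the distal pressure must then come from the periodic-state bias
estimator instead of the b/d projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import distal_pressure
from .rational_models import (
    HemoWaveforms,
    PoleResidueModel,
    TimeSeries,
    _exp_conv,
    pole_blocks,
)

__all__ = [
    "TdvfConfig",
    "LSProblem",
    "LSSolution",
    "FitResult",
    "exp_filter",
    "initial_poles",
    "assemble_ls",
    "solve_ls",
    "relocate_poles",
    "fit_tdvf",
    "DegenerateSolutionWarning",
    "RelocationError",
]

logger = logging.getLogger(__name__)


class DegenerateSolutionWarning(UserWarning):
    """Smallest singular value is not unique: null direction is ambiguous."""


class RelocationError(ValueError):
    """Denominator constant d0 vanished; pole relocation is undefined."""


@dataclass(frozen=True)
class TdvfConfig:
    """Settings for the fitting iteration.

    Parameters
    ----------
    order : number of poles n of the fitted impedance.
    max_iterations : cap on pole-relocation sweeps (default 100).
    pole_convergence_tol : maximum relative pole movement (after sorting by
        real then imaginary part) below which the pole set counts as
        stabilized.
    frequency_band : (f_min, f_max) in Hz over which initial poles are
        spread; default 0.5-25 Hz covers the cardiac fundamental and its
        clinically relevant harmonics.
    rng_seed : seed for the initial-pole jitter.
    enforce_stability : reflect relocated right-half-plane poles across the
        imaginary axis (on by default: fitted models are destined for
        time-stepping boundary-condition use).
    column_scaling : scale the LS matrix to unit column norms before the SVD
        (Pa, m^3/s and dimensionless columns otherwise wreck conditioning).
    pd_method : "ls" (projection b onto d), "bias" (periodic-state mean of
        p - H*q) or "auto" (ls when the record starts from rest, bias
        otherwise).
    bias_fraction : trailing fraction of the record used by the bias
        estimator.
    """

    order: int
    max_iterations: int = 100
    pole_convergence_tol: float = 1e-6
    frequency_band: tuple = (0.5, 25.0)
    rng_seed: int = 0
    enforce_stability: bool = True
    column_scaling: bool = True
    pd_method: str = "auto"
    bias_fraction: float = 0.2
    initial_poles: tuple | None = None

    def __post_init__(self) -> None:
        if self.initial_poles is not None:
            ip = tuple(complex(a) for a in self.initial_poles)
            if len(ip) != self.order:
                raise ValueError("initial_poles must match the order")
            object.__setattr__(self, "initial_poles", ip)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        f0, f1 = self.frequency_band
        if not 0 < f0 < f1:
            raise ValueError("frequency_band must satisfy 0 < f_min < f_max")
        if self.pd_method not in ("auto", "ls", "bias"):
            raise ValueError(f"unknown pd_method {self.pd_method!r}")


@dataclass(frozen=True)
class LSProblem:
    """Assembled homogeneous system A x ~= 0, A = [-Phi  Gamma  Theta].

    Columns come in one real column per real pole and (Re, Im) column pairs
    per complex-conjugate pole pair, so A is real and x = [d; c; b] is real.
    ``blocks`` records the pole structure used to build the columns.
    """

    Phi: np.ndarray
    Gamma: np.ndarray
    Theta: np.ndarray
    blocks: tuple
    poles: tuple

    @property
    def A(self) -> np.ndarray:
        return np.hstack([-self.Phi, self.Gamma, self.Theta])


@dataclass(frozen=True)
class LSSolution:
    """Solution of the homogeneous LS problem, normalized to d0 = 1.

    d, c, b are the real coefficient vectors in the split real basis (length
    n+1 each); ``blocks``/``poles`` carry the pole structure needed to
    reassemble complex residues or to relocate poles.  ``residual`` is
    ||A x||_2 of the unit-norm solution before renormalization (equal to the
    smallest singular value when the SVD route is used).
    """

    d: np.ndarray
    c: np.ndarray
    b: np.ndarray
    blocks: tuple
    poles: tuple
    residual: float
    singular_values: np.ndarray

    def numerator_residues(self) -> tuple:
        """Reassemble the split real coefficients c_1..c_n into complex residues."""
        return _reassemble(self.c[1:], self.blocks)

    def denominator_residues(self) -> tuple:
        return _reassemble(self.d[1:], self.blocks)


@dataclass(frozen=True)
class FitResult:
    model: PoleResidueModel
    iterations_used: int
    converged: bool
    pole_history: tuple
    ls_residual: tuple
    pd_method_used: str = ""
    solution: LSSolution | None = None


# --------------------------------------------------------------------------


def exp_filter(z: TimeSeries, a: complex) -> TimeSeries:
    """Causal convolution of z with the kernel e^{a t}.

    Computed by the one-step recursion z_i(t_k) = e^{a dt} z_i(t_{k-1}) +
    (local quadrature of z over [t_{k-1}, t_k]) with piecewise-linear input
    reconstruction; the first sample is 0 and a = 0 degrades to the running
    integral of z.
    """
    return z.with_values(_exp_conv(z.values, z.dt, a))


def initial_poles(n: int, band: tuple, rng_seed: int = 0) -> list:
    """Starting poles spread over the expected frequency band.

    n//2 weakly damped conjugate pairs with imaginary parts linearly spaced
    over 2*pi*[f_min, f_max] and real parts -omega/100 (plus one real pole at
    -2*pi*f_min when n is odd), each jittered uniformly by +-10%.
    """
    f0, f1 = band
    rng = np.random.default_rng(rng_seed)
    poles: list = []
    if n % 2:
        poles.append(-2 * np.pi * f0 * (1 + 0.1 * rng.uniform(-1, 1)))
    npairs = n // 2
    if npairs:
        freqs = np.linspace(f0, f1, npairs)
        for f in freqs:
            w = 2 * np.pi * f * (1 + 0.1 * rng.uniform(-1, 1))
            sig = -w / 100 * (1 + 0.1 * rng.uniform(-1, 1))
            poles.extend([sig + 1j * w, sig - 1j * w])
    return poles


def _filtered_columns(z: np.ndarray, dt: float, blocks) -> np.ndarray:
    """[z, z_1 .. z_n] with complex pairs split into (2 Re, -2 Im) columns."""
    cols = [np.asarray(z, dtype=float)]
    for kind, a, _ in blocks:
        y = _exp_conv(z, dt, a)
        if kind == "r":
            cols.append(y)
        else:
            cols.append(2.0 * y.real)
            cols.append(-2.0 * y.imag)
    return np.column_stack(cols)


def _reassemble(x: np.ndarray, blocks) -> tuple:
    """Split real coefficients -> complex conjugate-closed coefficient list."""
    out = []
    i = 0
    for kind, _, _ in blocks:
        if kind == "r":
            out.append(complex(x[i]))
            i += 1
        else:
            c = x[i] + 1j * x[i + 1]
            out.extend([c, np.conj(c)])
            i += 2
    return tuple(out)


def _block_poles(blocks) -> tuple:
    out = []
    for kind, a, _ in blocks:
        if kind == "r":
            out.append(complex(a))
        else:
            out.extend([complex(a), np.conj(complex(a))])
    return tuple(out)


def assemble_ls(w: HemoWaveforms, poles: Sequence[complex]) -> LSProblem:
    """Build the blocks Phi (pressure), Gamma (flow), Theta (step source).

    Column 0 of each block is the raw signal (Theta's is all ones,
    theta(t_k) = 1 for t_k >= 0); column j > 0 is the exponential-filter
    output for pole a_j, with conjugate pairs split into real/imaginary
    columns so the stacked system stays real.
    """
    poles = [complex(a) for a in poles]
    for i in range(len(poles)):
        for j in range(i + 1, len(poles)):
            if abs(poles[i] - poles[j]) <= 1e-12 * max(abs(poles[i]), 1.0):
                raise ValueError(f"duplicate pole {poles[i]} in trial set")
    blocks = tuple(pole_blocks(poles))
    dt = w.dt
    theta = np.ones(len(w))
    Phi = _filtered_columns(w.pressure.values, dt, blocks)
    Gamma = _filtered_columns(w.flow.values, dt, blocks)
    Theta = _filtered_columns(theta, dt, blocks)
    return LSProblem(Phi=Phi, Gamma=Gamma, Theta=Theta, blocks=blocks,
                     poles=_block_poles(blocks))


def solve_ls(prob: LSProblem, column_scaling: bool = True) -> LSSolution:
    """Null-direction solve of A x ~= 0 via the SVD.

    x is the right singular vector of the smallest singular value (optionally
    after scaling columns to unit norm, undone afterwards), then rescaled so
    that d0 = 1.  A tie in the smallest singular value (relative gap below
    1e-12) triggers :class:`DegenerateSolutionWarning`; the tie is broken by
    taking the last singular vector.
    """
    A = prob.A
    m, ncols = A.shape
    if m <= ncols:
        raise ValueError(f"need more rows than columns, got {A.shape}")
    if column_scaling:
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        A = A / norms
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    if len(s) > 1 and (s[-2] - s[-1]) <= 1e-12 * s[0]:
        warnings.warn("smallest singular value is not unique; null direction "
                      "ambiguous (tie broken by index)",
                      DegenerateSolutionWarning, stacklevel=2)
    x = Vt[-1]
    residual = float(s[-1])
    if column_scaling:
        x = x / norms
        x = x / np.linalg.norm(x)
        residual = float(np.linalg.norm(prob.A @ x))
    nn = ncols // 3
    d, c, b = x[:nn], x[nn:2 * nn], x[2 * nn:]
    if abs(d[0]) < 1e-12 * np.linalg.norm(d):
        raise RelocationError(f"denominator constant d0 = {d[0]:.3e} ~ 0")
    scale = d[0]
    return LSSolution(d=d / scale, c=c / scale, b=b / scale,
                      blocks=prob.blocks, poles=prob.poles,
                      residual=residual, singular_values=s)


def solve_residues(w: HemoWaveforms, poles: Sequence[complex],
                   column_scaling: bool = True) -> LSSolution:
    """Residue identification with the pole set fixed and D(s) frozen at 1.

    At a true relocation fixed point the denominator is constant, so the
    model relation becomes the ordinary (non-homogeneous) least-squares
    problem  p ~= c0 q + sum c_i q_i + b0 theta + sum b_i theta_i,  solved
    here for c and b.  Using this as the final stage guarantees the returned
    model is exactly N(s) over a unit denominator even when the iteration
    stopped short of a perfect fixed point (e.g. when stability enforcement
    keeps reflecting a spurious right-half-plane denominator zero).
    """
    prob = assemble_ls(w, poles)
    A = np.hstack([prob.Gamma, prob.Theta])
    rhs = prob.Phi[:, 0]
    if column_scaling:
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        A = A / norms
    x, _, _, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if column_scaling:
        x = x / norms
    nn = len(x) // 2
    c, b = x[:nn], x[nn:]
    d = np.zeros(nn)
    d[0] = 1.0
    residual = float(np.linalg.norm(np.hstack([prob.Gamma, prob.Theta]) @ x - rhs))
    return LSSolution(d=d, c=c, b=b, blocks=prob.blocks, poles=prob.poles,
                      residual=residual, singular_values=np.array([]))


def relocate_poles(sol: LSSolution, poles: Sequence[complex] | None = None,
                   enforce_stability: bool = False) -> list:
    """Next pole set: the zeros of the fitted denominator D(s).

    D(s) = d0 + sum d_i/(s - a_i) has the state-space realization
    (diag(a), 1, [d_1..d_n], d0); its zeros are the eigenvalues of
    diag(a) - 1 d0^{-1} [d_1..d_n], built here in real block form (a complex
    pair contributes a [[sigma, omega], [-omega, sigma]] block with input
    vector [2, 0] and output row [Re d, Im d]).  With *enforce_stability*,
    eigenvalues in the right half-plane are reflected across the imaginary
    axis.
    """
    blocks = sol.blocks
    d0 = sol.d[0]
    if abs(d0) < 1e-12 * np.linalg.norm(sol.d):
        raise RelocationError(f"d0 = {d0:.3e} ~ 0, relocation singular")
    n = sum(1 if k == "r" else 2 for k, _, _ in blocks)
    Ablk = np.zeros((n, n))
    bvec = np.zeros(n)
    cvec = np.zeros(n)
    i = 0
    j = 1  # index into sol.d (skip d0)
    for kind, a, _ in blocks:
        if kind == "r":
            Ablk[i, i] = a
            bvec[i] = 1.0
            cvec[i] = sol.d[j]
            i += 1
            j += 1
        else:
            sig, om = a.real, a.imag
            Ablk[i:i + 2, i:i + 2] = [[sig, om], [-om, sig]]
            bvec[i] = 2.0
            cvec[i] = sol.d[j]
            cvec[i + 1] = sol.d[j + 1]
            i += 2
            j += 2
    H = Ablk - np.outer(bvec, cvec) / d0
    eig = np.linalg.eigvals(H)
    new = []
    for lam in eig:
        if abs(lam.imag) <= 1e-10 * max(abs(lam), 1.0):
            lam = complex(lam.real)
        if enforce_stability and lam.real > 0:
            lam = -lam.real + 1j * lam.imag
        new.append(lam)
    return new


def _sorted_poles(poles) -> np.ndarray:
    arr = np.asarray([complex(a) for a in poles])
    order = np.lexsort((arr.imag, arr.real))
    return arr[order]


def _pole_movement(old, new) -> float:
    po, pn = _sorted_poles(old), _sorted_poles(new)
    return float(np.max(np.abs(pn - po) / np.maximum(np.abs(po), 1e-300)))


def _starts_from_rest(w: HemoWaveforms) -> bool:
    q = w.flow.values
    return abs(q[0]) <= 1e-6 * max(np.max(np.abs(q)), 1e-300)


def fit_tdvf(w: HemoWaveforms, cfg: TdvfConfig) -> FitResult:
    """Full TDVF iteration: assemble, SVD solve, relocate, until stable.

    Runs for at most ``cfg.max_iterations`` relocation sweeps, stopping when
    the sorted pole set moves by less than ``cfg.pole_convergence_tol``
    (relative).  A final residue solve at the converged poles yields the
    model H(s) = N(s) (the denominator is constant at the fixed point), and
    the distal pressure is estimated per ``cfg.pd_method``.  Never raises on
    non-convergence: ``converged=False`` with full diagnostics is returned.
    Records that start mid-beat (non-zero initial conditions) are handled
    without modification; only the Pd estimator choice changes.
    """
    if cfg.initial_poles is not None:
        poles = list(cfg.initial_poles)
    else:
        poles = initial_poles(cfg.order, cfg.frequency_band, cfg.rng_seed)
    history = [tuple(poles)]
    residuals = []
    converged = False
    nu = 0
    for nu in range(1, cfg.max_iterations + 1):
        prob = assemble_ls(w, poles)
        sol = solve_ls(prob, column_scaling=cfg.column_scaling)
        residuals.append(sol.residual)
        new_poles = relocate_poles(sol, enforce_stability=cfg.enforce_stability)
        movement = _pole_movement(sol.poles, new_poles)
        poles = new_poles
        history.append(tuple(poles))
        logger.debug("iteration %d: residual %.3e, pole movement %.3e",
                     nu, sol.residual, movement)
        if movement < cfg.pole_convergence_tol:
            converged = True
            break

    # residue identification at the final poles (D frozen at 1)
    sol = solve_residues(w, poles, column_scaling=cfg.column_scaling)
    residues = sol.numerator_residues()
    model = PoleResidueModel(c0=float(sol.c[0]), poles=sol.poles,
                             residues=residues, Pd=0.0)

    method = cfg.pd_method
    if method == "auto":
        method = "ls" if _starts_from_rest(w) else "bias"
    if method == "ls":
        pd = distal_pressure.pd_from_ls(sol)
    else:
        win = distal_pressure.BiasWindow.from_fraction(
            w.pressure, fraction=cfg.bias_fraction)
        pd = distal_pressure.pd_from_bias(w, model, win)
    logger.info("fit order %d: %s after %d iterations, residual %.3e, "
                "Pd = %.6g Pa via %s estimator",
                cfg.order, "converged" if converged else "not converged",
                nu, sol.residual, pd, method)
    model = model.with_Pd(float(pd))
    return FitResult(model=model, iterations_used=nu, converged=converged,
                     pole_history=tuple(history), ls_residual=tuple(residuals),
                     pd_method_used=method, solution=sol)
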