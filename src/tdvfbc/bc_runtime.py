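"""State-space runtime: use a fitted termination as a time-stepping BC.

A conjugate-closed pole-residue impedance splits into n_r real poles and n_c
complex pairs.  Each real pole contributes one state

    x_i' = a_r x_i + q(t),         p_r = sum c_r x_i,

and each complex pair (a = sigma + j omega, c = c' + j c'') two coupled states

    x'_i'  = sigma x'_i + omega x''_i + 2 q(t)
    x''_i' = -omega x'_i + sigma x''_i,      p_c = sum (c' x'_i + c'' x''_i).

The runtime advances these with the forward-Euler recurrence

    x(t_k) = x(t_{k-1}) + dt [a x(t_{k-1}) + q(t_{k-1})]

and returns p(t_k) = p_r + p_c + c0 q(t_k) + Pd.  Note the deliberate
asymmetry inherited from the scheme: states advance with the *previous* flow
sample while the direct term uses the *current* one.  A host 1D/3D solver
calls :func:`step` once per time step; the state is plain data and can be
serialized for restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rational_models import PoleResidueModel, TimeSeries, pole_blocks

__all__ = ["StateSpaceBC", "StepSizeError", "realize", "step", "run_steps",
           "simulate_bc"]


class StepSizeError(ValueError):
    """dt violates the forward-Euler stability bound |1 + dt a| < 1."""


@dataclass
class StateSpaceBC:
    """Real-valued realization of a pole-residue termination plus its state.

    Real-pole block: ``a_r``/``c_r`` gains with states ``x``.  Complex-pair
    block: ``sigma``/``omega``/``c_re``/``c_im`` with coupled states ``xp``
    (x') and ``xpp`` (x'').  ``k`` is the current step index; ``q_prev``
    stores the previous flow sample needed by the Euler update.
    """

    a_r: np.ndarray
    c_r: np.ndarray
    sigma: np.ndarray
    omega: np.ndarray
    c_re: np.ndarray
    c_im: np.ndarray
    c0: float
    Pd: float
    dt: float
    x: np.ndarray = field(default=None)
    xp: np.ndarray = field(default=None)
    xpp: np.ndarray = field(default=None)
    k: int = 0
    q_prev: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_r", "c_r", "sigma", "omega", "c_re", "c_im"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.x is None:
            self.x = np.zeros(len(self.a_r))
        if self.xp is None:
            self.xp = np.zeros(len(self.sigma))
        if self.xpp is None:
            self.xpp = np.zeros(len(self.sigma))

    @property
    def order(self) -> int:
        return len(self.a_r) + 2 * len(self.sigma)

    def to_dict(self) -> dict:
        """Serializable snapshot (restart support for host solvers)."""
        return {
            "a_r": self.a_r.tolist(), "c_r": self.c_r.tolist(),
            "sigma": self.sigma.tolist(), "omega": self.omega.tolist(),
            "c_re": self.c_re.tolist(), "c_im": self.c_im.tolist(),
            "c0": self.c0, "Pd": self.Pd, "dt": self.dt,
            "x": self.x.tolist(), "xp": self.xp.tolist(),
            "xpp": self.xpp.tolist(), "k": self.k, "q_prev": self.q_prev,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceBC":
        return cls(**{k: (np.asarray(v) if isinstance(v, list) else v)
                      for k, v in d.items()})


def realize(m: PoleResidueModel, dt: float,
            allow_unstable: bool = False) -> StateSpaceBC:
    """Split a conjugate-closed model into real/complex-pair Euler blocks.

    Raises :class:`StepSizeError` when dt violates |1 + dt a| < 1 for any
    pole (the forward-Euler stability disc), and refuses right-half-plane
    poles unless *allow_unstable* is set.  States start at zero.
    """
    a_r, c_r, sig, om, cre, cim = [], [], [], [], [], []
    for kind, a, c in pole_blocks(m.poles, m.residues):
        a_c = complex(a)
        if a_c.real >= 0:
            if not allow_unstable:
                raise ValueError(
                    f"pole {a} is not strictly stable; pass allow_unstable="
                    "True to realize it anyway")
        elif abs(1 + dt * a_c) >= 1:
            raise StepSizeError(
                f"dt = {dt:g} violates forward-Euler stability for pole {a} "
                f"(|1 + dt a| = {abs(1 + dt * a_c):.3f} >= 1)")
        if kind == "r":
            a_r.append(a_c.real)
            c_r.append(complex(c).real)
        else:
            sig.append(a_c.real)
            om.append(a_c.imag)
            cc = complex(c)
            cre.append(cc.real)
            cim.append(cc.imag)
    return StateSpaceBC(a_r=a_r, c_r=c_r, sigma=sig, omega=om,
                        c_re=cre, c_im=cim, c0=float(m.c0), Pd=float(m.Pd),
                        dt=dt)


def step(bc: StateSpaceBC, q_k: float) -> float:
    """Advance one forward-Euler step and return the outlet pressure.

    States are advanced with the previous flow sample; the direct term and
    the constant distal source use the current one.  The very first call
    returns p(t_0) = c0 q_0 + Pd with zero states.
    """
    if not np.isfinite(q_k):
        raise ValueError(f"non-finite flow sample {q_k}")
    dt = bc.dt
    if bc.k > 0:
        q = bc.q_prev
        bc.x = bc.x + dt * (bc.a_r * bc.x + q)
        xp_new = bc.xp + dt * (bc.sigma * bc.xp + bc.omega * bc.xpp + 2.0 * q)
        bc.xpp = bc.xpp + dt * (-bc.omega * bc.xp + bc.sigma * bc.xpp)
        bc.xp = xp_new
    p = (float(bc.c_r @ bc.x)
         + float(bc.c_re @ bc.xp + bc.c_im @ bc.xpp)
         + bc.c0 * q_k + bc.Pd)
    bc.q_prev = q_k
    bc.k += 1
    return p


def run_steps(bc: StateSpaceBC, q: np.ndarray) -> np.ndarray:
    """Map a flow sample array through :func:`step` (empty in, empty out)."""
    q = np.asarray(q, dtype=float)
    out = np.empty(len(q))
    for i, qi in enumerate(q):
        out[i] = step(bc, float(qi))
    return out


def simulate_bc(m: PoleResidueModel, q: TimeSeries,
                allow_unstable: bool = False) -> TimeSeries:
    """Reference entry point: realize the model and step through a flow record."""
    bc = realize(m, q.dt, allow_unstable=allow_unstable)
    return TimeSeries(q.t0, q.dt, run_steps(bc, q.values), unit_label="Pa")
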