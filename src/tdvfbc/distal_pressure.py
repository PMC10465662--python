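"""Two estimators for the distal pressure Pd of a fitted termination.

Pd enters the model relation P(s) ~= H(s) Q(s) + Pd/s bilinearly through the
least-squares unknowns b_i = Pd d_i, so it is recovered after the fit either

* from the least-squares variables themselves, as the projection
  Pd = d^T b / ||d||^2 — exact when the record starts from rest so that
  b_i = Pd d_i holds exactly; or
* as the periodic-state bias: once the start-up transient has extinguished,
  Pd ~= p(t) - p_m(t) where p_m is the response of H alone (no distal
  source), so Pd is the window mean of that difference.  This remains
  unbiased for records with non-zero initial conditions, where the natural
  response shifts b to b_i = Pd d_i + r_i and breaks the projection's
  premise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .rational_models import HemoWaveforms, PoleResidueModel, TimeSeries, approx_response

if TYPE_CHECKING:  # pragma: no cover
    from .tdvf_core import LSSolution

__all__ = ["BiasWindow", "pd_from_ls", "pd_from_bias"]


@dataclass(frozen=True)
class BiasWindow:
    """Trailing sample window [start..stop) assumed to lie in periodic state."""

    t_c: float
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty bias window")

    @classmethod
    def from_fraction(cls, ts: TimeSeries, fraction: float = 0.2,
                      period: float | None = None) -> "BiasWindow":
        """Window over the last *fraction* of the record.

        When the cycle *period* is known the window start is snapped down to
        a whole number of cycles from the end, so the mean is taken over
        complete beats.
        """
        n = len(ts)
        length = max(int(round(fraction * n)), 1)
        if period is not None:
            per_cycle = max(int(round(period / ts.dt)), 1)
            cycles = max(length // per_cycle, 1)
            length = cycles * per_cycle
        start = max(n - length, 0)
        return cls(t_c=ts.t0 + start * ts.dt, start=start, stop=n)


def pd_from_ls(sol: "LSSolution") -> float:
    """Pd from the least-squares variables: projection of b onto d.

    Solves d Pd ~= b in the least-squares sense, Pd = d^T b / ||d||^2,
    using the real split-basis coefficient vectors.  Valid only when the
    record starts from (numerically) vanishing initial conditions.
    """
    d = np.asarray(sol.d, dtype=float)
    b = np.asarray(sol.b, dtype=float)
    nd2 = float(d @ d)
    if nd2 == 0.0:
        raise ValueError("||d|| = 0: projection undefined")
    return float(d @ b) / nd2


def pd_from_bias(w: HemoWaveforms, m: PoleResidueModel, win: BiasWindow) -> float:
    """Pd as the periodic-state offset between data and the H-only response.

    Computes p_m = (impulse response of H) * q with no distal source and
    returns mean(p - p_m) over the window, which must lie after the start-up
    transient.
    """
    if win.stop > len(w):
        raise ValueError("bias window extends past the record")
    p_m = approx_response(m, w.flow, Pd=0.0)
    diff = w.pressure.values[win.start:win.stop] - p_m.values[win.start:win.stop]
    return float(np.mean(diff))
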