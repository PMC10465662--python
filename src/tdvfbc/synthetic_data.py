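"""Synthetic pulsatile waveforms with known ground truth.

Every experiment in this package runs on data generated here: a half-sine
systolic pulse train stands in for an aortic-branch inflow (parameterized by
heart rate, mean flow / cardiac output and systolic fraction), the pressure
response comes from one of the reference model oracles, and measurement
noise is zero-mean white Gaussian at a prescribed SNR.  Because the
generating model is always known, parameter-recovery assertions are exact
rather than anecdotal.

The pulse train is deliberately simple: identification only needs the inflow
to be pulsatile and spectrally rich (a half-sine train excites every cardiac
harmonic), not to reproduce any particular measured aortic waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rational_models import (
    HemoWaveforms,
    PoleResidueModel,
    TimeSeries,
    WindkesselParams,
    approx_response,
    wk_exact_response,
    wk_to_pole_residue,
)

__all__ = ["InflowSpec", "NoiseSpec", "make_inflow", "synth_waveforms",
           "add_noise", "add_noise_waveforms"]


@dataclass(frozen=True)
class InflowSpec:
    """Pulse-train inflow settings.

    Defaults are a resting adult operating point (heart rate 66.9 bpm,
    cardiac output 5.2 l/min); pass a branch-level cardiac output (a fraction
    of the systemic one) when synthesizing a single outlet.  ``ramp_cycles``
    > 0 fades the train in smoothly, emulating a record that starts from
    rest; 0 starts pulsing immediately (the flow still starts at zero since
    each pulse begins at zero).
    """

    hr_bpm: float = 66.9
    co_l_min: float = 5.2
    systolic_fraction: float = 0.35
    n_cycles: int = 20
    dt: float = 1e-3
    ramp_cycles: float = 0.0

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0 or self.co_l_min <= 0:
            raise ValueError("heart rate and cardiac output must be positive")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic fraction must lie in (0, 1)")
        if self.n_cycles < 1 or self.dt <= 0:
            raise ValueError("need n_cycles >= 1 and dt > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.hr_bpm

    @property
    def mean_flow(self) -> float:
        """Target mean flow in m^3/s (1 l/min = 1/60000 m^3/s)."""
        return self.co_l_min / 60000.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a prescribed SNR.

    ``convention`` selects the reference power: "ac" (mean-removed signal,
    default) or "total".  ``applies_to`` selects which waveform(s) a
    waveform-pair helper corrupts.
    """

    snr_db: float
    rng_seed: int = 0
    applies_to: str = "both"
    convention: str = "ac"

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.applies_to not in ("pressure", "flow", "both"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")
        if self.convention not in ("ac", "total"):
            raise ValueError(f"unknown convention {self.convention!r}")


def make_inflow(spec: InflowSpec) -> TimeSeries:
    """Half-sine systolic pulse train scaled to the requested mean flow.

    q(t) = A sin(pi t'/Ts) during systole (t' = phase within the cycle,
    Ts = systolic fraction * period), zero in diastole; A is set so the
    cycle-average equals the cardiac output.  An optional raised-cosine ramp
    over the first ``ramp_cycles`` cycles fades the train in.
    """
    T = spec.period
    Ts = spec.systolic_fraction * T
    if spec.dt > Ts / 10:
        raise ValueError(
            f"dt = {spec.dt:g} too coarse: need dt <= systolic duration/10 "
            f"= {Ts / 10:g}")
    n = int(round(spec.n_cycles * T / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    phase = np.mod(t, T)
    amp = spec.mean_flow * np.pi * T / (2.0 * Ts)
    q = np.where(phase < Ts, amp * np.sin(np.pi * phase / Ts), 0.0)
    if spec.ramp_cycles > 0:
        t_ramp = spec.ramp_cycles * T
        ramp = np.where(t < t_ramp, 0.5 * (1 - np.cos(np.pi * t / t_ramp)), 1.0)
        q = q * ramp
    return TimeSeries(0.0, spec.dt, q, unit_label="m3/s")


def synth_waveforms(spec: InflowSpec,
                    m: PoleResidueModel | WindkesselParams,
                    model_variant: str = "approximate") -> HemoWaveforms:
    """Inflow plus the pressure response of a known termination.

    ``model_variant`` picks the oracle: "approximate" (step distal source,
    any pole-residue model) or "exact" (full Windkessel circuit with its
    exponential Thevenin transient; requires WindkesselParams).
    """
    q = make_inflow(spec)
    if model_variant == "exact":
        if not isinstance(m, WindkesselParams):
            raise ValueError("the exact oracle needs WindkesselParams")
        p = wk_exact_response(m, q)
    elif model_variant == "approximate":
        pr = wk_to_pole_residue(m) if isinstance(m, WindkesselParams) else m
        p = approx_response(pr, q)
    else:
        raise ValueError(f"unknown model_variant {model_variant!r}")
    return HemoWaveforms(pressure=p, flow=q)


def add_noise(z: TimeSeries, spec: NoiseSpec) -> tuple:
    """Corrupt a series with white Gaussian noise at the requested SNR.

    The noise standard deviation is RMS(reference) * 10^(-snr_db/20) where
    the reference is the mean-removed signal ("ac" convention, default) or
    the raw signal ("total").  Returns ``(noisy_series, noise_std)``.
    """
    ref = z.values - np.mean(z.values) if spec.convention == "ac" else z.values
    rms = float(np.sqrt(np.mean(ref**2)))
    if rms == 0.0:
        raise ValueError("signal has zero reference power; SNR undefined")
    std = rms * 10.0 ** (-spec.snr_db / 20.0)
    rng = np.random.default_rng(spec.rng_seed)
    noisy = z.values + rng.normal(0.0, std, size=len(z))
    return z.with_values(noisy), std


def add_noise_waveforms(w: HemoWaveforms, spec: NoiseSpec) -> HemoWaveforms:
    """Corrupt pressure and/or flow with independent noise streams."""
    ss = np.random.SeedSequence(spec.rng_seed)
    seed_p, seed_q = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    p, q = w.pressure, w.flow
    if spec.applies_to in ("pressure", "both"):
        p, _ = add_noise(p, NoiseSpec(spec.snr_db, seed_p, convention=spec.convention))
    if spec.applies_to in ("flow", "both"):
        q, _ = add_noise(q, NoiseSpec(spec.snr_db, seed_q, convention=spec.convention))
    return HemoWaveforms(pressure=p, flow=q)
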