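# tdvfbc — vector-fitting estimation of lumped outflow boundary conditions

Truncated cardiovascular models (1D arterial networks, 3D CFD domains) need
outlet boundary conditions that stand in for the downstream vasculature. The
standard choice is the three-element Windkessel (RCR): proximal resistance
R1, distal resistance R2, compliance C and a constant distal pressure Pd,
i.e. the order-1 impedance

    H(s) = R1 + R2 / (s R2 C + 1),        P(s) ≈ H(s) Q(s) + Pd / s.

`tdvfbc` estimates such terminations — of *any* order, the Windkessel being
the n = 1 case — directly from co-located pressure and flow-rate waveforms
at the truncation point, using time-domain vector fitting (TDVF). The
impedance is parameterized in pole-residue form

    H(s) = c0 + Σᵢ cᵢ / (s − aᵢ),   i = 1..n,

as a ratio N(s)/D(s) of rational functions sharing an instrumental pole set.
Each least-squares sweep filters p, q and the Heaviside step through
exponential kernels e^{aᵢ t}, stacks the homogeneous system A x ≈ 0 with
x = [d; c; b] (b absorbs the bilinear distal-pressure unknowns b_i = Pd d_i),
solves it via the SVD, and relocates the poles to the zeros of the fitted
denominator — the eigenvalues of diag(a) − 1 d0⁻¹ [d₁..d_n]. At the fixed
point D is constant and the numerator is the model. The distal pressure
comes either from the projection Pd = dᵀb/‖d‖² or, for records that start
mid-beat, from the periodic-state mean of p − (H∗q).

The package also provides:

* an exact Windkessel-circuit oracle and an exponential-recursive-convolution
  oracle for validation,
* a forward-Euler state-space runtime (`bc_runtime`) with a one-call-per-step
  contract for embedding fitted models in 1D/3D solvers,
* a Nelder–Mead Windkessel baseline for cross-validation,
* a synthetic-data generator (pulsatile half-sine inflow, SNR-controlled
  Gaussian noise) so every claim is testable without external data,
* CSV/JSON I/O with mmHg / cm³/s / l/min converters and a CLI.

## Worked example

```python
import tdvfbc as t

# a brachiocephalic-like outlet termination (SI units)
wk = t.WindkesselParams(R1=0.26e8, R2=8.43e8, C=10.5e-10, Pd=1580.0)

# 20 cycles of pulsatile branch inflow and its pressure response
spec = t.InflowSpec(hr_bpm=66.9, co_l_min=0.75, n_cycles=20, dt=1e-3)
w = t.synth_waveforms(spec, wk)

fit = t.fit_tdvf(w, t.TdvfConfig(order=1, rng_seed=1))
print(fit.converged, fit.iterations_used)   # True 2
print(t.pole_residue_to_wk(fit.model))
```

prints

```
True 2
WindkesselParams(R1=25999999.999964833, R2=843000000.0000355,
                 C=1.049999999999912e-09, Pd=1579.9999999999875)
```

— the generator parameters recovered to machine precision in two pole
relocations: R1 and R2 in Pa·s/m³, C in m³/Pa, Pd in Pa (1.58 kPa, the
pressure at which distal flow ceases). The same pipeline is available from
the shell:

```sh
tdvfbc synth --model wk.json --co 0.75 --cycles 20 --out wave.csv
tdvfbc fit --input wave.csv --order 1 --seed 1 --out model.json
tdvfbc convert --input model.json --out wk_fit.json
tdvfbc report --reference wave.csv --model model.json --period 0.897
```

Higher-order terminations work identically (`--order 8`); the fitted model
JSON can be handed to `tdvfbc simulate` or embedded in a solver through
`tdvfbc.realize` / `tdvfbc.step`.

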