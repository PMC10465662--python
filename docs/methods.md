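# Methods

## Model class and assumptions

A vessel outlet is terminated by a linear time-invariant lumped impedance
H(s) of order n plus a constant distal pressure source Pd, related to the
outlet waveforms by P(s) ≈ H(s) Q(s) + Pd/s. The Heaviside convention is
θ(0) = 1: the distal source acts from the very first sample. For the
three-element Windkessel this step-source form is an *approximation* of the
physical circuit, whose Thevenin-equivalent source is the exponential
transient Pd(1 − e^{at}), a = −1/(R2 C): the two differ only during the
start-up transient of duration ~R2 C, and coincide at the pulsatile periodic
state, which is the regime of clinical interest. All internal units are
strict SI (Pa, m³/s); unit conversion (1 mmHg = 133.322387415 Pa) happens
only at the I/O boundary, because mixed units are the dominant source of
error in this problem class.

Repeated poles are rejected rather than given a Jordan-block extension; the
model class is conjugate-closed simple poles only.

## The fitting iteration

H is parameterized as N(s)/D(s) with both rational functions sharing an
instrumental pole set. One sweep: (1) filter p, q and θ through the kernels
e^{aᵢ t}; (2) stack the homogeneous system A x ≈ 0, A = [−Φ Γ Θ],
x = [d; c; b], over all samples; (3) take x as the right singular vector of
the smallest singular value; (4) relocate the poles to the zeros of D,
computed as eigenvalues of diag(a) − 1 d0⁻¹ [d₁..d_n] in real block form
(complex pairs contribute [[σ, ω], [−ω, σ]] blocks with input gain 2).
Sweeps repeat until the sorted pole set moves by less than a relative
tolerance (default 1e-6) or 100 sweeps have run, whichever comes first.
Records that start mid-beat need no special handling: non-zero initial
conditions only redefine the dummy variables b (b_i = Pd d_i + r_i, where
r_i parameterize the natural response), leaving c and d untouched.

Numerical choices, each of which the underlying formulation leaves open:

* **Quadrature in the exponential filter.** The input is reconstructed
  piecewise-linearly between samples, for which the one-step update
  y_k = e^{aΔt} y_{k−1} + α z_{k−1} + β z_k is exact. Zero-order-hold
  quadrature measurably biases the recovered compliance by O(Δt). The
  weights α, β switch to series expansions for |aΔt| < 1e-4 to avoid
  cancellation; a = 0 degrades to the cumulative trapezoid.
* **Initial poles.** n/2 weakly damped conjugate pairs with imaginary parts
  spread over 2π·[0.5, 25] Hz (cardiac fundamental through clinically
  relevant harmonics), real parts −ω/100, ±10% seeded jitter, plus one real
  pole at −2π f_min when n is odd. This is standard vector-fitting practice
  for a "randomly distributed over the expected band" start.
* **Real arithmetic.** Columns of complex-pair filters are split into
  (2 Re, −2 Im) pairs so A stays real and the solution vector is real;
  residues are reassembled as conjugate pairs afterwards.
* **Column scaling.** A mixes Pa, m³/s and dimensionless columns spanning
  ~12 decades; columns are scaled to unit norm before the SVD and the
  scaling is undone on the solution. This changes conditioning only, not
  the physics (verified by test).
* **Normalization.** The homogeneous solution is rescaled to d0 = 1; H and
  Pd are invariant to this choice.
* **Stability.** Relocated poles with positive real part are reflected
  across the imaginary axis (default on, since fitted models are destined
  for explicit time stepping). Whether to enforce stability is exposed as a
  flag.
* **Final stage: residue identification.** After the pole iteration, the
  returned model is obtained by freezing the poles, fixing D ≡ 1, and
  solving the *ordinary* least-squares problem
  p ≈ c0 q + Σ cᵢ qᵢ + b0 θ + Σ bᵢ θᵢ for c and b. At a genuine fixed point
  this coincides with the homogeneous solution. It matters in two edge
  cases: (i) when stability reflection keeps re-reflecting a spurious
  right-half-plane denominator zero, the pole set stops moving while D is
  *not* constant, and the numerator of the homogeneous solution alone is
  not the model; (ii) when the fit order exceeds the true order on exactly
  rational noiseless data, the homogeneous problem is degenerate (flagged
  by `DegenerateSolutionWarning`) while the residue stage remains
  well-posed.

Convergence is judged on pole movement, not on the LS residual (both are
recorded in `FitResult`); the formulation defines "the pole set stabilizes"
but no metric, so the metric and its 1e-6 default are package choices.

## Distal pressure

Two estimators are provided because each has a domain of validity:

* `pd_from_ls`: Pd = dᵀb/‖d‖², the projection of the dummy variables onto
  the denominator coefficients. Exact when the record starts from rest
  (b = Pd d holds identically).
* `pd_from_bias`: the mean of p − (H∗q) over a trailing window, valid once
  the start-up/natural transient has extinguished; unbiased also for
  mid-beat records, where the projection premise fails.

`fit_tdvf` defaults to "auto": the projection when the first flow sample is
numerically zero (record starts from rest), the bias otherwise. The default
window is the last 20% of the record, snapped to whole cycles when the
period is known. The heuristic can misfire when a truncated record happens
to begin in diastole (q ≈ 0 without the states being at rest); pass
`pd_method="bias"` explicitly in that situation.

## Boundary-condition runtime

`realize` splits a conjugate-closed model into real-pole states
ẋ = a x + q and complex-pair states (ẋ' = σx' + ωx'' + 2q,
ẋ'' = −ωx' + σx''), advanced by forward Euler:
x(t_k) = x(t_{k−1}) + Δt[a x(t_{k−1}) + q(t_{k−1})], with output
p(t_k) = Σ c_r x + Σ(c' x' + c'' x'') + c0 q(t_k) + Pd. The scheme is kept
bit-faithful to its usual solver-embedded form — states advance on the
*previous* flow sample while the direct term uses the *current* one, and
the input enters only x' with gain 2 — in preference to higher-accuracy
variants; the recursive-convolution oracle serves when accuracy is the
point. `realize` rejects Δt outside the Euler stability disc
(|1 + Δt a| ≥ 1) and right-half-plane poles without an explicit override.
The per-step contract (state, q_k) → (state', p_k) plus `to_dict`/
`from_dict` state serialization is what a host 1D/3D solver embeds.

## Nelder–Mead baseline

The cross-validation fitter minimizes the summed squared residual between
measured pressure and the step-source Windkessel response written with a
recursive convolution, over (R1, R2, C, Pd). The response form was chosen
so the cost vanishes exactly on data generated by the same parameters (the
self-consistency requirement); a formulation mixing the exponential
Thevenin source with the step-source convolution would leave a transient
residual and sign ambiguities. Parameters are normalized by the magnitudes
of a Thevenin-style initial guess — Pd from a deflated pressure minimum,
R1 + R2 from the DC pressure/flow ratio, the time constant from a
log-linear fit of the longest contiguous diastolic stretch — because the
raw parameters span ~18 decades and an unnormalized simplex stalls. The
search restarts once from its own optimum.

## Synthetic data

The generator emulates a single outlet of a truncated arterial tree: a
half-sine systolic pulse train (heart rate, branch mean flow, systolic
fraction 0.35 by default) driving a known termination via one of the two
oracles. Default operating point: 66.9 bpm; for single-branch runs the
"cardiac output" parameter is set to a branch-level 0.75 l/min so that mean
pressure lands in the physiological ~12 kPa range for the Windkessel
parameter sets used in the tests. Twenty cycles at Δt = 1 ms give a horizon
of ~20 R2 C for those parameter sets, safely past the start-up transient.
Noise is zero-mean white Gaussian with σ = RMS(signal − mean) ·
10^(−SNR/20); the SNR is referenced to mean-removed (AC) power by default,
with total power selectable, since either convention is defensible and the
choice is therefore documented rather than hidden.

What the generator does *not* emulate: measured aortic waveform shapes,
wave reflections between outlets, respiratory or autonomic variability,
nonlinear vessel mechanics, or correlated/colored measurement noise.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery on data within the model class, not clinical accuracy on in-vivo
records.

## Experiment scales

The built-in experiments are desk-scale by design: 10 noise realizations
per SNR level (20–100 dB) rather than a large ensemble, 20-cycle records,
and a single order-8 reference termination (two real poles plus three
resonant conjugate pairs near the 2nd, 5th and 10th cardiac harmonics) for
the order sweep. In the noise study the fitted model is re-exercised
through the forward-Euler runtime at the data Δt — exactly how such models
are consumed by a solver — so the reconstruction error carries the
discretization floor of that runtime (~0.07% at Δt = 1 ms for the default
termination); estimation noise stays below that floor for SNR ≥ 40 dB,
which is what "accuracy is flat down to 40 dB" operationally means here.

## Known limitations

* Under-order fits (e.g. order 1 or 2 on genuinely order-8 data) may not
  satisfy the pole-movement criterion within 100 sweeps; `fit_tdvf` then
  returns `converged=False` with the full pole/residual history, and the
  returned model is the residue fit at the last pole set — usable, but
  order selection is the caller's problem (no automatic order estimation).
* The homogeneous system is degenerate for over-order fits of noiseless
  exactly-rational data; a warning is raised and the residue stage keeps
  the result meaningful.
* `wk_exact_response` integrates the circuit ODE with DOP853 at rtol 1e-10
  and max_step = Δt (flow is interpolated linearly, so steps must not
  straddle kinks); it is an oracle, not a fast path.
* Estimation assumes co-located, uniformly sampled, simultaneous p and q;
  no resampling or alignment is performed beyond grid validation.
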