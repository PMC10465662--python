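"""The vector-fitting engine: filtering, LS assembly, SVD solve, relocation."""

import numpy as np
import pytest

import tdvfbc as t
from tdvfbc import tdvf_core as core
from tdvfbc.rational_models import IllConditionedFilterWarning, pole_blocks

from conftest import PERIOD, freq_grid


def make_solution(poles, d_complex, d0=None):
    """Build an LSSolution carrying denominator residues, for relocation tests."""
    blocks = tuple(pole_blocks(poles, d_complex))
    split = [1.0 if d0 is None else d0]
    for kind, _, dres in blocks:
        if kind == "r":
            split.append(dres)
        else:
            split.extend([dres.real, dres.imag])
    d = np.asarray(split, dtype=float)
    zeros = np.zeros_like(d)
    return core.LSSolution(d=d, c=zeros, b=zeros, blocks=blocks,
                           poles=core._block_poles(blocks), residual=0.0,
                           singular_values=np.ones(3 * len(d)))


def assert_pole_sets_close(got, ref, rtol=1e-8, atol=1e-9):
    """Multiset comparison by nearest-neighbour matching.

    Lexicographic complex sorting is unstable for conjugate pairs whose real
    parts differ only in the last floating-point digits.
    """
    ref = [complex(r) for r in ref]
    assert len(got) == len(ref)
    for g in got:
        j = int(np.argmin([abs(complex(g) - r) for r in ref]))
        r = ref.pop(j)
        assert abs(complex(g) - r) <= rtol * abs(r) + atol, (g, r)


def denominator_zeros_bruteforce(poles, d_complex, d0=1.0):
    """Roots of D(s) = d0 + sum d_i/(s - a_i) by clearing denominators."""
    poles = [complex(a) for a in poles]
    poly = d0 * np.poly(poles)
    for i, di in enumerate(d_complex):
        others = [a for j, a in enumerate(poles) if j != i]
        term = complex(di) * np.poly(others)
        poly = poly + np.pad(term, (len(poly) - len(term), 0))
    return np.roots(poly)


class TestExpFilter:
    def test_step_input_matches_integral(self):
        z = t.TimeSeries(0.0, 1e-3, np.ones(1500))
        a = -2.5
        y = core.exp_filter(z, a)
        np.testing.assert_allclose(y.values, (np.exp(a * z.times) - 1) / a,
                                   rtol=1e-12, atol=1e-15)
        assert y.values[0] == 0.0

    def test_zero_pole_is_running_integral(self):
        z = t.TimeSeries(0.0, 1e-3, np.linspace(0, 1, 1000))
        y = core.exp_filter(z, 0.0)
        np.testing.assert_allclose(y.values, 0.5 * z.times * z.values, atol=1e-12)

    def test_zero_input(self):
        z = t.TimeSeries(0.0, 0.01, np.zeros(100))
        assert np.all(core.exp_filter(z, -3.0).values == 0.0)

    def test_ill_conditioned_warning(self):
        z = t.TimeSeries(0.0, 1.0, np.ones(10))
        with pytest.warns(IllConditionedFilterWarning):
            core.exp_filter(z, -100.0)


class TestAssembly:
    def test_identical_inputs_give_identical_blocks(self):
        ones = t.TimeSeries(0.0, 0.1, np.ones(30))
        w = t.HemoWaveforms(pressure=ones, flow=ones)
        prob = core.assemble_ls(w, [-1.0])
        np.testing.assert_array_equal(prob.Phi, prob.Gamma)
        np.testing.assert_array_equal(prob.Phi, prob.Theta)

    def test_theta_first_column_is_ones(self, seg3_waveforms):
        prob = core.assemble_ls(seg3_waveforms, [-1.0, -2 + 9j, -2 - 9j])
        np.testing.assert_array_equal(prob.Theta[:, 0], 1.0)
        assert prob.A.shape == (len(seg3_waveforms), 3 * 4)

    def test_duplicate_pole_rejected(self, seg3_waveforms):
        with pytest.raises(ValueError):
            core.assemble_ls(seg3_waveforms, [-1.0, -1.0])

    def test_true_coefficients_annihilate(self, seg3_wk, seg3_waveforms):
        # with the trial pole at the generator pole, x = [d; c; b] built from
        # (d=[1,0], c=[c0,c1], b=Pd*d) is an exact model solution: A x is
        # bounded by quadrature error only
        m = t.wk_to_pole_residue(seg3_wk)
        prob = core.assemble_ls(seg3_waveforms, list(m.poles))
        x = np.concatenate([[1.0, 0.0],
                            [m.c0, m.residues[0].real],
                            [seg3_wk.Pd, 0.0]])
        r = -prob.Phi @ x[:2] + prob.Gamma @ x[2:4] + prob.Theta @ x[4:]
        scale = np.linalg.norm(prob.Phi[:, 0])
        assert np.linalg.norm(r) < 1e-9 * scale


class TestSolve:
    @staticmethod
    def _fabricated_problem(rng, K=40):
        # A with an exact known null vector: choose Phi, Gamma, d, c, b
        # freely and solve for Theta's first column
        Phi = rng.normal(size=(K, 2))
        Gamma = rng.normal(size=(K, 2))
        d = np.array([1.0, -0.3])
        c = np.array([0.8, 2.0])
        b = np.array([1.7, 0.0])
        theta1 = rng.normal(size=K)
        theta0 = (Phi @ d - Gamma @ c - theta1 * b[1]) / b[0]
        Theta = np.column_stack([theta0, theta1])
        blocks = (("r", -1.0, None),)
        prob = core.LSProblem(Phi=Phi, Gamma=Gamma, Theta=Theta,
                              blocks=blocks, poles=(-1.0 + 0j,))
        return prob, d, c, b

    def test_exact_null_vector_recovered(self):
        rng = np.random.default_rng(3)
        prob, d, c, b = self._fabricated_problem(rng)
        sol = core.solve_ls(prob)
        np.testing.assert_allclose(sol.d, d, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(sol.c, c, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(sol.b, b, rtol=1e-9, atol=1e-9)
        assert np.linalg.norm(prob.A @ np.concatenate([sol.d, sol.c, sol.b])) \
            < 1e-8 * np.linalg.norm(prob.A)

    def test_full_rank_residual_is_smallest_singular_value(self):
        rng = np.random.default_rng(4)
        Phi = rng.normal(size=(20, 2))
        Gamma = rng.normal(size=(20, 2))
        Theta = rng.normal(size=(20, 2))
        prob = core.LSProblem(Phi=Phi, Gamma=Gamma, Theta=Theta,
                              blocks=(("r", -1.0, None),), poles=(-1.0 + 0j,))
        sol = core.solve_ls(prob, column_scaling=False)
        svals = np.linalg.svd(prob.A, compute_uv=False)
        assert sol.residual == pytest.approx(svals[-1], rel=1e-10)

    def test_pressure_rescaling_rescales_model(self, seg3_wk, seg3_waveforms):
        # changing pressure units by k multiplies H and Pd by k: the fitted
        # physics is unit-equivariant, poles untouched
        k = 133.322387415
        scaled = t.HemoWaveforms(
            pressure=seg3_waveforms.pressure.with_values(
                seg3_waveforms.pressure.values * k),
            flow=seg3_waveforms.flow)
        cfg = t.TdvfConfig(order=1, rng_seed=5)
        f1 = t.fit_tdvf(seg3_waveforms, cfg)
        f2 = t.fit_tdvf(scaled, cfg)
        assert f2.model.poles[0] == pytest.approx(f1.model.poles[0], rel=1e-8)
        assert f2.model.c0 == pytest.approx(k * f1.model.c0, rel=1e-8)
        assert f2.model.Pd == pytest.approx(k * f1.model.Pd, rel=1e-8)

    def test_column_scaling_does_not_change_solution(self, seg3_waveforms):
        prob = core.assemble_ls(seg3_waveforms, [-1.5])
        s_on = core.solve_ls(prob, column_scaling=True)
        s_off = core.solve_ls(prob, column_scaling=False)
        np.testing.assert_allclose(s_on.d, s_off.d, rtol=1e-6)
        np.testing.assert_allclose(s_on.c, s_off.c, rtol=1e-6)


class TestRelocation:
    def test_scalar_closed_form(self):
        # D(s) = 1 + d1/(s - a) vanishes at s = a - d1
        sol = make_solution([-2.0], [0.5])
        (new,) = core.relocate_poles(sol)
        assert new == pytest.approx(-2.0 - 0.5, rel=1e-14)

    def test_zero_residues_are_fixed_point(self):
        sol = make_solution([-1.0, -3.0, -7.0], [0.0, 0.0, 0.0])
        new = core.relocate_poles(sol)
        np.testing.assert_allclose(sorted(x.real for x in new), [-7, -3, -1],
                                   rtol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_roots_real(self, seed):
        rng = np.random.default_rng(seed)
        poles = -np.sort(rng.uniform(0.5, 20, size=3))
        d = rng.normal(size=3)
        sol = make_solution(list(poles), list(d))
        assert_pole_sets_close(core.relocate_poles(sol),
                               denominator_zeros_bruteforce(list(poles), list(d)))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_bruteforce_roots_complex_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = complex(-rng.uniform(1, 5), rng.uniform(5, 30))
        dc = complex(rng.normal(), rng.normal())
        poles = [a, np.conj(a), -rng.uniform(0.5, 3)]
        d = [dc, np.conj(dc), rng.normal()]
        sol = make_solution(poles, d)
        assert_pole_sets_close(core.relocate_poles(sol),
                               denominator_zeros_bruteforce(poles, d))

    def test_stability_reflection(self):
        sol = make_solution([-1.0], [-3.0])  # zero at -1 + 3 = +2
        (new,) = core.relocate_poles(sol, enforce_stability=True)
        assert new == pytest.approx(-2.0)

    def test_singular_d0(self):
        sol = make_solution([-1.0], [1.0], d0=1e-30)
        with pytest.raises(core.RelocationError):
            core.relocate_poles(sol)


class TestFit:
    def test_recovers_generator_windkessel(self, seg3_wk, seg3_waveforms):
        fit = t.fit_tdvf(seg3_waveforms, t.TdvfConfig(order=1, rng_seed=1))
        assert fit.converged
        rec = t.pole_residue_to_wk(fit.model)
        assert rec.R1 == pytest.approx(seg3_wk.R1, rel=0.01)
        assert rec.R2 == pytest.approx(seg3_wk.R2, rel=0.01)
        assert rec.C == pytest.approx(seg3_wk.C, rel=0.01)
        assert rec.Pd == pytest.approx(seg3_wk.Pd, rel=0.01)

    def test_true_pole_is_fixed_point(self, seg3_wk, seg3_waveforms):
        a_true = t.wk_to_pole_residue(seg3_wk).poles[0]
        prob = core.assemble_ls(seg3_waveforms, [a_true])
        sol = core.solve_ls(prob)
        (new,) = core.relocate_poles(sol)
        assert abs(new - a_true) / abs(a_true) < 1e-8

    def test_fit_from_true_pole_converges_in_one_step(self, seg3_wk,
                                                      seg3_waveforms):
        a_true = t.wk_to_pole_residue(seg3_wk).poles[0]
        fit = t.fit_tdvf(seg3_waveforms,
                         t.TdvfConfig(order=1, initial_poles=(a_true,)))
        assert fit.converged
        assert fit.iterations_used == 1

    def test_flow_scale_equivariance(self, seg3_waveforms):
        k = 1e6  # e.g. m^3/s -> cm^3/s
        scaled = t.HemoWaveforms(
            pressure=seg3_waveforms.pressure,
            flow=seg3_waveforms.flow.with_values(seg3_waveforms.flow.values * k))
        cfg = t.TdvfConfig(order=1, rng_seed=2)
        f1 = t.fit_tdvf(seg3_waveforms, cfg)
        f2 = t.fit_tdvf(scaled, cfg)
        assert f2.model.poles[0] == pytest.approx(f1.model.poles[0], rel=1e-8)
        assert f2.model.c0 == pytest.approx(f1.model.c0 / k, rel=1e-8)
        assert f2.model.residues[0] == pytest.approx(f1.model.residues[0] / k,
                                                     rel=1e-8)
        assert f2.model.Pd == pytest.approx(f1.model.Pd, rel=1e-6)

    def test_iteration_cap_never_exceeded(self, order8_model):
        spec = t.InflowSpec(co_l_min=0.75, n_cycles=6)
        w = t.synth_waveforms(spec, order8_model)
        # order-1 fit of order-8 data cannot stabilize at a tight tolerance
        fit = t.fit_tdvf(w, t.TdvfConfig(order=1, rng_seed=0,
                                         pole_convergence_tol=1e-15,
                                         max_iterations=100))
        assert not fit.converged
        assert fit.iterations_used == 100
        assert len(fit.pole_history) == 101

    def test_identifiability_random_order2(self):
        # noiseless order-2 data refit at order 2: H recovered to < 1e-3
        # over the excited band
        m = t.PoleResidueModel(c0=2e7, poles=(-3 + 22j, -3 - 22j),
                               residues=(4e8 + 1e8j, 4e8 - 1e8j), Pd=1500.0)
        w = t.synth_waveforms(t.InflowSpec(co_l_min=0.75, n_cycles=12), m)
        fit = t.fit_tdvf(w, t.TdvfConfig(order=2, rng_seed=3))
        assert fit.converged
        for s in freq_grid():
            Ht, Hf = t.eval_H(m, s), t.eval_H(fit.model, s)
            assert abs(Hf - Ht) / abs(Ht) < 1e-3

    def test_truncated_record_same_H(self, seg3_waveforms):
        # a record starting mid-systole (non-zero ICs) must yield the same
        # impedance; only the distal-pressure estimator route changes
        k0 = int(14.1 * PERIOD / seg3_waveforms.dt)
        assert abs(seg3_waveforms.flow.values[k0]) > 0
        trunc = t.HemoWaveforms(
            pressure=t.TimeSeries(0.0, seg3_waveforms.dt,
                                  seg3_waveforms.pressure.values[k0:]),
            flow=t.TimeSeries(0.0, seg3_waveforms.dt,
                              seg3_waveforms.flow.values[k0:]))
        cfg = t.TdvfConfig(order=1, rng_seed=1)
        f_full = t.fit_tdvf(seg3_waveforms, cfg)
        f_trunc = t.fit_tdvf(trunc, cfg)
        assert f_trunc.pd_method_used == "bias"
        for s in freq_grid():
            Hf = t.eval_H(f_full.model, s)
            Ht = t.eval_H(f_trunc.model, s)
            assert abs(Ht - Hf) / abs(Hf) < 5e-3

    def test_pole_estimate_unbiased_across_snr(self, seg3_wk, seg3_waveforms):
        # the median recovered pole stays pinned to the generator value from
        # clean data down to 40 dB SNR (scaled-down noise study)
        from tdvfbc import synthetic_data as sd
        a_true = t.wk_to_pole_residue(seg3_wk).poles[0].real
        for snr in [100.0, 60.0, 40.0]:
            med = np.median([
                t.fit_tdvf(
                    sd.add_noise_waveforms(
                        seg3_waveforms, sd.NoiseSpec(snr_db=snr, rng_seed=r)),
                    t.TdvfConfig(order=1, rng_seed=1)).model.poles[0].real
                for r in range(5)])
            assert med == pytest.approx(a_true, rel=0.01)

    def test_initial_poles_are_conjugate_closed_and_in_band(self):
        poles = core.initial_poles(5, (0.5, 25.0), rng_seed=11)
        assert len(poles) == 5
        blocks = pole_blocks(poles)
        kinds = [k for k, _, _ in blocks]
        assert kinds.count("r") == 1 and kinds.count("c") == 2
        for _, a, _ in blocks:
            a = complex(a)
            assert a.real < 0
            assert abs(a) < 1.2 * 2 * np.pi * 25.0
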