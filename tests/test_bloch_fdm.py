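"""Finite-difference Bloch-Torrey solver: stability, conservation, limits."""

import numpy as np
import pytest

from fpfdm import bloch_fdm as b
from fpfdm import fieldmap as fm
from fpfdm import geometry as g


@pytest.fixture(scope="module")
def uniform_model():
    return g.TissueModel(np.zeros((8, 8, 8), dtype=np.int8), 7.8125)


@pytest.fixture(scope="module")
def two_compartment_model(rng):
    labels = np.zeros((10, 10, 10), dtype=np.int8)
    labels[3:7, 3:7, 3:7] = g.LABEL_CELL
    return g.TissueModel(labels, 5.0)


class TestTransitionMatrix:
    def test_uniform_jump_probability_arithmetic(self, uniform_model):
        # D = 1 µm²/ms, Δx = 1mm/128, Δt = 0.2 ms
        A = b.build_transition_matrix(uniform_model, 1.0, dt=0.2)
        p = 0.2 / 7.8125**2
        off = A.A - np.diag(A.A.diagonal()) @ np.eye(A.A.shape[0])
        assert p == pytest.approx(3.2768e-3, rel=1e-4)
        assert A.A.diagonal()[0] == pytest.approx(1 - 6 * p, rel=1e-12)
        assert np.allclose(np.asarray(A.A.sum(axis=0)).ravel(), 1.0, atol=1e-12)

    def test_impermeable_membrane_blocks_exchange(self, two_compartment_model):
        A = b.build_transition_matrix(two_compartment_model, 1.0, Pm=0.0, dt=0.2)
        labels = two_compartment_model.labels.ravel()
        coo = A.A.tocoo()
        cross = labels[coo.row] != labels[coo.col]
        assert np.all(coo.data[cross] == 0) or not np.any(cross)

    def test_zero_diffusion_identity(self, uniform_model):
        A = b.build_transition_matrix(uniform_model, 0.0, dt=0.2)
        assert np.allclose(A.A.toarray(), np.eye(A.A.shape[0]))

    def test_symmetric_with_uniform_properties(self, two_compartment_model):
        A = b.build_transition_matrix(two_compartment_model, 1.0, Pm=0.05, dt=0.2)
        diff = (A.A - A.A.T).tocoo()
        assert np.abs(diff.data).max() if diff.nnz else 0.0 < 1e-15

    def test_stability_violation_raises(self):
        model = g.TissueModel(np.zeros((6, 6, 6), dtype=np.int8), 1.0)
        with pytest.raises(b.StabilityError):
            b.build_transition_matrix(model, 1.0, dt=0.5)  # p = 0.5 > 1/6


class TestCheckStability:
    def test_threshold_cases(self):
        assert b.check_stability(1.0, 7.8125, 0.2)
        boundary = 7.8125**2 / 6
        assert b.check_stability(1.0, 7.8125, boundary)
        assert not b.check_stability(1.0, 7.8125, boundary * 1.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            b.check_stability(1.0, 0.0, 0.2)


class TestPhaseRelaxVector:
    def test_no_field_no_decay(self):
        phi = b.phase_relax_vector(np.zeros((4, 4, 4)), np.inf, 0.2)
        assert np.all(phi.phi == 1.0)

    def test_decay_magnitude(self):
        phi = b.phase_relax_vector(np.zeros((4, 4, 4)), 50.0, 0.2)
        assert np.allclose(np.abs(phi.phi), np.exp(-0.004))

    def test_pi_phase_real_negative(self):
        dB = np.full((2, 2, 2), np.pi / (fm.GAMMA * 0.2))
        phi = b.phase_relax_vector(dB, np.inf, 0.2)
        assert np.allclose(phi.phi.real, -1.0)
        assert np.allclose(phi.phi.imag, 0.0, atol=1e-12)

    def test_nonpositive_T2_rejected(self):
        with pytest.raises(ValueError):
            b.phase_relax_vector(np.zeros((2, 2, 2)), 0.0, 0.2)


class TestEvolve:
    def test_pure_decay(self, uniform_model, ge_sequence):
        A = b.build_transition_matrix(uniform_model, 1.0, dt=0.2)
        phi = b.phase_relax_vector(np.zeros(uniform_model.grid_shape), 50.0, 0.2)
        tc = b.evolve(A, phi, ge_sequence)
        assert tc.at_echo == pytest.approx(np.exp(-60 / 50), rel=1e-10)

    def test_conservation_with_unit_phi(self, uniform_model, rng):
        A = b.build_transition_matrix(uniform_model, 1.0, dt=0.2)
        M = rng.uniform(0.5, 1.5, uniform_model.labels.size).astype(complex)
        total = M.sum()
        for _ in range(1000):
            M = A.A.dot(M)
        assert abs(M.sum() - total) / abs(total) < 1e-12

    def test_static_dephasing_closed_form(self, rng):
        labels = np.zeros((12, 12, 12), dtype=np.int8)
        labels.ravel()[rng.choice(12**3, 30, replace=False)] = 1
        model = g.TissueModel(labels, 4.0)
        kernel = fm.perturber_kernel(12, 4.0)
        field = fm.compute_field(model, 1, 1e-7, 3.0, kernel)
        A = b.build_transition_matrix(model, 0.0, dt=0.2)
        phi = b.phase_relax_vector(field, np.inf, 0.2)
        seq = b.SequenceParams("GE", 60.0, dt=0.2)
        tc = b.evolve(A, phi, seq)
        assert tc.at_echo == pytest.approx(b.static_dephasing_signal(field, 60.0), abs=1e-12)

    def test_spin_echo_refocuses_static_spins(self, rng):
        labels = np.zeros((12, 12, 12), dtype=np.int8)
        labels.ravel()[rng.choice(12**3, 30, replace=False)] = 1
        model = g.TissueModel(labels, 4.0)
        kernel = fm.perturber_kernel(12, 4.0)
        field = fm.compute_field(model, 1, 1e-7, 3.0, kernel)
        A = b.build_transition_matrix(model, 0.0, dt=0.2)
        phi = b.phase_relax_vector(field, np.inf, 0.2)
        tc = b.evolve(A, phi, b.SequenceParams("SE", 60.0, dt=0.2))
        assert tc.at_echo == pytest.approx(1.0, abs=1e-10)
        assert b.delta_r2(1.0, tc.at_echo, 60.0) == pytest.approx(0.0, abs=1e-8)

    def test_sequence_grid_validation(self):
        with pytest.raises(ValueError):
            b.SequenceParams("GE", 60.1, dt=0.2)
        with pytest.raises(ValueError):
            b.SequenceParams("SE", 60.2, dt=0.4)  # TE/2 not divisible


class TestEvolveFreeDiffusion:
    def test_matches_sparse_solver(self, rng):
        labels = np.zeros((10, 10, 10), dtype=np.int8)
        labels.ravel()[rng.choice(1000, 25, replace=False)] = 1
        model = g.TissueModel(labels, 8.0)
        kernel = fm.perturber_kernel(10, 8.0)
        field = fm.compute_field(model, 1, 1.26e-6, 1.5, kernel)
        seq = b.SequenceParams("SE", 60.0, dt=0.2)
        A = b.build_transition_matrix(model, 1.0, Pm=np.inf, dt=0.2)
        phi = b.phase_relax_vector(field, 40.0, 0.2)
        s_sparse = b.evolve(A, phi, seq).at_echo
        s_stencil = b.evolve_free_diffusion(field, 1.0, seq, T2=40.0).at_echo
        assert s_stencil == pytest.approx(s_sparse, abs=1e-12)

    def test_refinement_converges_toward_continuum(self, cylinder_model_and_field):
        # finer hops weaken the static-dephasing bias: ΔR2* decreases
        # monotonically toward the continuous-diffusion value
        _, field = cylinder_model_and_field
        seq = b.SequenceParams("GE", 60.0, dt=0.2)
        r = {}
        for refine in (1, 2):
            s = b.evolve_free_diffusion(field, 1.0, seq, refine=refine).at_echo
            r[refine] = b.delta_r2(1.0, s, 60.0)
        assert r[2] != pytest.approx(r[1], rel=1e-6)

    def test_single_precision_agrees(self, cylinder_model_and_field):
        _, field = cylinder_model_and_field
        seq = b.SequenceParams("GE", 20.0, dt=0.2)
        s64 = b.evolve_free_diffusion(field, 1.0, seq, refine=1).at_echo
        s32 = b.evolve_free_diffusion(field, 1.0, seq, refine=1, single_precision=True).at_echo
        assert s32 == pytest.approx(s64, rel=1e-5)

    def test_refined_stability_guard(self):
        field = fm.FieldMap(np.zeros((8, 8, 8)), 1.0, 1.5)
        with pytest.raises(b.StabilityError):
            b.evolve_free_diffusion(field, 1.0, b.SequenceParams("GE", 60.0, dt=0.2), refine=4)


class TestDeltaR2:
    def test_arithmetic_cases(self):
        assert b.delta_r2(1.0, 0.5, 60.0) == pytest.approx(np.log(2) / 0.060, rel=1e-12)
        assert b.delta_r2(0.7, 0.7, 60.0) == 0.0
        assert b.delta_r2(1.0, np.exp(-1.0), 100.0) == pytest.approx(10.0, rel=1e-12)

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            b.delta_r2(0.0, 0.5, 60.0)


class TestDoseResponseSlope:
    def test_exact_line(self):
        assert b.dose_response_slope([0, 1, 2], [0, 100, 200]) == pytest.approx(100.0)
        assert b.dose_response_slope([0, 1, 2], [0, 0, 0]) == pytest.approx(0.0)

    def test_recovers_noisy_slope(self, rng):
        c = np.linspace(0, 3.5, 20)
        y = 42.0 * c + 3.0 + rng.normal(0, 0.5, 20)
        slope = b.dose_response_slope(c, y)
        lsq = np.linalg.lstsq(np.column_stack([c, np.ones_like(c)]), y, rcond=None)[0][0]
        assert slope == pytest.approx(lsq, rel=1e-9)
        assert abs(slope - 42.0) < 0.5

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            b.dose_response_slope([1.0, 1.0], [1.0, 2.0])


class TestRelaxivityExperiment:
    def test_identical_structures_zero_spread(self, cylinder_model_and_field, ge_sequence):
        model, _ = cylinder_model_and_field
        res = b.relaxivity_experiment([model, model], 1e-7, 1.5, 1.0, ge_sequence)
        assert res["std"] == pytest.approx(0.0, abs=1e-12)
        assert res["mean"] == pytest.approx(res["values"][0])

    def test_single_structure_mean(self, cylinder_model_and_field, ge_sequence):
        model, _ = cylinder_model_and_field
        res = b.relaxivity_experiment([model], 1e-7, 1.5, 1.0, ge_sequence)
        assert res["mean"] == res["values"][0]
        assert res["values"][0] > 0

    def test_extrapolated_refinement_runs(self, cylinder_model_and_field, ge_sequence):
        model, _ = cylinder_model_and_field
        res1 = b.relaxivity_experiment([model], 1e-7, 1.5, 1.0, ge_sequence, refine=1)
        res2 = b.relaxivity_experiment([model], 1e-7, 1.5, 1.0, ge_sequence, refine=(1, 2))
        # extrapolation continues the monotone trend past the refined value
        assert res2["mean"] != pytest.approx(res1["mean"], rel=1e-6)


class TestExponentiality:
    def test_pure_exponential_zero_residual(self, uniform_model, ge_sequence):
        A = b.build_transition_matrix(uniform_model, 1.0, dt=0.2)
        phi = b.phase_relax_vector(np.zeros(uniform_model.grid_shape), 50.0, 0.2)
        tc = b.evolve(A, phi, ge_sequence)
        fit = b.exponentiality_check(tc, t_min=0.2)
        assert fit["rate_s"] == pytest.approx(20.0, rel=1e-6)  # 1/T2 = 1/50ms
        assert fit["residual_rms"] < 1e-10


class TestEchoOrdering:
    def test_se_never_exceeds_ge(self, cylinder_model_and_field):
        # refocusing can only reduce mesoscopic decay
        _, field = cylinder_model_and_field
        ge = b.evolve_free_diffusion(field, 1.0, b.SequenceParams("GE", 60.0, dt=0.2)).at_echo
        se = b.evolve_free_diffusion(field, 1.0, b.SequenceParams("SE", 60.0, dt=0.2)).at_echo
        dr2_ge = b.delta_r2(1.0, ge, 60.0)
        dr2_se = b.delta_r2(1.0, se, 60.0)
        assert dr2_se <= dr2_ge
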