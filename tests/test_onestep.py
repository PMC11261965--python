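"""Equilibrium solver: trivial limits, bisection-oracle agreement, conservation."""

import numpy as np
import pytest

from bmpinfer import (
    PAPER_SHAPE,
    CellContext,
    ModelParameters,
    ModelShape,
    ValidationError,
    readout_signal,
    simulate_dataset,
    solve_equilibrium,
)
from bmpinfer.onestep import trimer_oracle_111

from conftest import random_instance


class TestShapesAndParameters:
    def test_paper_scale_has_sixty_parameters(self):
        assert PAPER_SHAPE.n_parameters == 60

    @pytest.mark.parametrize("bad", [dict(nA=0, nB=1, nL=1), dict(nA=1, nB=-1, nL=1)])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValidationError):
            ModelShape(**bad)

    def test_flat_round_trip(self, rng):
        shape = ModelShape(2, 3, 4)
        theta = 10.0 ** rng.uniform(-4, 2, shape.n_parameters)
        params = ModelParameters.from_flat(theta, shape)
        assert np.array_equal(params.to_flat(), theta)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ModelParameters(K=-np.ones((1, 1, 1)), eps=np.ones((1, 1, 1)))

    def test_negative_totals_rejected(self):
        with pytest.raises(ValidationError):
            CellContext(A0=[-1.0], B0=[1.0], L0=[1.0])


class TestSolveEquilibrium:
    def test_no_ligand_means_no_complexes(self, unit_params_111):
        ctx = CellContext(A0=[2.0], B0=[3.0], L0=[0.0])
        state = solve_equilibrium(unit_params_111, ctx)
        assert np.all(state.T == 0)
        assert state.freeA[0] == 2.0 and state.freeB[0] == 3.0

    def test_zero_equilibrium_constant(self, unit_context_111):
        params = ModelParameters(K=np.zeros((1, 1, 1)), eps=np.ones((1, 1, 1)))
        state = solve_equilibrium(params, unit_context_111)
        assert np.all(state.T == 0)

    def test_unit_cube_matches_cubic_root(self, unit_params_111, unit_context_111):
        # T solves T = (1 - T)^3 for K = A0 = B0 = L0 = 1
        state = solve_equilibrium(unit_params_111, unit_context_111)
        T = state.T.ravel()[0]
        assert T == pytest.approx(0.31767, abs=1e-5)
        assert T == pytest.approx((1 - T) ** 3, abs=1e-9)

    def test_deterministic(self, rng):
        params, ctx = random_instance(rng, ModelShape(2, 2, 2))
        s1 = solve_equilibrium(params, ctx)
        s2 = solve_equilibrium(params, ctx)
        assert np.array_equal(s1.T, s2.T)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_111(self, seed):
        rng = np.random.default_rng(seed)
        K = 10.0 ** rng.uniform(-4, 2)
        A0, B0, L0 = 10.0 ** rng.uniform(-2, 2, 3)
        params = ModelParameters(K=np.full((1, 1, 1), K), eps=np.ones((1, 1, 1)))
        state = solve_equilibrium(params, CellContext([A0], [B0], [L0]))
        expected = trimer_oracle_111(K, A0, B0, L0)
        assert state.T.ravel()[0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("shape", [ModelShape(1, 1, 1), ModelShape(2, 2, 2), ModelShape(3, 2, 5)])
    def test_conservation_laws(self, seed, shape):
        rng = np.random.default_rng(seed)
        params, ctx = random_instance(rng, shape)
        state = solve_equilibrium(params, ctx, tol=1e-10)
        assert np.allclose(ctx.A0, state.freeA + state.T.sum(axis=(1, 2)), rtol=0, atol=1e-8 * (1 + ctx.A0.max()))
        assert np.allclose(ctx.L0, state.freeL + state.T.sum(axis=(0, 2)), rtol=0, atol=1e-8 * (1 + ctx.L0.max()))
        assert np.allclose(ctx.B0, state.freeB + state.T.sum(axis=(0, 1)), rtol=0, atol=1e-8 * (1 + ctx.B0.max()))
        # equilibrium condition
        expected_T = params.K * state.freeA[:, None, None] * state.freeL[None, :, None] * state.freeB[None, None, :]
        assert np.allclose(state.T, expected_T, rtol=1e-8, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonicity_in_K(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = ModelShape(2, 2, 2)
        params, ctx = random_instance(rng, shape)
        idx = (rng.integers(2), rng.integers(2), rng.integers(2))
        T_before = solve_equilibrium(params, ctx).T[idx]
        K2 = params.K.copy()
        K2[idx] *= 10.0
        T_after = solve_equilibrium(ModelParameters(K=K2, eps=params.eps), ctx).T[idx]
        assert T_after >= T_before - 1e-12

    def test_saturation_limit(self):
        params = ModelParameters(K=np.full((1, 1, 1), 1e8), eps=np.ones((1, 1, 1)))
        ctx = CellContext([2.0], [1.0], [3.0])
        state = solve_equilibrium(params, ctx)
        assert state.T.ravel()[0] == pytest.approx(1.0, rel=0.01)

    def test_invalid_tolerance(self, unit_params_111, unit_context_111):
        with pytest.raises(ValidationError):
            solve_equilibrium(unit_params_111, unit_context_111, tol=0.0)

    def test_shape_mismatch(self, unit_params_111):
        with pytest.raises(ValidationError):
            solve_equilibrium(unit_params_111, CellContext([1.0, 1.0], [1.0], [1.0]))


class TestReadout:
    def test_zero_efficiency_silences_signal(self, unit_context_111):
        params = ModelParameters(K=np.ones((1, 1, 1)), eps=np.zeros((1, 1, 1)))
        assert solve_equilibrium(params, unit_context_111).signal == 0.0

    def test_unit_efficiency_sums_complexes(self, rng):
        params, ctx = random_instance(rng, ModelShape(2, 2, 2))
        params = ModelParameters(K=params.K, eps=np.ones_like(params.eps))
        state = solve_equilibrium(params, ctx)
        assert state.signal == pytest.approx(state.T.sum(), rel=1e-12)

    def test_scaled_efficiency(self, unit_context_111):
        params = ModelParameters(K=np.ones((1, 1, 1)), eps=np.full((1, 1, 1), 2.0))
        state = solve_equilibrium(params, unit_context_111)
        assert state.signal == pytest.approx(2 * 0.31767, abs=1e-4)

    def test_shape_mismatch_rejected(self, unit_params_111, unit_context_111):
        state = solve_equilibrium(unit_params_111, unit_context_111)
        other = ModelParameters(K=np.ones((2, 1, 1)), eps=np.ones((2, 1, 1)))
        with pytest.raises(ValidationError):
            readout_signal(state, other)


class TestSimulateDataset:
    def test_matches_per_context_calls(self, rng):
        shape = ModelShape(2, 2, 2)
        params, _ = random_instance(rng, shape)
        contexts = [random_instance(rng, shape)[1] for _ in range(3)]
        batch = simulate_dataset(params, contexts)
        loop = np.array([solve_equilibrium(params, c).signal for c in contexts])
        assert np.array_equal(batch, loop)

    def test_duplicated_context_identical_entries(self, unit_params_111, unit_context_111):
        out = simulate_dataset(unit_params_111, [unit_context_111] * 3)
        assert out[0] == out[1] == out[2]

    def test_empty_contexts_rejected(self, unit_params_111):
        with pytest.raises(ValidationError):
            simulate_dataset(unit_params_111, [])
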