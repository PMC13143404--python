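"""Fitting algorithms: schedule, partitions, SGD algebra, oracle limits."""

import numpy as np
import pytest

import gmfact as g
from gmfact.core_model import FitConfig, GMFParams, full_gradients, penalized_objective
from gmfact.errors import GMFConfigError
from gmfact.estimators import (
    SGDState,
    learning_rate,
    minibatch_gradients,
    minibatch_partition,
    sgd_step,
)

from conftest import random_instance


class TestLearningRate:
    def test_initial_step_is_k0(self):
        assert learning_rate(0, 0.3, 0.01, 0.75) == pytest.approx(0.3)

    def test_printed_formula_value(self):
        # k0=1, k1=1, tau=1, t=3 -> 1/(1+3) = 1/4
        assert learning_rate(3, 1.0, 1.0, 1.0) == pytest.approx(0.25)

    def test_monotone_nonincreasing(self):
        rates = [learning_rate(t, 0.05, 0.01, 0.6) for t in range(200)]
        assert all(r2 <= r1 for r1, r2 in zip(rates, rates[1:]))
        assert all(r > 0 for r in rates)

    def test_robbins_monro_guard(self):
        with pytest.raises(GMFConfigError):
            learning_rate(1, 0.1, 0.1, 0.4)
        with pytest.raises(GMFConfigError):
            learning_rate(1, 0.1, 0.1, 1.2)


class TestPartition:
    def test_single_chunk_degenerate(self):
        rows, cols = minibatch_partition(10, 4, 1, 1, seed=0)
        assert sorted(rows[0].tolist()) == list(range(10))

    def test_balanced_sizes(self):
        rows, _ = minibatch_partition(10, 4, 3, 1, seed=1)
        assert sorted(len(r) for r in rows) == [3, 3, 4]
        # exact partition
        assert sorted(np.concatenate(rows).tolist()) == list(range(10))

    def test_deterministic_in_seed(self):
        a = minibatch_partition(20, 8, 4, 2, seed=5)
        b = minibatch_partition(20, 8, 4, 2, seed=5)
        for x, y in zip(a[0] + a[1], b[0] + b[1]):
            assert np.array_equal(x, y)

    def test_invalid_counts_rejected(self):
        with pytest.raises(GMFConfigError):
            minibatch_partition(5, 5, 6, 1, seed=0)


class TestMinibatchGradients:
    def test_full_block_equals_full_gradients(self):
        data, params, fam = random_instance("poisson", seed=1, n=12, m=8, d=2)
        full = full_gradients(data, params, 0.5, fam)
        mb = minibatch_gradients(
            data, params, np.arange(12), np.arange(8), 0.5, fam
        )
        assert np.allclose(mb.G_U, full.G_U, atol=1e-12)
        assert np.allclose(mb.G_V, full.G_V, atol=1e-12)
        assert np.allclose(mb.H_B, full.H_B, atol=1e-12)
        assert np.allclose(mb.G_Gamma, full.G_Gamma, atol=1e-12)

    def test_exhaustive_average_unbiased(self):
        """Averaging the rescaled stochastic gradients over all equal-size
        row chunks of a fixed partition reproduces the full-batch blocks."""
        data, params, fam = random_instance("poisson", seed=2, n=6, m=4, d=2,
                                            masked=False)
        full = full_gradients(data, params, 0.5, fam)
        rows, cols = minibatch_partition(6, 4, 3, 2, seed=3)
        for J in cols:
            GV = np.zeros_like(full.G_V[J])
            HV = np.zeros_like(full.H_V[J])
            GB = np.zeros_like(full.G_B[J])
            for I in rows:
                mb = minibatch_gradients(data, params, I, J, 0.5, fam)
                GV += mb.G_V / len(rows)
                HV += mb.H_V / len(rows)
                GB += mb.G_B / len(rows)
            assert np.allclose(GV, full.G_V[J], atol=1e-10)
            assert np.allclose(HV, full.H_V[J], atol=1e-10)
            assert np.allclose(GB, full.G_B[J], atol=1e-10)
        for I in rows:
            GU = np.zeros_like(full.G_U[I])
            for J in cols:
                GU += minibatch_gradients(data, params, I, J, 0.5, fam).G_U / len(cols)
            assert np.allclose(GU, full.G_U[I], atol=1e-10)

    def test_rescaling_keeps_expectation_fixed(self):
        """Halving chunk sizes doubles the scaling factors; the average over
        the finer partition still reproduces the full-batch gradient."""
        data, params, fam = random_instance("poisson", seed=4, n=6, m=4, d=2,
                                            masked=False)
        full = full_gradients(data, params, 0.0, fam)
        J = np.arange(4)
        for R in (2, 3, 6):
            rows, _ = minibatch_partition(6, 4, R, 1, seed=1)
            GV = sum(
                minibatch_gradients(data, params, I, J, 0.0, fam).G_V
                for I in rows
            ) / R
            assert np.allclose(GV, full.G_V, atol=1e-10)

    def test_empty_block_rejected(self):
        data, params, fam = random_instance("poisson", seed=5)
        with pytest.raises(GMFConfigError):
            minibatch_gradients(data, params, np.array([], int),
                                np.arange(3), 0.0, fam)


class TestSGDStep:
    def _setup(self, seed=0):
        data, params, fam = random_instance("poisson", seed=seed, n=10, m=6,
                                            d=2, masked=False)
        state = SGDState.initialize(data, 2, 2, 2, seed=seed)
        return data, params, fam, state

    def test_first_step_bias_correction_exact(self):
        """t=1, zero accumulators: Gbar = a1*Ghat, Hbar = a2*Hhat and
        alpha_1 = (1 - 0.01)/(1 - 0.1) = 1.1 exactly."""
        data, params, fam, state = self._setup()
        cfg = FitConfig(d=2, smoothing=(0.1, 0.01), schedule=(0.02, 0.01, 0.75))
        I, J = state.row_partition[0], state.col_partition[0]
        grads = minibatch_gradients(data, params, I, J, cfg.penalty, fam)
        before = params.copy()
        state, params = sgd_step(state, grads, params, cfg, I, J)
        assert np.allclose(state.Gbar_U[I], 0.1 * grads.G_U, atol=1e-14)
        assert np.allclose(state.Hbar_U[I], 0.01 * grads.H_U, atol=1e-14)
        alpha_1 = (1 - 0.01) / (1 - 0.1)
        assert alpha_1 == pytest.approx(1.1)
        expect_V = before.V[J] + 0.02 * (
            -alpha_1 * (0.1 * grads.G_V) / np.maximum(0.01 * grads.H_V, 1e-8)
        )
        assert np.allclose(params.V[J], expect_V, atol=1e-12)

    def test_no_smoothing_limit_is_quasi_newton(self):
        data, params, fam, state = self._setup(seed=1)
        cfg = FitConfig(d=2, smoothing=(1.0, 1.0), schedule=(0.05, 0.01, 0.75))
        I, J = state.row_partition[0], state.col_partition[0]
        grads = minibatch_gradients(data, params, I, J, cfg.penalty, fam)
        before = params.copy()
        state, params = sgd_step(state, grads, params, cfg, I, J)
        assert np.allclose(state.Gbar_U[I], grads.G_U)
        expect = before.U[I] + 0.05 * (-grads.G_U / np.maximum(grads.H_U, 1e-8))
        assert np.allclose(params.U[I], expect, atol=1e-12)

    def test_locality_rows_outside_block_bitwise_unchanged(self):
        data, params, fam, state = self._setup(seed=2)
        cfg = FitConfig(d=2)
        I, J = state.row_partition[0], state.col_partition[1]
        before = params.copy()
        grads = minibatch_gradients(data, params, I, J, cfg.penalty, fam)
        state, params = sgd_step(state, grads, params, cfg, I, J)
        out_rows = np.setdiff1d(np.arange(10), I)
        out_cols = np.setdiff1d(np.arange(6), J)
        assert np.array_equal(params.U[out_rows], before.U[out_rows])
        assert np.array_equal(params.Gamma[out_rows], before.Gamma[out_rows])
        assert np.array_equal(params.V[out_cols], before.V[out_cols])
        assert np.array_equal(params.B[out_cols], before.B[out_cols])


@pytest.fixture(scope="module")
def svd_problem():
    """Gaussian identity, lambda=0, no covariates: the model's closed-form
    solution is the truncated SVD."""
    rng = np.random.default_rng(42)
    n, m, d = 60, 30, 3
    Y = rng.standard_normal((n, d)) @ rng.standard_normal((d, m)) \
        + 0.3 * rng.standard_normal((n, m))
    data = g.GMFData(Y, X=np.zeros((n, 0)), Z=np.zeros((m, 0)))
    L, s, Vt = np.linalg.svd(Y, full_matrices=False)
    svd3 = (L[:, :d] * s[:d]) @ Vt[:d]
    rng2 = np.random.default_rng(7)
    init = GMFParams(
        np.zeros((m, 0)), np.zeros((n, 0)),
        0.5 * rng2.standard_normal((n, d)), 0.5 * rng2.standard_normal((m, d)),
    )
    return data, svd3, init


@pytest.mark.parametrize("alg,tol_rel,cfg_extra", [
    ("airwls", 1e-4, dict(max_epochs=300)),
    ("newton", 1e-4, dict(max_epochs=4000, step=0.5)),
    ("sgd", 1e-2, dict(max_epochs=3000, schedule=(0.05, 0.001, 0.75))),
])
def test_fit_reaches_truncated_svd(svd_problem, alg, tol_rel, cfg_extra):
    data, svd3, init = svd_problem
    fam = g.make_family("gaussian")
    cfg = FitConfig(d=3, penalty=0.0, algorithm=alg, tol=1e-13, seed=1,
                    **cfg_extra)
    res = g.fit(data, cfg, fam, init=init.copy())
    rec = res.params.U @ res.params.V.T
    err = np.linalg.norm(rec - svd3) / np.linalg.norm(svd3)
    assert err <= tol_rel


class TestGLMOracle:
    def test_d0_poisson_matches_column_glms(self):
        import statsmodels.api as sm

        data, _ = g.simulate_gmf(50, 8, 0, "poisson", snr=0.0, seed=2)
        data0 = g.GMFData(data.Y, np.ones((50, 1)), np.zeros((8, 0)))
        fam = g.make_family("poisson")
        res = g.fit(data0, FitConfig(d=0, algorithm="newton", max_epochs=500,
                                     tol=1e-12, step=0.5), fam)
        oracle = np.array([
            sm.GLM(data.Y[:, j], np.ones((50, 1)),
                   family=sm.families.Poisson()).fit().params[0]
            for j in range(8)
        ])
        assert np.abs(res.params.B[:, 0] - oracle).max() < 1e-6

    def test_airwls_v_cycle_reproduces_glm_with_fixed_u(self):
        """With U fixed and lambda=0, one V-cycle solves the per-column GLM
        with design [X, U] (compared at the IRLS fixed point)."""
        import statsmodels.api as sm

        data, params, fam = random_instance("poisson", seed=3, n=40, m=6, d=2,
                                            p=1, q=1, masked=False)
        from gmfact._glm import fit_glm_many

        A = np.hstack([data.X, params.U])
        offset = params.Gamma @ data.Z.T
        ours = fit_glm_many(data.Y, A, fam, offset=offset, max_iter=100,
                            tol=1e-12).coef
        for j in range(6):
            ref = sm.GLM(data.Y[:, j], A, family=sm.families.Poisson(),
                         offset=offset[:, j]).fit().params
            assert np.abs(ours[j] - ref).max() < 1e-6


class TestDescentContracts:
    @pytest.mark.parametrize("alg", ["newton", "airwls"])
    def test_objective_monotone_on_accepted_steps(self, alg):
        data, _, fam = random_instance("poisson", seed=9, n=40, m=20, d=2)
        cfg = FitConfig(d=2, algorithm=alg, max_epochs=60, tol=1e-12)
        res = g.fit(data, cfg, fam)
        trace = np.array(res.trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_extra_epoch_changes_little_at_fixed_point(self):
        # penalty 0 so the objective is invariant under the final
        # identifiability projection of the first fit; poisson keeps the
        # dispersion fixed so traces are on one likelihood scale
        data, _, fam = random_instance("poisson", seed=10, n=30, m=15, d=2)
        cfg = FitConfig(d=2, penalty=0.0, algorithm="airwls", max_epochs=200,
                        tol=1e-10)
        res = g.fit(data, cfg, fam)
        assert res.converged
        more = g.fit(data, FitConfig(d=2, penalty=0.0, algorithm="airwls",
                                     max_epochs=1, tol=1e-10),
                     fam, init=res.params.copy())
        rel = abs(more.trace[-1] - res.trace[-1]) / max(1.0, abs(res.trace[-1]))
        assert rel < 1e-6

    def test_divergence_aborts_with_diagnostic(self):
        from gmfact.errors import GMFNumericalError

        data, _, fam = random_instance("poisson", seed=11, n=40, m=20, d=2)
        cfg = FitConfig(d=2, algorithm="sgd", max_epochs=50,
                        schedule=(1.0, 0.001, 0.75))  # wildly large step
        with pytest.raises(GMFNumericalError, match="diverged"):
            g.fit(data, cfg, fam)


class TestAgreementAndRecovery:
    def test_three_fitters_agree_on_small_instances(self):
        """Gaussian and Poisson: the three algorithms minimize the same
        objective, reaching values within 1% of each other."""
        for famname, seed in [("gaussian", 0), ("poisson", 1)]:
            data, _ = g.simulate_gmf(150, 40, 2, famname, snr=0.7, seed=seed)
            fam = g.make_family(famname)
            objs = {}
            for alg, ep, extra in [
                ("airwls", 200, {}),
                ("newton", 800, {}),
                ("sgd", 2000, dict(schedule=(0.05, 0.001, 0.75))),
            ]:
                cfg = FitConfig(d=2, algorithm=alg, max_epochs=ep, tol=1e-9,
                                seed=3, **extra)
                objs[alg] = g.fit(data, cfg, fam).manifest["final_objective"]
            ref = min(objs.values())
            for alg, o in objs.items():
                assert (o - ref) / abs(ref) < 0.01, (famname, objs)

    def test_subspace_recovery_improves_with_n(self):
        """Principal angles between span(U-hat) and span(U-true) shrink as
        the sample grows (fixed m, d)."""
        from scipy.linalg import subspace_angles

        angles = []
        for n in (150, 400, 1000):
            data, truth = g.simulate_gmf(n, 40, 2, "poisson", snr=0.8, seed=12)
            fam = g.make_family("poisson")
            cfg = FitConfig(d=2, algorithm="airwls", max_epochs=80, tol=1e-8)
            res = g.fit(data, cfg, fam)
            angles.append(subspace_angles(res.params.U, truth.U).max())
        assert angles[2] < angles[0]
        assert angles[2] < 0.2


class TestDeterminism:
    @pytest.mark.parametrize("alg", ["sgd", "newton", "airwls"])
    def test_identical_seed_bitwise_identical(self, alg):
        data, _, fam = random_instance("poisson", seed=13, n=30, m=15, d=2)
        cfg = FitConfig(d=2, algorithm=alg, max_epochs=20, seed=4,
                        schedule=(0.02, 0.01, 0.75))
        r1 = g.fit(data, cfg, fam)
        r2 = g.fit(data, cfg, fam)
        for attr in ("B", "Gamma", "U", "V"):
            assert np.array_equal(getattr(r1.params, attr),
                                  getattr(r2.params, attr))
        assert r1.trace == r2.trace
        assert r1.params.phi == r2.params.phi
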