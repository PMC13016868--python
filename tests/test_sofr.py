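"""Basis construction, design assembly, REML fitting, partial effects."""

import numpy as np
import pandas as pd
import pytest

import physofr as pf
from physofr import sofr
from physofr.sofr import DesignMatrices, PenaltyBlock


def toy_functional_problem(n=60, K=8, noise=0.5, seed=3):
    """Single-smooth scalar-on-function problem with a smooth true coefficient.

    A smooth truth keeps the REML optimum in the interior of the
    log-lambda range (a rough truth drives lambda to the unpenalized
    boundary, where optimum comparisons are meaningless).
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, 1, 30)
    basis = sofr.build_basis(grid, K=K)
    X = np.empty((n, K))
    for i in range(n):
        x = np.sin(2 * np.pi * grid * rng.uniform(0.5, 2)) + rng.normal(0, 0.3, 30)
        X[i] = basis.design_rows(x)
    f = 1.5 * np.sin(2 * np.pi * grid) + grid
    beta, *_ = np.linalg.lstsq(basis.B, f, rcond=None)
    y = X @ beta + rng.normal(0, noise, n)
    blocks = [PenaltyBlock("s", slice(0, K), basis.S, K - 2)]
    des = DesignMatrices(y=y, X=X, blocks=blocks,
                         col_names=[f"b{i}" for i in range(K)],
                         block_slices={"s": slice(0, K)}, participants=[],
                         odors=[], contrast=None, basis=basis, spec=None)
    return des, basis


class TestBasis:
    @pytest.mark.parametrize("kind", ["tprs", "bspline"])
    def test_penalty_psd_with_two_dim_null_space(self, kind):
        grid = pf.analysis_grid()
        b = sofr.build_basis(grid, K=10, kind=kind)
        e = np.linalg.eigvalsh(b.S)
        assert e.min() > -1e-10
        assert (e < 1e-8).sum() == 2
        assert np.linalg.matrix_rank(b.B) == 10

    def test_null_space_spans_linear_functions(self):
        grid = pf.analysis_grid()
        b = sofr.build_basis(grid, K=10)
        # a linear coefficient function is representable with zero penalty
        target = 0.3 + 0.2 * grid
        coef, res, *_ = np.linalg.lstsq(b.B, target, rcond=None)
        assert np.abs(b.B @ coef - target).max() < 1e-8
        assert coef @ b.S @ coef < 1e-10

    def test_interpolating_limit_spans_grid_functions(self):
        grid = pf.analysis_grid()
        b = sofr.build_basis(grid, K=len(grid))
        rng = np.random.default_rng(0)
        target = rng.normal(0, 1, len(grid))
        coef, *_ = np.linalg.lstsq(b.B, target, rcond=None)
        assert np.abs(b.B @ coef - target).max() < 1e-6

    def test_k_bounds(self):
        grid = pf.analysis_grid()
        with pytest.raises(ValueError):
            sofr.build_basis(grid, K=31)
        with pytest.raises(ValueError):
            sofr.build_basis(grid, K=2)


class TestDesignRow:
    def test_zero_signal_gives_zero_row(self, basis30):
        assert np.allclose(sofr.functional_design_row(np.zeros(30), basis30), 0.0)

    def test_matches_brute_force_double_loop(self, basis30):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        row = sofr.functional_design_row(x, basis30)
        expect = np.zeros(basis30.K)
        for k in range(basis30.K):
            for t in range(30):
                expect[k] += basis30.w[t] * x[t] * basis30.B[t, k]
        assert np.allclose(row, expect, atol=1e-12)

    def test_constant_signal_integrates_basis(self, basis30):
        row = sofr.functional_design_row(np.ones(30), basis30)
        assert np.allclose(row, (basis30.w[:, None] * basis30.B).sum(axis=0))

    def test_grid_mismatch_rejected(self, basis30):
        with pytest.raises(ValueError):
            sofr.functional_design_row(np.zeros(29), basis30)


class TestAssemble:
    def _small(self, P=2, trials_per=4, K=3):
        design = pf.generate_design(P, seed=2).groupby("participant_id").head(trials_per).reset_index(drop=True)
        truth = pf.simulate_truth(pf.SimulationConfig(n_participants=P), seed=2)
        sig, sc = pf.simulate_model_data(design, truth, seed=2)
        basis = sofr.build_basis(pf.analysis_grid(), K=K)
        return sc, sig, basis

    def test_column_count_matches_hand_formula(self):
        sc, sig, basis = self._small(P=2, trials_per=4, K=3)
        des = sofr.assemble_design(sc, sig, sc["latent_valence"].to_numpy(),
                                   sofr.ModelSpec(), basis)
        P, K, n_odors = 2, 3, sc["odor"].nunique()
        expect = 1 + (n_odors - 1) + 1 + P + 4 * K + 4 * (P - 1) * K
        assert des.X.shape == (8, expect)
        assert len(des.col_names) == expect

    def test_reduced_spec_drops_blocks(self):
        sc, sig, basis = self._small()
        spec = sofr.ModelSpec(indiv_smooths=())
        des = sofr.assemble_design(sc, sig, sc["latent_valence"].to_numpy(), spec, basis)
        assert not any(n.startswith("indiv:") for n in des.block_slices)

    def test_duplicated_trials_give_identical_rows(self):
        sc, sig, basis = self._small()
        sc2 = pd.concat([sc, sc.iloc[:1]], ignore_index=True)
        sig2 = np.concatenate([sig, sig[:1]], axis=0)
        des = sofr.assemble_design(sc2, sig2, np.zeros(len(sc2)), sofr.ModelSpec(), basis)
        assert np.allclose(des.X[0], des.X[-1])

    def test_missing_epochs_rejected(self):
        sc, sig, basis = self._small()
        sig = sig.copy()
        sig[2] = np.nan
        with pytest.raises(ValueError, match="2"):
            sofr.assemble_design(sc, sig, np.zeros(len(sc)), sofr.ModelSpec(), basis)

    def test_individual_smooth_centering(self):
        sc, sig, basis = self._small(P=3, trials_per=6)
        des = sofr.assemble_design(sc, sig, sc["latent_valence"].to_numpy(),
                                   sofr.ModelSpec(), basis)
        # the contrast columns are orthonormal and sum to zero over participants
        C = des.contrast
        assert np.allclose(C.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(C.T @ C, np.eye(C.shape[1]), atol=1e-12)


class TestREML:
    def test_lambda_zero_equals_ols(self):
        des, _ = toy_functional_problem()
        fit = sofr.fit_reml(des, fixed_lambdas={"s": 0.0})
        ols, *_ = np.linalg.lstsq(des.X, des.y, rcond=None)
        assert np.abs(fit.beta - ols).max() < 1e-8

    def test_large_lambda_shrinks_ridge_block_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 6))
        y = rng.normal(0, 1, 50)
        blocks = [PenaltyBlock("r", slice(2, 6), np.eye(4), 4)]
        des = DesignMatrices(y=y, X=X, blocks=blocks, col_names=list("abcdef"),
                             block_slices={"fixed": slice(0, 2), "r": slice(2, 6)},
                             participants=[], odors=[], contrast=None,
                             basis=None, spec=None)
        fit = sofr.fit_reml(des, fixed_lambdas={"r": 1e12})
        assert np.abs(fit.beta[2:]).max() < 1e-6
        assert fit.edf_by_block["r"] < 1e-4

    def test_optimum_matches_dense_grid_search(self):
        des, _ = toy_functional_problem()
        fit = sofr.fit_reml(des)
        rho = np.linspace(-12, 12, 400)
        vals = [sofr.reml_criterion(des.y, des.X, des.blocks,
                                    {"s": float(np.exp(r))})[0] for r in rho]
        best = rho[int(np.argmin(vals))]
        step = rho[1] - rho[0]
        assert abs(np.log(fit.lambdas["s"]) - best) <= step

    def test_grid_method_agrees_with_quasinewton(self):
        des, _ = toy_functional_problem(seed=7)
        qn = sofr.fit_reml(des)
        gr = sofr.fit_reml(des, method="grid", grid=np.linspace(-12, 12, 200))
        assert abs(np.log(qn.lambdas["s"]) - np.log(gr.lambdas["s"])) < 0.3

    def test_reml_path_monotone_within_accepted_steps(self):
        des, _ = toy_functional_problem(seed=9)
        fit = sofr.fit_reml(des, lambda_starts=(1.0,))
        # the optimizer's accepted iterates never increase the criterion:
        # the final criterion value is the minimum of everything evaluated
        assert fit.reml <= min(fit.reml_path) + 1e-9

    def test_edf_bounds(self):
        des, _ = toy_functional_problem()
        fit = sofr.fit_reml(des)
        assert 0 < fit.edf_by_block["s"] <= 8
        assert fit.edf_total < len(des.y)

    def test_augmented_least_squares_equivalence(self):
        des, basis = toy_functional_problem(seed=11)
        fit = sofr.fit_reml(des)
        lam = fit.lambdas["s"]
        # stack sqrt(lambda) * matrix square root of S as pseudo-observations
        e, V = np.linalg.eigh(basis.S)
        keep = e > 1e-12
        root = (V[:, keep] * np.sqrt(e[keep])).T
        Xa = np.vstack([des.X, np.sqrt(lam) * root])
        ya = np.concatenate([des.y, np.zeros(root.shape[0])])
        beta_aug, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
        assert np.abs(fit.beta - beta_aug).max() < 1e-8

    def test_residual_orthogonal_to_unpenalized_columns(self):
        sc = pf.generate_design(2, seed=3).groupby("participant_id").head(20).reset_index(drop=True)
        truth = pf.simulate_truth(pf.SimulationConfig(n_participants=2), seed=3)
        sig, scores = pf.simulate_model_data(sc, truth, seed=3)
        basis = sofr.build_basis(pf.analysis_grid(), K=4)
        des = sofr.assemble_design(scores, sig, scores["latent_valence"].to_numpy(),
                                   sofr.ModelSpec(indiv_smooths=()), basis)
        fit = sofr.fit_reml(des)
        resid = des.y - fit.fitted
        scale = len(des.y)
        for name in ("intercept", "odor", "half"):
            sl = des.block_slices[name]
            assert np.abs(des.X[:, sl].T @ resid).max() / scale < 1e-6


class TestPartialEffect:
    def test_zero_truth_block_flat_with_symmetric_ci(self):
        des, basis = toy_functional_problem(noise=0.1, seed=13)
        fit = sofr.fit_reml(des)
        fit.beta[:] = 0.0
        pe = sofr.partial_effect(fit, "s")
        assert np.allclose(pe.estimate, 0.0)
        assert np.allclose(pe.hi + pe.lo, 0.0, atol=1e-12)

    def test_group_plus_deviation_reconstruction(self):
        P = 3
        design = pf.generate_design(P, seed=4).groupby("participant_id").head(24).reset_index(drop=True)
        truth = pf.simulate_truth(pf.SimulationConfig(n_participants=P), seed=4)
        sig, sc = pf.simulate_model_data(design, truth, seed=4)
        basis = sofr.build_basis(pf.analysis_grid(), K=5)
        des = sofr.assemble_design(sc, sig, sc["latent_valence"].to_numpy(),
                                   sofr.ModelSpec(), basis)
        fit = sofr.fit_reml(des)
        pid = des.participants[1]
        g = sofr.partial_effect(fit, "group:respiration")
        d = sofr.partial_effect(fit, "indiv:respiration", level=pid)
        gd = sofr.partial_effect(fit, "indiv:respiration", level=pid, include_group=True)
        assert np.allclose(gd.estimate, g.estimate + d.estimate, atol=1e-10)
        # deviations sum to zero over participants at every time point
        total = sum(sofr.partial_effect(fit, "indiv:respiration", level=p).estimate
                    for p in des.participants)
        assert np.abs(total).max() < 1e-8

    def test_unknown_term_rejected(self):
        des, _ = toy_functional_problem()
        fit = sofr.fit_reml(des)
        with pytest.raises(ValueError):
            sofr.partial_effect(fit, "group:eda")
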