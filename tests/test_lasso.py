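"""Solver correctness: oracle equivalence, KKT conditions, penalty mechanics."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from burdenlasso import CollapseConfig, PenaltySpec, build_design, fit_lasso
from burdenlasso.collapse import CollapsedDesign, PENALIZED, UNPENALIZED
from burdenlasso.errors import ConfigurationError
from burdenlasso.lasso import (
    cv_lasso,
    fit_all_replicates,
    fit_differential,
    kkt_max_violation,
    lambda_grid,
    lambda_max,
    objective_value,
)


def plain_design(X, penalty_classes=None, names=None):
    """Wrap a raw matrix as a CollapsedDesign with given penalty classes."""
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if penalty_classes is None:
        penalty_classes = [PENALIZED] * p
    cols = pd.DataFrame(
        {
            "feature": names,
            "kind": ["covariate" if c == UNPENALIZED else "common_variant" for c in penalty_classes],
            "gene": [""] * p,
            "annotation": [""] * p,
            "penalty_class": penalty_classes,
        }
    )
    return CollapsedDesign(values=np.asarray(X, float), columns=cols,
                           individual_ids=[f"i{k}" for k in range(n)])


from oracles import l1_oracle_objective, random_l1_instance


@pytest.mark.parametrize("link,n_instances,p", [("identity", 15, 5), ("logit", 10, 4)])
def test_solver_matches_sign_enumeration_oracle(link, n_instances, p):
    """fit_lasso's objective equals the exhaustive-enumeration optimum within
    1e-6, with KKT conditions satisfied, on random mixed-penalty instances."""
    rng = np.random.default_rng(2024)
    for k in range(n_instances):
        X, y, lam, factors = random_l1_instance(rng, p=p, link=link)
        classes = [UNPENALIZED if f == 0 else PENALIZED for f in factors]
        names = [f"x{j}" for j in range(p)]
        design = plain_design(X, classes, names)
        spec = PenaltySpec(
            lambda_common=lam,
            per_feature_factor={nm: f for nm, f in zip(names, factors) if f > 0},
        )
        # intercept is an explicit free coordinate in the oracle
        Xa = np.hstack([X, np.ones((len(y), 1))])
        lam_vec = np.append(spec.effective_lambdas(design), 0.0)
        fit = fit_lasso(design, y, link, spec, standardize=False, tol=1e-12)
        obj = objective_value(design, y, fit)
        oracle = l1_oracle_objective(Xa, y, lam_vec, link)
        assert obj == pytest.approx(oracle, abs=1e-6), f"instance {k}"
        assert kkt_max_violation(design, y, fit) < 1e-6


class TestPenaltyLimits:
    def _design_y(self, seed=0, n=80, p=6, n_unpen=2):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        classes = [UNPENALIZED] * n_unpen + [PENALIZED] * (p - n_unpen)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        return plain_design(X, classes), y

    def test_huge_lambda_zeroes_all_penalized(self):
        design, y = self._design_y()
        fit = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=1e6))
        pen = design.penalty_classes() == PENALIZED
        assert (fit.coefficients.to_numpy()[pen] == 0.0).all()
        # covariates stay in the model and the intercept absorbs the rest
        resid = y - design.values[:, ~pen] @ fit.coefficients.to_numpy()[~pen]
        assert fit.intercept == pytest.approx(resid.mean(), abs=1e-6)

    def test_zero_lambda_identity_equals_ols(self):
        design, y = self._design_y()
        fit = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=0.0), tol=1e-12)
        Xa = np.hstack([design.values, np.ones((len(y), 1))])
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta[:-1], atol=1e-7)
        assert fit.intercept == pytest.approx(beta[-1], abs=1e-7)

    def test_lambda_max_gives_all_zero_solution(self):
        design, y = self._design_y(seed=5)
        lmax = lambda_max(design, y)
        fit = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=lmax * 1.0001))
        pen = design.penalty_classes() == PENALIZED
        assert (fit.coefficients.to_numpy()[pen] == 0.0).all()
        fit2 = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=lmax * 0.9))
        assert (fit2.coefficients.to_numpy()[pen] != 0.0).any()

    def test_per_feature_factor_equals_column_rescaling(self):
        """Penalizing feature j with factor f_j is the same optimization as
        rescaling column j by 1/f_j under a uniform penalty."""
        rng = np.random.default_rng(3)
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        factors = np.array([0.5, 1.0, 2.0, 1.5, 0.8])
        lam = 0.2
        names = [f"x{j}" for j in range(p)]
        d1 = plain_design(X, names=names)
        fit1 = fit_lasso(
            d1, y, penalties=PenaltySpec(lambda_common=lam,
                                         per_feature_factor=dict(zip(names, factors))),
            standardize=False, tol=1e-12,
        )
        d2 = plain_design(X / factors, names=names)
        fit2 = fit_lasso(d2, y, penalties=PenaltySpec(lambda_common=lam),
                         standardize=False, tol=1e-12)
        # beta1_j = beta2_j / f_j
        np.testing.assert_allclose(
            fit1.coefficients.to_numpy(),
            fit2.coefficients.to_numpy() / factors,
            atol=1e-6,
        )

    def test_selection_monotone_along_lambda_path(self):
        design, y = self._design_y(seed=9, n=100, p=8, n_unpen=1)
        lmax = lambda_max(design, y)
        sizes = []
        for lam in lambda_grid(lmax, n_lambda=25):
            fit = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=float(lam)))
            sizes.append(int(fit.selected[design.penalty_classes() == PENALIZED].sum()))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_input_errors(self):
        design, y = self._design_y()
        with pytest.raises(ConfigurationError):
            fit_lasso(design, np.r_[y[:-1], np.nan])
        with pytest.raises(ConfigurationError):
            fit_lasso(design, y, link="logit")  # non-binary outcome
        with pytest.raises(ConfigurationError):
            PenaltySpec(lambda_common=-1.0)


def test_logit_toy_matches_dense_grid_search():
    """On a sign-symmetric two-feature toy, the logit-link fit attains the
    penalized-likelihood optimum located by dense grid search over the two
    coefficients (intercept 0 by symmetry) within 1e-3."""
    rng = np.random.default_rng(12)
    n = 30
    X0 = rng.normal(size=(n, 2))
    eta = X0 @ np.array([1.0, -0.5])
    y0 = (rng.random(n) < expit(eta)).astype(float)
    X = np.vstack([X0, -X0])
    y = np.concatenate([y0, 1 - y0])
    lam = 0.05
    design = plain_design(X)
    fit = fit_lasso(design, y, link="logit",
                    penalties=PenaltySpec(lambda_common=lam),
                    standardize=False, tol=1e-12)
    assert abs(fit.intercept) < 1e-6
    b1 = np.arange(-1.5, 1.5, 0.005)
    B = np.array(np.meshgrid(b1, b1)).reshape(2, -1)
    E = X @ B
    nll = (np.logaddexp(0, E) - y[:, None] * E).mean(axis=0)
    obj = nll + lam * np.abs(B).sum(axis=0)
    grid_min = obj.min()
    fit_obj = objective_value(design, y, fit)
    assert fit_obj <= grid_min + 1e-3
    k = int(np.argmin(obj))
    np.testing.assert_allclose(fit.coefficients.to_numpy(), B[:, k], atol=0.01)


class TestDifferential:
    def _split_setup(self, seed=0, n=120, causal_ns=True):
        rng = np.random.default_rng(seed)
        dosage_cols, genes, annos = [], [], []
        from burdenlasso.types import NONSYNONYMOUS, SYNONYMOUS

        for gi in range(6):
            for k in range(3):
                dosage_cols.append(rng.binomial(2, 0.03, n))
                genes.append(f"g{gi}")
                annos.append(NONSYNONYMOUS if k < 2 else SYNONYMOUS)
        from conftest import make_genotypes

        g = make_genotypes(np.column_stack(dosage_cols), genes, annos)
        cov = pd.DataFrame(
            {"Age": rng.normal(50, 10, n), "Smoke": rng.integers(0, 2, n)},
            index=g.individual_ids,
        )
        design = build_design(
            g, cov, CollapseConfig(method="PROP", split_by_annotation=True)
        )
        ns_cols = design.columns["penalty_class"] == "penalized_ns"
        signal = design.values[:, ns_cols.to_numpy()] @ rng.uniform(1, 2, ns_cols.sum())
        y = (signal if causal_ns else rng.normal(size=n) * 0) + rng.normal(size=n)
        return design, y

    def test_degenerate_grids_equal_single_penalty(self):
        design, y = self._split_setup()
        lam = 0.1
        diff = fit_differential(
            design, y, lambda_grid_ns=np.array([lam]), lambda_grid_s=np.array([lam]),
            k_folds=3, seed=1,
        )
        single = fit_lasso(
            design, y,
            penalties=PenaltySpec(lambda_common=lam, lambda_ns=lam, lambda_s=lam),
        )
        np.testing.assert_allclose(
            diff.coefficients.to_numpy(), single.coefficients.to_numpy(), atol=1e-10
        )

    def test_huge_lambda_s_zeroes_synonymous(self):
        design, y = self._split_setup()
        fit = fit_differential(
            design, y,
            lambda_grid_ns=lambda_grid(lambda_max(design, y), 5),
            lambda_grid_s=np.array([1e6]),
            k_folds=3, seed=2,
        )
        s_cols = (design.columns["penalty_class"] == "penalized_s").to_numpy()
        assert (fit.coefficients.to_numpy()[s_cols] == 0.0).all()

    def test_cv_prefers_heavier_synonymous_shrinkage(self):
        """With all causal variants nonsynonymous, the CV-selected lambda_s is
        >= lambda_ns in a majority of seeded replicates."""
        wins = 0
        runs = 20
        for s in range(runs):
            design, y = self._split_setup(seed=100 + s)
            fit = fit_differential(design, y, n_grid=6, k_folds=3, seed=s)
            if fit.chosen_penalties.lambda_s >= fit.chosen_penalties.lambda_ns:
                wins += 1
        assert wins > runs / 2

    def test_requires_split_design(self):
        rng = np.random.default_rng(0)
        design = plain_design(rng.normal(size=(30, 3)))
        with pytest.raises(ConfigurationError):
            fit_differential(design, rng.normal(size=30), k_folds=2)


class TestFitAllReplicates:
    def test_single_replicate_equals_direct_fit(self, small_study):
        g, reps, _ = small_study
        config = CollapseConfig(method="PROP")
        fits = fit_all_replicates(g, reps, "Q1", config, seed=3, replicates=[0])
        design = build_design(g, reps.covariates, config)
        y = reps.trait_replicate("Q1", 0)
        direct = cv_lasso(design, y, seed=int((3 + 0) % (2**31 - 1)))
        np.testing.assert_allclose(
            fits[0].coefficients.to_numpy(), direct.coefficients.to_numpy()
        )

    def test_determinism(self, small_study):
        g, reps, _ = small_study
        config = CollapseConfig(method="DAS")
        f1 = fit_all_replicates(g, reps, "Q2", config, seed=5, replicates=[0, 1])
        f2 = fit_all_replicates(g, reps, "Q2", config, seed=5, replicates=[0, 1])
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(
                a.selected.to_numpy(), b.selected.to_numpy()
            )
            np.testing.assert_allclose(
                a.coefficients.to_numpy(), b.coefficients.to_numpy()
            )

    def test_noise_trait_selects_fewer_than_causal(self, small_study):
        """Median number of selected genetic features for a pure-noise trait
        (Q4 analog) does not exceed that for a genetically driven trait."""
        g, reps, _ = small_study
        config = CollapseConfig(method="PROP")
        fits_noise = fit_all_replicates(g, reps, "Q4", config, seed=7)
        fits_causal = fit_all_replicates(g, reps, "Q2", config, seed=7)
        genetic = (fits_noise[0].design_columns["kind"] != "covariate").to_numpy()

        def median_selected(fits):
            return np.median([f.selected.to_numpy()[genetic].sum() for f in fits])

        assert median_selected(fits_noise) <= median_selected(fits_causal)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_identity_fit_matches_glmnet():
    """Independent cross-check: coefficients at a fixed lambda agree with R
    glmnet on the same standardized-objective formulation."""
    rng = np.random.default_rng(21)
    n, p = 100, 8
    X = rng.normal(size=(n, p))
    y = X @ (rng.normal(size=p) * (rng.random(p) < 0.5)) + rng.normal(size=n)
    lam = 0.15
    design = plain_design(X)
    fit = fit_lasso(design, y, penalties=PenaltySpec(lambda_common=lam),
                    standardize=True, tol=1e-12)
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        np.savetxt(td / "X.csv", X, delimiter=",")
        np.savetxt(td / "y.csv", y, delimiter=",")
        script = td / "fit.R"
        script.write_text(
            'suppressMessages(library(glmnet))\n'
            f'X <- as.matrix(read.csv("{td}/X.csv", header=FALSE))\n'
            f'y <- scan("{td}/y.csv", quiet=TRUE)\n'
            f'f <- glmnet(X, y, lambda={lam}, standardize=TRUE, thresh=1e-14)\n'
            'cat(as.numeric(coef(f)), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
    assert fit.intercept == pytest.approx(ref[0], abs=1e-4)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), ref[1:], atol=1e-4)
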