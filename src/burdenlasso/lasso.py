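"""L1-penalized multimarker regression with per-feature penalty factors.

The model regresses a trait on covariates, individual common-variant dosages
and collapsed gene scores:

    g(mu_i) = beta_0 + E_i' beta_E + sum_v beta_v CV_iv + sum_l beta_l S_il

with an identity link for quantitative traits and a logit link for disease.
Estimation minimizes

    (1/n) * NLL(beta) + sum_j lambda_j |beta_j|

by cyclical coordinate descent with soft-thresholding (inactive coefficients
are exact zeros).  Covariates are never penalized (lambda_j = 0).  The
per-feature penalty lambda_j is a class-level penalty — a single lambda, or
separate lambda_ns / lambda_s for nonsynonymous vs. synonymous collapsed
terms — times an optional per-feature factor.

The differential-penalty fit tunes (lambda_ns, lambda_s) over a 2-D grid by
within-replicate k-fold cross-validation, letting the two annotation classes
be shrunk to different extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import KFold

from .collapse import (
    DAS,
    PENALIZED,
    PENALIZED_NS,
    PENALIZED_S,
    UNPENALIZED,
    WS,
    CollapseConfig,
    CollapsedDesign,
    build_design,
)
from .errors import ConfigurationError, PipelineError
from .types import DISEASE_TRAIT, GenotypeSet, ReplicateSet

IDENTITY = "identity"
LOGIT = "logit"

_MAX_ETA = 30.0
_MIN_WEIGHT = 1e-5


@dataclass(frozen=True)
class PenaltySpec:
    """Class-level L1 penalties plus optional per-feature multipliers.

    ``lambda_common`` applies to every penalized feature without its own
    class penalty; ``lambda_ns`` / ``lambda_s`` override it for collapsed
    nonsynonymous / synonymous terms.  Covariates always get factor 0.
    """

    lambda_common: float = 0.0
    lambda_ns: float | None = None
    lambda_s: float | None = None
    per_feature_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lam in (self.lambda_common, self.lambda_ns, self.lambda_s):
            if lam is not None and lam < 0:
                raise ConfigurationError("penalties must be non-negative")
        for f in self.per_feature_factor.values():
            if f < 0:
                raise ConfigurationError("penalty factors must be non-negative")

    def effective_lambdas(self, design: CollapsedDesign) -> np.ndarray:
        """Per-feature effective penalty lambda_eff(j)."""
        lams = np.empty(design.n_features)
        classes = design.penalty_classes()
        for j, (cls, name) in enumerate(zip(classes, design.feature_names)):
            if cls == UNPENALIZED:
                lams[j] = 0.0
                continue
            if cls == PENALIZED_NS and self.lambda_ns is not None:
                base = self.lambda_ns
            elif cls == PENALIZED_S and self.lambda_s is not None:
                base = self.lambda_s
            else:
                base = self.lambda_common
            lams[j] = base * self.per_feature_factor.get(name, 1.0)
        return lams


@dataclass
class FitResult:
    """A fitted penalized regression for one phenotype replicate."""

    coefficients: pd.Series
    intercept: float
    selected: pd.Series
    link: str
    chosen_penalties: PenaltySpec
    cv_error: float | None
    linear_predictor: np.ndarray
    design_columns: pd.DataFrame
    n_iter: int = 0
    converged: bool = True
    effective_lambda: np.ndarray | None = None  # on the original feature scale

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        """Linear predictor (identity) or probability (logit)."""
        lp = (
            self.linear_predictor
            if X is None
            else self.intercept + X @ self.coefficients.to_numpy()
        )
        return expit(lp) if self.link == LOGIT else lp

    def selected_features(self) -> list[str]:
        return list(self.selected.index[self.selected])


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _sweep_py(G, c, lam, beta, s, diag, solvable, idx):
    delta = 0.0
    for j in idx:
        if not solvable[j]:
            continue
        bj = beta[j]
        rj = c[j] - s[j] + diag[j] * bj
        new = _soft(rj, lam[j]) / diag[j]
        if new != bj:
            step = new - bj
            np.add(s, G[:, j] * step, out=s)
            beta[j] = new
            delta = max(delta, abs(step))
    return delta


try:  # hot loop compiled when numba is present; pure numpy otherwise
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _sweep_jit(G, c, lam, beta, s, diag, solvable, idx):  # pragma: no cover
        delta = 0.0
        p = G.shape[0]
        for k in range(idx.shape[0]):
            j = idx[k]
            if not solvable[j]:
                continue
            bj = beta[j]
            rj = c[j] - s[j] + diag[j] * bj
            t = lam[j]
            if rj > t:
                new = (rj - t) / diag[j]
            elif rj < -t:
                new = (rj + t) / diag[j]
            else:
                new = 0.0
            if new != bj:
                step = new - bj
                for i in range(p):
                    s[i] += G[i, j] * step
                beta[j] = new
                if abs(step) > delta:
                    delta = abs(step)
        return delta

    _sweep = _sweep_jit
except ImportError:  # pragma: no cover
    _sweep = _sweep_py


def _cd_gram(
    G: np.ndarray,
    c: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Coordinate descent on  (1/2) b'Gb - c'b + sum lam_j |b_j|.

    G and c are (1/n)-scaled Gram matrix and cross-products, so lam is on the
    mean-loss scale.  Returns exact zeros for inactive coordinates.  Full
    sweeps alternate with sweeps restricted to the active set.
    """
    p = len(c)
    G = np.ascontiguousarray(G, dtype=np.float64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    lam = np.ascontiguousarray(lam, dtype=np.float64)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    s = G @ beta  # running G @ beta
    diag = np.ascontiguousarray(np.diag(G))
    solvable = diag > 0

    all_idx = np.arange(p, dtype=np.int64)
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        delta = _sweep(G, c, lam, beta, s, diag, solvable, all_idx)
        if delta < tol:
            return beta, n_iter, True
        active = np.flatnonzero(beta).astype(np.int64)
        while True:
            n_iter += 1
            if n_iter >= max_iter:
                return beta, n_iter, False
            d = _sweep(G, c, lam, beta, s, diag, solvable, active)
            if d < tol:
                break
    return beta, n_iter, False


def _gaussian_solve(X, y, lam, beta_init, tol, max_iter):
    n = len(y)
    G = X.T @ X / n
    c = X.T @ y / n
    return _cd_gram(G, c, lam, beta_init.copy(), tol, max_iter)


def _logistic_solve(X, y, lam, beta_init, tol, max_iter):
    """Proximal-Newton (IRLS) with a weighted coordinate-descent inner loop."""
    n = len(y)
    beta = beta_init.copy()
    n_iter_total = 0
    converged = False
    for _ in range(50):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), _MIN_WEIGHT)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        G = X.T @ Xw / n
        c = Xw.T @ z / n
        old = beta.copy()
        beta, it, _ = _cd_gram(G, c, lam, beta, tol, max_iter)
        n_iter_total += it
        if np.max(np.abs(beta - old)) < max(tol, 1e-8):
            converged = True
            break
    return beta, n_iter_total, converged


def _prepare(design: CollapsedDesign, standardize: bool):
    """Column means/scales and the augmented matrix with intercept column last."""
    X = np.asarray(design.values, dtype=float)
    n = X.shape[0]
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        usable = sd > 0
        scale = np.where(usable, sd, 1.0)
        Xs = (X - mean) / scale
        Xs[:, ~usable] = 0.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
        usable = X.std(axis=0) > 0
        Xs = X.copy()
        Xs[:, ~usable] = 0.0
    Xa = np.hstack([Xs, np.ones((n, 1))])
    return Xa, mean, scale, usable


def _check_y(y: np.ndarray, link: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ConfigurationError("trait vector contains non-finite values")
    if link == LOGIT and not np.isin(y, (0.0, 1.0)).all():
        raise ConfigurationError("logit link requires a binary 0/1 trait")
    if link not in (IDENTITY, LOGIT):
        raise ConfigurationError(f"unknown link {link!r}")
    return y


def fit_lasso(
    design: CollapsedDesign,
    y: np.ndarray,
    link: str = IDENTITY,
    penalties: PenaltySpec = PenaltySpec(),
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 10000,
    _warm: np.ndarray | None = None,
) -> FitResult:
    """Minimize (1/n) NLL + sum_j lambda_eff(j) |beta_j|.

    When ``standardize`` is true (default) features are scaled to unit
    variance before penalization and coefficients are mapped back to the
    original scale; the penalty then effectively acts on the standardized
    coefficients.
    """
    y = _check_y(y, link)
    if len(y) != design.values.shape[0]:
        raise ConfigurationError("design and trait vector have different lengths")
    lam = penalties.effective_lambdas(design)
    Xa, mean, scale, usable = _prepare(design, standardize)
    lam_a = np.append(lam, 0.0)  # intercept unpenalized

    beta0 = _warm if _warm is not None else np.zeros(Xa.shape[1])
    if link == IDENTITY:
        beta, n_iter, conv = _gaussian_solve(Xa, y, lam_a, beta0, tol, max_iter)
    else:
        beta, n_iter, conv = _logistic_solve(Xa, y, lam_a, beta0, tol, max_iter)

    coef_std = beta[:-1]
    coef = np.where(usable, coef_std / scale, 0.0)
    intercept = beta[-1] - float((coef * mean).sum()) if standardize else beta[-1]
    names = design.feature_names
    coefficients = pd.Series(coef, index=names)
    selected = pd.Series(coef != 0.0, index=names)
    lp = intercept + design.values @ coef
    return FitResult(
        coefficients=coefficients,
        intercept=float(intercept),
        selected=selected,
        link=link,
        chosen_penalties=penalties,
        cv_error=None,
        linear_predictor=lp,
        design_columns=design.columns,
        n_iter=n_iter,
        converged=conv,
        effective_lambda=lam * scale,  # penalty seen by original-scale coefficients
    )


def smooth_gradient(
    design: CollapsedDesign, y: np.ndarray, fit: FitResult
) -> np.ndarray:
    """Gradient of the (1/n) negative log-likelihood at the fitted coefficients."""
    X = np.asarray(design.values, dtype=float)
    n = len(y)
    eta = fit.intercept + X @ fit.coefficients.to_numpy()
    if fit.link == LOGIT:
        resid = expit(eta) - y
    else:
        resid = eta - y
    return X.T @ resid / n


def kkt_max_violation(design: CollapsedDesign, y: np.ndarray, fit: FitResult) -> float:
    """Largest violation of the L1 stationarity (subgradient) conditions.

    For zero coefficients the smooth gradient must lie within [-lambda_j,
    lambda_j]; for active ones it must equal -lambda_j * sign(beta_j).
    """
    grad = smooth_gradient(design, y, fit)
    lam = fit.effective_lambda
    beta = fit.coefficients.to_numpy()
    sd_ok = design.values.std(axis=0) > 0
    viol = 0.0
    for j in range(len(beta)):
        if not sd_ok[j] and beta[j] == 0.0:
            continue
        if beta[j] == 0.0:
            viol = max(viol, abs(grad[j]) - lam[j])
        else:
            viol = max(viol, abs(grad[j] + lam[j] * np.sign(beta[j])))
    return max(viol, 0.0)


def objective_value(design: CollapsedDesign, y: np.ndarray, fit: FitResult) -> float:
    """(1/n) NLL + penalty, with the penalty on the scale it was applied."""
    X = np.asarray(design.values, dtype=float)
    n = len(y)
    eta = fit.intercept + X @ fit.coefficients.to_numpy()
    if fit.link == LOGIT:
        eta_c = np.clip(eta, -_MAX_ETA, _MAX_ETA)
        nll = float(np.mean(np.log1p(np.exp(eta_c)) - y * eta_c))
    else:
        nll = float(0.5 * np.mean((y - eta) ** 2))
    pen = float(np.abs(fit.coefficients.to_numpy()) @ fit.effective_lambda)
    return nll + pen


# ---------------------------------------------------------------------------
# lambda selection


def _null_gradient(design: CollapsedDesign, y: np.ndarray, link: str, standardize: bool):
    """Smooth gradient at the covariates-only optimum, on the solving scale."""
    Xa, mean, scale, usable = _prepare(design, standardize)
    lam0 = np.zeros(design.n_features)
    pen_mask = np.append(design.penalty_classes() != UNPENALIZED, False)
    huge = np.where(pen_mask, 1e12, 0.0)
    if link == IDENTITY:
        beta, _, _ = _gaussian_solve(Xa, y, huge, np.zeros(Xa.shape[1]), 1e-10, 5000)
        resid = Xa @ beta - y
    else:
        beta, _, _ = _logistic_solve(Xa, y, huge, np.zeros(Xa.shape[1]), 1e-9, 5000)
        resid = expit(np.clip(Xa @ beta, -_MAX_ETA, _MAX_ETA)) - y
    return Xa.T @ resid / len(y)


def lambda_max(
    design: CollapsedDesign,
    y: np.ndarray,
    link: str = IDENTITY,
    penalties: PenaltySpec = PenaltySpec(lambda_common=1.0),
    standardize: bool = True,
) -> float:
    """Smallest class-level lambda at which every penalized coefficient is zero."""
    grad = _null_gradient(design, y, link, standardize)[:-1]
    rel = PenaltySpec(
        lambda_common=1.0,
        lambda_ns=1.0 if penalties.lambda_ns is not None else None,
        lambda_s=1.0 if penalties.lambda_s is not None else None,
        per_feature_factor=penalties.per_feature_factor,
    ).effective_lambdas(design)
    with np.errstate(divide="ignore"):
        ratios = np.where(rel > 0, np.abs(grad) / np.where(rel > 0, rel, 1.0), 0.0)
    lmax = float(ratios.max())
    if lmax <= 0:
        lmax = 1e-3
    return lmax


def lambda_grid(
    lmax: float, n_lambda: int = 50, lambda_min_ratio: float = 0.001
) -> np.ndarray:
    """Log-spaced descending grid from lambda_max to lambda_min_ratio * lambda_max."""
    return np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)


class _GaussianPathSolver:
    """Reusable Gram-matrix context for pathwise identity-link fits.

    Builds the (standardized, intercept-augmented) Gram once and solves a
    sequence of penalty vectors with warm starts — the workhorse behind
    cross-validation grids.
    """

    def __init__(self, design: CollapsedDesign, y: np.ndarray, standardize: bool):
        self.Xa, self.mean, self.scale, self.usable = _prepare(design, standardize)
        n = len(y)
        self.G = self.Xa.T @ self.Xa / n
        self.c = self.Xa.T @ y / n
        self.standardize = standardize
        self._beta = np.zeros(self.Xa.shape[1])

    def solve(self, lam: np.ndarray, tol: float, max_iter: int = 10000) -> np.ndarray:
        lam_a = np.append(lam, 0.0)
        self._beta, _, _ = _cd_gram(self.G, self.c, lam_a, self._beta.copy(), tol, max_iter)
        return self._beta

    def original_scale(self, beta: np.ndarray) -> tuple[np.ndarray, float]:
        coef = np.where(self.usable, beta[:-1] / self.scale, 0.0)
        b0 = beta[-1] - float((coef * self.mean).sum()) if self.standardize else beta[-1]
        return coef, b0


def _cv_error(y_true: np.ndarray, pred: np.ndarray, link: str) -> float:
    if link == LOGIT:
        p = np.clip(pred, 1e-12, 1 - 1e-12)
        return float(-2.0 * np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))
    return float(np.mean((y_true - pred) ** 2))


def _fold_design(design: CollapsedDesign, idx: np.ndarray) -> CollapsedDesign:
    return CollapsedDesign(
        values=design.values[idx],
        columns=design.columns,
        individual_ids=[design.individual_ids[i] for i in idx],
    )


def cv_lasso(
    design: CollapsedDesign,
    y: np.ndarray,
    link: str = IDENTITY,
    k_folds: int = 5,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.001,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-7,
) -> FitResult:
    """Single-penalty fit with lambda chosen by k-fold cross-validation.

    The error-minimizing lambda on a 50-point log grid from lambda_max down
    to 0.001 * lambda_max is used for the final full-data refit.
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    y = _check_y(y, link)
    lmax = lambda_max(design, y, link, standardize=standardize)
    grid = lambda_grid(lmax, n_lambda, lambda_min_ratio)

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    tol_cv = max(tol, 1e-5)  # fold fits only score the grid; refit is tight
    errors = np.zeros(len(grid))
    for train, test in kf.split(y):
        d_tr = _fold_design(design, train)
        Xte = design.values[test]
        if link == IDENTITY:
            solver = _GaussianPathSolver(d_tr, y[train], standardize)
            for i, lam in enumerate(grid):
                lam_vec = PenaltySpec(lambda_common=float(lam)).effective_lambdas(d_tr)
                beta = solver.solve(lam_vec, tol_cv)
                coef, b0 = solver.original_scale(beta)
                errors[i] += _cv_error(y[test], b0 + Xte @ coef, link)
        else:
            warm = None
            for i, lam in enumerate(grid):
                fit = fit_lasso(
                    d_tr,
                    y[train],
                    link,
                    PenaltySpec(lambda_common=float(lam)),
                    standardize=standardize,
                    tol=tol_cv,
                    _warm=warm,
                )
                warm = _warm_vector(fit, d_tr, standardize)
                errors[i] += _cv_error(y[test], fit.predict(Xte), link)
    errors /= k_folds
    best = int(np.argmin(errors))
    final = fit_lasso(
        design,
        y,
        link,
        PenaltySpec(lambda_common=float(grid[best])),
        standardize=standardize,
        tol=tol,
    )
    final.cv_error = float(errors[best])
    return final


def _warm_vector(fit: FitResult, design: CollapsedDesign, standardize: bool) -> np.ndarray:
    """Re-express a fit on the solver's (standardized + intercept) scale."""
    X = design.values
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0) if standardize else np.ones(X.shape[1])
    coef = fit.coefficients.to_numpy() * scale
    b0 = fit.intercept + float((fit.coefficients.to_numpy() * X.mean(axis=0)).sum()) if standardize else fit.intercept
    return np.append(coef, b0)


def fit_differential(
    design: CollapsedDesign,
    y: np.ndarray,
    link: str = IDENTITY,
    lambda_grid_ns: np.ndarray | None = None,
    lambda_grid_s: np.ndarray | None = None,
    k_folds: int = 5,
    n_grid: int = 10,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-7,
    lambda_common_rule: str = "min",
) -> FitResult:
    """Two-penalty fit: (lambda_ns, lambda_s) tuned by within-replicate CV.

    Requires a design built with ``split_by_annotation``.  Common-variant
    columns are penalized at min(lambda_ns, lambda_s) (rule configurable to
    ``"ns"`` or ``"s"``).  The CV-error-minimizing pair on the 2-D grid is
    refit on the full replicate.
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    classes = set(design.penalty_classes())
    if PENALIZED_NS not in classes and PENALIZED_S not in classes:
        raise ConfigurationError(
            "differential fit requires a design built with split_by_annotation"
        )
    y = _check_y(y, link)
    if lambda_grid_ns is None or lambda_grid_s is None:
        lmax = lambda_max(design, y, link, standardize=standardize)
        if lambda_grid_ns is None:
            lambda_grid_ns = lambda_grid(lmax, n_grid)
        if lambda_grid_s is None:
            lambda_grid_s = lambda_grid(lmax, n_grid)
    lambda_grid_ns = np.asarray(lambda_grid_ns, dtype=float)
    lambda_grid_s = np.asarray(lambda_grid_s, dtype=float)
    if lambda_grid_ns.size == 0 or lambda_grid_s.size == 0:
        raise ConfigurationError("lambda grids must be non-empty")

    def spec_for(l_ns: float, l_s: float) -> PenaltySpec:
        common = {"min": min(l_ns, l_s), "ns": l_ns, "s": l_s}[lambda_common_rule]
        return PenaltySpec(lambda_common=common, lambda_ns=l_ns, lambda_s=l_s)

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    tol_cv = max(tol, 1e-5)
    errors = np.zeros((len(lambda_grid_ns), len(lambda_grid_s)))
    for train, test in kf.split(y):
        d_tr = _fold_design(design, train)
        Xte = design.values[test]
        if link == IDENTITY:
            solver = _GaussianPathSolver(d_tr, y[train], standardize)
            for a, l_ns in enumerate(lambda_grid_ns):
                for b, l_s in enumerate(lambda_grid_s):
                    lam_vec = spec_for(float(l_ns), float(l_s)).effective_lambdas(d_tr)
                    beta = solver.solve(lam_vec, tol_cv)
                    coef, b0 = solver.original_scale(beta)
                    errors[a, b] += _cv_error(y[test], b0 + Xte @ coef, link)
        else:
            for a, l_ns in enumerate(lambda_grid_ns):
                warm = None
                for b, l_s in enumerate(lambda_grid_s):
                    fit = fit_lasso(
                        d_tr,
                        y[train],
                        link,
                        spec_for(float(l_ns), float(l_s)),
                        standardize=standardize,
                        tol=tol_cv,
                        _warm=warm,
                    )
                    warm = _warm_vector(fit, d_tr, standardize)
                    errors[a, b] += _cv_error(y[test], fit.predict(Xte), link)
    errors /= k_folds
    a, b = np.unravel_index(int(np.argmin(errors)), errors.shape)
    final = fit_lasso(
        design,
        y,
        link,
        spec_for(float(lambda_grid_ns[a]), float(lambda_grid_s[b])),
        standardize=standardize,
        tol=tol,
    )
    final.cv_error = float(errors[a, b])
    return final


def fit_all_replicates(
    g: GenotypeSet,
    reps: ReplicateSet,
    trait: str,
    config: CollapseConfig,
    protocol: str = "single",
    k_folds: int = 5,
    n_lambda: int = 50,
    n_grid: int = 10,
    seed: int = 0,
    replicates: "list[int] | None" = None,
) -> list[FitResult]:
    """Fit one penalized model per phenotype replicate.

    DAS orientations and disease-trait WS weights depend on the phenotype,
    so those designs are rebuilt per replicate; PROP and quantitative-trait
    WS designs are built once and reused.  The single-penalty lambda (or the
    differential pair) is chosen by within-replicate cross-validation.
    """
    if trait not in reps.traits:
        raise ConfigurationError(f"trait {trait!r} not present in replicate set")
    if protocol not in ("single", "differential"):
        raise ConfigurationError(f"unknown penalty protocol {protocol!r}")
    link = LOGIT if trait == DISEASE_TRAIT else IDENTITY
    y_dependent = config.method == DAS or (
        config.method == WS and config.ws_frequency_source == "unaffected_only"
    )
    shared = (
        None
        if y_dependent
        else build_design(g, reps.covariates, config, y=None, link=link)
    )
    indices = list(range(reps.R)) if replicates is None else list(replicates)
    fits: list[FitResult] = []
    for r in indices:
        y = reps.trait_replicate(trait, r)
        rep_seed = int((seed + 1000003 * r) % (2**31 - 1))
        try:
            design = shared if shared is not None else build_design(
                g, reps.covariates, config, y=y, link=link
            )
            if protocol == "single":
                fit = cv_lasso(
                    design, y, link, k_folds=k_folds, n_lambda=n_lambda, seed=rep_seed
                )
            else:
                fit = fit_differential(
                    design, y, link, k_folds=k_folds, n_grid=n_grid, seed=rep_seed
                )
        except Exception as exc:  # annotate with replicate context
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(
                "fit", str(exc), trait=trait, method=config.method, replicate=r
            ) from exc
        fits.append(fit)
    return fits
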