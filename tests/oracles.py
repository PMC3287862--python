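"""Independent brute-force oracles used by the test suite and acceptance script.

These deliberately avoid the package's own solver paths: the L1 optimum is
found by exhaustively enumerating sign patterns of the penalized coordinates
and solving each smooth equality-constrained subproblem, and the ROC AUC by
counting concordant positive-negative pairs.
"""

import itertools

import numpy as np
from scipy.special import expit


def _gaussian_subproblem(X, y, lam, signs, free):
    n = len(y)
    A = X[:, free]
    lam_s = np.array([lam[j] * signs.get(j, 0) for j in free])
    G = A.T @ A / n
    c = A.T @ y / n - lam_s
    try:
        beta_f = np.linalg.solve(G, c)
    except np.linalg.LinAlgError:
        beta_f, *_ = np.linalg.lstsq(G, c, rcond=None)
    beta = np.zeros(X.shape[1])
    beta[free] = beta_f
    return beta


def _logistic_subproblem(X, y, lam, signs, free):
    """Damped Newton on the smooth subproblem (strictly convex in beta_free)."""
    n = len(y)
    A = X[:, free]
    lam_s = np.array([lam[j] * signs.get(j, 0) for j in free])

    def f(b):
        eta = A @ b
        return np.mean(np.logaddexp(0, eta) - y * eta) + lam_s @ b

    b = np.zeros(len(free))
    fb = f(b)
    for _ in range(100):
        eta = A @ b
        p_hat = expit(eta)
        g = A.T @ (p_hat - y) / n + lam_s
        if np.abs(g).max() < 1e-12:
            break
        w = np.maximum(p_hat * (1 - p_hat), 1e-10)
        H = (A * w[:, None]).T @ A / n + 1e-12 * np.eye(len(free))
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-12:
            cand = b - t * step
            fc = f(cand)
            if fc <= fb - 1e-4 * t * (g @ step):
                b, fb = cand, fc
                break
            t /= 2
        else:
            break
    beta = np.zeros(X.shape[1])
    beta[free] = b
    return beta


def l1_oracle_objective(X, y, lam, link="identity"):
    """Global minimum of (1/n) NLL + sum lam_j |beta_j| by sign enumeration."""
    n, p = X.shape
    penalized = [j for j in range(p) if lam[j] > 0]
    always_free = [j for j in range(p) if lam[j] == 0]
    best = np.inf
    for pattern in itertools.product((-1, 0, 1), repeat=len(penalized)):
        signs = {j: s for j, s in zip(penalized, pattern)}
        free = always_free + [j for j, s in signs.items() if s != 0]
        if not free:
            beta = np.zeros(p)
        elif link == "identity":
            beta = _gaussian_subproblem(X, y, lam, signs, free)
        else:
            beta = _logistic_subproblem(X, y, lam, signs, free)
        ok = all(signs[j] * beta[j] >= -1e-10 for j in signs if signs[j] != 0)
        if not ok:
            continue
        eta = X @ beta
        if link == "identity":
            nll = 0.5 * np.mean((y - eta) ** 2)
        else:
            nll = np.mean(np.logaddexp(0, eta) - y * eta)
        obj = nll + np.abs(beta) @ lam
        best = min(best, obj)
    return best


def random_l1_instance(rng, n=50, p=5, link="identity"):
    """A random design/trait/penalty instance with mixed penalty factors."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=1.0, size=p) * (rng.random(p) < 0.6)
    eta = X @ beta
    if link == "identity":
        y = eta + rng.normal(size=n)
    else:
        y = (rng.random(n) < expit(eta)).astype(float)
    factors = rng.choice([0.0, 0.5, 1.0, 2.0], size=p, p=[0.2, 0.2, 0.4, 0.2])
    lam = rng.uniform(0.05, 0.4)
    return X, y, lam, factors


def pairwise_concordance_auc(counts, labels):
    """AUC as the proportion of concordant positive-negative pairs (ties 0.5)."""
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = counts[labels]
    neg = counts[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
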