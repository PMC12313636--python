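"""Minimal CMA-ES (covariance matrix adaptation evolution strategy).

Standard (mu/mu_w, lambda) CMA-ES with cumulative step-size adaptation and
rank-one plus rank-mu covariance updates, following Hansen's tutorial
formulation.  Box constraints are enforced by evaluating a repaired
(clipped) candidate and adding a quadratic out-of-bounds penalty, which
keeps the objective defined everywhere while discouraging boundary camping.

Only what this package needs is implemented: small dimension, a plain
callable objective, full reproducibility through a numpy Generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAResult", "cma_es"]


@dataclass
class CMAResult:
    x: np.ndarray          # incumbent (best-ever) point
    fun: float             # its objective value
    n_evals: int
    n_iter: int
    seed: int
    history: list = field(default_factory=list)  # (iteration, best f) pairs


def cma_es(objective, x0, sigma0: float, bounds=None, popsize: int | None = None,
           max_iter: int = 200, seed: int = 0, ftol: float = 1e-12,
           xtol: float = 1e-11) -> CMAResult:
    """Minimize ``objective(x)`` from ``x0`` with initial step size ``sigma0``.

    Parameters
    ----------
    bounds
        Optional ``(lower, upper)`` arrays; candidates are clipped into the
        box before evaluation and penalized by the squared repair distance.
    popsize
        Offspring per generation; default ``4 + floor(3 ln n)``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    weights = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights /= weights.sum()
    mu_eff = 1.0 / np.sum(weights**2)

    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    if bounds is not None:
        lower = np.asarray(bounds[0], dtype=float)
        upper = np.asarray(bounds[1], dtype=float)
    else:
        lower = upper = None

    def eval_candidate(x):
        if lower is None:
            return float(objective(x)), x
        xr = np.clip(x, lower, upper)
        pen = float(np.sum((x - xr) ** 2))
        return float(objective(xr)) + pen, xr

    rng = np.random.default_rng(seed)
    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    eigen_B = np.eye(n)
    eigen_D = np.ones(n)

    best_x = x0.copy()
    best_f = np.inf
    n_evals = 0
    history = []
    prev_best = np.inf

    for it in range(max_iter):
        # sample offspring
        z = rng.standard_normal((lam, n))
        y = z @ (eigen_B * eigen_D).T  # B D z
        xs = mean + sigma * y
        fs = np.empty(lam)
        for k in range(lam):
            fs[k], xr = eval_candidate(xs[k])
            n_evals += 1
            if fs[k] < best_f:
                best_f = fs[k]
                best_x = xr.copy()
        order = np.argsort(fs)
        y_sel = y[order[:mu]]
        y_w = weights @ y_sel
        mean = mean + sigma * y_w

        # step-size path (uses C^{-1/2} y_w)
        c_inv_sqrt_yw = eigen_B @ ((eigen_B.T @ y_w) / eigen_D)
        p_sigma = (1 - c_sigma) * p_sigma + np.sqrt(c_sigma * (2 - c_sigma) * mu_eff) * c_inv_sqrt_yw
        sigma = sigma * np.exp((c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_n - 1))

        h_sigma = (np.linalg.norm(p_sigma) / np.sqrt(1 - (1 - c_sigma) ** (2 * (it + 1)))
                   < (1.4 + 2 / (n + 1)) * chi_n)
        p_c = (1 - c_c) * p_c + (np.sqrt(c_c * (2 - c_c) * mu_eff) * y_w if h_sigma else 0.0)

        rank_mu = sum(wk * np.outer(yk, yk) for wk, yk in zip(weights, y_sel))
        C = ((1 - c_1 - c_mu) * C
             + c_1 * (np.outer(p_c, p_c) + (0.0 if h_sigma else c_c * (2 - c_c)) * C)
             + c_mu * rank_mu)
        C = (C + C.T) / 2
        evals, vecs = np.linalg.eigh(C)
        eigen_D = np.sqrt(np.maximum(evals, 1e-20))
        eigen_B = vecs

        history.append((it, best_f))
        if it > 10 and abs(prev_best - best_f) < ftol and sigma * eigen_D.max() < xtol:
            break
        prev_best = best_f
        if sigma * eigen_D.max() < xtol:
            break

    return CMAResult(x=best_x, fun=best_f, n_evals=n_evals, n_iter=it + 1,
                     seed=seed, history=history)
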