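"""Maximum-likelihood multinomial logistic fitting with per-category designs.

Model updating needs multinomial fits that standard implementations do not
expose: each non-reference category k may have its *own* design matrix
X_k and fixed offset o_k, so that

    eta_ik = o_ik + X_k[i] . theta_k,       eta_reference = 0,
    P_ik   = exp(eta_ik) / (1 + sum_j exp(eta_ij)).

This covers the unconstrained joint refit (all X_k equal), logistic
recalibration (X_k = [1, eta_k^orig], distinct per category) and
intercept-only re-estimation with shrunken coefficients held fixed in the
offset.  Estimation is full Newton on the joint log-likelihood with
step-halving, tolerance 1e-8 on the relative log-likelihood change,
at most 100 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MultinomialFit", "ConvergenceError", "fit_multinomial", "null_loglik"]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message + (f" (log-likelihood trace: {trace})" if trace else ""))
        self.trace = trace or []


@dataclass
class MultinomialFit:
    """Result of a per-category-design multinomial ML fit.

    ``params[j]`` is the coefficient vector of the j-th non-reference
    category; ``cov`` is the observed-information covariance of the stacked
    parameter vector (block order follows the category order).
    """

    params: list[np.ndarray]
    loglik: float
    n_iter: int
    cov: np.ndarray
    converged: bool

    def standard_errors(self) -> list[np.ndarray]:
        se = np.sqrt(np.diag(self.cov))
        out, pos = [], 0
        for p in self.params:
            out.append(se[pos : pos + p.size])
            pos += p.size
        return out


def _etas(designs, offsets, params):
    return np.column_stack(
        [
            (offsets[j] if offsets[j] is not None else 0.0) + designs[j] @ params[j]
            for j in range(len(designs))
        ]
    )


def _probs(eta):
    # reference category has eta = 0; stabilise by the row max
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    P = ex / ex.sum(axis=1, keepdims=True)
    return P  # columns: [reference, cat_1, ..., cat_{K-1}]

def _loglik(eta, y_idx):
    # y_idx: 0 for the reference, j+1 for non-reference category j
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    m = full.max(axis=1)
    lse = m + np.log(np.exp(full - m[:, None]).sum(axis=1))
    return float(np.sum(full[np.arange(len(y_idx)), y_idx] - lse))


def fit_multinomial(
    y_idx: np.ndarray,
    designs: list[np.ndarray],
    offsets: list[np.ndarray | None] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MultinomialFit:
    """Fit the per-category-design multinomial logistic model by Newton.

    Parameters
    ----------
    y_idx
        Integer outcome codes: 0 is the reference category, ``j + 1`` the
        j-th non-reference category (matching ``designs`` order).
    designs
        One (n, p_j) design matrix per non-reference category (include an
        intercept column explicitly if wanted).
    offsets
        Optional fixed per-category offset vectors added to eta.
    """
    y_idx = np.asarray(y_idx, dtype=int)
    n = y_idx.shape[0]
    m = len(designs)
    designs = [np.asarray(X, dtype=float).reshape(n, -1) for X in designs]
    if offsets is None:
        offsets = [None] * m
    if y_idx.min() < 0 or y_idx.max() > m:
        raise ValueError("y_idx codes must lie in 0..K-1")
    Y = np.zeros((n, m))
    for j in range(m):
        Y[:, j] = y_idx == j + 1

    params = [np.zeros(X.shape[1]) for X in designs]
    sizes = [X.shape[1] for X in designs]
    total = sum(sizes)
    starts = np.cumsum([0] + sizes)

    eta = _etas(designs, offsets, params)
    ll = _loglik(eta, y_idx)
    trace = [ll]
    converged = False
    H = np.eye(total)
    for it in range(1, max_iter + 1):
        P = _probs(eta)[:, 1:]
        grad = np.concatenate([designs[j].T @ (Y[:, j] - P[:, j]) for j in range(m)])
        H = np.zeros((total, total))
        for j in range(m):
            for l in range(j, m):
                w = P[:, j] * ((1.0 if j == l else 0.0) - P[:, l])
                block = -(designs[j] * w[:, None]).T @ designs[l]
                H[starts[j] : starts[j + 1], starts[l] : starts[l + 1]] = block
                if l != j:
                    H[starts[l] : starts[l + 1], starts[j] : starts[j + 1]] = block.T
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix at iteration {it}: {e}", trace)
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            new_params = [params[j] + scale * step[starts[j] : starts[j + 1]] for j in range(m)]
            new_eta = _etas(designs, offsets, new_params)
            new_ll = _loglik(new_eta, y_idx)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve the log-likelihood", trace)
        params, eta = new_params, new_eta
        if max(np.abs(p).max() for p in params) > 1e5:
            raise ConvergenceError(
                "parameter estimates diverging (complete separation suspected)", trace
            )
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        trace.append(ll)
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations", trace)
    if ll > -1e-8 * n:
        # a perfect fit of non-degenerate data means the MLE does not exist
        raise ConvergenceError(
            "log-likelihood reached 0: complete separation, no finite MLE", trace
        )
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.full((total, total), np.nan)
    return MultinomialFit(params=params, loglik=ll, n_iter=it, cov=cov, converged=True)


def null_loglik(y_idx: np.ndarray, n_categories: int) -> float:
    """Log-likelihood of the intercept-only multinomial model (closed form)."""
    y_idx = np.asarray(y_idx, dtype=int)
    n = len(y_idx)
    counts = np.bincount(y_idx, minlength=n_categories).astype(float)
    p = counts / n
    return float(np.sum(counts[counts > 0] * np.log(p[counts > 0])))
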