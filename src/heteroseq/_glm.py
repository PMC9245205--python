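"""Vectorised negative-binomial GLM fitting.

Fits the same log-link NB regression to many genes at once (one design
matrix shared across genes, per-gene response vectors and dispersions)
by iteratively reweighted least squares.  The NB variance function is
Var(Y) = mu + alpha * mu**2, so the IRLS working weight for the log link
is w = mu / (1 + alpha * mu), which is also the expected Fisher
information weight used for the Wald standard errors.
"""

from __future__ import annotations

import numpy as np

# mean floor and linear-predictor bound keep IRLS finite when a whole
# group is zero (the MLE then runs to -inf)
_MU_FLOOR = 1e-10
_ETA_BOUND = 50.0


def nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray | float,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Fit NB GLMs with log link for a stack of genes.

    Parameters
    ----------
    y : (G, n) non-negative counts, one row per gene.
    X : (n, p) design matrix shared by all genes.
    alpha : per-gene dispersion, scalar or shape (G,); alpha = 0 is Poisson.
    offset : optional (n,) or (G, n) log-scale offset (e.g. log size factors).

    Returns
    -------
    dict with keys ``beta`` (G, p), ``se`` (G, p), ``converged`` (G,) bool,
    ``fisher`` (G, p, p) the final expected-information matrices.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    X = np.asarray(X, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
    if offset is None:
        offset = np.zeros(n)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))

    beta = np.zeros((G, p))
    # start from the intercept of the offset-adjusted mean
    base = np.mean(y * np.exp(-offset), axis=1)
    beta[:, 0] = np.log(np.maximum(base, _MU_FLOOR))

    converged = np.zeros(G, dtype=bool)
    A = np.empty((G, p, p))
    ridge = 1e-12 * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(offset + beta @ X.T, -_ETA_BOUND, _ETA_BOUND)
        mu = np.maximum(np.exp(eta), _MU_FLOOR)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X) + ridge
        b = np.einsum("gn,gn,ni->gi", w, z, X)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            beta_new = np.einsum("gij,gj->gi", np.linalg.pinv(A), b)
        step = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        newly = step < tol
        converged |= newly
        if converged.all():
            break

    eta = np.clip(offset + beta @ X.T, -_ETA_BOUND, _ETA_BOUND)
    mu = np.maximum(np.exp(eta), _MU_FLOOR)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,ni,nj->gij", w, X, X) + ridge
    cov = np.linalg.inv(A)
    var = np.einsum("gii->gi", cov)
    se = np.sqrt(np.maximum(var, 0.0))
    return {"beta": beta, "se": se, "converged": converged, "fisher": A}


def wald_pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values for beta/se, elementwise; NaN-safe."""
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))
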