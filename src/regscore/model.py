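"""Elastic-net regression of expression on TFRS features, with grid-search
cross-validation and RMSE-based scoring-scheme selection.

The objective minimised is, for N genes and p TFs::

    min_{b0, b}  (1/2N) sum_g (y_g - b0 - x_g^T b)^2
                 + lambda * [ (1 - alpha) ||b||_2^2 + alpha ||b||_1 ]

Note the ridge term is NOT halved — this is the form used with the scoring
schemes and differs from the glmnet/sklearn convention by a factor of two
on the L2 part; ``glmnet_compat=True`` switches to the halved form.  The
intercept b0 is never penalised.  Features are standardised (zero mean,
unit variance) before fitting and coefficients are reported on the
standardised scale.

Solved by cyclic coordinate descent with exact soft-threshold updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .tfrs import PROMOTER_SCHEMES, TFRSMatrix, build_design_matrix

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 2.0001, 0.1), 10))
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 10))
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100_000


@dataclass
class ElasticNetFit:
    beta0: float
    beta: np.ndarray
    lambda_: float
    alpha: float
    objective: float
    converged: bool
    n_iter: int = 0


def elastic_net_objective(
    X: np.ndarray,
    y: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    lambda_: float,
    alpha: float,
    glmnet_compat: bool = False,
) -> float:
    """Evaluate the penalised objective at (beta0, beta)."""
    n = len(y)
    resid = y - beta0 - X @ beta
    ridge_w = (1.0 - alpha) * (0.5 if glmnet_compat else 1.0)
    return float(
        resid @ resid / (2 * n)
        + lambda_ * (ridge_w * beta @ beta + alpha * np.abs(beta).sum())
    )


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


@njit(cache=False)
def _cd_kernel(C, b, beta, l1, ridge, tol, max_iter):  # pragma: no cover
    """Cyclic coordinate descent in covariance form.

    C = Xc^T Xc / n, b = Xc^T yc / n on centred data; updates beta in
    place.  Returns (sweeps used, converged flag).
    """
    p = b.shape[0]
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        dmax = 0.0
        for j in range(p):
            cjj = C[j, j]
            if cjj == 0.0:
                continue  # constant column: coefficient stays put
            z = b[j] - np.dot(C[j], beta) + cjj * beta[j]
            if z > l1:
                bj = (z - l1) / (cjj + ridge)
            elif z < -l1:
                bj = (z + l1) / (cjj + ridge)
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                beta[j] = bj
                if abs(d) > dmax:
                    dmax = abs(d)
        if dmax < tol:
            converged = True
            break
    return it, converged


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    alpha: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    glmnet_compat: bool = False,
    warm_start: ElasticNetFit | None = None,
) -> ElasticNetFit:
    """Cyclic coordinate descent for the penalised least-squares objective.

    ``X`` is assumed standardised by the caller (see :func:`standardize`);
    ``lambda_ >= 0``, ``alpha`` in [0, 1].  At lambda_ = 0 the solution is
    ordinary least squares regardless of alpha.  ``warm_start`` seeds the
    coefficients from a neighbouring fit (glmnet-style pathwise descent).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if lambda_ < 0 or not 0 <= alpha <= 1:
        raise ValueError("lambda_ must be >= 0 and alpha in [0, 1]")

    # un-halved ridge: d/db of lambda*(1-alpha)*b^2 is 2*lambda*(1-alpha)*b
    ridge = lambda_ * (1.0 - alpha) * (1.0 if glmnet_compat else 2.0)
    l1 = lambda_ * alpha

    # the unpenalised intercept decouples after centring: minimising over
    # beta0 at fixed beta gives beta0 = mean(y - X beta)
    colmean = X.mean(axis=0)
    Xc = X - colmean
    yc = y - y.mean()
    C = Xc.T @ Xc / n
    b = Xc.T @ yc / n
    # at lambda = 0 the iteration is alpha-independent; a cold start keeps
    # the least-squares limit bitwise identical across the alpha grid
    use_warm = warm_start is not None and len(warm_start.beta) == p and lambda_ > 0
    beta = warm_start.beta.copy() if use_warm else np.zeros(p)
    it, converged = _cd_kernel(C, b, beta, l1, ridge, tol, max_iter)
    beta0 = float(y.mean() - colmean @ beta)
    if not converged:
        log.warning("coordinate descent did not converge in %d sweeps", max_iter)
    return ElasticNetFit(
        beta0=beta0,
        beta=beta,
        lambda_=lambda_,
        alpha=alpha,
        objective=elastic_net_objective(X, y, beta0, beta, lambda_, alpha, glmnet_compat),
        converged=converged,
        n_iter=it,
    )


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardise X; constant columns are centred and left at sd 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


@dataclass
class SchemeEvaluation:
    scheme: str
    best_lambda: float
    best_alpha: float
    cv_rmse: float
    fold_assignments: np.ndarray
    seed: int
    rmse_grid: np.ndarray = field(default=None, repr=False)  # lambda x alpha
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    alpha_grid: tuple = DEFAULT_ALPHA_GRID


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded balanced random partition into n_folds (sizes within 1)."""
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds N={n}")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % n_folds
    return folds[rng.permutation(n)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_folds: int = 2,
    seed: int = 0,
    repeats: int = 1,
    glmnet_compat: bool = False,
    scheme: str = "",
    folds: np.ndarray | None = None,
) -> SchemeEvaluation:
    """Grid-search (lambda, alpha) by k-fold cross-validated RMSE.

    For each grid point the model is fitted on each training fold
    (standardising X within the fold) and scored on the held-out fold;
    the per-fold RMSEs are averaged (and over ``repeats`` seeded splits
    when repeats > 1).  Returns the argmin pair; ties break toward the
    earliest grid position.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lambda_grid = tuple(lambda_grid)
    alpha_grid = tuple(alpha_grid)
    if not lambda_grid or not alpha_grid:
        raise ValueError("empty parameter grid")
    n = len(y)
    rmse = np.zeros((len(lambda_grid), len(alpha_grid)))
    all_folds = (
        [np.asarray(folds)]
        if folds is not None
        else [make_folds(n, n_folds, seed + 7919 * r) for r in range(repeats)]
    )
    for fold_ids in all_folds:
        for k in np.unique(fold_ids):
            train, test = fold_ids != k, fold_ids == k
            Xt, mean, sd = standardize(X[train])
            Xv = (X[test] - mean) / sd
            yt, yv = y[train], y[test]
            # pathwise descent: within each alpha, sweep lambda from
            # strongest to weakest, warm-starting from the previous fit
            for ai, a in enumerate(alpha_grid):
                fit = None
                for li in np.argsort(lambda_grid)[::-1]:
                    fit = fit_elastic_net(Xt, yt, lambda_grid[li], a,
                                          glmnet_compat=glmnet_compat,
                                          warm_start=fit)
                    pred = fit.beta0 + Xv @ fit.beta
                    rmse[li, ai] += np.sqrt(np.mean((yv - pred) ** 2))
    rmse /= sum(len(np.unique(f)) for f in all_folds)
    # near-ties (within solver tolerance of the minimum, e.g. every alpha
    # at lambda = 0) resolve to the earliest grid position
    m = float(rmse.min())
    close = np.argwhere(rmse <= m + 1e-9 * max(1.0, m))
    li, ai = close[0]
    return SchemeEvaluation(
        scheme=scheme,
        best_lambda=float(lambda_grid[li]),
        best_alpha=float(alpha_grid[ai]),
        cv_rmse=float(rmse[li, ai]),
        fold_assignments=all_folds[0],
        seed=seed,
        rmse_grid=rmse,
        lambda_grid=lambda_grid,
        alpha_grid=alpha_grid,
    )


def expression_target(expr: pd.DataFrame) -> np.ndarray:
    """Regression target: per-gene mean of log2(FPKM + 1) over replicates."""
    return np.log2(expr.values + 1.0).mean(axis=1)


def select_scheme(
    promoter_hits,
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    tfs: list[str] | None = None,
    schemes=PROMOTER_SCHEMES,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_folds: int = 2,
    seed: int = 0,
    glmnet_compat: bool = False,
) -> tuple[str, dict[str, SchemeEvaluation], dict[str, TFRSMatrix]]:
    """Build the design matrix under each scheme, cross-validate each with
    the same fold split, and pick the scheme with smallest CV RMSE.

    ``expr`` is the target cell type's gene x replicate FPKM frame indexed
    by the modelled genes.  Ties break toward the earlier scheme in
    ``schemes`` with a logged warning.
    """
    hits = list(promoter_hits)
    if genes is None:
        genes = list(expr.index.astype(str))
    if tfs is None:
        tfs = sorted({h.tf_name for h in hits})
    if len(genes) < 2:
        raise ValueError("need >= 2 genes with hits")
    y = expression_target(expr.loc[genes])
    folds = make_folds(len(genes), n_folds, seed)
    evals: dict[str, SchemeEvaluation] = {}
    matrices: dict[str, TFRSMatrix] = {}
    any_nonzero = False
    for scheme in schemes:
        mat = build_design_matrix(hits, genes, tfs, scheme)
        matrices[scheme] = mat
        any_nonzero = any_nonzero or bool((mat.scores != 0).any())
        ev = cross_validate(
            mat.scores, y, lambda_grid, alpha_grid, n_folds=n_folds, seed=seed,
            glmnet_compat=glmnet_compat, scheme=scheme, folds=folds,
        )
        evals[scheme] = ev
    if not any_nonzero:
        raise ValueError("all-zero design matrix for every scheme")
    best = min(schemes, key=lambda s: evals[s].cv_rmse)
    ties = [s for s in schemes if evals[s].cv_rmse == evals[best].cv_rmse]
    if len(ties) > 1:
        log.warning("scheme CV RMSE tie between %s; keeping %s", ties, ties[0])
        best = ties[0]
    return best, evals, matrices


def predicted_targets(
    tfrs: TFRSMatrix,
    tf_name: str,
    top_k: int | None = None,
    score_min: float | None = None,
) -> pd.DataFrame:
    """Rank a TF's candidate target genes by regulatory score (descending).

    Only genes with a nonzero score are reported; ties break by gene id
    for determinism.  ``top_k`` truncates, ``score_min`` thresholds.
    """
    if tf_name not in tfrs.tfs:
        raise KeyError(f"TF {tf_name!r} not in TFRS matrix")
    col = tfrs.scores[:, tfrs.tfs.index(tf_name)]
    rows = [
        (g, s) for g, s in zip(tfrs.genes, col) if s > 0
    ]
    rows.sort(key=lambda gs: (-gs[1], gs[0]))
    if score_min is not None:
        rows = [(g, s) for g, s in rows if s >= score_min]
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["gene_id", "score"])
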