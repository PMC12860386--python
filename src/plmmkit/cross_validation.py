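"""k-fold cross-validation with the whole pipeline redone inside every fold.

Preconditioning has implications for exchangeability: CV is only honest if
*every* step — standardization, relatedness, η estimation, rotation, path
fitting — is recomputed from the training rows of each fold.  Held-out rows
contribute nothing to centers/scales, K, or η̂ of their fold's model; held-out
outcomes are predicted by BLUP (default) using the training-fold context.

The λ sequence is computed once from the full data and shared across folds so
the cross-validation error (CVE) is comparable per λ; λ is selected at the CVE
minimum (a one-standard-error variant is reported too).  Errors are mean
squared prediction errors on the raw outcome scale; RMSPE is their square
root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .design import Design, design_from_arrays
from .exceptions import ConfigurationError
from .penalized_fit import PlmmFit, plmm
from .prediction import BlupContext, predict_blup, predict_linear


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Uniformly random balanced fold labels in {1..k}; deterministic given seed."""
    if not (2 <= k <= n):
        raise ConfigurationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % k) + 1
    return labels[rng.permutation(n)]


@dataclass
class CvResult:
    lambdas: np.ndarray
    cve: np.ndarray
    cvse: np.ndarray
    fold_assignments: np.ndarray
    lambda_min_index: int
    lambda_1se_index: int
    fit: PlmmFit
    fold_etas: np.ndarray
    fold_converged: np.ndarray
    seed: int
    predict_method: str

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.lambda_min_index])

    @property
    def rmspe(self) -> np.ndarray:
        return np.sqrt(self.cve)


def _fold_errors(
    design: Design,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    lambdas: np.ndarray,
    penalty: str,
    gamma: float | None,
    alpha: float,
    precondition: bool,
    predict_method: str,
    tol: float,
    max_iter: int,
    return_fit: bool = False,
):
    """Refit everything on the training rows; return per-λ MSE on the held-out rows."""
    X_raw = np.array(design.X_raw)
    y = np.asarray(design.y, dtype=np.float64)
    sub = design_from_arrays(
        X_raw[train_rows],
        y[train_rows],
        n_unpenalized=design.n_unpenalized,
        column_names=list(design.column_names),
    )
    kept = set(sub.column_names)
    kept_idx = np.array(
        [j for j, nm in enumerate(design.column_names) if nm in kept], dtype=np.intp
    )
    fit = plmm(
        sub,
        penalty=penalty,
        gamma=gamma,
        alpha=alpha,
        precondition=precondition,
        lambdas=lambdas,
        tol=tol,
        max_iter=max_iter,
    )
    X_test = X_raw[np.ix_(test_rows, kept_idx)]
    if predict_method == "blup":
        ctx = BlupContext.from_fit(sub, fit)
        pred = predict_blup(ctx, fit, X_test)
    else:
        pred = predict_linear(fit, X_test)
    err = np.mean((y[test_rows, None] - pred) ** 2, axis=0)
    if return_fit:
        return err, fit.eta, bool(np.all(fit.converged)), fit.beta_original.toarray()
    return err, fit.eta, bool(np.all(fit.converged))


def cv_plmm(
    design: Design,
    penalty: str = "lasso",
    gamma: float | None = None,
    alpha: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: np.ndarray | None = None,
    predict_method: str = "blup",
    precondition: bool = True,
    tol: float = 1e-4,
    max_iter: int = 10_000,
    n_jobs: int = 1,
) -> CvResult:
    """Cross-validate λ for the penalized linear mixed model.

    ``k = n`` gives leave-one-out CV.  ``precondition=False`` cross-validates
    the naive unrotated penalized regression instead (prediction falls back to
    the linear predictor).  Fold execution may be parallelized over
    ``n_jobs``; results are combined in fold order, so serial and parallel
    runs are identical given the same seed.
    """
    n = design.n_samples
    if predict_method not in ("blup", "linear"):
        raise ConfigurationError(f"unknown predict_method {predict_method!r}")
    if not precondition:
        predict_method = "linear"
    folds = assign_folds(n, k, seed)
    min_train = min(int(np.sum(folds != f)) for f in range(1, k + 1))
    if min_train < design.n_unpenalized + 2:
        raise ConfigurationError(
            f"smallest training fold has {min_train} rows; need at least "
            f"{design.n_unpenalized + 2} (unpenalized columns + 2)"
        )

    full_fit = plmm(
        design,
        penalty=penalty,
        gamma=gamma,
        alpha=alpha,
        precondition=precondition,
        lambdas=lambdas,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
        max_iter=max_iter,
    )
    lambdas = full_fit.lambdas

    tasks = []
    for f in range(1, k + 1):
        test_rows = np.flatnonzero(folds == f)
        train_rows = np.flatnonzero(folds != f)
        tasks.append((train_rows, test_rows))

    def run(train_rows, test_rows):
        return _fold_errors(
            design, train_rows, test_rows, lambdas, penalty, gamma, alpha,
            precondition, predict_method, tol, max_iter,
        )

    if n_jobs == 1:
        results = [run(tr, te) for tr, te in tasks]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(run)(tr, te) for tr, te in tasks)

    fold_mse = np.vstack([r[0] for r in results])  # k x L
    cve = fold_mse.mean(axis=0)
    cvse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    lambda_min_index = int(np.argmin(cve))
    within = np.flatnonzero(cve <= cve[lambda_min_index] + cvse[lambda_min_index])
    lambda_1se_index = int(within[0]) if within.size else lambda_min_index

    return CvResult(
        lambdas=lambdas,
        cve=cve,
        cvse=cvse,
        fold_assignments=folds,
        lambda_min_index=lambda_min_index,
        lambda_1se_index=lambda_1se_index,
        fit=full_fit,
        fold_etas=np.array([r[1] for r in results]),
        fold_converged=np.array([r[2] for r in results]),
        seed=seed,
        predict_method=predict_method,
    )
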