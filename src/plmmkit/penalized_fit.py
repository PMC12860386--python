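"""Coordinate-descent path solver for the penalized (whitened) objective.

The objective is ``(1/2n)·‖ỹ − X̃β‖² + Σⱼ pfⱼ·Pλ(βⱼ)`` where ``Pλ`` is the
lasso, MCP or SCAD penalty, optionally mixed with a ridge component via the
elastic-net fraction α (penalty ``α·P + (1−α)·λ·β²/2``); ``pfⱼ = 0`` marks
unpenalized columns (intercept, covariates).

Rotated columns are *not* re-standardized — re-standardizing after whitening
would change the estimand.  Instead each coordinate update uses the column
curvature ``vⱼ = (1/n)·x̃ⱼᵀx̃ⱼ``; the one-dimensional minimizer of
``(v/2)β² − zβ + penalty`` has a closed form for every supported family
(:func:`scalar_update`).  The path runs from λ_max (where the exact solution
is the unpenalized-block least-squares fit with all penalized coefficients
zero, assigned analytically) down a log-spaced grid, warm-starting each λ from
the previous solution and alternating active-set sweeps with full sweeps that
certify no KKT violator is left out.

The inner sweep is compiled with numba and operates on column blocks: for
in-memory designs the whole matrix is a single block, for filebacked designs
blocks are streamed from the memory map.  The per-column operation order is
identical either way, so the two paths agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .design import Design
from .exceptions import ConfigurationError
from .relatedness import EigenRelatedness, compute_grm, eigendecompose
from .variance_components import (
    VarianceComponents,
    build_preconditioner,
    estimate_eta,
    rotate,
)

_FAMILIES = {"lasso": 0, "mcp": 1, "scad": 2}
DEFAULT_GAMMA = {"lasso": np.inf, "mcp": 3.0, "scad": 3.7}


@dataclass
class PenaltySpec:
    """Penalty family + concavity (γ) + elastic-net mixing (α)."""

    family: str = "lasso"
    gamma: float | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        fam = self.family.lower()
        if fam not in _FAMILIES:
            raise ConfigurationError(f"unknown penalty family {self.family!r}")
        self.family = fam
        if self.gamma is None:
            self.gamma = DEFAULT_GAMMA[fam]
        if fam == "mcp" and self.gamma <= 1:
            raise ConfigurationError("MCP requires gamma > 1")
        if fam == "scad" and self.gamma <= 2:
            raise ConfigurationError("SCAD requires gamma > 2")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must be in (0, 1]")

    @property
    def family_code(self) -> int:
        return _FAMILIES[self.family]


def soft_threshold(z: float, t: float) -> float:
    """sign(z)·max(|z| − t, 0)."""
    if t < 0:
        raise ConfigurationError("threshold must be >= 0")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


@njit(cache=True)
def _update_1d(z, lam, pf, alpha, gamma, fam, v):  # pragma: no cover - jitted
    lp = lam * pf
    denom = v + (1.0 - alpha) * lp
    if fam == 0:  # lasso / elastic net
        s = abs(z) - alpha * lp
        if s <= 0.0:
            return 0.0
        return (s if z > 0 else -s) / denom
    if fam == 1:  # MCP firm threshold
        if abs(z) > gamma * lp * denom:
            return z / denom
        s = abs(z) - alpha * lp
        if s <= 0.0:
            return 0.0
        return (s if z > 0 else -s) / (denom - alpha / gamma)
    # SCAD three-piece rule
    if abs(z) <= lp * (denom + alpha):
        s = abs(z) - alpha * lp
        if s <= 0.0:
            return 0.0
        return (s if z > 0 else -s) / denom
    if abs(z) > gamma * lp * denom:
        return z / denom
    s = abs(z) - alpha * gamma * lp / (gamma - 1.0)
    if s <= 0.0:
        return 0.0
    return (s if z > 0 else -s) / (denom - alpha / (gamma - 1.0))


def scalar_update(
    z: float,
    lam: float,
    spec: PenaltySpec,
    v: float = 1.0,
    penalty_factor: float = 1.0,
) -> float:
    """One-dimensional minimizer of (v/2)β² − zβ + α·Pλ·pf(β) + (1−α)·λ·pf·β²/2.

    ``z`` is the partial-residual inner product (1/n)·x̃ⱼᵀr + vⱼβⱼ.
    """
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    return float(
        _update_1d(
            float(z), float(lam), float(penalty_factor), spec.alpha,
            float(spec.gamma), spec.family_code, float(v),
        )
    )


@njit(cache=True)
def _cd_sweep(X, r, beta, mask, lam, pf, alpha, gamma, fam, v):  # pragma: no cover
    n = X.shape[0]
    maxd = 0.0
    for j in range(X.shape[1]):
        if not mask[j] or v[j] <= 0.0:
            continue
        z = 0.0
        for i in range(n):
            z += X[i, j] * r[i]
        z = z / n + v[j] * beta[j]
        b = _update_1d(z, lam, pf[j], alpha, gamma, fam, v[j])
        d = b - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = b
            ad = abs(d) * np.sqrt(v[j])
            if ad > maxd:
                maxd = ad
    return maxd


class _ColumnSource:
    """Uniform block access over an in-memory array or a memory map."""

    def __init__(self, X: np.ndarray, chunk: int | None):
        self.X = X
        self.n, self.p = X.shape
        self.is_mapped = isinstance(X, np.memmap)
        if chunk is None:
            chunk = self.p if not self.is_mapped else 4096
        self.chunk = max(int(chunk), 1)
        if not self.is_mapped:
            self._dense = np.asfortranarray(X)

    def blocks(self):
        if not self.is_mapped and self.chunk >= self.p:
            yield 0, self._dense
            return
        base = self._dense if not self.is_mapped else self.X
        for j0 in range(0, self.p, self.chunk):
            j1 = min(j0 + self.chunk, self.p)
            yield j0, np.asfortranarray(np.array(base[:, j0:j1]))

    def column_sq_means(self) -> np.ndarray:
        v = np.empty(self.p)
        for j0, blk in self.blocks():
            v[j0 : j0 + blk.shape[1]] = np.mean(blk**2, axis=0)
        return v

    def gradient(self, r: np.ndarray) -> np.ndarray:
        g = np.empty(self.p)
        for j0, blk in self.blocks():
            g[j0 : j0 + blk.shape[1]] = blk.T @ r / self.n
        return g

    def matvec(self, beta: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for j0, blk in self.blocks():
            out += blk @ beta[j0 : j0 + blk.shape[1]]
        return out


def _sweep(src: _ColumnSource, r, beta, mask, lam, pf, alpha, gamma, fam, v) -> float:
    maxd = 0.0
    for j0, blk in src.blocks():
        j1 = j0 + blk.shape[1]
        d = _cd_sweep(
            blk, r, beta[j0:j1], mask[j0:j1], lam, pf[j0:j1], alpha, gamma, fam, v[j0:j1]
        )
        maxd = max(maxd, d)
    return maxd


def penalty_value(beta: np.ndarray, lam: float, spec: PenaltySpec, pf: np.ndarray) -> float:
    """Σⱼ α·P(βⱼ; λ·pfⱼ, γ) + (1−α)·λ·pfⱼ·βⱼ²/2."""
    b = np.abs(np.asarray(beta, dtype=np.float64))
    lp = lam * np.asarray(pf, dtype=np.float64)
    alpha, gamma = spec.alpha, spec.gamma
    if spec.family == "lasso":
        core = lp * b
    elif spec.family == "mcp":
        inner = b <= gamma * lp
        core = np.where(inner, lp * b - b**2 / (2.0 * gamma), gamma * lp**2 / 2.0)
    else:  # scad
        core = np.where(
            b <= lp,
            lp * b,
            np.where(
                b <= gamma * lp,
                (2.0 * gamma * lp * b - b**2 - lp**2) / (2.0 * (gamma - 1.0)),
                lp**2 * (gamma + 1.0) / 2.0,
            ),
        )
    return float(np.sum(alpha * core + (1.0 - alpha) * lp * b**2 / 2.0))


def penalized_objective(
    Xt: np.ndarray, yt: np.ndarray, beta: np.ndarray, lam: float,
    spec: PenaltySpec, pf: np.ndarray,
) -> float:
    r = yt - Xt @ beta
    n = yt.shape[0]
    return float(np.sum(r**2) / (2.0 * n)) + penalty_value(beta, lam, spec, pf)


def lambda_path(
    Xt: np.ndarray,
    yt: np.ndarray,
    penalty_factor: np.ndarray,
    alpha: float = 1.0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    chunk_features: int | None = None,
) -> np.ndarray:
    """Log-spaced descending λ sequence from λ_max.

    λ_max = maxⱼ |(1/n)·x̃ⱼᵀr₀| / (α·pfⱼ) over penalized columns, with r₀ the
    rotated outcome residualized on the unpenalized block (including the
    rotated intercept).  The default floor ratio is 0.01 when n > p and 0.05
    otherwise.
    """
    pf = np.asarray(penalty_factor, dtype=np.float64)
    pen = pf > 0
    if not pen.any():
        raise ConfigurationError("all columns unpenalized: no path to compute")
    src = _ColumnSource(Xt, chunk_features)
    n, total = src.n, src.p
    unpen_idx = np.flatnonzero(~pen)
    if unpen_idx.size:
        W = np.array(Xt[:, unpen_idx])
        coef, *_ = np.linalg.lstsq(W, yt, rcond=None)
        r0 = yt - W @ coef
    else:
        r0 = np.asarray(yt, dtype=np.float64)
    grad = src.gradient(r0)
    with np.errstate(divide="ignore"):
        lam_max = float(np.max(np.abs(grad[pen]) / (alpha * pf[pen])))
    if lam_max <= 0:
        lam_max = 1e-3
    if lambda_min_ratio is None:
        p_pen = int(pen.sum())
        lambda_min_ratio = 0.01 if n > p_pen else 0.05
    return np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda)
    )


@dataclass
class PathFit:
    """Rotated-scale coefficients over the λ path (columns of ``beta``)."""

    beta: np.ndarray  # (total, L)
    lambdas: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    objectives: list | None = None


def fit_path(
    Xt: np.ndarray,
    yt: np.ndarray,
    spec: PenaltySpec,
    lambdas: np.ndarray,
    penalty_factor: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 10_000,
    beta_init: np.ndarray | None = None,
    chunk_features: int | None = None,
    record_objective: bool = False,
) -> PathFit:
    """Warm-started coordinate descent over a descending λ sequence.

    Convergence at each λ: max over updated coordinates of |Δβⱼ|·√vⱼ below
    ``tol``·RMS(ỹ).  Non-convergence at ``max_iter`` sweeps is recorded, not
    fatal.  When ``record_objective`` is set, the penalized objective is
    evaluated after every sweep of the first λ below λ_max and returned for
    monotonicity diagnostics.
    """
    yt = np.asarray(yt, dtype=np.float64)
    pf = np.asarray(penalty_factor, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if np.any(np.diff(lambdas) > 0):
        raise ConfigurationError("lambda sequence must be descending")
    src = _ColumnSource(Xt, chunk_features)
    n, total = src.n, src.p
    fam, alpha, gamma = spec.family_code, spec.alpha, float(spec.gamma)
    v = src.column_sq_means()
    thresh = tol * max(float(np.sqrt(np.mean(yt**2))), 1e-12)

    pen = pf > 0
    unpen_idx = np.flatnonzero(~pen)
    beta = np.zeros(total) if beta_init is None else np.array(beta_init, dtype=np.float64)
    if beta_init is None and unpen_idx.size:
        W = np.array(Xt[:, unpen_idx])
        coef, *_ = np.linalg.lstsq(W, yt, rcond=None)
        beta[unpen_idx] = coef
    r = yt - src.matvec(beta)

    # λ at or above which the current null/warm state is already the exact solution
    grad0 = src.gradient(r)
    with np.errstate(divide="ignore"):
        ratios = np.abs(grad0[pen]) / (alpha * pf[pen])
    lam_null = float(np.max(ratios)) if ratios.size else 0.0

    L = lambdas.shape[0]
    B = np.empty((total, L))
    iters = np.zeros(L, dtype=np.int64)
    converged = np.ones(L, dtype=bool)
    objectives: list | None = [] if record_objective else None
    started = False
    all_mask = np.ones(total, dtype=bool)

    for l, lam in enumerate(lambdas):
        if not started and lam >= lam_null * (1.0 - 1e-12) and not np.any(beta[pen] != 0):
            B[:, l] = beta  # exact: KKT holds with the null penalized block
            continue
        started = True
        obj_trace = [] if (record_objective and objectives is not None and not objectives) else None
        it = 0
        while True:
            d_full = _sweep(src, r, beta, all_mask, lam, pf, alpha, gamma, fam, v)
            it += 1
            if obj_trace is not None:
                obj_trace.append(_objective_from_residual(r, beta, lam, spec, pf, n))
            active = (beta != 0.0) | (~pen)
            while it < max_iter:
                d_act = _sweep(src, r, beta, active, lam, pf, alpha, gamma, fam, v)
                it += 1
                if obj_trace is not None:
                    obj_trace.append(_objective_from_residual(r, beta, lam, spec, pf, n))
                if d_act < thresh:
                    break
            d_check = _sweep(src, r, beta, all_mask, lam, pf, alpha, gamma, fam, v)
            it += 1
            if obj_trace is not None:
                obj_trace.append(_objective_from_residual(r, beta, lam, spec, pf, n))
            if d_check < thresh or it >= max_iter:
                break
        iters[l] = it
        converged[l] = it < max_iter
        if obj_trace is not None and objectives is not None:
            objectives.append((float(lam), obj_trace))
        B[:, l] = beta

    return PathFit(beta=B, lambdas=lambdas, iterations=iters, converged=converged,
                   objectives=objectives)


def _objective_from_residual(r, beta, lam, spec, pf, n) -> float:
    return float(np.sum(r**2) / (2.0 * n)) + penalty_value(beta, lam, spec, pf)


def kkt_violation(
    Xt: np.ndarray,
    yt: np.ndarray,
    beta: np.ndarray,
    lam: float,
    penalty_factor: np.ndarray,
    alpha: float = 1.0,
) -> float:
    """Max KKT violation for the lasso / elastic-net objective.

    Zero penalized coefficients must satisfy |(1/n)x̃ⱼᵀr| ≤ αλ·pfⱼ; active ones
    (and unpenalized columns) must zero their subgradient exactly.
    """
    pf = np.asarray(penalty_factor, dtype=np.float64)
    r = yt - Xt @ beta
    n = yt.shape[0]
    g = Xt.T @ r / n
    viol = 0.0
    for j in range(len(beta)):
        if pf[j] == 0 or beta[j] != 0:
            viol = max(
                viol,
                abs(g[j] - alpha * lam * pf[j] * np.sign(beta[j]) - lam * (1 - alpha) * pf[j] * beta[j]),
            )
        else:
            viol = max(viol, abs(g[j]) - alpha * lam * pf[j])
    return float(viol)


def format_coefficients(
    beta_std: np.ndarray, centers: np.ndarray, scales: np.ndarray
) -> np.ndarray:
    """Back-transform standardized-scale coefficients to the raw data scale.

    ``beta_std`` is (1 + m) x L with the intercept in row 0.  Raw-scale slopes
    are βⱼ/scaleⱼ; the intercept absorbs −Σⱼ βⱼ·centerⱼ/scaleⱼ so that
    predictions on raw data equal predictions on standardized data.
    """
    beta_std = np.asarray(beta_std, dtype=np.float64)
    scales = np.asarray(scales, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if scales.shape[0] != beta_std.shape[0] - 1:
        raise ConfigurationError(
            f"{scales.shape[0]} scales for {beta_std.shape[0] - 1} coefficient rows"
        )
    if np.any(scales <= 0):
        raise ConfigurationError("non-positive scale; standardization metadata corrupt")
    out = np.empty_like(beta_std)
    out[1:] = beta_std[1:] / scales[:, None]
    out[0] = beta_std[0] - centers @ out[1:]
    return out


@dataclass
class PlmmFit:
    """Fitted penalized linear mixed model over a λ path.

    ``beta_original`` and ``beta_std`` are sparse (1 + q + p) x L matrices on
    the raw and standardized scales respectively (row 0 = intercept);
    ``linear_predictors`` are on the original outcome scale.
    """

    beta_original: sp.csc_matrix
    beta_std: sp.csc_matrix
    lambdas: np.ndarray
    eta: float
    vc: VarianceComponents | None
    eig: EigenRelatedness | None
    centers: np.ndarray
    scales: np.ndarray
    penalty_factor: np.ndarray
    column_names: list[str]
    linear_predictors: np.ndarray
    y: np.ndarray
    n_unpenalized: int
    iterations: np.ndarray
    converged: np.ndarray
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    design: Design | None = field(default=None, repr=False)

    @property
    def n_lambda(self) -> int:
        return self.lambdas.shape[0]

    def coefficients(self, lambda_index: int) -> dict[str, float]:
        """Raw-scale {name: value} at one λ, nonzero entries only."""
        col = self.beta_original[:, lambda_index].toarray().ravel()
        names = ["(Intercept)"] + self.column_names
        return {nm: float(b) for nm, b in zip(names, col) if b != 0.0}

    def nonzero_counts(self) -> np.ndarray:
        """Number of nonzero *penalized* coefficients at each λ."""
        pen_rows = np.flatnonzero(np.concatenate([[0.0], self.penalty_factor]) > 0)
        sub = self.beta_original[pen_rows]
        return np.asarray((sub != 0).sum(axis=0)).ravel()


def plmm(
    design: Design,
    penalty: str = "lasso",
    gamma: float | None = None,
    alpha: float = 1.0,
    eta: float | None = None,
    precondition: bool = True,
    eig: EigenRelatedness | None = None,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 10_000,
    chunk_features: int | None = None,
    rotated_backing: str | None = None,
) -> PlmmFit:
    """Fit the full penalized linear mixed model pipeline on a design.

    Steps: relatedness K and its eigendecomposition ("prep"), variance-ratio
    estimate η̂ under the null model (unless ``eta`` is given), whitening
    rotation of ``[1, X_std]`` and ``y``, coordinate-descent path fit ("fit"),
    and back-transformation of coefficients to the raw scale ("format").

    ``precondition=False`` skips relatedness entirely and fits an ordinary
    penalized regression on the standardized, unrotated data (η treated as 0);
    useful as the naive comparator.
    """
    spec = PenaltySpec(family=penalty, gamma=gamma, alpha=alpha)
    n = design.n_samples
    q = design.n_unpenalized
    X_std = design.X_std
    y = design.y

    vc = None
    if precondition:
        if eig is None:
            K = compute_grm(design, chunk_features)
            eig = eigendecompose(K, p=design.n_penalized)
        if eta is None:
            vc = estimate_eta(eig, y, design.unpenalized_block() if q else None)
            eta_hat = vc.eta
        else:
            eta_hat = float(eta)
        pc = build_preconditioner(eig, eta_hat)
        ones = np.ones((n, 1))
        if design.storage_mode == "filebacked":
            import tempfile

            if rotated_backing is None:
                fh = tempfile.NamedTemporaryFile(suffix=".rot.bin", delete=False)
                rotated_backing = fh.name
                fh.close()
            Xt_store = np.memmap(
                rotated_backing, dtype=np.float64, mode="w+",
                shape=(n, 1 + X_std.shape[1]), order="F",
            )
            Xt_store[:, :1] = pc.apply(ones)
            _, yt = rotate(pc, X_std, y, out=Xt_store[:, 1:],
                           chunk_features=chunk_features or 4096)
            Xt = Xt_store
        else:
            X_aug = np.concatenate([ones, np.asarray(X_std)], axis=1)
            Xt, yt = rotate(pc, X_aug, y)
    else:
        eta_hat = 0.0
        Xt = np.asfortranarray(
            np.concatenate([np.ones((n, 1)), np.asarray(X_std)], axis=1)
        ) if design.storage_mode == "in_memory" else _augment_memmap(design)
        yt = np.asarray(y, dtype=np.float64)

    pf_aug = np.concatenate([[0.0], design.penalty_factor])
    if lambdas is None:
        lambdas = lambda_path(
            Xt, yt, pf_aug, alpha=spec.alpha, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, chunk_features=chunk_features,
        )
    path = fit_path(
        Xt, yt, spec, lambdas, pf_aug, tol=tol, max_iter=max_iter,
        chunk_features=chunk_features,
    )

    beta_std = path.beta
    beta_orig = format_coefficients(beta_std, design.centers, design.scales)
    # linear predictor on the original outcome scale (equals raw-X predictions)
    lp = np.asarray(design.X_std) @ beta_std[1:] + beta_std[0]

    return PlmmFit(
        beta_original=sp.csc_matrix(beta_orig),
        beta_std=sp.csc_matrix(beta_std),
        lambdas=np.asarray(lambdas, dtype=np.float64),
        eta=eta_hat,
        vc=vc,
        eig=eig,
        centers=design.centers,
        scales=design.scales,
        penalty_factor=design.penalty_factor,
        column_names=design.column_names,
        linear_predictors=lp,
        y=np.asarray(y, dtype=np.float64),
        n_unpenalized=q,
        iterations=path.iterations,
        converged=path.converged,
        penalty=spec,
        design=design,
    )


def _augment_memmap(design: Design) -> np.ndarray:
    """[1, X_std] for a filebacked design, materialized as a temp memmap."""
    import tempfile

    n, m = design.X_std.shape
    fh = tempfile.NamedTemporaryFile(suffix=".aug.bin", delete=False)
    fh.close()
    out = np.memmap(fh.name, dtype=np.float64, mode="w+", shape=(n, m + 1), order="F")
    out[:, 0] = 1.0
    for j0 in range(0, m, 4096):
        out[:, 1 + j0 : 1 + min(j0 + 4096, m)] = design.X_std[:, j0 : j0 + 4096]
    out.flush()
    return out
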