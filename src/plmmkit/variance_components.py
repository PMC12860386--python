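"""Structure variance estimation and whitening preconditioner.

The linear mixed model decomposes the outcome covariance as
``Σ = σ²ₛ K + σ²ε I`` with ``K`` the genomic relatedness matrix.  After
normalizing total variance to 1 this is ``Σ_unit = η K + (1 − η) I`` with a
single parameter ``η = σ²ₛ / (σ²ₛ + σ²ε) ∈ [0, 1]``: the proportion of outcome
variance attributable to sample structure.  Fitted coefficients are invariant
to the overall scale of Σ, so only η matters for the preconditioner; the total
variance is retained for reporting.

η is estimated by maximizing the restricted (residual) profile likelihood of
the *null* model (intercept plus any unpenalized covariates) on the eigenbasis
of K: after rotating by ``Uᵀ`` the covariance is diagonal,
``d_i = η s_i + 1 − η``, each likelihood evaluation is O(n·q²), and the
residual variance profiles out in closed form.  The restricted form is
essential, not cosmetic: column standardization gives K an exact null vector
along the all-ones direction, which the intercept absorbs, so the plain
likelihood gains a spurious ``−½·log(1 − η)`` term and diverges toward η = 1;
the restricted likelihood's ``log det(Wᵀ D⁻¹ W)`` correction cancels that
degeneracy exactly.  A 100-point grid scan brackets the optimum, then a
bounded scalar search refines it.  η is capped below 1 (default 0.999)
because K is singular whenever columns are centered or p < n.

The preconditioner is ``F = diag(w) Uᵀ`` with ``w_i = (η s_i + 1 − η)^{−1/2}``,
so ``F Σ_unit Fᵀ = I``: multiplying the model through by F whitens the errors.
Rows of the rotated data no longer correspond to samples, but columns — and
hence coefficients — keep their meaning.  The rotation destroys the implicit
intercept, so an explicit all-ones column must be rotated along with X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError, DegenerateDataError, SingularityError
from .relatedness import EigenRelatedness

ETA_CAP = 0.999
_MIN_WEIGHT = 1e-12


@dataclass
class VarianceComponents:
    eta: float
    sigma2_s: float
    sigma2_e: float
    loglik_profile: np.ndarray  # (grid_size, 2): eta, profile log-likelihood

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_s + self.sigma2_e


@dataclass
class Preconditioner:
    """Whitening map F = diag(w) Uᵀ for Σ_unit = η K + (1 − η) I."""

    U: np.ndarray
    w: np.ndarray
    eta: float

    def matrix(self) -> np.ndarray:
        return self.w[:, None] * self.U.T

    def apply(self, M: np.ndarray) -> np.ndarray:
        """F @ M for a vector or matrix M (columns rotated independently)."""
        M = np.asarray(M)
        if M.ndim == 1:
            return self.w * (self.U.T @ M)
        return self.w[:, None] * (self.U.T @ M)


def profile_loglik(
    eta: float, S: np.ndarray, y_rot: np.ndarray, W_rot: np.ndarray
) -> float:
    """Restricted profile Gaussian log-likelihood of the null model at a given η.

    ``y_rot`` and ``W_rot`` are the outcome and the fixed-effect block
    (intercept + unpenalized covariates) already rotated by ``Uᵀ``.  The GLS
    coefficients and the total variance are profiled out in closed form; the
    ``log det(Wᵀ D⁻¹ W)`` term restricts the likelihood to the fixed-effect
    residual space, which keeps it bounded when K is singular along a
    direction the fixed effects span (the all-ones direction, after column
    standardization).
    """
    n, m = W_rot.shape
    d = eta * S + (1.0 - eta)
    if np.any(d <= _MIN_WEIGHT):
        return -np.inf
    sw = 1.0 / np.sqrt(d)
    A = W_rot * sw[:, None]
    b = y_rot * sw
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = b - A @ coef
    s2 = float(r @ r) / (n - m)
    if s2 <= 0:
        return np.inf
    sign, logdet = np.linalg.slogdet(A.T @ A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - m) * np.log(2.0 * np.pi * s2)
        + float(np.sum(np.log(d)))
        + logdet
        + (n - m)
    )


def estimate_eta(
    eig: EigenRelatedness,
    y: np.ndarray,
    X_unpen: np.ndarray | None = None,
    grid_size: int = 100,
    eta_max: float = ETA_CAP,
) -> VarianceComponents:
    """Restricted profile-likelihood estimate of η under the null model.

    The null model carries the intercept and any unpenalized covariates.  A
    grid scan over ``[0, eta_max]`` brackets the maximizer; a bounded
    golden-section/Brent refinement polishes it.  Deterministic.
    """
    y = np.asarray(y, dtype=np.float64)
    if float(np.std(y)) < 1e-12:
        raise DegenerateDataError("outcome is constant; variance components undefined")
    n = y.shape[0]
    W = np.ones((n, 1)) if X_unpen is None or X_unpen.size == 0 else np.column_stack(
        [np.ones(n), X_unpen]
    )
    y_rot = eig.U.T @ y
    W_rot = eig.U.T @ W

    grid = np.linspace(0.0, eta_max, grid_size)
    lls = np.array([profile_loglik(e, eig.S, y_rot, W_rot) for e in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda e: -profile_loglik(e, eig.S, y_rot, W_rot),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        eta_hat = float(res.x)
        if profile_loglik(eta_hat, eig.S, y_rot, W_rot) < lls[i]:
            eta_hat = float(grid[i])
    else:
        eta_hat = float(grid[i])

    d = eta_hat * eig.S + (1.0 - eta_hat)
    sw = 1.0 / np.sqrt(d)
    A = W_rot * sw[:, None]
    b = y_rot * sw
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = b - A @ coef
    s2_total = float(r @ r) / (n - W.shape[1])
    return VarianceComponents(
        eta=eta_hat,
        sigma2_s=eta_hat * s2_total,
        sigma2_e=(1.0 - eta_hat) * s2_total,
        loglik_profile=np.column_stack([grid, lls]),
    )


def build_preconditioner(eig: EigenRelatedness, eta: float) -> Preconditioner:
    """F = diag(w) Uᵀ with w_i = (η s_i + 1 − η)^{−1/2}."""
    if not (0.0 <= eta <= 1.0):
        raise ConfigurationError(f"eta must be in [0, 1], got {eta}")
    d = eta * eig.S + (1.0 - eta)
    if np.any(d <= _MIN_WEIGHT):
        raise SingularityError(
            "η s_i + 1 − η is numerically zero for some eigenvalue; "
            f"cap eta below 1 (e.g. {ETA_CAP})"
        )
    return Preconditioner(U=eig.U, w=1.0 / np.sqrt(d), eta=eta)


def rotate(
    pc: Preconditioner,
    X_aug: np.ndarray,
    y: np.ndarray,
    out: np.ndarray | None = None,
    chunk_features: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Whiten: X̃ = F X_aug, ỹ = F y.

    ``X_aug`` must carry an explicit leading all-ones intercept column — the
    rotation destroys the implicit intercept (F·1 is generally not constant).
    Row i of X̃ no longer corresponds to sample i; column j still corresponds
    to feature j.  If ``out`` is given (e.g. a memmap for the out-of-core
    path), columns are rotated in blocks and written into it.
    """
    y = np.asarray(y, dtype=np.float64)
    if X_aug.shape[0] != y.shape[0] or X_aug.shape[0] != pc.U.shape[0]:
        raise ConfigurationError(
            f"shape mismatch: X {X_aug.shape}, y {y.shape}, F {pc.U.shape}"
        )
    y_t = pc.apply(y)
    if out is None and isinstance(X_aug, np.ndarray) and not isinstance(X_aug, np.memmap):
        return np.asfortranarray(pc.apply(X_aug)), y_t
    total = X_aug.shape[1]
    if out is None:
        out = np.empty((X_aug.shape[0], total), order="F")
    for j0 in range(0, total, chunk_features):
        j1 = min(j0 + chunk_features, total)
        out[:, j0:j1] = pc.apply(np.array(X_aug[:, j0:j1]))
    if isinstance(out, np.memmap):
        out.flush()
    return out, y_t
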