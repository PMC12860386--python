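"""Prediction for new samples: linear predictor and BLUP.

The best linear unbiased predictor augments the linear predictor with a
correlation-based adjustment:

    ŷ₂ = X₂β̂ + Σ̂₂₁ Σ̂₁₁⁻¹ (y₁ − X₁β̂)

where Σ̂₁₁ = η K + (1 − η) I is the (unit-total-variance) training covariance
already used in preconditioning, and the cross-relatedness between new and
training samples is K₂₁ = (1/p) X₂ X₁ᵀ over the standardized penalized
features.  The cross-covariance block is Σ̂₂₁ = η K₂₁ plus, for any new sample
that *is* a training sample (matched by sample ID), the shared-noise term
(1 − η) on the matching entry — the covariance of an observation with itself
includes its noise.  For disjoint samples this reduces to η K₂₁; when the new
data are exactly the training data it makes Σ̂₂₁ = Σ̂₁₁ and BLUP returns y₁
identically.

New samples are always standardized with TRAINING centers and scales, never
their own; missing entries become the training mean (0 after standardization).
Σ̂₁₁⁻¹ is applied through the eigendecomposition: U diag(1/(η s + 1 − η)) Uᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Design
from .exceptions import AlignmentError, ConfigurationError
from .penalized_fit import PlmmFit
from .relatedness import EigenRelatedness


@dataclass
class BlupContext:
    """Training-side quantities needed to BLUP-predict new samples."""

    X1_std_pen: np.ndarray  # training standardized penalized block (n x p)
    y1: np.ndarray
    eta: float
    eig: EigenRelatedness
    centers: np.ndarray
    scales: np.ndarray
    n_unpenalized: int
    sample_ids: list | None = None

    @classmethod
    def from_fit(cls, design: Design, fit: PlmmFit) -> "BlupContext":
        if fit.eig is None:
            raise ConfigurationError(
                "fit carries no eigendecomposition; refit with precondition=True"
            )
        return cls(
            X1_std_pen=design.penalized_block(),
            y1=np.asarray(design.y, dtype=np.float64),
            eta=fit.eta,
            eig=fit.eig,
            centers=fit.centers,
            scales=fit.scales,
            n_unpenalized=fit.n_unpenalized,
            sample_ids=list(design.sample_order),
        )


def _standardize_new(
    X2_raw: np.ndarray, centers: np.ndarray, scales: np.ndarray
) -> np.ndarray:
    X2 = np.asarray(X2_raw, dtype=np.float64)
    if X2.shape[1] != centers.shape[0]:
        raise AlignmentError(
            f"new data has {X2.shape[1]} columns; training had {centers.shape[0]}"
        )
    X2 = np.where(np.isnan(X2), centers, X2)
    return (X2 - centers) / scales


def align_features(
    X2_raw: np.ndarray, new_ids: list[str], training_ids: list[str]
) -> np.ndarray:
    """Reorder new-data columns to the training layout; reject missing columns."""
    pos = {fid: j for j, fid in enumerate(new_ids)}
    missing = [fid for fid in training_ids if fid not in pos]
    if missing:
        raise AlignmentError(
            f"new data lacks {len(missing)} training features, e.g. {missing[:5]}"
        )
    idx = np.array([pos[fid] for fid in training_ids])
    return np.asarray(X2_raw)[:, idx]


def predict_linear(
    fit: PlmmFit, X2_raw: np.ndarray, lambda_index: int | None = None
) -> np.ndarray:
    """Raw-scale linear predictor: intercept + X₂β̂ (columns in training order)."""
    X2 = np.asarray(X2_raw, dtype=np.float64)
    B = fit.beta_original.toarray()
    if X2.shape[1] != B.shape[0] - 1:
        raise AlignmentError(
            f"new data has {X2.shape[1]} columns; fit expects {B.shape[0] - 1}"
        )
    X2 = np.where(np.isnan(X2), fit.centers, X2)
    pred = B[0][None, :] + X2 @ B[1:]
    return pred if lambda_index is None else pred[:, lambda_index]


def predict_blup(
    ctx: BlupContext,
    fit: PlmmFit,
    X2_raw: np.ndarray,
    lambda_index: int | None = None,
    sample_ids: list | None = None,
) -> np.ndarray:
    """BLUP: linear predictor plus the relatedness-based adjustment.

    ``sample_ids`` (optional) are the identities of the new samples; entries
    matching training sample IDs receive the shared-noise (1 − η) term in
    Σ̂₂₁.  Omit it for genuinely new samples.
    """
    eta = ctx.eta
    X2_std = _standardize_new(X2_raw, ctx.centers, ctx.scales)
    X2_pen = X2_std[:, ctx.n_unpenalized :]
    p = ctx.X1_std_pen.shape[1]
    lin2 = predict_linear(fit, X2_raw, lambda_index=None)

    K21 = X2_pen @ np.asarray(ctx.X1_std_pen).T / p
    Sigma21 = eta * K21
    if sample_ids is not None and ctx.sample_ids is not None and eta < 1.0:
        train_pos = {sid: i for i, sid in enumerate(ctx.sample_ids)}
        for i2, sid in enumerate(sample_ids):
            i1 = train_pos.get(sid)
            if i1 is not None:
                Sigma21[i2, i1] += 1.0 - eta

    resid = ctx.y1[:, None] - fit.linear_predictors  # n x L
    d = eta * ctx.eig.S + (1.0 - eta)
    inv_resid = ctx.eig.U @ ((ctx.eig.U.T @ resid) / d[:, None])
    pred = lin2 + Sigma21 @ inv_resid
    return pred if lambda_index is None else pred[:, lambda_index]


def predict(
    ctx: BlupContext | None,
    fit: PlmmFit,
    X2_raw: np.ndarray,
    method: str = "blup",
    lambda_index: int | None = None,
    sample_ids: list | None = None,
) -> np.ndarray:
    """Dispatch to BLUP (default) or the plain linear predictor."""
    if method == "blup":
        if ctx is None:
            raise ConfigurationError("BLUP prediction requires a BlupContext")
        return predict_blup(ctx, fit, X2_raw, lambda_index, sample_ids)
    if method == "linear":
        return predict_linear(fit, X2_raw, lambda_index)
    raise ConfigurationError(f"unknown prediction method {method!r}")
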