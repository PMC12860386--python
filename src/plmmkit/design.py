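"""Build a standardized, outcome-aligned model design.

``create_design`` merges a :class:`~plmmkit.io_plink.GenotypeMatrix` with an
outcome table by sample ID, applies a minor-allele-frequency filter, attaches
unpenalized covariates (sex, age, site, ...) and column-standardizes
everything.  Standardization uses the population (1/n) convention for the
scale, i.e. every retained column of ``X_std`` has mean 0 and mean square 1;
this makes ``trace(K) = n`` exact for the relatedness matrix built downstream.

Missing dosages are imputed to the column mean computed from observed entries
(so imputed entries are exactly 0 on the standardized scale); allele
frequencies for the MAF filter are likewise computed from observed alleles
only, before imputation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, IntegrityError
from .io_plink import GenotypeMatrix

logger = logging.getLogger(__name__)

_ZERO_SCALE_TOL = 1e-12


def standardize_column(x: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """Impute missing entries to the column mean, center, and scale to mean square 1.

    Returns ``(x_std, center, scale, is_constant)``.  A column whose centered
    mean square is (numerically) zero — including an all-missing column — is
    flagged constant; its ``x_std`` is returned as zeros and callers drop it.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 2:
        raise ConfigurationError("standardization needs at least 2 samples")
    miss = np.isnan(x)
    if miss.all():
        return np.zeros_like(x), 0.0, 0.0, True
    center = float(np.mean(x[~miss]))
    filled = np.where(miss, center, x) - center
    scale = float(np.sqrt(np.mean(filled**2)))
    if scale < _ZERO_SCALE_TOL:
        return np.zeros_like(x), center, 0.0, True
    return filled / scale, center, scale, False


@dataclass
class Design:
    """Model-ready standardized design: covariate block first, then features.

    ``X_std`` has ``q`` unpenalized covariate columns followed by ``p``
    penalized feature columns; rows of ``X_std``, ``X_raw`` and entries of
    ``y`` all follow ``sample_order``.  ``X_raw`` keeps the aligned raw values
    (``NaN`` for missing) so cross-validation can redo standardization inside
    every fold.
    """

    X_std: np.ndarray
    X_raw: np.ndarray
    y: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    penalty_factor: np.ndarray
    column_names: list[str]
    kept_feature_ids: list[str]
    dropped_features: list[tuple[str, str]]
    sample_order: list[tuple[str, str]]
    n_unpenalized: int
    storage_mode: str = "in_memory"
    dropped_samples: int = 0

    @property
    def n_samples(self) -> int:
        return self.X_std.shape[0]

    @property
    def n_penalized(self) -> int:
        return self.X_std.shape[1] - self.n_unpenalized

    def penalized_block(self) -> np.ndarray:
        return self.X_std[:, self.n_unpenalized :]

    def unpenalized_block(self) -> np.ndarray:
        return self.X_std[:, : self.n_unpenalized]


def _minor_allele_frequency(x: np.ndarray) -> float:
    """MAF from observed (non-missing) dosages, assuming allele-count coding."""
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        return 0.0
    af = float(np.mean(obs)) / 2.0
    return min(af, 1.0 - af)


def create_design(
    g: GenotypeMatrix,
    outcome_table: pd.DataFrame,
    outcome_id: str,
    outcome_col: str,
    unpenalized: list[str] | None = None,
    maf_min: float = 0.0,
    maf_filter: bool | None = None,
    backing_path: str | Path | None = None,
    chunk_features: int = 4096,
) -> Design:
    """Merge genotypes with an outcome table, filter, and standardize.

    Samples are the ID intersection (matched on individual ID), kept in
    genotype order; samples lacking an outcome are dropped and counted.
    Features are dropped with reason ``"maf"`` when their observed minor
    allele frequency is below ``maf_min`` (only applied when ``maf_filter`` is
    true, which defaults to ``maf_min > 0``) and with reason ``"zero_variance"``
    when constant.  Unpenalized covariates from the outcome table get
    ``penalty_factor`` 0 and come first in ``X_std``.

    When ``g`` is filebacked (or ``backing_path`` is given) the standardized
    and raw matrices are written to flat binary files next to ``backing_path``
    and memory-mapped, chunking over ``chunk_features`` columns at a time.
    """
    unpenalized = list(unpenalized or [])
    if not (0.0 <= maf_min < 0.5):
        raise ConfigurationError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if maf_filter is None:
        maf_filter = maf_min > 0.0

    if outcome_id not in outcome_table.columns:
        raise AlignmentError(
            f"outcome ID column {outcome_id!r} not in table columns "
            f"{list(outcome_table.columns)}"
        )
    for col in [outcome_col, *unpenalized]:
        if col not in outcome_table.columns:
            raise AlignmentError(
                f"column {col!r} not in outcome table columns {list(outcome_table.columns)}"
            )
    tab = outcome_table.copy()
    tab[outcome_id] = tab[outcome_id].astype(str)
    if tab[outcome_id].duplicated().any():
        dup = tab.loc[tab[outcome_id].duplicated(), outcome_id].iloc[0]
        raise IntegrityError(f"duplicate ID {dup!r} in outcome table")
    tab = tab.set_index(outcome_id)

    if not pd.api.types.is_numeric_dtype(tab[outcome_col]):
        coerced = pd.to_numeric(tab[outcome_col], errors="coerce")
        if coerced.isna()[tab[outcome_col].notna()].any():
            raise TypeError(f"outcome column {outcome_col!r} is not numeric")
        tab[outcome_col] = coerced

    geno_iids = [iid for _, iid in g.sample_ids]
    have = set(tab.index) & set(geno_iids)
    keep_rows = [i for i, iid in enumerate(geno_iids) if iid in have]
    if not keep_rows:
        raise AlignmentError("no sample IDs shared between genotypes and outcome table")
    dropped_samples = g.n_samples - len(keep_rows)
    if dropped_samples:
        logger.info("dropping %d samples without an outcome", dropped_samples)
    sample_order = [g.sample_ids[i] for i in keep_rows]
    kept_iids = [iid for _, iid in sample_order]
    aligned = tab.loc[kept_iids]
    y = aligned[outcome_col].to_numpy(dtype=np.float64)
    if np.isnan(y).any():
        bad = [kept_iids[i] for i in np.flatnonzero(np.isnan(y))[:5]]
        raise IntegrityError(f"missing outcome values for samples {bad}")

    cov_raw = (
        aligned[unpenalized].to_numpy(dtype=np.float64)
        if unpenalized
        else np.empty((len(keep_rows), 0))
    )

    row_idx = np.asarray(keep_rows)
    n = len(keep_rows)
    q = cov_raw.shape[1]

    filebacked = g.storage_mode == "filebacked" or backing_path is not None
    if filebacked and backing_path is None:
        backing_path = Path(str(g.backing_path) + ".design")
    # First pass: decide which feature columns survive, collect centers/scales.
    kept_idx: list[int] = []
    dropped: list[tuple[str, str]] = []
    feat_centers: list[float] = []
    feat_scales: list[float] = []
    for j0, block in g.iter_column_blocks(chunk_features):
        block = block[row_idx]
        for k in range(block.shape[1]):
            j = j0 + k
            fid = g.feature_ids[j]
            col = block[:, k]
            if maf_filter and _minor_allele_frequency(col) < maf_min:
                dropped.append((fid, "maf"))
                continue
            _, center, scale, const = standardize_column(col)
            if const:
                dropped.append((fid, "zero_variance"))
                continue
            kept_idx.append(j)
            feat_centers.append(center)
            feat_scales.append(scale)
    kept_feature_ids = [g.feature_ids[j] for j in kept_idx]
    if dropped:
        logger.info(
            "dropped %d features (%s)",
            len(dropped),
            ", ".join(sorted({r for _, r in dropped})),
        )

    # Covariate block: standardized like features; constants dropped too.
    cov_cols: list[np.ndarray] = []
    cov_raw_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    cov_centers: list[float] = []
    cov_scales: list[float] = []
    for k, name in enumerate(unpenalized):
        xs, center, scale, const = standardize_column(cov_raw[:, k])
        if const:
            dropped.append((name, "zero_variance"))
            continue
        cov_cols.append(xs)
        cov_raw_cols.append(cov_raw[:, k])
        cov_names.append(name)
        cov_centers.append(center)
        cov_scales.append(scale)
    q = len(cov_cols)

    p = len(kept_idx)
    total = q + p
    if filebacked:
        backing_path = Path(backing_path)
        X_std = np.memmap(
            backing_path.with_suffix(".xstd.bin"), dtype=np.float64, mode="w+",
            shape=(n, total), order="F",
        )
        X_raw = np.memmap(
            backing_path.with_suffix(".xraw.bin"), dtype=np.float64, mode="w+",
            shape=(n, total), order="F",
        )
    else:
        X_std = np.empty((n, total), order="F")
        X_raw = np.empty((n, total), order="F")

    for k in range(q):
        X_std[:, k] = cov_cols[k]
        X_raw[:, k] = cov_raw_cols[k]

    kept_arr = np.asarray(kept_idx, dtype=np.intp)
    out_j = q
    for j0 in range(0, p, chunk_features):
        sel = kept_arr[j0 : j0 + chunk_features]
        block = np.array(g.dosages[:, sel][row_idx]) if sel.size else np.empty((n, 0))
        for k in range(block.shape[1]):
            col = block[:, k]
            center = feat_centers[j0 + k]
            scale = feat_scales[j0 + k]
            filled = np.where(np.isnan(col), center, col)
            X_std[:, out_j] = (filled - center) / scale
            X_raw[:, out_j] = col
            out_j += 1

    if filebacked:
        X_std.flush()
        X_raw.flush()
        meta = {
            "shape": [n, total],
            "n_unpenalized": q,
            "column_names": cov_names + kept_feature_ids,
        }
        backing_path.with_suffix(".design.json").write_text(json.dumps(meta))

    centers = np.array(cov_centers + feat_centers)
    scales = np.array(cov_scales + feat_scales)
    penalty_factor = np.concatenate([np.zeros(q), np.ones(p)])
    return Design(
        X_std=X_std,
        X_raw=X_raw,
        y=y,
        centers=centers,
        scales=scales,
        penalty_factor=penalty_factor,
        column_names=cov_names + kept_feature_ids,
        kept_feature_ids=kept_feature_ids,
        dropped_features=dropped,
        sample_order=sample_order,
        n_unpenalized=q,
        storage_mode="filebacked" if filebacked else "in_memory",
        dropped_samples=dropped_samples,
    )


def design_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str] | None = None,
    n_unpenalized: int = 0,
    column_names: list[str] | None = None,
) -> Design:
    """Standardize an already-aligned (X, y) pair into a :class:`Design`.

    The first ``n_unpenalized`` columns of ``X`` are treated as covariates.
    This is the programmatic shortcut mirroring a plain ``(x, y)`` model call;
    constant columns are dropped with reason ``"zero_variance"``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, total = X.shape
    if y.shape[0] != n:
        raise AlignmentError(f"X has {n} rows but y has {y.shape[0]} entries")
    if column_names is None:
        if feature_ids is not None:
            column_names = [f"cov{k}" for k in range(n_unpenalized)] + list(feature_ids)
        else:
            column_names = [f"x{j}" for j in range(total)]
    cols, raw_cols, centers, scales, names = [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    q_kept = 0
    for j in range(total):
        xs, center, scale, const = standardize_column(X[:, j])
        if const:
            dropped.append((column_names[j], "zero_variance"))
            continue
        cols.append(xs)
        raw_cols.append(X[:, j])
        centers.append(center)
        scales.append(scale)
        names.append(column_names[j])
        if j < n_unpenalized:
            q_kept += 1
    X_std = np.asfortranarray(np.column_stack(cols)) if cols else np.empty((n, 0))
    X_raw = np.asfortranarray(np.column_stack(raw_cols)) if raw_cols else np.empty((n, 0))
    p = X_std.shape[1] - q_kept
    return Design(
        X_std=X_std,
        X_raw=X_raw,
        y=y,
        centers=np.array(centers),
        scales=np.array(scales),
        penalty_factor=np.concatenate([np.zeros(q_kept), np.ones(p)]),
        column_names=names,
        kept_feature_ids=names[q_kept:],
        dropped_features=dropped,
        sample_order=[(str(i), str(i)) for i in range(n)],
        n_unpenalized=q_kept,
    )
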