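"""Structured genotype/phenotype simulation for building and testing the model.

The generator produces exactly the kinds of latent sample correlation the
mixed model targets: ancestry strata (per-population allele-frequency
perturbation in the Balding–Nichols style), family blocks (children drawn
Mendelianly from two shared pseudo-parents, so within-family genotype
correlation exceeds between-family), uniform missingness, and sparse causal
effects.  Phenotypes follow the generative model

    y = X_causal β + u + ε,   u ~ N(0, η σ² K),   ε ~ N(0, (1 − η) σ² I)

with ``K`` the realized relatedness of the simulated genotypes, so η is the
true proportion of outcome variance due to structure and estimator-recovery
tests have a known truth.  Everything is deterministic given the seed.

The ``confounded`` flag makes a slice of *null* features strongly stratified
(large between-population frequency differences) while causal features are
drawn from the weakly stratified remainder: because u loads on population
structure, those null features correlate with y, which is exactly the
false-positive trap a naive independent-observations lasso falls into.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import design_from_arrays, standardize_column
from .exceptions import ConfigurationError
from .io_plink import GenotypeMatrix
from .relatedness import eigendecompose


@dataclass
class SimSpec:
    """Knobs of the generative model; defaults give a moderately structured cohort."""

    n_samples: int = 300
    n_features: int = 2000
    n_causal: int = 5
    beta_effect: float = 0.5
    eta_true: float = 0.5
    n_families: int | None = None  # default: families of ~4
    n_populations: int = 2
    fst_like_divergence: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    confounded: bool = False
    confounded_fraction: float = 0.1
    sigma2_total: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_causal <= self.n_features):
            raise ConfigurationError("need 0 <= n_causal <= n_features")
        if not (0.0 <= self.eta_true <= 1.0):
            raise ConfigurationError("eta_true must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie inside (0, 0.5]")
        if self.n_families is None:
            self.n_families = max(self.n_samples // 4, 1)
        if self.n_families > self.n_samples:
            raise ConfigurationError("more families than samples")


def _population_frequencies(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_populations, n_features) allele frequencies, Balding–Nichols perturbed."""
    lo, hi = spec.maf_range
    base = rng.uniform(lo, hi, size=spec.n_features)
    F = spec.fst_like_divergence
    if F <= 0 or spec.n_populations == 1:
        return np.tile(base, (spec.n_populations, 1))
    a = base * (1.0 - F) / F
    b = (1.0 - base) * (1.0 - F) / F
    freqs = rng.beta(a, b, size=(spec.n_populations, spec.n_features))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Family-structured, population-stratified dosage matrix (0/1/2, NaN missing)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    freqs = _population_frequencies(spec, rng)

    confounded_mask = np.zeros(p, dtype=bool)
    if spec.confounded and spec.n_populations > 1:
        n_conf = max(int(round(spec.confounded_fraction * p)), 1)
        confounded_mask[rng.choice(p, size=n_conf, replace=False)] = True
        # strongly stratified null features: push frequencies apart across pops
        shifts = np.linspace(-0.3, 0.3, spec.n_populations)
        for c in range(spec.n_populations):
            freqs[c, confounded_mask] = np.clip(
                freqs[c, confounded_mask] + shifts[c], 0.02, 0.98
            )

    # families round-robin over populations; members contiguous
    fam_of_sample = np.sort(np.arange(n) % spec.n_families)
    pop_of_family = np.arange(spec.n_families) % spec.n_populations

    dosages = np.empty((n, p))
    for fam in range(spec.n_families):
        members = np.flatnonzero(fam_of_sample == fam)
        if members.size == 0:
            continue
        f = freqs[pop_of_family[fam]]
        haplotypes = (rng.random((4, p)) < f).astype(np.float64)  # 2 parents x 2
        for i in members:
            m = rng.integers(0, 2, size=p)
            d = rng.integers(0, 2, size=p)
            dosages[i] = haplotypes[m, np.arange(p)] + haplotypes[2 + d, np.arange(p)]

    if spec.missing_rate > 0:
        dosages[rng.random((n, p)) < spec.missing_rate] = np.nan

    pops = pop_of_family[fam_of_sample]
    sample_ids = [(f"fam{fam_of_sample[i]}", f"id{i}") for i in range(n)]
    feature_ids = [f"snp{j}" for j in range(p)]
    return GenotypeMatrix(
        dosages,
        sample_ids,
        feature_ids,
        sample_groups={
            "family": fam_of_sample,
            "population": pops,
            "confounded_features": np.flatnonzero(confounded_mask),
        },
    )


def simulate_phenotype(
    g: GenotypeMatrix, spec: SimSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict]:
    """Draw y = X_causal β + u + ε from the mixed model on the realized K.

    Returns ``(y, truth)`` where ``truth`` records causal feature ids, their
    raw effect vector on the standardized scale, and the true η.  ``u`` is
    drawn in the eigenbasis of K as U·diag(√(η σ² s))·z, so Var(u) = η σ² K
    exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n, p = g.dosages.shape
    X_std = np.empty((n, p))
    keep = np.ones(p, dtype=bool)
    for j in range(p):
        xs, _, _, const = standardize_column(np.asarray(g.dosages[:, j]))
        X_std[:, j] = xs
        keep[j] = not const

    candidates = np.flatnonzero(keep)
    if g.sample_groups is not None and len(g.sample_groups.get("confounded_features", [])):
        conf = set(g.sample_groups["confounded_features"].tolist())
        clean = np.array([j for j in candidates if j not in conf])
        candidates = clean if clean.size >= spec.n_causal else candidates
    causal = rng.choice(candidates, size=spec.n_causal, replace=False) if spec.n_causal else np.array([], dtype=int)
    beta = np.full(spec.n_causal, spec.beta_effect)
    signs = rng.choice([-1.0, 1.0], size=spec.n_causal)
    beta = beta * signs

    K = X_std[:, keep] @ X_std[:, keep].T / max(int(keep.sum()), 1)
    eig = eigendecompose((K + K.T) / 2.0)
    s2 = spec.sigma2_total
    z = rng.standard_normal(n)
    u = eig.U @ (np.sqrt(np.clip(spec.eta_true * s2 * eig.S, 0.0, None)) * z)
    eps = rng.standard_normal(n) * np.sqrt((1.0 - spec.eta_true) * s2)
    y = X_std[:, causal] @ beta + u + eps

    truth = {
        "causal_features": [g.feature_ids[j] for j in causal],
        "causal_indices": causal.tolist(),
        "beta": beta.tolist(),
        "eta": spec.eta_true,
        "sigma2_total": s2,
    }
    return y, truth


def simulate_dataset(spec: SimSpec):
    """Convenience: genotypes + phenotype + aligned Design in one call.

    Returns ``(g, y, truth, design)``; the design has no unpenalized
    covariates and no MAF filter applied.
    """
    g = simulate_genotypes(spec)
    y, truth = simulate_phenotype(g, spec)
    design = design_from_arrays(
        np.asarray(g.dosages), y, feature_ids=list(g.feature_ids)
    )
    return g, y, truth, design
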