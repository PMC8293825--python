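"""Synthetic genotype/phenotype generation.

The study data this package was designed around (individual genotypes with
adjusted molecular-phenotype residuals) are access-restricted, so every
pipeline stage is exercised on simulated data with the same statistical
structure: Hardy-Weinberg additive dosages at specified minor allele
frequencies, a large panel of null SNPs, optional Balding-Nichols
population substructure (so genuinely divergent multi-SNP genotypes exist
for the leverage diagnostics), and a unit-variance phenotype built directly
on the residual scale as ``y = sum_k a_k g_k + noise``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import SnpEffect, explained_variance

__all__ = [
    "PopulationStructure",
    "ArchitectureSpec",
    "defb119_architecture",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "inject_outliers",
]

#: MAF / per-allele effect pairs of the three SNPs associated with the
#: DEFB119 protein residuals, jointly explaining 10% of phenotype variance.
#: Used as the default simulation architecture throughout.
DEFB119_EFFECTS = (
    SnpEffect("rs9296004", maf=0.082, effect=0.606),
    SnpEffect("rs11845244", maf=0.354, effect=0.241),
    SnpEffect("rs12301299", maf=0.163, effect=0.254),
)


@dataclass(frozen=True)
class PopulationStructure:
    """Balding-Nichols substructure: subpopulation allele frequencies are
    drawn from a Beta distribution around each ancestral MAF with the given
    fixation index."""

    n_subpops: int = 3
    fst: float = 0.05
    mixture: tuple[float, ...] = (0.49, 0.49, 0.02)

    def __post_init__(self) -> None:
        if self.n_subpops < 2:
            raise ValueError("need at least 2 subpopulations")
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"F_ST must lie in (0,1), got {self.fst}")
        if len(self.mixture) != self.n_subpops:
            raise ValueError("mixture length must equal n_subpops")
        if abs(sum(self.mixture) - 1.0) > 1e-8 or min(self.mixture) <= 0:
            raise ValueError("mixture fractions must be positive and sum to 1")


@dataclass
class ArchitectureSpec:
    """Genetic architecture of a simulated phenotype.

    ``causal`` lists the associated SNPs (MAF + per-allele effect);
    ``n_null`` non-associated SNPs are added with MAFs uniform in
    ``null_maf_range``.  ``structure`` optionally adds population
    substructure so that divergent genotypes exist.
    """

    causal: list[SnpEffect]
    n_null: int = 1000
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    structure: Optional[PopulationStructure] = None
    n: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.causal = list(self.causal)
        if self.n_null < 0:
            raise ValueError("n_null must be nonnegative")
        lo, hi = self.null_maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ValueError(f"null MAF range must lie within [0.01, 0.5], got {self.null_maf_range}")
        if self.n < 1:
            raise ValueError("need at least one individual")
        if self.causal and explained_variance(self.causal) >= 1.0:
            raise ValueError("total explained variance of the causal SNPs must be < 1")

    @property
    def explained_variance(self) -> float:
        return explained_variance(self.causal) if self.causal else 0.0

    @property
    def causal_ids(self) -> list[str]:
        return [e.snp_id for e in self.causal]


def defb119_architecture(
    n: int = 3301,
    n_null: int = 1000,
    structure: bool = True,
    seed: int = 0,
) -> ArchitectureSpec:
    """Default emulation preset: a pool of ``n`` individuals, the three
    DEFB119-associated SNPs, and ``n_null`` independent null SNPs.

    With ``structure=True`` a small (2% mass) third subpopulation is
    included so that an identifiable divergent genotype exists in most
    500-individual subsamples.
    """
    return ArchitectureSpec(
        causal=list(DEFB119_EFFECTS),
        n_null=n_null,
        structure=PopulationStructure() if structure else None,
        n=n,
        seed=seed,
    )


def _balding_nichols_freqs(
    mafs: np.ndarray, structure: PopulationStructure, rng: np.random.Generator
) -> np.ndarray:
    """Subpopulation allele frequencies, shape (n_subpops, n_snps)."""
    f = structure.fst
    scale = (1.0 - f) / f
    alpha = mafs * scale
    beta = (1.0 - mafs) * scale
    freqs = rng.beta(alpha, beta, size=(structure.n_subpops, len(mafs)))
    # keep frequencies polymorphic
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def simulate_genotypes(
    spec: ArchitectureSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an (n x p) additive dosage matrix plus per-SNP metadata.

    Without substructure each dosage is Binomial(2, MAF) (Hardy-Weinberg).
    With substructure, individuals are assigned to subpopulations by the
    mixture fractions and dosages are Binomial(2, subpop frequency), the
    subpop frequencies following the Balding-Nichols Beta distribution.

    Returns
    -------
    G : ndarray of shape (n, p)
        Dosages in {0, 1, 2}; causal SNPs first, then null SNPs.
    meta : DataFrame
        Columns ``snp_id``, ``maf``, ``effect``, ``is_causal`` and, with
        substructure, a per-individual ``subpop`` array in ``meta.attrs``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.null_maf_range
    null_mafs = rng.uniform(lo, hi, size=spec.n_null)
    mafs = np.concatenate([[e.maf for e in spec.causal], null_mafs])
    effects = np.concatenate([[e.effect for e in spec.causal], np.zeros(spec.n_null)])
    ids = spec.causal_ids + [f"null_{i:04d}" for i in range(spec.n_null)]

    meta = pd.DataFrame(
        {
            "snp_id": ids,
            "maf": mafs,
            "effect": effects,
            "is_causal": [True] * len(spec.causal) + [False] * spec.n_null,
        }
    )

    if spec.structure is None:
        G = rng.binomial(2, mafs[None, :], size=(spec.n, len(mafs))).astype(float)
    else:
        freqs = _balding_nichols_freqs(mafs, spec.structure, rng)
        subpop = rng.choice(
            spec.structure.n_subpops, size=spec.n, p=spec.structure.mixture
        )
        G = rng.binomial(2, freqs[subpop, :]).astype(float)
        meta.attrs["subpop"] = subpop
    return G, meta


def simulate_phenotype(
    G: np.ndarray,
    spec: ArchitectureSpec,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Unit-variance phenotype on the residual scale.

    ``y_i = sum_k a_k g_ik + eps_i`` with Gaussian noise of variance
    ``1 - explained_variance(causal)``, so total variance is ~1 and the
    realized genetic variance share matches the architecture.  The causal
    SNPs are assumed to occupy the first columns of ``G`` (as produced by
    :func:`simulate_genotypes`).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    m = len(spec.causal)
    if G.shape[1] < m:
        raise ValueError("genotype matrix does not contain the causal SNPs")
    ev = spec.explained_variance
    if ev >= 1.0:
        raise ValueError(f"explained variance must be < 1, got {ev}")
    if m:
        effects = np.array([e.effect for e in spec.causal])
        mafs = np.array([e.maf for e in spec.causal])
        # center by the expected dosage so y sits on the residual (zero-mean) scale
        genetic = (G[:, :m] - 2.0 * mafs) @ effects
    else:
        genetic = np.zeros(G.shape[0])
    return genetic + rng.normal(0.0, np.sqrt(1.0 - ev), size=G.shape[0])


def simulate_dataset(
    spec: ArchitectureSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Convenience wrapper: seeded genotypes and phenotype in one call."""
    rng = np.random.default_rng(spec.seed)
    G, meta = simulate_genotypes(spec, rng)
    y = simulate_phenotype(G, spec, rng)
    return G, y, meta


def inject_outliers(y: np.ndarray, indices: Sequence[int], value: float) -> np.ndarray:
    """Return a copy of ``y`` with the phenotype at ``indices`` *replaced*
    (not shifted) by the artificial residual ``value``."""
    y = np.asarray(y, dtype=float)
    idx = np.asarray(indices, dtype=int)
    if idx.ndim == 0:
        idx = idx[None]
    if len(np.unique(idx)) != len(idx):
        raise ValueError("outlier indices must be distinct")
    if idx.size and (idx.min() < 0 or idx.max() >= len(y)):
        raise ValueError(f"outlier index out of range [0, {len(y)})")
    out = y.copy()
    out[idx] = value
    return out
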