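"""Evaluation statistics for the LASSO comparison study.

Covers the additive-locus explained variance, Jaccard concordance of
selected-SNP sets, false/true-positive rates over simulation iterations,
Fisher-consistent rank correlations and percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SnpEffect",
    "SelectionHistory",
    "explained_variance",
    "jaccard",
    "mean_pairwise_jaccard",
    "false_positive_rate",
    "true_positive_rate",
    "kendall_fisher",
    "spearman_fisher",
    "squared_correlation",
    "empirical_ci",
]


@dataclass(frozen=True)
class SnpEffect:
    """A SNP's minor allele frequency and per-allele effect size.

    ``effect`` is expressed in phenotype standard deviations per copy of
    the minor allele.  A list of these records defines a phenotype's
    genetic architecture.
    """

    snp_id: str
    maf: float
    effect: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF must lie in (0, 0.5], got {self.maf}")
        if not np.isfinite(self.effect):
            raise ValueError(f"effect size must be finite, got {self.effect}")

    @property
    def variance_contribution(self) -> float:
        """``2 * maf * (1 - maf) * effect**2`` — see :func:`explained_variance`."""
        return 2.0 * self.maf * (1.0 - self.maf) * self.effect**2


@dataclass
class SelectionHistory:
    """Selected-SNP sets over simulation iterations, against a truth split.

    ``associated`` and ``null`` must be disjoint; every selected SNP must
    belong to their union (covariates are excluded upstream).
    """

    selections: list[set]
    associated: set
    null: set

    def __post_init__(self) -> None:
        self.selections = [set(s) for s in self.selections]
        self.associated = set(self.associated)
        self.null = set(self.null)
        if self.associated & self.null:
            raise ValueError("associated and null SNP sets must be disjoint")
        universe = self.associated | self.null
        for i, sel in enumerate(self.selections):
            stray = sel - universe
            if stray:
                raise ValueError(
                    f"iteration {i} selected SNPs outside the associated/null "
                    f"universe: {sorted(stray)[:5]}"
                )


def explained_variance(effects: Iterable[SnpEffect]) -> float:
    """Total phenotype variance explained by additive biallelic loci.

    Computed as ``sum_k 2 * MAF_k * (1 - MAF_k) * a_k**2``, the textbook
    variance contribution of an additive locus in Hardy-Weinberg
    equilibrium with per-allele effect ``a_k`` on a unit-variance
    phenotype.  Note the effect size enters *squared*: this is what
    reproduces the published per-SNP explained variances from the printed
    (MAF, effect) pairs, even though shorthand statements of the formula
    sometimes omit the exponent.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("need at least one SnpEffect")
    return float(sum(e.variance_contribution for e in effects))


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B| between two selected-SNP sets.

    1 means identical predictor sets, 0 means no shared predictor.  Two
    empty sets are defined as identical (index 1).
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def mean_pairwise_jaccard(selections: Sequence[Iterable]) -> float:
    """Average Jaccard index over all unordered pairs of selected sets.

    With 100 iterations this averages over 100*99/2 = 4950 pairs and
    quantifies the cross-iteration concordance of the fitted models.
    """
    sets = [set(s) for s in selections]
    if len(sets) < 2:
        raise ValueError("need at least two selected sets")
    return float(np.mean([jaccard(a, b) for a, b in combinations(sets, 2)]))


def false_positive_rate(history: SelectionHistory) -> float:
    """Mean over iterations of (selected null SNPs) / (total null SNPs)."""
    if not history.null:
        raise ValueError("null SNP set is empty")
    n_null = len(history.null)
    return float(
        np.mean([len(sel & history.null) / n_null for sel in history.selections])
    )


def true_positive_rate(history: SelectionHistory, snp_id: str) -> float:
    """Fraction of iterations in which an associated SNP was selected."""
    if snp_id not in history.associated:
        raise ValueError(f"{snp_id!r} is not in the associated SNP set")
    return float(np.mean([snp_id in sel for sel in history.selections]))


def _check_rank_inputs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input vector")
    return x, y


def kendall_fisher(x, y) -> float:
    """Fisher-consistent version of Kendall's correlation.

    Returns ``sin(pi * tau_b / 2)`` where ``tau_b`` is the tie-corrected
    Kendall rank correlation: under a bivariate normal this estimates the
    Pearson correlation while remaining robust.  The signed coefficient is
    returned; square it (or use :func:`squared_correlation`) for the
    prediction-accuracy measure.
    """
    x, y = _check_rank_inputs(x, y)
    tau = stats.kendalltau(x, y).statistic
    return float(np.sin(np.pi * tau / 2.0))


def spearman_fisher(x, y) -> float:
    """Fisher-consistent Spearman correlation, ``2 sin(pi * rho_S / 6)``."""
    x, y = _check_rank_inputs(x, y)
    rho_s = stats.spearmanr(x, y).statistic
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def squared_correlation(x, y, method: str = "kendall") -> float:
    """Square of the chosen Fisher-consistent rank correlation."""
    if method == "kendall":
        return kendall_fisher(x, y) ** 2
    if method == "spearman":
        return spearman_fisher(x, y) ** 2
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic ** 2)
    raise ValueError(f"unknown method {method!r}")


def empirical_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Percentile confidence interval from the empirical distribution of
    estimates over iterations (linear interpolation between order
    statistics)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or len(samples) < 20:
        raise ValueError("need a 1-D sample of at least 20 estimates")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0,1), got {level}")
    alpha = 100.0 * (1.0 - level) / 2.0
    low, high = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(low), float(high)
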