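"""Synthetic genotype-phenotype cohorts for testing and calibration.

Three generators cover the study conditions every other module is tested
under:

* :func:`fisher_sim` - the classical additive/dominance (Fisher) model:
  a biallelic causal SNP in Hardy-Weinberg proportions shifting a
  normally distributed phenotype.  Defaults are the reference simulation
  conditions: n = 1000 individuals, phenotype mean 68 and variance 4,
  allele frequency 0.8 (genotype frequencies 64/32/4%), gene effect equal
  to the phenotype standard deviation (2), no dominance.
* :func:`theoretic_snp` - a "theoretic SNP": a microstate multiset with
  exact (N+, N0, N-) counts in random order, used to characterize the
  permutation null and calibrate thresholds.
* :func:`null_scan_dataset` - an all-null panel (phenotype independent of
  every SNP) for type-I-error and threshold checks.

``REFERENCE_NULL_COMPOSITIONS`` lists the six reference compositions at
N = 565 (25 "+1" microstates throughout, with 100 microstates moved from
the "-1" to the "0" class between consecutive entries) used for null
calibration and its scale-collapse checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import MicrostateVector

__all__ = [
    "SimConfig",
    "REFERENCE_NULL_COMPOSITIONS",
    "fisher_sim",
    "theoretic_snp",
    "null_scan_dataset",
    "hwe_genotype_freqs",
    "two_subpopulation_mixture",
]

REFERENCE_NULL_COMPOSITIONS: tuple[tuple[int, int, int], ...] = (
    (25, 25, 515),
    (25, 125, 415),
    (25, 225, 315),
    (25, 325, 215),
    (25, 425, 115),
    (25, 525, 15),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the Fisher-model causal-SNP simulation."""

    n: int = 1000
    phenotype_mean: float = 68.0
    phenotype_variance: float = 4.0
    allele_freq: float = 0.8
    gene_effect: float = 2.0  # phenotype units; default = phenotype sd
    dominance: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.phenotype_variance <= 0:
            raise ValueError("phenotype variance must be positive")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele frequency must lie in (0, 1)")


def hwe_genotype_freqs(allele_freq: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions (p^2, 2pq, q^2) for the
    (+1-homozygote, heterozygote, -1-homozygote) classes."""
    p = float(allele_freq)
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    return (p * p, 2 * p * q, q * q)


def _draw_microstates(n: int, allele_freq: float, rng: np.random.Generator) -> np.ndarray:
    probs = hwe_genotype_freqs(allele_freq)
    return rng.choice(np.array([1, 0, -1], dtype=np.int8), size=n, p=probs)


def fisher_sim(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one causal SNP under the additive/dominance model.

    Genotypes are drawn from Hardy-Weinberg proportions at
    ``allele_freq``; the phenotype is Normal(mean, variance) plus
    a * x + d * (1 - |x|) for microstate x in {+1, 0, -1}, so the
    dominance term shifts heterozygotes only (classical a/d
    parameterization).  Returns a one-column genotype frame of dosages
    (0/1/2) and the phenotype series, indexed by individual id.
    """
    rng = np.random.default_rng(config.seed)
    x = _draw_microstates(config.n, config.allele_freq, rng)
    baseline = rng.normal(
        config.phenotype_mean, np.sqrt(config.phenotype_variance), config.n
    )
    phenotype = (
        baseline
        + config.gene_effect * x
        + config.dominance * (1 - np.abs(x))
    )
    ids = [f"ind{i:04d}" for i in range(config.n)]
    genotypes = pd.DataFrame({"causal": (x + 1).astype(np.int8)}, index=ids)
    return genotypes, pd.Series(phenotype, index=ids, name="phenotype")


def theoretic_snp(
    counts, seed: int | None = None, snp_id: str = "theoretic"
) -> MicrostateVector:
    """A microstate multiset with exact counts, uniformly shuffled."""
    n_plus, n_zero, n_minus = (int(c) for c in counts)
    if min(n_plus, n_zero, n_minus) < 0:
        raise ValueError("counts must be nonnegative")
    if n_plus + n_zero + n_minus == 0:
        raise ValueError("all-zero composition")
    rng = np.random.default_rng(seed)
    vals = np.repeat(
        np.array([1, 0, -1], dtype=np.int8), [n_plus, n_zero, n_minus]
    )
    rng.shuffle(vals)
    return MicrostateVector(
        snp_id=snp_id, values=vals, missing=np.zeros(len(vals), dtype=bool)
    )


def null_scan_dataset(
    n_snps: int,
    n_individuals: int,
    composition_sampler=None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """All-null panel: phenotype independent of every SNP.

    ``composition_sampler(rng)`` may return an allele frequency for each
    SNP; the default draws frequencies uniformly on [0.1, 0.9] so panels
    pass the default MAF filter.  Genotypes are returned as dosages.
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    rng = np.random.default_rng(seed)
    if composition_sampler is None:
        composition_sampler = lambda r: r.uniform(0.1, 0.9)  # noqa: E731
    cols = {}
    for j in range(n_snps):
        freq = float(composition_sampler(rng))
        x = _draw_microstates(n_individuals, freq, rng)
        cols[f"null{j:04d}"] = (x + 1).astype(np.int8)
    ids = [f"ind{i:04d}" for i in range(n_individuals)]
    genotypes = pd.DataFrame(cols, index=ids)
    phenotype = pd.Series(
        rng.normal(0.0, 1.0, n_individuals), index=ids, name="phenotype"
    )
    return genotypes, phenotype


def two_subpopulation_mixture(
    n: int,
    allele_freqs: tuple[float, float] = (0.9, 0.3),
    phenotype_shift: float = 3.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Experimental: two-subpopulation mixture producing sigmoid-shaped
    genetic paths.

    Two equally sized subpopulations differ both in allele frequency and
    in phenotype location, so microstate composition changes across the
    phenotype ranking in a scale-dependent (sigmoidal) rather than
    segregating (paraboloid) manner.  This is a demonstration utility,
    not a mechanistic model of such associations.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    sizes = (half, n - half)
    xs, ys = [], []
    for (freq, shift, m) in zip(allele_freqs, (0.0, phenotype_shift), sizes):
        x = _draw_microstates(m, freq, rng)
        xs.append(x)
        ys.append(rng.normal(shift, 1.0, m))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ids = [f"ind{i:04d}" for i in range(n)]
    genotypes = pd.DataFrame({"mixture": (x + 1).astype(np.int8)}, index=ids)
    return genotypes, pd.Series(y, index=ids, name="phenotype")
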