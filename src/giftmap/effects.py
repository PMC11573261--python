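"""Classical per-SNP statistics used as a comparison baseline.

Group means of phenotypic residuals per microstate class give the
gene/size effect a = (mu+ - mu-)/2 (half the distance between the two
homozygote means) and the dominance d = mu0 - (mu+ + mu-)/2 (offset of
the heterozygote mean from the homozygote midpoint).  A least-squares
regression of residual on microstate dosage provides a GWAS-style
association p-value, and a pooled-variance two-sample t-test backs the
false-positive check between two microstate classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoding import MicrostateVector

__all__ = ["EffectEstimate", "gene_effect_dominance", "ols_assoc", "two_group_t"]


@dataclass(frozen=True)
class EffectEstimate:
    snp_id: str
    group_means: tuple[float, float, float]  # (mu+, mu0, mu-), NaN if empty
    group_sizes: tuple[int, int, int]
    a: float  # gene/size effect, NaN when a homozygote class is empty
    d: float  # dominance, NaN when any class is empty
    beta: float = float("nan")
    se: float = float("nan")
    p_gwas: float = float("nan")


def _group_residuals(residuals, ms: MicrostateVector):
    res = np.asarray(residuals, dtype=float)
    if len(res) != len(ms.values):
        raise ValueError("residuals and microstates must align")
    ok = ~ms.missing & np.isfinite(res)
    return [res[ok & (ms.values == v)] for v in (1, 0, -1)]


def gene_effect_dominance(residuals, ms: MicrostateVector) -> EffectEstimate:
    """Estimate gene effect ``a`` and dominance ``d`` from group means.

    ``a`` requires both homozygote classes, ``d`` additionally the
    heterozygote class; missing classes yield NaN (mirroring N/A entries
    for effect columns), never zero.
    """
    groups = _group_residuals(residuals, ms)
    sizes = tuple(len(g) for g in groups)
    means = tuple(float(g.mean()) if len(g) else float("nan") for g in groups)
    mu_p, mu_0, mu_m = means
    a = (mu_p - mu_m) / 2.0 if sizes[0] and sizes[2] else float("nan")
    d = mu_0 - (mu_p + mu_m) / 2.0 if all(sizes) else float("nan")
    return EffectEstimate(
        snp_id=ms.snp_id, group_means=means, group_sizes=sizes, a=a, d=d
    )


def ols_assoc(residuals, ms: MicrostateVector) -> EffectEstimate:
    """OLS regression of residual on microstate dosage (+1/0/-1).

    Returns the slope, its standard error and the two-sided p-value of
    the t-test on the slope; a constant dosage yields NaN statistics
    rather than an error.
    """
    res = np.asarray(residuals, dtype=float)
    ok = ~ms.missing & np.isfinite(res)
    x = ms.values[ok].astype(float)
    y = res[ok]
    est = gene_effect_dominance(residuals, ms)
    if len(x) < 3 or np.ptp(x) == 0:
        return est
    fit = stats.linregress(x, y)
    return EffectEstimate(
        snp_id=ms.snp_id,
        group_means=est.group_means,
        group_sizes=est.group_sizes,
        a=est.a,
        d=est.d,
        beta=float(fit.slope),
        se=float(fit.stderr),
        p_gwas=float(fit.pvalue),
    )


def two_group_t(residuals_a, residuals_b) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test (two-sided).

    Used to confirm suspected false positives by comparing the
    phenotypic means of two microstate classes directly.
    """
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
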