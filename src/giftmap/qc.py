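"""Phenotype precorrection and genotype quality control.

Phenotypes are adjusted for fixed effects (e.g. farm, sex) with an
ordinary least-squares model y = mu + F_i + S_j + e, optionally on the
natural-log scale; GIFT ranks the residuals e.  Genotypes are filtered on
minor allele frequency, per-SNP missingness and a 1-df chi-square
Hardy-Weinberg test, and an LD-pruned independent-SNP count feeds the
Bonferroni genome-wide significance line -log10(alpha / N_independent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "fixed_effect_residuals",
    "microstate_frame",
    "qc_filters",
    "ld_prune",
    "ld_prune_count",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """Raw phenotype values, covariates, and fitted residuals."""

    data: pd.DataFrame  # indexed by individual id
    value_col: str
    covariate_cols: tuple[str, ...]
    residuals: pd.Series

    @property
    def individual_ids(self) -> pd.Index:
        return self.residuals.index


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Full-rank treatment-coded design with intercept."""
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "ifu" and col.nunique() > 2:
            cols.append(col.to_numpy(dtype=float))
            continue
        levels = pd.unique(col)
        if len(levels) < 2:
            warnings.warn(
                f"covariate {name!r} has a single level; dropped from model",
                stacklevel=3,
            )
            continue
        dummies = pd.get_dummies(col.astype("category"), drop_first=True)
        cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    return np.column_stack(cols)


def fixed_effect_residuals(
    values: pd.Series,
    covariates: pd.DataFrame | None = None,
    log_transform: bool = False,
) -> pd.Series:
    """Least-squares residuals of (log-)phenotype on additive fixed effects.

    Rows with missing values (or non-positive values under the log
    transform) are dropped with a warning.  With no covariates the model
    is intercept-only, i.e. residuals are centered values.
    """
    y = pd.Series(values, dtype=float)
    keep = y.notna()
    if log_transform:
        bad = keep & (y <= 0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-positive value(s) dropped before log transform",
                stacklevel=2,
            )
        keep &= y > 0
    if keep.sum() == 0:
        raise ValueError("no usable phenotype values")
    if (~keep).any() and not log_transform:
        warnings.warn(
            f"{int((~keep).sum())} missing phenotype value(s) dropped", stacklevel=2
        )
    y = y[keep]
    if log_transform:
        y = np.log(y)
    if covariates is not None:
        cov = covariates.loc[y.index]
        x = _design_matrix(cov)
    else:
        x = np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(x, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - x @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    logger.info(
        "fixed-effect model: n=%d, rank=%d, R^2=%.4f", len(y), rank, r2
    )
    return pd.Series(resid, index=y.index, name="residual")


def microstate_frame(values: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Coerce an individuals x SNPs microstate matrix to a float frame
    with NaN for missing calls."""
    return pd.DataFrame(values).astype(float)


def _snp_stats(col: pd.Series) -> tuple[float, float, float]:
    """(missing fraction, MAF, HWE p-value) for one encoded SNP column."""
    vals = col.to_numpy(dtype=float)
    miss = float(np.mean(~np.isfinite(vals)))
    obs = vals[np.isfinite(vals)]
    n = len(obs)
    if n == 0:
        return 1.0, 0.0, 1.0
    n_plus = int(np.sum(obs == 1))
    n_zero = int(np.sum(obs == 0))
    n_minus = int(np.sum(obs == -1))
    freq = (2 * n_plus + n_zero) / (2 * n)
    maf = min(freq, 1.0 - freq)
    expected = n * np.array(
        [freq**2, 2 * freq * (1 - freq), (1 - freq) ** 2]
    )
    observed = np.array([n_plus, n_zero, n_minus], dtype=float)
    nz = expected > 0
    chi2 = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    hwe_p = float(stats.chi2.sf(chi2, df=1))
    return miss, maf, hwe_p


def qc_filters(
    genotypes: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_max_missing: float = 0.10,
    hwe_p_min: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter an encoded genotype matrix (individuals x SNPs, values in
    {+1, 0, -1, NaN}) on missingness, MAF and Hardy-Weinberg equilibrium.

    Returns the filtered matrix and a per-SNP report with the first
    failing reason (checked in the order call rate, MAF, HWE).  Raises if
    no SNP survives.
    """
    rows = []
    kept_cols = []
    for snp in genotypes.columns:
        miss, maf, hwe_p = _snp_stats(genotypes[snp])
        if miss > call_rate_max_missing:
            reason = "call rate"
        elif maf < maf_min:
            reason = "MAF"
        elif hwe_p < hwe_p_min:
            reason = "HWE"
        else:
            reason = ""
            kept_cols.append(snp)
        rows.append(
            {
                "snp_id": snp,
                "missing_frac": miss,
                "maf": maf,
                "hwe_p": hwe_p,
                "kept": not reason,
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    n_removed = int((~report["kept"]).sum())
    logger.info("QC: %d/%d SNPs removed", n_removed, len(report))
    if not kept_cols:
        raise ValueError(
            "no SNPs pass QC; consider relaxing --maf/--missing/--hwe-p"
        )
    return genotypes[kept_cols], report


def ld_prune(
    genotypes: pd.DataFrame,
    r2_max: float = 0.1,
    chromosomes: pd.Series | None = None,
) -> list:
    """Greedy left-to-right LD pruning on encoded dosages.

    Walking SNPs in positional order (within chromosome when
    ``chromosomes`` maps SNP id -> chromosome), a SNP is dropped when its
    squared Pearson correlation with any previously retained SNP on the
    same chromosome exceeds ``r2_max``.  Deterministic given SNP order.
    """
    mat = genotypes.to_numpy(dtype=float)
    # mean-impute missing calls for the correlation only
    col_means = np.nanmean(mat, axis=0)
    inds = np.where(np.isnan(mat))
    mat[inds] = np.take(col_means, inds[1])
    centered = mat - mat.mean(axis=0)
    norms = np.sqrt(np.sum(centered**2, axis=0))
    kept: list[int] = []
    chrom_of = (
        chromosomes.reindex(genotypes.columns).to_numpy()
        if chromosomes is not None
        else np.zeros(mat.shape[1])
    )
    for j in range(mat.shape[1]):
        same = [i for i in kept if chrom_of[i] == chrom_of[j]]
        if same and norms[j] > 0:
            r = centered[:, same].T @ centered[:, j] / (
                norms[same] * norms[j]
            )
            if np.max(r**2) > r2_max:
                continue
        kept.append(j)
    return [genotypes.columns[j] for j in kept]


def ld_prune_count(
    genotypes: pd.DataFrame,
    r2_max: float = 0.1,
    chromosomes: pd.Series | None = None,
) -> int:
    """Number of LD-independent SNPs (Bonferroni denominator)."""
    return len(ld_prune(genotypes, r2_max=r2_max, chromosomes=chromosomes))


def bonferroni_threshold(n_independent: int, alpha: float) -> float:
    """Genome-wide line -log10(alpha / N_independent)."""
    if n_independent < 1:
        raise ValueError("need at least one independent SNP")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return float(-np.log10(alpha / n_independent))
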