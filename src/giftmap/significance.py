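"""Combinatorial path probability p^GIFT, null-quantile calibration, FDR.

The observed genetic path is split into three contiguous regions delimited
by the global maximum and minimum of Delta-theta(i).  With (n_q)_p the
number of microstates of type q in region p, the number of arrangements
reproducing the observed region composition is the product of per-region
multinomial coefficients

    N_p = (Delta-i_p)! / ((n+)_p! (n0)_p! (n-)_p!),   p = 1, 2, 3,

and the path probability is p^GIFT = N1 N2 N3 / Npath0 with
Npath0 = N!/(N+! N0! N-!) the total number of arrangements.  A strongly
segregated path concentrates each microstate type in few regions, making
its region composition combinatorially rare and p^GIFT small.  Scan-level
multiplicity is controlled with Benjamini-Hochberg FDR (p_GIFT), and
genome-wide significance lines come from permutation-null quantiles of
-log10 p^GIFT pooled over reference compositions.

All p-value arithmetic is done in natural-log space via log-gamma, so
cohorts of thousands of individuals (where p^GIFT underflows double
precision) remain exact on the -log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .encoding import GeneticPath, MicrostateVector, genetic_path, rank_phenotype
from .nullmodel import random_microstate_matrix

__all__ = [
    "GiftResult",
    "partition_regions",
    "region_counts",
    "p_gift_raw",
    "bh_adjust",
    "bh_adjust_log",
    "Calibration",
    "calibrate_thresholds",
    "scan_microstates",
]

_LN10 = math.log(10.0)


@dataclass
class GiftResult:
    """Per-SNP record of the path-probability test."""

    snp_id: str
    i_ext1: int
    i_ext2: int
    region_widths: tuple[int, int, int]
    region_counts: np.ndarray  # rows q in (+, 0, -), columns p in (1, 2, 3)
    log10_npath0: float
    log_p_raw: float  # natural log
    p_raw: float
    neglog10_p_raw: float
    p_adj: float = float("nan")
    neglog10_p_adj: float = float("nan")


def _log_multinomial(n: np.ndarray, ks: np.ndarray, axis: int = -1) -> np.ndarray:
    """log of n! / prod(k_i!) with sum(k_i) = n, via log-gamma."""
    return gammaln(np.asarray(n, dtype=float) + 1.0) - np.sum(
        gammaln(np.asarray(ks, dtype=float) + 1.0), axis=axis
    )


def partition_regions(path: GeneticPath, on: str = "delta") -> tuple[int, int, tuple[int, int, int]]:
    """Locate the path extrema and the three regions they delimit.

    Returns ``(i_ext1, i_ext2, (w1, w2, w3))`` with 1-based positions
    ``i_ext1 < i_ext2`` of the global maximum and minimum (first
    occurrence on ties) of Delta-theta (or of theta when ``on="theta"``),
    sorted left-to-right.  Region 1 covers positions 1..i_ext1, region 2
    covers i_ext1+1..i_ext2, region 3 the remainder.  A flat path (argmax
    coincides with argmin) degenerates to boundaries (i, N) with region 3
    empty.
    """
    if on == "delta":
        curve = path.delta
    elif on == "theta":
        curve = path.theta
    else:
        raise ValueError(f"unknown extremum curve {on!r}")
    n = len(curve)
    i_max = int(np.argmax(curve)) + 1
    i_min = int(np.argmin(curve)) + 1
    if i_max == i_min:  # flat curve
        i1, i2 = i_max, n
    else:
        i1, i2 = sorted((i_max, i_min))
    widths = (i1, i2 - i1, n - i2)
    return i1, i2, widths


def region_counts(values_ordered: np.ndarray, i1: int, i2: int) -> np.ndarray:
    """Tally microstates per region: 3x3 matrix, rows (+1, 0, -1), cols regions."""
    vals = np.asarray(values_ordered)
    out = np.empty((3, 3), dtype=np.int64)
    bounds = (0, i1, i2, len(vals))
    for p in range(3):
        seg = vals[bounds[p] : bounds[p + 1]]
        out[0, p] = np.sum(seg == 1)
        out[1, p] = np.sum(seg == 0)
        out[2, p] = np.sum(seg == -1)
    return out


def p_gift_raw(
    path: GeneticPath, ms: MicrostateVector, on: str = "delta"
) -> GiftResult:
    """Score one genetic path with the combinatorial path probability.

    Degenerate flat paths (single microstate type, or Delta-theta
    identically zero) get p_raw = 1.
    """
    if path.n != ms.n:
        raise ValueError("path and microstate vector disagree on cohort size")
    i1, i2, widths = partition_regions(path, on=on)
    vals = ms.values[path.ordering]
    counts = region_counts(vals, i1, i2)
    totals = counts.sum(axis=1)
    if not np.array_equal(totals, np.array(ms.counts)):
        raise AssertionError("region counts inconsistent with microstate totals")
    log_npath0 = float(_log_multinomial(ms.n, totals))
    log_regions = float(
        np.sum(_log_multinomial(np.array(widths), counts.T, axis=-1))
    )
    log_p = min(log_regions - log_npath0, 0.0)
    return GiftResult(
        snp_id=ms.snp_id,
        i_ext1=i1,
        i_ext2=i2,
        region_widths=widths,
        region_counts=counts,
        log10_npath0=log_npath0 / _LN10,
        log_p_raw=log_p,
        p_raw=float(np.exp(log_p)),
        neglog10_p_raw=-log_p / _LN10,
    )


def _log_p_matrix(vals: np.ndarray) -> np.ndarray:
    """Vectorized natural-log p^GIFT for K arrangements of one multiset.

    ``vals`` is a (K, N) microstate matrix; every row shares the same
    composition.  Each row is partitioned at its own Delta-theta extrema.
    """
    k, n = vals.shape
    totals = np.array(
        [np.sum(vals[0] == 1), np.sum(vals[0] == 0), np.sum(vals[0] == -1)]
    )
    slope = (totals[0] - totals[2]) / n
    theta = np.cumsum(vals, axis=1, dtype=np.int64)
    delta = theta - slope * np.arange(1, n + 1)
    i_max = np.argmax(delta, axis=1) + 1
    i_min = np.argmin(delta, axis=1) + 1
    flat = i_max == i_min
    i1 = np.minimum(i_max, i_min)
    i2 = np.maximum(i_max, i_min)
    i2[flat] = n
    # prefix counts per type, with a leading zero column
    rows = np.arange(k)
    log_regions = np.zeros(k)
    prev_b = np.zeros(k, dtype=np.intp)
    cums = [
        np.concatenate(
            [np.zeros((k, 1), dtype=np.int64), np.cumsum(vals == v, axis=1)],
            axis=1,
        )
        for v in (1, 0, -1)
    ]
    for bounds in (i1, i2, np.full(k, n, dtype=np.intp)):
        widths = bounds - prev_b
        ks = np.stack(
            [c[rows, bounds] - c[rows, prev_b] for c in cums], axis=1
        )
        log_regions += _log_multinomial(widths, ks, axis=1)
        prev_b = bounds
    log_npath0 = float(_log_multinomial(n, totals))
    return np.minimum(log_regions - log_npath0, 0.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_log(log_p) -> np.ndarray:
    """BH adjustment in natural-log space, safe against underflow.

    Equivalent to ``log(bh_adjust(exp(log_p)))`` but exact for p-values
    far below double-precision range (common for p^GIFT at large N).
    """
    lp = np.asarray(log_p, dtype=float)
    if lp.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any(lp > 0):
        raise ValueError("log p-values must be <= 0")
    m = lp.size
    order = np.argsort(lp, kind="stable")
    adj = lp[order] + np.log(m) - np.log(np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 0.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class Calibration:
    """Null-quantile significance thresholds on the -log10 p^GIFT scale."""

    thresholds: dict[float, float]
    per_composition: pd.DataFrame
    k: int
    seed: int | None
    alphas: tuple[float, ...] = field(default_factory=tuple)

    def stability(self, alpha: float) -> float:
        """Relative spread (max-min)/mean of a threshold across compositions."""
        sub = self.per_composition[self.per_composition["alpha"] == alpha]
        vals = sub["threshold"].to_numpy()
        return float((vals.max() - vals.min()) / vals.mean())

    def to_frame(self) -> pd.DataFrame:
        return self.per_composition.copy()


def calibrate_thresholds(
    compositions,
    k: int = 1000,
    alphas=(0.05, 0.01),
    seed: int | None = None,
) -> Calibration:
    """Permutation-null thresholds for -log10 p^GIFT.

    For each (N+, N0, N-) composition, ``k`` random arrangements are
    scored with the path probability; the threshold at level ``alpha``
    is the (1 - alpha) quantile of the pooled -log10 p values (so the
    conventional 95%/99% confidence lines are alphas 0.05 and 0.01, and
    alpha = 1 returns the pooled minimum).  Per-composition quantiles are
    reported alongside for a stability check.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = []
    rows = []
    for comp in compositions:
        comp = tuple(int(c) for c in comp)
        vals = random_microstate_matrix(comp, k, rng)
        neglog10 = -_log_p_matrix(vals) / _LN10
        pooled.append(neglog10)
        for alpha in alphas:
            rows.append(
                {
                    "n_plus": comp[0],
                    "n_zero": comp[1],
                    "n_minus": comp[2],
                    "alpha": alpha,
                    "threshold": float(np.quantile(neglog10, 1.0 - alpha)),
                }
            )
    pooled = np.concatenate(pooled)
    thresholds = {
        float(a): float(np.quantile(pooled, 1.0 - a)) for a in alphas
    }
    return Calibration(
        thresholds=thresholds,
        per_composition=pd.DataFrame(rows),
        k=k,
        seed=seed,
        alphas=tuple(float(a) for a in alphas),
    )


def scan_microstates(
    microstates,
    residuals,
    tie_policy: str = "stable",
    on: str = "delta",
) -> tuple[list[GiftResult], dict[str, GeneticPath]]:
    """Score a panel of SNPs against one phenotype-residual vector.

    ``residuals`` is aligned with the cohort order of every
    MicrostateVector.  Individuals missing a genotype are dropped for
    that SNP only (counts and ordering recomputed per SNP).  BH
    adjustment is applied across all scanned SNPs in log space.
    """
    microstates = list(microstates)
    if not microstates:
        raise ValueError("no SNPs to scan")
    res = np.asarray(residuals, dtype=float)
    base_order = rank_phenotype(res, tie_policy=tie_policy)
    base_valid = np.zeros(len(res), dtype=bool)
    base_valid[base_order] = True
    results: list[GiftResult] = []
    paths: dict[str, GeneticPath] = {}
    for ms in microstates:
        if len(ms.values) != len(res):
            raise ValueError(
                f"SNP {ms.snp_id!r}: cohort size mismatch with residuals"
            )
        if np.any(ms.missing & base_valid) or np.any(~ms.missing & ~base_valid):
            keep = ~ms.missing & base_valid
            if not keep.any():
                raise ValueError(f"SNP {ms.snp_id!r}: no usable individuals")
            sub = MicrostateVector(
                ms.snp_id, np.where(keep, ms.values, 0), ~keep
            )
            ordering = base_order[keep[base_order]]
            path = genetic_path(sub, ordering)
            result = p_gift_raw(path, sub, on=on)
        else:
            path = genetic_path(ms, base_order)
            result = p_gift_raw(path, ms, on=on)
        results.append(result)
        paths[ms.snp_id] = path
    log_adj = bh_adjust_log(np.array([r.log_p_raw for r in results]))
    for r, la in zip(results, log_adj):
        r.p_adj = float(np.exp(la))
        r.neglog10_p_adj = -la / _LN10
    return results, paths
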