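"""Permutation null ensemble for genetic paths.

Scrambling the string of microstates destroys all phenotypic information,
so the ensemble of paths over random arrangements of a fixed microstate
multiset (N+, N0, N-) is the null reference for a SNP.  Its per-position
mean is the straight line (N+ - N-) * i / N, and its per-position standard
deviation follows the without-replacement cumulative-sum law

    sd(i) = sqrt( i (N - i) / (N - 1) * s^2 ),
    s^2   = (N+ + N-)/N - ((N+ - N-)/N)^2,

a quadratic-in-i envelope whose normalized form sd(i/N)/sqrt(N) is
independent of the sample size.  Both laws serve as analytic oracles for
the Monte-Carlo ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NullEnsemble",
    "random_microstate_matrix",
    "permute_ensemble",
    "null_mean_line",
    "closed_form_sd",
]


@dataclass(frozen=True)
class NullEnsemble:
    """Summary of K random-arrangement paths for one composition."""

    counts: tuple[int, int, int]
    k: int
    seed: int | None
    mean_path: np.ndarray
    sd_path: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    quantiles: tuple[float, float]

    @property
    def n(self) -> int:
        return sum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: position, mean, sd, envelope bounds."""
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n + 1),
                "mean": self.mean_path,
                "sd": self.sd_path,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _base_multiset(counts) -> np.ndarray:
    n_plus, n_zero, n_minus = (int(c) for c in counts)
    if min(n_plus, n_zero, n_minus) < 0:
        raise ValueError("microstate counts must be nonnegative")
    n = n_plus + n_zero + n_minus
    if n == 0:
        raise ValueError("empty microstate composition (N = 0)")
    return np.repeat(
        np.array([1, 0, -1], dtype=np.int8), [n_plus, n_zero, n_minus]
    )


def random_microstate_matrix(
    counts, k: int, rng: np.random.Generator
) -> np.ndarray:
    """K independent uniformly random arrangements of the multiset, as a
    (K, N) int8 matrix.  Shuffling the explicit multiset (rather than
    drawing positions independently) conserves the path endpoint
    theta(N) = N+ - N- in every replicate.
    """
    base = _base_multiset(counts)
    if k < 1:
        raise ValueError("K must be >= 1")
    return rng.permuted(np.tile(base, (k, 1)), axis=1)


def permute_ensemble(
    ms_counts,
    k: int,
    seed: int | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> NullEnsemble:
    """Monte-Carlo null ensemble for one microstate composition.

    Generates ``k`` uniformly random arrangements of the (N+, N0, N-)
    multiset, accumulates their cumulative-sum paths and returns the
    per-position mean, standard deviation (ddof=1) and envelope
    quantiles.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    vals = random_microstate_matrix(ms_counts, k, rng)
    paths = np.cumsum(vals, axis=1, dtype=np.int64)
    mean = paths.mean(axis=0)
    sd = paths.std(axis=0, ddof=1) if k > 1 else np.zeros(paths.shape[1])
    lo, hi = np.quantile(paths, quantiles, axis=0)
    return NullEnsemble(
        counts=tuple(int(c) for c in ms_counts),
        k=int(k),
        seed=seed,
        mean_path=mean,
        sd_path=sd,
        lower=lo,
        upper=hi,
        quantiles=tuple(quantiles),
    )


def null_mean_line(ms_counts) -> float:
    """Slope of the ensemble-average null path: (N+ - N-) / N."""
    n_plus, n_zero, n_minus = (int(c) for c in ms_counts)
    n = n_plus + n_zero + n_minus
    if n < 1:
        raise ValueError("composition must contain at least one microstate")
    return (n_plus - n_minus) / n


def closed_form_sd(ms_counts, i) -> float | np.ndarray:
    """Exact per-position sd of the null path (finite-population law).

    The partial sum of i draws without replacement from the multiset has
    variance i (N - i)/(N - 1) * s^2 where s^2 is the population variance
    of the microstate values.  Returns 0 by convention when N = 1.
    """
    n_plus, n_zero, n_minus = (int(c) for c in ms_counts)
    n = n_plus + n_zero + n_minus
    if n < 1:
        raise ValueError("composition must contain at least one microstate")
    i = np.asarray(i, dtype=float)
    if np.any((i < 0) | (i > n)):
        raise ValueError(f"position must lie in [0, {n}]")
    if n == 1:
        out = np.zeros_like(i)
        return float(out) if out.ndim == 0 else out
    s2 = (n_plus + n_minus) / n - ((n_plus - n_minus) / n) ** 2
    var = i * (n - i) / (n - 1) * s2
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out
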