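"""Microstate encoding of biallelic genotypes and genetic-path construction.

A *microstate* is the encoded genotype of one individual at one biallelic
SNP: +1 for one homozygote class, 0 for heterozygotes, -1 for the other
homozygote class.  Ranking individuals by their phenotypic residual and
taking the running cumulative sum of microstates yields the *genetic path*
theta(i), the central object of the GIFT association method.  Under the
null hypothesis (no genotype-phenotype information) the ensemble-average
path is the straight line theta0(i) = (N+ - N-) * i / N, so all inference
concentrates on the difference Delta-theta(i) = theta(i) - theta0(i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MicrostateVector",
    "GeneticPath",
    "encode_microstates",
    "rank_phenotype",
    "genetic_path",
]

# Literal base-pair encoding rule: AA = TT = +1, GG = CC = -1, 0 otherwise.
_PLUS_CALLS = {"AA", "TT"}
_MINUS_CALLS = {"GG", "CC"}
_MISSING_TOKENS = {"", ".", "..", "./.", ".|.", "NN", "00", "--", "NA", "NAN"}
_VALID_BASES = set("ACGT")

# Numeric dosage convention: 2 -> +1, 1 -> 0, 0 -> -1 (count of the allele
# whose homozygote encodes +1).
_DOSAGE_MAP = {2: 1, 1: 0, 0: -1}


@dataclass(frozen=True)
class MicrostateVector:
    """Encoded genotypes of one SNP across a cohort.

    ``values`` holds the microstate of every individual in cohort order
    (0 at missing positions); ``missing`` flags individuals without a
    usable call.  Counts refer to non-missing individuals only.
    """

    snp_id: str
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        missing = np.asarray(self.missing, dtype=bool)
        if values.shape != missing.shape or values.ndim != 1:
            raise ValueError("values and missing must be 1-D arrays of equal length")
        if not np.isin(values[~missing], (-1, 0, 1)).all():
            raise ValueError("microstate values must lie in {+1, 0, -1}")
        if missing.all():
            raise ValueError(f"SNP {self.snp_id!r}: all genotypes missing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing", missing)

    @property
    def n_plus(self) -> int:
        return int(np.sum((self.values == 1) & ~self.missing))

    @property
    def n_zero(self) -> int:
        return int(np.sum((self.values == 0) & ~self.missing))

    @property
    def n_minus(self) -> int:
        return int(np.sum((self.values == -1) & ~self.missing))

    @property
    def counts(self) -> tuple[int, int, int]:
        """(N+, N0, N-) over non-missing individuals."""
        return (self.n_plus, self.n_zero, self.n_minus)

    @property
    def n(self) -> int:
        """Number of non-missing individuals."""
        return int(np.sum(~self.missing))

    @property
    def delta_n(self) -> int:
        """N+ - N-, the conserved endpoint of every genetic path."""
        return self.n_plus - self.n_minus

    def flipped(self) -> "MicrostateVector":
        """Swap the two homozygote classes (+1 <-> -1)."""
        return MicrostateVector(self.snp_id, -self.values, self.missing.copy())


@dataclass(frozen=True)
class GeneticPath:
    """Cumulative-sum path of one SNP under a phenotype ordering.

    ``theta[i-1]`` is theta(i) for i = 1..N (theta(0) = 0 is implicit);
    ``delta`` is Delta-theta(i) = theta(i) - slope * i with
    slope = (N+ - N-)/N, so delta is pinned to 0 at both ends.
    ``ordering`` records the cohort indices used, in rank order.
    """

    snp_id: str
    theta: np.ndarray
    theta0_slope: float
    delta: np.ndarray
    ordering: np.ndarray

    @property
    def n(self) -> int:
        return len(self.theta)


def _encode_call(call, idx: int, snp_id: str) -> int | None:
    """Return the microstate for one call, None if missing."""
    if call is None:
        return None
    if isinstance(call, float) and np.isnan(call):
        return None
    if isinstance(call, (int, np.integer, float, np.floating)):
        dose = float(call)
        if not dose.is_integer() or int(dose) not in _DOSAGE_MAP:
            raise ValueError(
                f"SNP {snp_id!r}, individual {idx}: dosage {call!r} is not 0/1/2"
            )
        return _DOSAGE_MAP[int(dose)]
    token = str(call).strip().upper().replace("/", "").replace("|", "")
    if token in _MISSING_TOKENS or str(call).strip().upper() in _MISSING_TOKENS:
        return None
    if len(token) != 2 or not set(token) <= _VALID_BASES:
        raise ValueError(
            f"SNP {snp_id!r}, individual {idx}: malformed biallelic call {call!r}"
        )
    if token in _PLUS_CALLS:
        return 1
    if token in _MINUS_CALLS:
        return -1
    return 0


def encode_microstates(
    genotype_calls: Iterable, snp_id: str = "", convention: str = "auto"
) -> MicrostateVector:
    """Encode per-individual biallelic calls into a :class:`MicrostateVector`.

    Parameters
    ----------
    genotype_calls
        One call per individual.  String calls are two nucleotide
        characters (separators ``/`` and ``|`` tolerated) encoded by the
        literal rule AA = TT = +1, GG = CC = -1, anything else 0.
        Numeric calls are allelic dosages with 2 -> +1, 1 -> 0, 0 -> -1.
        ``None``/NaN and tokens such as ``./.`` or ``NN`` are missing.
    convention
        ``"bases"``, ``"dosage"`` or ``"auto"`` (dispatch per call type).

    Raises
    ------
    ValueError
        On malformed or non-biallelic calls, or if every call is missing.
    """
    calls = list(genotype_calls)
    if convention not in ("auto", "bases", "dosage"):
        raise ValueError(f"unknown encoding convention {convention!r}")
    values = np.zeros(len(calls), dtype=np.int8)
    missing = np.zeros(len(calls), dtype=bool)
    for idx, call in enumerate(calls):
        if convention == "bases" and isinstance(call, (int, float, np.number)):
            if not (isinstance(call, float) and np.isnan(call)):
                raise ValueError(
                    f"SNP {snp_id!r}, individual {idx}: numeric call {call!r} "
                    "under 'bases' convention"
                )
        ms = _encode_call(call, idx, snp_id)
        if ms is None:
            missing[idx] = True
        else:
            values[idx] = ms
    return MicrostateVector(snp_id=snp_id, values=values, missing=missing)


def rank_phenotype(
    residuals: Sequence[float],
    tie_policy: str = "stable",
    seed: int | None = None,
) -> np.ndarray:
    """Order individuals by increasing phenotypic residual.

    Returns the permutation of 0-based indices that sorts ``residuals``
    ascending.  Individuals with missing (NaN) residuals are dropped with
    a warning.  GIFT assumes phenotypic values are measured precisely
    enough to be unique; ties therefore trigger a warning and are broken
    per ``tie_policy``: ``"stable"`` keeps input order, ``"random"``
    shuffles tied entries reproducibly via ``seed``.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim != 1:
        raise ValueError("residuals must be one-dimensional")
    keep = np.flatnonzero(np.isfinite(res))
    if len(keep) < len(res):
        warnings.warn(
            f"{len(res) - len(keep)} individual(s) dropped for missing residuals",
            stacklevel=2,
        )
    vals = res[keep]
    if len(np.unique(vals)) < len(vals):
        warnings.warn(
            "tied phenotypic residuals: GIFT assumes unique values; "
            f"breaking ties with policy {tie_policy!r}",
            stacklevel=2,
        )
    if tie_policy == "stable":
        order = np.argsort(vals, kind="stable")
    elif tie_policy == "random":
        rng = np.random.default_rng(seed)
        jitter = rng.permutation(len(vals))
        order = np.lexsort((jitter, vals))
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return keep[order]


def genetic_path(ms: MicrostateVector, ordering: Sequence[int]) -> GeneticPath:
    """Build the genetic path theta(i) of ``ms`` under ``ordering``.

    ``ordering`` must be a permutation of the indices of all non-missing
    individuals (typically from :func:`rank_phenotype` on the same
    cohort).  theta(i) is the cumulative sum of microstates along the
    ordering; the null line has slope (N+ - N-)/N and delta is the
    difference, zero at both endpoints by construction.
    """
    order = np.asarray(ordering, dtype=np.intp)
    valid = np.flatnonzero(~ms.missing)
    if len(order) != len(valid) or not np.array_equal(np.sort(order), valid):
        raise ValueError(
            f"SNP {ms.snp_id!r}: ordering must be a permutation of the "
            f"{len(valid)} non-missing individuals"
        )
    vals = ms.values[order].astype(np.int64)
    theta = np.cumsum(vals)
    n = len(vals)
    slope = ms.delta_n / n
    delta = theta - slope * np.arange(1, n + 1)
    return GeneticPath(
        snp_id=ms.snp_id,
        theta=theta,
        theta0_slope=slope,
        delta=delta,
        ordering=order,
    )
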