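"""Model-style front end: :class:`GiftScan` fitted to a cohort returns a
:class:`GiftScanResults` carrying per-SNP path probabilities, calibrated
significance thresholds, classical effect estimates and diagnostics.

Typical use::

    model = GiftScan(genotypes, phenotype, covariates=covs, apply_qc=True)
    res = model.fit(seed=0)
    print(res.summary())
    res.plot_manhattan("scan.png")
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .effects import ols_assoc
from .encoding import MicrostateVector, encode_microstates
from .qc import fixed_effect_residuals, qc_filters
from .significance import Calibration, calibrate_thresholds, scan_microstates

logger = logging.getLogger(__name__)

__all__ = ["GiftScan", "GiftScanResults"]

_TABLE_COLUMNS = [
    "chrom",
    "snp_id",
    "pos",
    "n_plus",
    "n_zero",
    "n_minus",
    "i_ext1",
    "i_ext2",
    "p_raw",
    "neglog10_p_raw",
    "p_adj",
    "neglog10_p_adj",
    "a",
    "d",
    "beta",
    "p_gwas",
]


def _chrom_key(chrom) -> tuple:
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


class GiftScan:
    """Genome scan model: genetic-path association of SNPs with one
    quantitative phenotype.

    Parameters
    ----------
    genotypes
        Individuals x SNPs DataFrame of biallelic calls (two-character
        strings) or 0/1/2 dosages; NaN marks missing calls.
    phenotype
        Raw phenotype values indexed by individual id (or a column of
        the covariates frame named by ``value_col``).
    covariates
        Optional DataFrame of fixed-effect covariates (categorical or
        continuous), indexed by individual id.
    snp_info
        Optional frame indexed by SNP id with ``chrom`` and ``pos``;
        defaults to chromosome "0" with ordinal positions.
    log_transform
        Natural-log the phenotype before fixed-effect adjustment.
    apply_qc
        Run MAF / call-rate / HWE filters before scanning.
    """

    def __init__(
        self,
        genotypes: pd.DataFrame,
        phenotype: pd.Series,
        covariates: pd.DataFrame | None = None,
        snp_info: pd.DataFrame | None = None,
        *,
        log_transform: bool = False,
        apply_qc: bool = True,
        maf_min: float = 0.05,
        call_rate_max_missing: float = 0.10,
        hwe_p_min: float = 1e-6,
        tie_policy: str = "stable",
        extremum_on: str = "delta",
    ) -> None:
        phenotype = pd.Series(phenotype)
        phenotype.index = phenotype.index.astype(str)
        genotypes = genotypes.copy()
        genotypes.index = genotypes.index.astype(str)
        common = genotypes.index.intersection(phenotype.index)
        if len(common) == 0:
            missing_g = list(phenotype.index.difference(genotypes.index)[:5])
            raise ValueError(
                "no overlap between genotype and phenotype individual ids "
                f"(e.g. phenotyped-only ids {missing_g})"
            )
        dropped = len(genotypes.index.union(phenotype.index)) - len(common)
        if dropped:
            logger.info("%d individual(s) without both genotype and phenotype dropped", dropped)
        if covariates is not None:
            covariates = covariates.copy()
            covariates.index = covariates.index.astype(str)
            covariates = covariates.loc[common]
        residuals = fixed_effect_residuals(
            phenotype.loc[common], covariates, log_transform=log_transform
        )
        self.residuals: pd.Series = residuals
        cohort = residuals.index
        self.genotype_calls = genotypes.loc[cohort]
        self.tie_policy = tie_policy
        self.extremum_on = extremum_on

        microstates: dict[str, MicrostateVector] = {}
        bad: list[str] = []
        for snp in self.genotype_calls.columns:
            try:
                microstates[snp] = encode_microstates(
                    self.genotype_calls[snp].tolist(), snp_id=str(snp)
                )
            except ValueError as exc:
                bad.append(str(snp))
                warnings.warn(f"SNP rejected: {exc}", stacklevel=2)
        if not microstates:
            raise ValueError("no SNP could be encoded")
        self.rejected_snps = bad

        frame = pd.DataFrame(
            {
                sid: np.where(ms.missing, np.nan, ms.values)
                for sid, ms in microstates.items()
            },
            index=cohort,
        )
        if apply_qc:
            kept, report = qc_filters(
                frame,
                maf_min=maf_min,
                call_rate_max_missing=call_rate_max_missing,
                hwe_p_min=hwe_p_min,
            )
            self.qc_report = report
            snp_ids = list(kept.columns)
        else:
            self.qc_report = None
            snp_ids = list(frame.columns)
        self.microstates = {sid: microstates[sid] for sid in snp_ids}
        self.microstate_frame = frame[snp_ids]

        if snp_info is None:
            snp_info = pd.DataFrame(
                {"chrom": "0", "pos": np.arange(1, len(frame.columns) + 1)},
                index=frame.columns,
            )
        snp_info = snp_info.copy()
        snp_info.index = snp_info.index.astype(str)
        self.snp_info = snp_info.reindex(snp_ids)
        self.snp_info["chrom"] = self.snp_info["chrom"].fillna("0").astype(str)
        self.snp_info["pos"] = (
            self.snp_info["pos"].fillna(0).astype(int)
        )

    @classmethod
    def from_files(
        cls,
        genotype_path,
        phenotype_path,
        *,
        genotype_format: str = "auto",
        value_col: str | None = None,
        covariate_cols: list[str] | None = None,
        **kwargs,
    ) -> "GiftScan":
        """Build the model from a genotype file and a phenotype table."""
        calls, snp_info = gio.read_genotypes(genotype_path, fmt=genotype_format)
        pheno = gio.read_phenotypes(phenotype_path, value_col=value_col)
        vcol = value_col or pheno.columns[0]
        covs = None
        if covariate_cols:
            missing = set(covariate_cols) - set(pheno.columns)
            if missing:
                raise ValueError(f"covariate column(s) not found: {sorted(missing)}")
            covs = pheno[list(covariate_cols)]
        return cls(calls, pheno[vcol], covariates=covs, snp_info=snp_info, **kwargs)

    def fit(
        self,
        *,
        fdr: float = 0.05,
        calibrate: bool = True,
        calibration_k: int = 1000,
        alphas=(0.05, 0.01),
        calibration_compositions=None,
        seed: int | None = None,
    ) -> "GiftScanResults":
        """Run the genome scan and return its results.

        ``seed`` drives the permutation-null calibration (and random tie
        breaking if selected); the scan itself is deterministic.  With
        ``calibration_compositions=None``, up to six compositions spread
        over the scanned SNPs' heterozygote fractions are used (threshold
        quantiles are insensitive to composition, which the calibration
        report quantifies); pass e.g. ``REFERENCE_NULL_COMPOSITIONS`` to
        calibrate on the reference theoretic-SNP panel instead.
        """
        mslist = list(self.microstates.values())
        results, paths = scan_microstates(
            mslist,
            self.residuals.to_numpy(),
            tie_policy=self.tie_policy,
            on=self.extremum_on,
        )
        res_arr = self.residuals.to_numpy()
        rows = []
        for ms, r in zip(mslist, results):
            eff = ols_assoc(res_arr, ms)
            info = self.snp_info.loc[ms.snp_id]
            rows.append(
                {
                    "chrom": info["chrom"],
                    "snp_id": ms.snp_id,
                    "pos": int(info["pos"]),
                    "n_plus": ms.n_plus,
                    "n_zero": ms.n_zero,
                    "n_minus": ms.n_minus,
                    "i_ext1": r.i_ext1,
                    "i_ext2": r.i_ext2,
                    "p_raw": r.p_raw,
                    "neglog10_p_raw": r.neglog10_p_raw,
                    "p_adj": r.p_adj,
                    "neglog10_p_adj": r.neglog10_p_adj,
                    "a": eff.a,
                    "d": eff.d,
                    "beta": eff.beta,
                    "p_gwas": eff.p_gwas,
                }
            )
        table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
        table = table.sort_values(
            by=["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
        ).reset_index(drop=True)

        calibration = None
        thresholds: dict[float, float] = {}
        if calibrate:
            comps = calibration_compositions
            if comps is None:
                comps = self._default_calibration_compositions()
            calibration = calibrate_thresholds(
                comps, k=calibration_k, alphas=alphas, seed=seed
            )
            thresholds = calibration.thresholds
        return GiftScanResults(
            model=self,
            table=table,
            thresholds=thresholds,
            calibration=calibration,
            paths=paths,
            fdr=fdr,
        )

    def _default_calibration_compositions(self, max_comps: int = 6):
        comps = sorted(
            {ms.counts for ms in self.microstates.values()},
            key=lambda c: c[1] / sum(c),
        )
        if len(comps) <= max_comps:
            return comps
        idx = np.linspace(0, len(comps) - 1, max_comps).round().astype(int)
        return [comps[i] for i in idx]


@dataclass
class GiftScanResults:
    """Results of a fitted :class:`GiftScan`."""

    model: GiftScan
    table: pd.DataFrame
    thresholds: dict[float, float]
    calibration: Calibration | None
    paths: dict = field(repr=False, default_factory=dict)
    fdr: float = 0.05

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def n_individuals(self) -> int:
        return len(self.model.residuals)

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """SNPs passing BH FDR control at level ``fdr``.

        Note that p^GIFT is a combinatorial path probability, small even
        under the null for large cohorts, so the calibrated null-quantile
        lines (:meth:`above_threshold`) are the operative significance
        rule for a scan; BH-adjusted values are reported alongside.
        """
        level = self.fdr if fdr is None else fdr
        return self.table[self.table["p_adj"] <= level]

    def above_threshold(self, alpha: float = 0.05) -> pd.DataFrame:
        """SNPs whose -log10 p^GIFT exceeds the calibrated null quantile."""
        if alpha not in self.thresholds:
            raise ValueError(f"no calibrated threshold for alpha={alpha}")
        return self.table[
            self.table["neglog10_p_raw"] > self.thresholds[alpha]
        ]

    def get_path(self, snp_id: str):
        return self.paths[str(snp_id)]

    def plot_manhattan(self, path=None, y_col: str = "neglog10_p_adj", **kwargs):
        from .plotting import render_manhattan

        return render_manhattan(
            self.table, thresholds=self.thresholds, path=path, y_col=y_col, **kwargs
        )

    def plot_path(self, snp_id: str, path=None, **kwargs):
        from .plotting import plot_path

        return plot_path(self.get_path(snp_id), path=path, **kwargs)

    def save(self, path) -> None:
        gio.write_results(self.table, path)

    def summary(self, top: int = 10) -> str:
        """Human-readable scan summary in the style of model-results
        summaries: cohort size, QC attrition, thresholds, top hits."""
        lines = [
            "GIFT genome scan results",
            "=" * 64,
            f"individuals (with residuals): {self.n_individuals}",
            f"SNPs scanned:                 {self.n_snps}",
        ]
        if self.model.qc_report is not None:
            removed = int((~self.model.qc_report["kept"]).sum())
            lines.append(f"SNPs removed by QC:           {removed}")
        for alpha, thr in sorted(self.thresholds.items(), reverse=True):
            lines.append(
                f"null {100 * (1 - alpha):g}% line (-log10 p^GIFT): {thr:.4f}"
                f"   SNPs above: {len(self.above_threshold(alpha))}"
            )
        n_sig = len(self.significant())
        lines.append(f"significant at BH FDR {self.fdr:g}:    {n_sig}")
        lines.append("-" * 64)
        cols = [
            "chrom",
            "snp_id",
            "pos",
            "n_plus",
            "n_zero",
            "n_minus",
            "neglog10_p_adj",
            "a",
            "d",
        ]
        head = (
            self.table.sort_values("neglog10_p_adj", ascending=False)
            .head(top)[cols]
            .to_string(index=False, float_format=lambda v: f"{v:.4f}")
        )
        lines.append(f"top {top} SNPs by -log10(p_GIFT):")
        lines.append(head)
        return "\n".join(lines)


def scan_files(
    genotype_path,
    phenotype_path,
    out_path,
    **kwargs,
) -> GiftScanResults:
    """One-call convenience: build, fit, and write a scan."""
    fit_keys = {
        "fdr",
        "calibrate",
        "calibration_k",
        "alphas",
        "calibration_compositions",
        "seed",
    }
    fit_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in fit_keys}
    model = GiftScan.from_files(genotype_path, phenotype_path, **kwargs)
    res = model.fit(**fit_kwargs)
    if out_path is not None:
        res.save(out_path)
    return res
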