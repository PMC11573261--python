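"""Readers and writers: genotypes (VCF / PLINK bed-bim-fam / delimited
table), phenotype tables, and scan result files.

All readers return the same pair: a calls DataFrame (individuals x SNPs;
two-character base strings or 0/1/2 dosages, NaN for missing) and a SNP
metadata frame indexed by SNP id with ``chrom`` and ``pos`` columns.
Unplaced SNPs are assigned chromosome "0".  Coordinates are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "write_results",
    "read_results",
    "write_genotypes_table",
]

_RESULT_FLOAT_COLS = {
    "neglog10_p_raw": "{:.4f}",
    "neglog10_p_adj": "{:.4f}",
    "a": "{:.4f}",
    "d": "{:.4f}",
    "beta": "{:.4f}",
}


def read_genotypes(path, fmt: str = "auto") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genotype file; see module docstring for the return shape.

    ``fmt`` is ``"auto"`` (from the file suffix), ``"vcf"``, ``"plink"``
    (path may be the ``.bed`` file or the fileset prefix) or ``"table"``
    (delimited text, first column = individual id, remaining columns =
    SNPs holding two-character calls or 0/1/2 dosages).
    """
    path = Path(path)
    if fmt == "auto":
        suffixes = "".join(path.suffixes).lower()
        if suffixes.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif path.suffix in (".bed", ".bim", ".fam") or (
            not path.exists() and Path(str(path) + ".bed").exists()
        ):
            fmt = "plink"
        else:
            fmt = "table"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink":
        return _read_plink(path)
    if fmt == "table":
        return _read_table(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty genotype file: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta = []
    for idx, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: record {idx + 1} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        calls = []
        for b in var.gt_bases:
            token = b.replace("/", "").replace("|", "")
            calls.append(np.nan if "." in token else token)
        cols[snp_id] = np.array(calls, dtype=object)
        meta.append({"snp_id": snp_id, "chrom": str(var.CHROM), "pos": int(var.POS)})
    vcf.close()
    if not meta:
        raise ValueError(f"no variant records in {path}")
    frame = pd.DataFrame(cols, index=samples)
    info = pd.DataFrame(meta).set_index("snp_id")
    logger.info("read %d samples x %d SNPs from %s", *frame.shape, path)
    return frame, info


def _read_plink(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decode a PLINK bed/bim/fam fileset (SNP-major 2-bit .bed layout)."""
    prefix = path.with_suffix("") if path.suffix in (".bed", ".bim", ".fam") else path
    bed, bim, fam = (Path(f"{prefix}{ext}") for ext in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, usecols=[0, 1],
                         names=["fid", "iid"], dtype=str)
    raw = np.frombuffer(bed.read_bytes(), dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{bed}: not a PLINK .bed file")
    if raw[2] != 0x01:
        raise ValueError(f"{bed}: only SNP-major .bed files are supported")
    n_ind, n_snp = len(fam_df), len(bim_df)
    bytes_per_snp = (n_ind + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * n_snp:
        raise ValueError(f"{bed}: size inconsistent with .bim/.fam")
    codes = (
        body.reshape(n_snp, bytes_per_snp)[:, :, None]
        >> (2 * np.arange(4))[None, None, :]
    ) & 0b11
    codes = codes.reshape(n_snp, -1)[:, :n_ind]  # per-SNP 2-bit codes
    cols = {}
    for j, row in bim_df.iterrows():
        a1, a2 = row["a1"], row["a2"]
        lut = np.array(
            [a1 + a1, "", a1 + a2, a2 + a2], dtype=object
        )  # 0b01 = missing
        calls = lut[codes[j]]
        calls[codes[j] == 1] = np.nan
        cols[row["snp_id"]] = calls
    frame = pd.DataFrame(cols, index=fam_df["iid"].tolist())
    info = bim_df.set_index("snp_id")[["chrom", "pos"]]
    logger.info("read %d samples x %d SNPs from %s", *frame.shape, prefix)
    return frame, info


def _read_table(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty genotype file: {path}")
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if frame.empty or frame.shape[1] == 0:
        raise ValueError(f"no genotype columns found in {path}")
    frame.index = frame.index.astype(str)
    # numeric columns are dosages; everything else stays as call strings
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.notna().sum() >= frame[col].notna().sum():
            frame[col] = converted
    info = pd.DataFrame(
        {
            "chrom": "0",
            "pos": np.arange(1, frame.shape[1] + 1),
        },
        index=pd.Index(frame.columns, name="snp_id"),
    )
    logger.info("read %d samples x %d SNPs from %s", *frame.shape, path)
    return frame, info


def read_phenotypes(
    path, id_col: str | int = 0, value_col: str | None = None
) -> pd.DataFrame:
    """Read a delimited phenotype table indexed by individual id.

    The first non-id column is taken as the phenotype when ``value_col``
    is not given; remaining columns are treated as covariates by callers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=id_col)
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise ValueError(f"no phenotype column found in {path}")
    if value_col is not None and value_col not in df.columns:
        raise ValueError(f"phenotype column {value_col!r} not in {path}")
    return df


def write_results(results: pd.DataFrame, path) -> None:
    """Write a scan result table as TSV with fixed column order and
    4-decimal formatting for -log10 and effect columns."""
    if results.empty:
        raise ValueError("no results to write")
    out = results.copy()
    for col, fmt in _RESULT_FLOAT_COLS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, f=fmt: f.format(v) if np.isfinite(v) else "NA"
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_genotypes_table(genotypes: pd.DataFrame, path) -> None:
    """Write an individuals x SNPs genotype matrix as TSV (id column first)."""
    genotypes.to_csv(path, sep="\t", index_label="individual_id")
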