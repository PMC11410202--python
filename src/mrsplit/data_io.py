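"""Containers and file I/O for individual-level Mendelian randomization data.

The central container is :class:`MRData`, which holds an N×p additive-coded
genotype dosage matrix, a quantitative exposure and a (quantitative or binary)
outcome, with sample and SNP identifiers.  Genotypes can be read from a plain
delimited matrix (samples in rows, SNPs in columns) or from a PLINK1
.bed/.bim/.fam triple; phenotypes come from a delimited table with a
sample-id column.  Samples are matched by identifier across the two files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MRData", "read_mrdata", "write_results", "write_mrdata", "read_plink_bed"]


@dataclass
class MRData:
    """Aligned genotype/exposure/outcome data for one-sample MR.

    Parameters
    ----------
    genotypes
        N×p dosage matrix, additive 0/1/2 coding (fractional dosages in
        [0, 2] are accepted).
    exposure
        Length-N exposure vector X.
    outcome
        Length-N outcome vector Y; coded 0/1 when ``outcome_binary``.
    outcome_binary
        Whether the outcome is binary (second stage then uses logistic
        regression).
    sample_ids, snp_ids
        Identifiers; generated as ``S0..`` / ``snp0..`` when omitted.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    outcome_binary: bool = False
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    snp_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float).ravel()
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, p = self.genotypes.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples to split and fit, got {n}")
        if p < 1:
            raise ValueError("need at least one SNP")
        if len(self.exposure) != n or len(self.outcome) != n:
            raise ValueError(
                f"sample dimension mismatch: genotypes {n}, "
                f"exposure {len(self.exposure)}, outcome {len(self.outcome)}"
            )
        for name, arr in (("genotypes", self.genotypes), ("exposure", self.exposure),
                          ("outcome", self.outcome)):
            if np.isnan(arr).any():
                raise ValueError(f"{name} contain {int(np.isnan(arr).sum())} missing values; "
                                 "impute or drop before constructing MRData")
        bad = np.where((self.genotypes < 0) | (self.genotypes > 2))
        if bad[0].size:
            j = int(bad[1][0])
            sid = self.snp_ids[j] if self.snp_ids is not None else f"column {j}"
            raise ValueError(f"dosage outside [0, 2] at SNP {sid} "
                             f"(value {self.genotypes[bad[0][0], j]:g})")
        if self.outcome_binary:
            vals = np.unique(self.outcome)
            if not np.isin(vals, [0.0, 1.0]).all() or len(vals) != 2:
                raise ValueError("binary outcome must take exactly the two values 0 and 1")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length mismatch")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(p)], dtype=object)
        else:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)
            if len(self.snp_ids) != p:
                raise ValueError("snp_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def read_plink_bed(bed_path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a PLINK1 SNP-major .bed/.bim/.fam triple.

    Returns ``(dosages, sample_ids, snp_ids)`` with dosages counting A1
    alleles (0/1/2, NaN for missing).  Only the SNP-major layout (magic
    bytes 0x6c 0x1b 0x01) written by modern PLINK is supported.
    """
    bed_path = Path(bed_path)
    bim = pd.read_csv(bed_path.with_suffix(".bim"), sep=r"\s+", header=None,
                      usecols=[1], dtype=str)
    fam = pd.read_csv(bed_path.with_suffix(".fam"), sep=r"\s+", header=None,
                      usecols=[1], dtype=str)
    snp_ids = bim[1].to_numpy(dtype=object)
    sample_ids = fam[1].to_numpy(dtype=object)
    n, p = len(sample_ids), len(snp_ids)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != b"\x6c\x1b\x01":
        raise ValueError(f"{bed_path}: not a SNP-major PLINK1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * p:
        raise ValueError(f"{bed_path}: size inconsistent with .bim/.fam dimensions")
    body = body.reshape(p, bytes_per_snp)
    # unpack 2-bit genotype codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    return lut[codes].T.copy(), sample_ids, snp_ids


def _read_delimited_genotypes(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return (df.to_numpy(dtype=float), df.index.to_numpy(dtype=object).astype(str),
            df.columns.to_numpy(dtype=object))


def read_mrdata(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    exposure_name: str,
    outcome_name: str,
    outcome_binary: bool = False,
    impute_missing: bool = False,
) -> MRData:
    """Read genotypes and phenotypes, intersect samples by id, validate.

    ``genotype_path`` may be a PLINK1 ``.bed`` file (with ``.bim``/``.fam``
    beside it) or a delimited text matrix whose first column holds sample
    ids and whose header holds SNP ids; tab vs comma is auto-detected.
    ``phenotype_path`` is a delimited table whose first column holds sample
    ids.  Missing dosages are a hard error unless ``impute_missing``, which
    replaces them with the per-SNP mean.
    """
    genotype_path, phenotype_path = Path(genotype_path), Path(phenotype_path)
    if genotype_path.suffix == ".bed":
        G, gids, snp_ids = read_plink_bed(genotype_path)
    else:
        G, gids, snp_ids = _read_delimited_genotypes(genotype_path)
    pheno = pd.read_csv(phenotype_path, sep=None, engine="python", index_col=0)
    pheno.index = pheno.index.astype(str)
    for col in (exposure_name, outcome_name):
        if col not in pheno.columns:
            raise ValueError(f"column {col!r} not found in {phenotype_path}")

    gindex = pd.Index(gids.astype(str))
    common = gindex.intersection(pheno.index)
    if len(common) == 0:
        raise ValueError(
            f"no samples shared between {genotype_path} and {phenotype_path}")
    order = gindex.get_indexer(common)
    G = G[order]
    pheno = pheno.loc[common]

    n_missing = int(np.isnan(G).sum())
    if n_missing:
        if not impute_missing:
            per_snp = np.isnan(G).sum(axis=0)
            worst = snp_ids[int(np.argmax(per_snp))]
            raise ValueError(
                f"{n_missing} missing dosages in {genotype_path} (worst SNP: {worst}); "
                "pass impute_missing=True for per-SNP mean imputation")
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
        logger.info("imputed %d missing dosages with per-SNP means", n_missing)

    return MRData(
        genotypes=G,
        exposure=pheno[exposure_name].to_numpy(dtype=float),
        outcome=pheno[outcome_name].to_numpy(dtype=float),
        outcome_binary=outcome_binary,
        sample_ids=common.to_numpy(dtype=object),
        snp_ids=snp_ids,
    )


def write_mrdata(data: MRData, out_dir: str | Path, prefix: str = "sim") -> tuple[Path, Path]:
    """Export an MRData to delimited text readable by :func:`read_mrdata`.

    Writes ``<prefix>_genotypes.tsv`` (samples × SNPs) and
    ``<prefix>_phenotypes.tsv`` (columns ``exposure``, ``outcome``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gpath = out_dir / f"{prefix}_genotypes.tsv"
    ppath = out_dir / f"{prefix}_phenotypes.tsv"
    pd.DataFrame(data.genotypes, index=data.sample_ids,
                 columns=data.snp_ids).to_csv(gpath, sep="\t", float_format="%.10g",
                                              index_label="sample_id")
    pd.DataFrame({"exposure": data.exposure, "outcome": data.outcome},
                 index=data.sample_ids).to_csv(ppath, sep="\t", float_format="%.10g",
                                               index_label="sample_id")
    return gpath, ppath


def write_results(result, path: str | Path) -> None:
    """Serialize a multi-split (or comparison-table) result to delimited text.

    For a :class:`~mrsplit.multi_split.MultiSplitResult` the file has one row
    per attempted split (estimate, SE, p, IV counts, status) and a final
    ``summary`` row carrying the aggregated estimate and the Cauchy-combined
    p-value.  A pandas DataFrame (comparison table) is written as-is.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        if result.empty:
            raise ValueError("refusing to write an empty comparison table")
        result.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return
    splits = getattr(result, "splits", None)
    if not splits:
        raise ValueError("refusing to write an empty result")
    rows = []
    for i, s in enumerate(splits):
        rows.append({
            "split": i, "status": s.status,
            "estimate": s.beta_l, "se": s.se_l, "pval": s.pval_l,
            "n_selected": s.n_selected, "n_major": s.n_major, "n_weak": s.n_weak,
        })
    rows.append({
        "split": "summary", "status": f"{result.n_failed} failed",
        "estimate": result.beta_aggregated, "se": np.nan,
        "pval": result.p_combined, "n_selected": np.nan,
        "n_major": np.nan, "n_weak": np.nan,
    })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
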