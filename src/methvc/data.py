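"""Region data containers and standard-format readers/writers.

A methylation region is a long-format table of per-CpG binomial counts —
one record per (sample, position) with methylated reads ``Y`` out of total
reads ``X`` — together with an N x P genotype dosage matrix for the
candidate SNPs.  Records with zero total reads carry no likelihood
information and are dropped at ingestion (counted in the module logger).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methvc")

METH_COLUMNS = ["sample_id", "position", "meth_reads", "total_reads"]


@dataclass
class RegionDataset:
    """Per-record methylation counts plus the sample genotype matrix.

    Attributes
    ----------
    sample_idx : (M,) int array
        Row index into ``genotypes`` for each record.
    positions : (M,) float array
        Genomic bp position of each record (1-based, as in VCF).
    meth : (M,) array
        Methylated read counts ``Y_ij``.
    total : (M,) array
        Total read counts ``X_ij`` (all >= 1).
    genotypes : (N, P) float array
        Dosages in [0, 2]; imputed dosages are allowed.
    """

    sample_idx: np.ndarray
    positions: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sample_idx = np.asarray(self.sample_idx, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.meth = np.asarray(self.meth, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=float))
        M = self.sample_idx.size
        if not (self.positions.size == self.meth.size == self.total.size == M):
            raise ValueError("record arrays must share one length")
        if np.any(self.total < 1):
            raise ValueError("records with total_reads < 1 are not allowed")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValueError("need 0 <= meth_reads <= total_reads for every record")
        if M and (self.sample_idx.min() < 0 or self.sample_idx.max() >= self.N):
            raise ValueError("record sample index without a genotype row")
        if np.any(self.genotypes < 0) or np.any(self.genotypes > 2):
            raise ValueError("genotype dosages must lie in [0, 2]")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.N)]
        if not self.snp_ids:
            self.snp_ids = [f"snp{p + 1}" for p in range(self.P)]

    @property
    def M(self) -> int:
        return self.sample_idx.size

    @property
    def N(self) -> int:
        return self.genotypes.shape[0]

    @property
    def P(self) -> int:
        return self.genotypes.shape[1]

    def subset_records(self, mask: np.ndarray) -> "RegionDataset":
        """Dataset restricted to the records where ``mask`` is True.

        The genotype matrix is shared, so sample indices stay valid; used
        for by-individual cross-validation splits.
        """
        mask = np.asarray(mask, dtype=bool)
        return RegionDataset(
            sample_idx=self.sample_idx[mask],
            positions=self.positions[mask],
            meth=self.meth[mask],
            total=self.total[mask],
            genotypes=self.genotypes,
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [self.sample_ids[i] for i in self.sample_idx],
                "position": self.positions.astype(int),
                "meth_reads": self.meth.astype(int),
                "total_reads": self.total.astype(int),
            }
        )


def read_methylation(path) -> pd.DataFrame:
    """Read a long-format methylation count TSV and validate it.

    Expects header columns sample_id, position, meth_reads, total_reads.
    Rows with total_reads = 0 are dropped (logged); fractional counts or
    meth_reads > total_reads raise with the offending row index.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation file {path} lacks columns {missing}")
    for col in ("position", "meth_reads", "total_reads"):
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            bad = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
            raise ValueError(f"non-integer {col} at row {bad} of {path}")
    zero = df["total_reads"] == 0
    if zero.any():
        logger.info("dropped %d zero-coverage rows from %s", int(zero.sum()), path)
        df = df[~zero].reset_index(drop=True)
    bad = df["meth_reads"] > df["total_reads"]
    if bad.any():
        raise ValueError(
            f"meth_reads > total_reads at row {int(np.flatnonzero(bad)[0])} of {path}"
        )
    return df


def write_methylation(df_or_dataset, path) -> None:
    df = (
        df_or_dataset.to_frame()
        if isinstance(df_or_dataset, RegionDataset)
        else df_or_dataset
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Samples x SNPs dosage TSV; first column = sample id, header = SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    Z = df.to_numpy(dtype=float)
    sample_ids = [str(s) for s in df.index]
    snp_ids = [str(s) for s in df.columns]
    Z = _impute_missing(Z)
    return Z, sample_ids, snp_ids


def read_genotypes_vcf(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read GT fields from a VCF as alternate-allele counts (0/1/2).

    Missing genotypes are mean-imputed per SNP with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns, snp_ids = [], []
    for variant in vcf:
        gt = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        columns.append(dose)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    Z = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    Z = _impute_missing(Z)
    return Z, sample_ids, snp_ids


def _impute_missing(Z: np.ndarray) -> np.ndarray:
    missing = ~np.isfinite(Z)
    if missing.any():
        logger.info("mean-imputed %d missing genotypes", int(missing.sum()))
        means = np.nanmean(np.where(missing, np.nan, Z), axis=0)
        means = np.nan_to_num(means, nan=0.0)
        Z = np.where(missing, means[None, :], Z)
    return Z


def write_genotypes(Z, sample_ids, snp_ids, path) -> None:
    pd.DataFrame(Z, index=sample_ids, columns=snp_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def load_region(meth_path, geno_path, geno_format: str = "tsv") -> RegionDataset:
    """Assemble a RegionDataset from a methylation TSV and a genotype file.

    Sample order is reconciled by id; a mismatch raises with the symmetric
    difference of the two id sets.
    """
    df = read_methylation(meth_path)
    if geno_format == "vcf":
        Z, geno_samples, snp_ids = read_genotypes_vcf(geno_path)
    else:
        Z, geno_samples, snp_ids = read_genotypes_tsv(geno_path)
    meth_samples = list(dict.fromkeys(str(s) for s in df["sample_id"]))
    diff = set(meth_samples) ^ set(geno_samples)
    if diff:
        raise ValueError(f"sample ids differ between files: {sorted(diff)}")
    order = {s: i for i, s in enumerate(meth_samples)}
    Z = Z[[geno_samples.index(s) for s in meth_samples]]
    const = np.all(Z == 0, axis=0)
    if const.any():
        logger.warning(
            "%d genotype columns are constant zero (selectable but inert)",
            int(const.sum()),
        )
    return RegionDataset(
        sample_idx=np.array([order[str(s)] for s in df["sample_id"]]),
        positions=df["position"].to_numpy(dtype=float),
        meth=df["meth_reads"].to_numpy(dtype=float),
        total=df["total_reads"].to_numpy(dtype=float),
        genotypes=Z,
        sample_ids=meth_samples,
        snp_ids=snp_ids,
    )


def ld_prune(Z: np.ndarray, r2_threshold: float) -> np.ndarray:
    """Greedy LD pruning in genomic (column) order.

    A SNP is kept iff its squared Pearson correlation with every previously
    kept SNP is below the threshold.  Constant columns have undefined r^2
    and are kept (treated as r^2 = 0, logged).
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2 threshold must lie in (0, 1]")
    Z = np.asarray(Z, dtype=float)
    n, P = Z.shape
    sd = Z.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant SNP columns kept trivially in LD pruning",
                    int(constant.sum()))
    centered = Z - Z.mean(axis=0)
    denom = np.where(constant, 1.0, sd * np.sqrt(n))
    U = centered / denom  # unit-norm columns (constant cols are zero)
    kept: list[int] = []
    for p in range(P):
        if constant[p]:
            kept.append(p)
            continue
        ok = True
        for q in kept:
            if constant[q]:
                continue
            if (U[:, p] @ U[:, q]) ** 2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(p)
    return np.asarray(kept, dtype=int)
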