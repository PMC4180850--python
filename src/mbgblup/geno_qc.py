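"""Genotype and phenotype quality control.

SNP-chip style QC for 0/1/2 genotype tables: per-call confidence masking,
SNP call-rate, heterozygosity-outlier, minor-allele-frequency,
sex-chromosome and Hardy-Weinberg filters, duplicate-sample detection,
mean imputation of missing calls and phenotype outlier trimming.

Filters are applied sequentially in a fixed, documented order
(confidence -> call rate -> heterozygosity -> MAF -> chromosome -> HWE);
each SNP is attributed to the first filter that removes it, and the
:class:`QCReport` records every removal with its reason and the thresholds
used, so that panel counts reconcile exactly (before = after + removed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # sentinel for a missing genotype call

__all__ = [
    "GenotypeTable",
    "QCThresholds",
    "QCReport",
    "qc_snps",
    "qc_samples",
    "impute_missing",
    "trim_phenotype_outliers",
    "hwe_test",
]


@dataclass
class GenotypeTable:
    """Animals x SNPs genotype calls with optional per-call confidence.

    Parameters
    ----------
    animal_ids
        Sample identifiers, one per row of ``calls``.
    snps
        Per-SNP metadata with columns ``snp_id``, ``chrom``, ``pos``,
        ``a1``, ``a2``.
    calls
        ``int8`` matrix of second-allele counts in {0, 1, 2} with
        :data:`MISSING` (-1) for no-calls.
    confidence
        Optional per-call score in [0, 1] (GenCall-like); same shape as
        ``calls``.
    """

    animal_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if np.issubdtype(self.calls.dtype, np.integer) or self.calls.dtype == bool:
            self.calls = self.calls.astype(np.int8)
            if not np.isin(self.calls, (MISSING, 0, 1, 2)).all():
                raise ValueError("genotype calls must be in {0,1,2} or missing (-1)")
        else:
            # float dosage table (post-imputation); values in [0, 2] or NaN
            ok = np.isnan(self.calls) | ((self.calls >= 0) & (self.calls <= 2))
            if not ok.all():
                raise ValueError("float dosages must lie in [0, 2] or be NaN")
        if self.calls.shape != (len(self.animal_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snps)} SNPs"
            )
        if self.confidence is not None and self.confidence.shape != self.calls.shape:
            raise ValueError("confidence matrix shape must match calls")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            list(self.animal_ids),
            self.snps.copy(),
            self.calls.copy(),
            None if self.confidence is None else self.confidence.copy(),
        )

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeTable":
        """Return a new table restricted to the given row/column indices."""
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeTable(
            [self.animal_ids[i] for i in ai],
            self.snps.iloc[si].reset_index(drop=True),
            self.calls[np.ix_(ai, si)],
            None if self.confidence is None else self.confidence[np.ix_(ai, si)],
        )

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d


@dataclass
class QCThresholds:
    """Filter thresholds for :func:`qc_snps` (defaults are the standard
    chip-QC settings: 95% call rate, 0.6 confidence, 3-SD heterozygosity
    band, 1% MAF, HWE p < 1e-15, autosomes only)."""

    call_rate: float = 0.95
    confidence: float = 0.6
    het_sd: float = 3.0
    maf: float = 0.01
    hwe_p: float = 1e-15
    sex_chromosomes: tuple[str, ...] = ("X", "Y")


@dataclass
class QCReport:
    """Itemized record of a QC pass."""

    n_snps_before: int = 0
    n_snps_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0
    snp_removals: dict[str, list[str]] = field(default_factory=dict)
    sample_removals: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    filter_order: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def removed_snps(self) -> set[str]:
        return {s for ids in self.snp_removals.values() for s in ids}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _column_stats(calls: np.ndarray):
    """Per-SNP call rate, allele frequency and heterozygosity over
    non-missing calls."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_obs / calls.shape[0]
        dose = np.where(obs, calls, 0).astype(float)
        p = dose.sum(axis=0) / np.maximum(2 * n_obs, 1)
        het = (np.where(obs, calls == 1, False)).sum(axis=0) / np.maximum(n_obs, 1)
    return call_rate, p, het, n_obs


def hwe_test(genotype_counts: Sequence[int]) -> float:
    """One-degree-of-freedom chi-square goodness-of-fit p-value against
    Hardy-Weinberg expectations.

    ``genotype_counts`` is the (n0, n1, n2) triple of observed genotype
    counts. The expected counts use the observed allele frequency
    ``p = (n1 + 2 n2) / 2n``. Monomorphic SNPs are in perfect (degenerate)
    HWE and return p = 1.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("zero total genotype count")
    p = (n1 + 2 * n2) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_snps(
    table: GenotypeTable, thresholds: QCThresholds | None = None
) -> tuple[GenotypeTable, QCReport]:
    """Apply the SNP filter cascade and return the filtered table plus report.

    Order of application (each SNP is charged to the first filter that
    triggers): (1) per-call confidence masking (calls with score below the
    confidence threshold become missing); (2) SNP call rate; (3) SNP
    heterozygosity more than ``het_sd`` standard deviations from the panel
    mean heterozygosity; (4) minor allele frequency; (5) sex-chromosome
    drop; (6) Hardy-Weinberg exact deviation at ``hwe_p``.

    Heterozygosity statistics are computed across the SNPs still in the
    panel when that filter runs. HWE is computed on all animals pooled.
    """
    if table.n_snps == 0:
        raise ValueError("empty genotype table")
    thr = thresholds or QCThresholds()
    work = table.copy()
    report = QCReport(
        n_snps_before=table.n_snps,
        n_samples_before=table.n_animals,
        n_samples_after=table.n_animals,
        thresholds=asdict(thr),
        filter_order=[
            "confidence_mask",
            "call_rate",
            "heterozygosity",
            "maf",
            "sex_chromosome",
            "hwe",
        ],
    )

    # 1. confidence masking (changes calls, removes nothing by itself)
    if work.confidence is not None:
        mask = (work.confidence < thr.confidence) & (work.calls != MISSING)
        work.calls[mask] = MISSING
        report.notes.append(f"confidence_mask: {int(mask.sum())} calls set missing")

    keep = np.ones(work.n_snps, dtype=bool)
    ids = work.snps["snp_id"].to_numpy()

    def drop(reason: str, bad: np.ndarray) -> None:
        bad = bad & keep
        if bad.any():
            report.snp_removals.setdefault(reason, []).extend(ids[bad].tolist())
        keep[bad] = False

    call_rate, p, het, n_obs = _column_stats(work.calls)
    drop("call_rate", call_rate < thr.call_rate)

    # heterozygosity band from the surviving panel
    mu, sd = het[keep].mean(), het[keep].std()
    if sd > 0:
        drop("heterozygosity", np.abs(het - mu) > thr.het_sd * sd)

    maf = np.minimum(p, 1 - p)
    drop("maf", maf < thr.maf)

    chrom = work.snps["chrom"].astype(str).to_numpy()
    drop("sex_chromosome", np.isin(chrom, thr.sex_chromosomes))

    hwe_p = np.ones(work.n_snps)
    for j in np.flatnonzero(keep):
        col = work.calls[:, j]
        counts = ((col == 0).sum(), (col == 1).sum(), (col == 2).sum())
        hwe_p[j] = hwe_test(counts)
    drop("hwe", hwe_p < thr.hwe_p)

    if not keep.any():
        raise ValueError("empty panel: QC removed every SNP")
    out = work.subset(snp_idx=np.flatnonzero(keep))
    report.n_snps_after = out.n_snps
    return out, report


def qc_samples(
    table: GenotypeTable, dup_threshold: float = 0.99
) -> tuple[GenotypeTable, QCReport]:
    """Remove near-duplicate samples.

    Pairwise Pearson correlations of the 0/1/2 genotype vectors are
    computed over jointly non-missing calls; for each pair at or above
    ``dup_threshold`` the later-indexed sample is removed (the
    first-indexed one is kept). A fast mean-imputed screen at a safely
    lower cutoff pre-selects candidate pairs; flagged pairs are then
    re-evaluated exactly on jointly observed calls.
    """
    if table.n_animals < 2:
        raise ValueError("need at least 2 samples")
    d = table.dosage()
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean, d)
    z = filled - filled.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = (z @ z.T) / np.outer(norm, norm)
    screen = max(0.0, dup_threshold - 0.05)
    cand = np.argwhere(np.triu(corr >= screen, k=1))

    removed: set[int] = set()
    for i, j in cand:
        if j in removed:
            continue
        both = (~np.isnan(d[i])) & (~np.isnan(d[j]))
        if both.sum() < 2:
            continue
        xi, xj = d[i, both], d[j, both]
        if xi.std() == 0 or xj.std() == 0:
            r = 1.0 if np.array_equal(xi, xj) else 0.0
        else:
            r = float(np.corrcoef(xi, xj)[0, 1])
        if r >= dup_threshold:
            removed.add(int(j))

    report = QCReport(
        n_snps_before=table.n_snps,
        n_snps_after=table.n_snps,
        n_samples_before=table.n_animals,
        thresholds={"dup_threshold": dup_threshold},
        filter_order=["duplicate_sample"],
        sample_removals=[table.animal_ids[i] for i in sorted(removed)],
    )
    keep_idx = [i for i in range(table.n_animals) if i not in removed]
    if not keep_idx:
        raise ValueError("duplicate filter removed every sample")
    out = table.subset(animal_idx=keep_idx)
    report.n_samples_after = out.n_animals
    return out, report


def impute_missing(table: GenotypeTable, rounded: bool = False) -> GenotypeTable:
    """Replace missing calls with the SNP mean genotype ``2 p_hat``.

    This is a deliberate, frequency-preserving stand-in for phasing-based
    imputation; at the low missingness left after QC it leaves genomic
    relationship matrices essentially unchanged. With ``rounded`` the
    imputed value is rounded to the nearest integer genotype.

    Returns a table whose ``calls`` array is float when ``rounded`` is
    False (dosages are no longer integers).
    """
    d = table.dosage()
    miss = np.isnan(d)
    if not miss.any():
        return table.copy()
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = table.snps["snp_id"][n_obs == 0].tolist()
        raise ValueError(f"SNPs with all calls missing (filter first): {bad}")
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(miss, col_mean, d)
    out = table.copy()
    if rounded:
        out.calls = np.clip(np.rint(filled), 0, 2).astype(np.int8)
    else:
        # float dosage matrix; assignment bypasses the int8 constructor check
        out.calls = filled
    return out


def trim_phenotype_outliers(
    records: pd.DataFrame, value_col: str = "y", k_sd: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records more than ``k_sd`` standard deviations from the mean.

    The mean and SD are computed once on the full record set (no
    re-iteration after removal). Returns (kept, removed).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    y = records[value_col].to_numpy(dtype=float)
    mu, sd = y.mean(), y.std()
    if sd == 0:
        if np.any(y != mu):  # pragma: no cover - unreachable with sd == 0
            warnings.warn("zero variance with deviating values; nothing removed")
        return records.copy(), records.iloc[0:0].copy()
    out = np.abs(y - mu) > k_sd * sd
    return records.loc[~out].copy(), records.loc[out].copy()
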