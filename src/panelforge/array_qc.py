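"""Microarray genotyping QC cascade.

Sample-level QC drops samples whose (call rate, P10 intensity) point falls
outside the majority cluster; the platform workflow does this visually, so
it is operationalized here as a robust-distance rule: coordinates are
standardized by median/MAD and samples beyond the chi-square(2) cutoff at
1 - alpha (default alpha = 0.01) are excluded.  An explicit exclusion list
can be supplied instead.

SNP-level QC then applies the standard thresholds with strict inequalities:
Cluster Sep < 0.3, more than 10 % no-calls, AB R Mean < 0.12 — followed by
a biallelic requirement and a pooled minor-allele-frequency filter
(MAF > 0.01).  No-call fraction and MAF are recomputed over the retained
samples, i.e. sample exclusion precedes the SNP statistics (the cascade
order is fixed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "flag_outlier_samples",
    "filter_array_snps",
    "recompute_snp_stats",
    "array_pipeline",
]

DEFAULT_THRESHOLDS = {"cluster_sep": 0.3, "nocall": 0.10, "ab_r_mean": 0.12}


def flag_outlier_samples(samples: pd.DataFrame, alpha: float = 0.01) -> list[str]:
    """Sample ids falling outside the majority cluster in (call_rate, p10).

    Robust squared distance: sum over the two coordinates of
    ((x - median) / (1.4826 * MAD))^2, compared against the chi-square(2)
    quantile at 1 - alpha.  A zero MAD (constant coordinate) contributes 0
    for on-median values and infinity otherwise.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to define a majority cluster")
    x = samples[["call_rate", "p10"]].to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0) * 1.4826
    d2 = np.zeros(len(x))
    for j in range(2):
        dev = x[:, j] - med[j]
        if mad[j] == 0:
            d2 += np.where(dev == 0, 0.0, np.inf)
        else:
            d2 += (dev / mad[j]) ** 2
    cutoff = stats.chi2.ppf(1.0 - alpha, df=2)
    out = d2 > cutoff
    return samples.loc[out, "sample_id"].tolist()


def filter_array_snps(
    snps: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Exclude SNPs with cluster_sep < 0.3 OR nocall_fraction > 0.10 OR
    ab_r_mean < 0.12 (strict inequalities; defaults overridable).

    Returns (retained records, report).  The report counts exclusions per
    reason — a record may carry several reasons — and the retained/excluded
    sets always partition the input.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    bad_sep = snps["cluster_sep"] < th["cluster_sep"]
    bad_nc = snps["nocall_fraction"] > th["nocall"]
    bad_ab = snps["ab_r_mean"] < th["ab_r_mean"]
    excluded = bad_sep | bad_nc | bad_ab
    report = {
        "input": int(len(snps)),
        "excluded": int(excluded.sum()),
        "retained": int((~excluded).sum()),
        "by_reason": {
            "cluster_sep": int(bad_sep.sum()),
            "nocall": int(bad_nc.sum()),
            "ab_r_mean": int(bad_ab.sum()),
        },
    }
    return snps.loc[~excluded].copy(), report


def _genotype_columns(snps: pd.DataFrame) -> list[str]:
    return [c for c in snps.columns if c.startswith("gt_")]


def recompute_snp_stats(snps: pd.DataFrame, retained_samples: list[str]) -> pd.DataFrame:
    """Recompute nocall_fraction and MAF over the retained samples only.

    Genotype columns are ``gt_<sample_id>`` with calls AA/AB/BB/NC.
    """
    cols = [f"gt_{s}" for s in retained_samples]
    missing = [c for c in cols if c not in snps.columns]
    if missing:
        raise ValueError(f"genotype columns absent for samples: {missing}")
    calls = snps[cols].to_numpy(dtype=object)
    nc = calls == "NC"
    n = len(cols)
    out = snps.copy()
    out["nocall_fraction"] = nc.sum(axis=1) / n
    b_alleles = (calls == "AB").sum(axis=1) + 2 * (calls == "BB").sum(axis=1)
    total = 2 * (n - nc.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(total > 0, b_alleles / np.maximum(total, 1), 0.0)
    out["maf"] = np.minimum(freq_b, 1.0 - freq_b)
    return out


def array_pipeline(
    sample_table: pd.DataFrame,
    snp_table: pd.DataFrame,
    maf_min: float = 0.01,
    alpha: float = 0.01,
    thresholds: dict[str, float] | None = None,
    exclude_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full array QC cascade, in fixed order:

    1. exclude outlier samples (robust-distance rule, or an explicit list);
    2. recompute no-call fraction and MAF over the retained samples;
    3. drop SNPs failing cluster-separation / no-call / AB-intensity;
    4. keep biallelic SNPs only;
    5. keep SNPs with MAF strictly > ``maf_min``.

    Returns (final site list with chrom/pos, report).
    """
    if exclude_samples is None:
        exclude_samples = flag_outlier_samples(sample_table, alpha=alpha)
    retained_samples = [
        s for s in sample_table["sample_id"] if s not in set(exclude_samples)
    ]
    if not retained_samples:
        raise ValueError("all samples excluded by sample QC")

    snps = recompute_snp_stats(snp_table, retained_samples)
    snps, snp_report = filter_array_snps(snps, thresholds)
    n_after_qc = len(snps)
    if "biallelic" in snps.columns:
        snps = snps[snps["biallelic"].astype(bool)]
    n_after_biallelic = len(snps)
    snps = snps[snps["maf"] > maf_min]

    keep_cols = [c for c in ["snp_id", "chrom", "pos", "maf"] if c in snps.columns]
    sites = snps[keep_cols].reset_index(drop=True)
    report = {
        "excluded_samples": list(exclude_samples),
        "retained_samples": len(retained_samples),
        "snp_qc": snp_report,
        "after_biallelic": n_after_biallelic,
        "removed_non_biallelic": n_after_qc - n_after_biallelic,
        "removed_low_maf": n_after_biallelic - len(sites),
        "final_snps": len(sites),
    }
    return sites, report
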