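"""SNP, sample, ancestry-outlier, relatedness and phenotype QC filters.

The filters mirror a standard biobank-scale cleaning protocol for
cross-population analyses: per-SNP missingness / MAF / Hardy-Weinberg
filters, a per-sample call-rate filter, removal of ancestry outliers on the
first two principal components, greedy pruning of one member of each
related pair, and per-group phenotype preparation (outlier removal,
covariate adjustment, rank-based inverse-normal transform).  All filters
are idempotent and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .simulate import MISSING, GenotypeDataset

__all__ = [
    "QcThresholds",
    "hwe_exact_test",
    "snp_qc",
    "sample_qc",
    "pc_outlier_filter",
    "relatedness_prune",
    "phenotype_prep",
]


@dataclass
class QcThresholds:
    """Default cut-offs for the filtering pipeline.

    SNPs with missing rate > ``snp_missing_max``, MAF < ``maf_min`` or HWE
    exact-test P < ``hwe_p_min`` are removed; samples with call rate
    < ``sample_callrate_min`` are removed (strict inequality); PC outliers
    beyond ``pc_sd_cut`` reference SDs on PC1 or PC2 are removed; of each
    pair with relatedness > ``relatedness_max`` one member is dropped;
    phenotype values beyond ``pheno_sd_cut`` SDs are excluded before the
    inverse-normal transform.
    """

    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    sample_callrate_min: float = 0.90
    pc_sd_cut: float = 6.0
    relatedness_max: float = 0.05
    pheno_sd_cut: float = 5.0


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test P-value from genotype counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one (the standard exact test; no mid-p correction).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability of each possible het count with `rare` minor alleles in n diploids
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1.0)
        - gammaln(hom_r + 1.0)
        - gammaln(hom_c + 1.0)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def snp_qc(
    dataset: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeDataset, dict[str, int]]:
    """Remove SNPs failing missingness, MAF or HWE, in that fixed order.

    Returns the filtered dataset and per-criterion removal counts
    ``{"missingness": ..., "maf": ..., "hwe": ...}``; a SNP is counted
    against the first criterion it fails.  The HWE test is applied to the
    pooled sample (run per population and intersect if the cohorts are
    strongly diverged).
    """
    g = dataset.genotypes
    n, m = g.shape
    missing = (g == MISSING).mean(axis=0)
    keep = np.ones(m, dtype=bool)
    counts = {"missingness": 0, "maf": 0, "hwe": 0}

    fail = missing > thresholds.snp_missing_max
    counts["missingness"] = int(fail.sum())
    keep &= ~fail

    freq = dataset.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    fail = (maf < thresholds.maf_min) & keep
    counts["maf"] = int(fail.sum())
    keep &= ~fail

    for j in np.where(keep)[0]:
        col = g[:, j]
        n_het = int((col == 1).sum())
        n_hom1 = int((col == 2).sum())
        n_hom2 = int((col == 0).sum())
        if hwe_exact_test(n_het, n_hom1, n_hom2) < thresholds.hwe_p_min:
            keep[j] = False
            counts["hwe"] += 1

    if not keep.any():
        raise ValueError("SNP QC removed every SNP: empty panel")
    return dataset.subset_snps(np.where(keep)[0]), counts


def sample_qc(
    dataset: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
) -> GenotypeDataset:
    """Remove individuals with call rate strictly below the threshold."""
    call_rate = (dataset.genotypes != MISSING).mean(axis=1)
    keep = ~(call_rate < thresholds.sample_callrate_min)
    if not keep.any():
        raise ValueError("sample QC removed every individual")
    return dataset.subset_samples(np.where(keep)[0])


def pc_outlier_filter(
    pcs: np.ndarray,
    reference_mean: np.ndarray,
    reference_sd: np.ndarray,
    sd_cut: float = 6.0,
) -> np.ndarray:
    """Indices of samples within ``sd_cut`` reference SDs on both PC1 and PC2.

    The reference mean/SD would come from an external panel on real data;
    on synthetic data the target population's own (robust) moments serve.
    """
    mu = np.asarray(reference_mean, float)[:2]
    sd = np.asarray(reference_sd, float)[:2]
    if np.any(sd <= 0):
        raise ValueError("reference SDs must be positive")
    dev = np.abs(pcs[:, :2] - mu) / sd
    return np.where(~(dev > sd_cut).any(axis=1))[0]


def relatedness_prune(grm_matrix: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Greedy pruning: indices of samples retained so no pair exceeds threshold.

    Repeatedly drops the individual participating in the most over-threshold
    pairs (ties broken by lowest sample index) until none remain — a
    deterministic vertex cover of the relatedness graph.
    """
    a = np.asarray(grm_matrix, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("GRM must be square and symmetric")
    n = a.shape[0]
    over = np.triu(a > threshold, 1)
    adj = over | over.T
    active = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(int)
    while True:
        if degree[active].max(initial=0) == 0:
            break
        d = np.where(active, degree, -1)
        worst = int(np.argmax(d))  # argmax takes the lowest index on ties
        active[worst] = False
        degree[adj[worst]] -= 1
        degree[worst] = 0
        adj[worst, :] = False
        adj[:, worst] = False
    return np.where(active)[0]


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform Phi^{-1}((rank - 0.5)/k).

    Ties get average ranks; NaNs pass through untouched.
    """
    x = np.asarray(values, float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    k = int(ok.sum())
    if k:
        ranks = rankdata(x[ok], method="average")
        out[ok] = norm.ppf((ranks - 0.5) / k)
    return out


def phenotype_prep(
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray],
    groups: np.ndarray,
    sd_cut: float = 5.0,
) -> np.ndarray:
    """Analysis-ready phenotype: per-group outlier removal, covariate
    adjustment, and rank-based inverse-normal transform of the residuals.

    ``groups`` labels the sex-by-cohort cells the protocol operates within.
    Outliers (|x - mean| > sd_cut * SD, moments of the group) are set to NaN
    first, as the protocol removes them before any adjustment; covariates
    are then regressed out of the survivors and the residuals are
    inverse-normal transformed, giving mean ~0 and variance ~1 per group.
    """
    y = np.asarray(phenotype, float).copy()
    groups = np.asarray(groups)
    out = np.full_like(y, np.nan)
    for gval in pd.unique(groups):
        mask = (groups == gval) & ~np.isnan(y)
        if mask.sum() < 3:
            raise ValueError(f"group {gval!r} has fewer than 3 non-missing values")
        sub = y[mask]
        mu, sd = sub.mean(), sub.std(ddof=1)
        ok = np.abs(sub - mu) <= sd_cut * sd if sd > 0 else np.ones(len(sub), bool)
        idx = np.where(mask)[0][ok]
        resid = y[idx]
        if covariates is not None:
            x = np.column_stack([np.ones(len(idx)), np.asarray(covariates, float)[idx]])
            beta, *_ = np.linalg.lstsq(x, resid, rcond=None)
            resid = resid - x @ beta
        out[idx] = inverse_normal_transform(resid)
    return out
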