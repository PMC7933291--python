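"""GWAS scan, LD clumping to sentinel SNPs, split-sample re-estimation, and
the error-corrected cross-population effect correlation r_b.

The r_b statistic is the correlation of per-SNP effect sizes between two
sets of GWAS estimates after removing the attenuation caused by estimation
error: the naive Pearson correlation of noisy effect estimates is biased
towards zero by the error variance in each set, so both variances are
corrected by the mean squared standard error before forming the ratio,

    r_b = cov(b_a, b_b) / sqrt[(var(b_a) - mean(se_a^2)) (var(b_b) - mean(se_b^2))],

valid when the two sets' errors are independent (disjoint samples).  Its
standard error comes from a delete-one jackknife over the sentinel SNPs.
Winner's curse is avoided by re-estimating effects at sentinels chosen in a
disjoint discovery sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .simulate import MISSING, GenotypeDataset

__all__ = [
    "read_ma",
    "write_ma",
    "gwas_scan",
    "clump",
    "clump_two_round",
    "SentinelSet",
    "split_sample_reestimate",
    "rb_estimate",
    "negative_control",
]

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def read_ma(path: str) -> pd.DataFrame:
    """Read a COJO-style .ma file: SNP A1 A2 freq b se p N (header required)."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str, "A1": str, "A2": str})
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing .ma columns {missing}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{path}: non-positive standard errors")
    return df[MA_COLUMNS]


def write_ma(sumstats: pd.DataFrame, path: str) -> None:
    sumstats[MA_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class SentinelSet:
    """Sentinel SNP ids (in selection order) plus full clump membership."""

    sentinels: list[str]
    clumps: dict[str, list[str]]  # sentinel -> member SNP ids (incl. itself)

    def __len__(self) -> int:
        return len(self.sentinels)

    def write(self, path: str) -> None:
        """One sentinel id per line, in selection order."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.sentinels) + "\n")


def gwas_scan(
    dataset: GenotypeDataset,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    sample_index: np.ndarray | None = None,
    snp_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP least squares of the phenotype on A1 dosage with covariates.

    Covariates (plus an intercept) are projected out of both the phenotype
    and the genotypes once, after which each SNP's per-allele effect, SE and
    two-sided P follow in closed form with the correct residual degrees of
    freedom.  Missing genotypes are mean-imputed; monomorphic SNPs are
    skipped (NaN row).  Returns a COJO-style .ma table.
    """
    idx = np.arange(dataset.n_samples) if sample_index is None else np.asarray(sample_index)
    jdx = np.arange(dataset.n_snps) if snp_index is None else np.asarray(snp_index)
    y = np.asarray(phenotype, float)[idx]
    keep = ~np.isnan(y)
    idx, y = idx[keep], y[keep]
    n = len(idx)
    g = dataset.genotypes[np.ix_(idx, jdx)].astype(float)
    g[g == MISSING] = np.nan
    n_obs = (~np.isnan(g)).sum(axis=0)
    freq = np.nanmean(g, axis=0) / 2.0
    col_mean = np.nanmean(g, axis=0)
    ginds = np.where(np.isnan(g))
    g[ginds] = col_mean[ginds[1]]

    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != dataset.n_samples:
            cov = cov.T
        x = np.column_stack([np.ones(n), cov[idx]])
    else:
        x = np.ones((n, 1))
    p_cov = np.linalg.matrix_rank(x)
    q, _ = np.linalg.qr(x)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)

    sxx = (g_r * g_r).sum(axis=0)
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (g_r * y_r[:, None]).sum(axis=0) / sxx_safe
    dof = n - p_cov - 1
    rss = (y_r * y_r).sum() - beta * beta * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
        pval = 2.0 * t_dist.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan

    st = dataset.snp_table.iloc[jdx]
    return pd.DataFrame(
        {
            "SNP": st["snp"].to_numpy(),
            "A1": st["a1"].to_numpy(),
            "A2": st["a2"].to_numpy(),
            "freq": freq,
            "b": beta,
            "se": se,
            "p": pval,
            "N": n_obs,
        }
    )


def clump(
    sumstats: pd.DataFrame,
    dataset: GenotypeDataset,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 1000.0,
    sample_index: np.ndarray | None = None,
) -> SentinelSet:
    """Greedy p-value-ordered LD clumping.

    Repeatedly the smallest-p unassigned SNP below ``p_threshold`` becomes a
    sentinel and absorbs every unassigned SNP within +/- ``window_kb`` whose
    LD r^2 with it (computed from ``dataset``'s dosages) exceeds
    ``r2_threshold``.  Ties in p are broken by position, then id.  The
    result is invariant to input row order.
    """
    st = dataset.snp_table.set_index("snp")
    ss = sumstats.dropna(subset=["p"]).copy()
    unknown = set(ss["SNP"]) - set(st.index)
    if unknown:
        raise ValueError(f"{len(unknown)} sumstats SNPs absent from the LD reference")
    ss["pos"] = st.loc[ss["SNP"], "pos"].to_numpy()
    ss["chrom"] = st.loc[ss["SNP"], "chrom"].to_numpy()
    ss = ss[ss["p"] < p_threshold]
    ss = ss.sort_values(["p", "pos", "SNP"], kind="stable").reset_index(drop=True)

    snp_col = {s: j for j, s in enumerate(dataset.snp_table["snp"])}
    idx = np.arange(dataset.n_samples) if sample_index is None else np.asarray(sample_index)
    g = dataset.genotypes[idx].astype(float)
    g[g == MISSING] = np.nan

    def r2(j1: int, j2: int) -> float:
        a, b = g[:, j1], g[:, j2]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            return 0.0
        a, b = a[ok], b[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    assigned = np.zeros(len(ss), dtype=bool)
    sentinels: list[str] = []
    clumps: dict[str, list[str]] = {}
    window = window_kb * 1000.0
    pos = ss["pos"].to_numpy()
    chrom = ss["chrom"].to_numpy()
    ids = ss["SNP"].to_numpy()
    for i in range(len(ss)):
        if assigned[i]:
            continue
        assigned[i] = True
        sent = ids[i]
        sentinels.append(sent)
        members = [sent]
        near = np.where(
            ~assigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        )[0]
        for j in near:
            if r2(snp_col[sent], snp_col[ids[j]]) > r2_threshold:
                assigned[j] = True
                members.append(ids[j])
        clumps[sent] = members
    return SentinelSet(sentinels, clumps)


def clump_two_round(
    sumstats: pd.DataFrame,
    dataset: GenotypeDataset,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 1000.0,
    window2_kb: float = 10_000.0,
    sample_index: np.ndarray | None = None,
) -> SentinelSet:
    """Two-round clumping: a second pass over round-1 sentinels with a much
    larger window removes residual long-range LD between sentinels."""
    first = clump(sumstats, dataset, p_threshold, r2_threshold, window_kb, sample_index)
    ss2 = sumstats[sumstats["SNP"].isin(first.sentinels)]
    return clump(ss2, dataset, p_threshold, r2_threshold, window2_kb, sample_index)


def split_sample_reestimate(
    dataset: GenotypeDataset,
    phenotype: np.ndarray,
    discovery_fraction: float,
    rng: np.random.Generator,
    population: int | None = None,
    covariates: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Disjoint discovery/estimation split with GWAS in each half.

    Returns ``(sumstats_discovery, sumstats_estimation, idx_discovery,
    idx_estimation)``.  Selecting sentinels in the discovery half and taking
    their effects from the estimation half removes winner's-curse bias, the
    design used when external-consortium discovery is replayed in-sample.
    """
    if not 0.0 < discovery_fraction < 1.0:
        raise ValueError("discovery_fraction must lie in (0, 1)")
    pool = (
        np.arange(dataset.n_samples)
        if population is None
        else np.where(dataset.population_mask(population))[0]
    )
    perm = rng.permutation(len(pool))
    n_disc = int(round(discovery_fraction * len(pool)))
    idx_d = np.sort(pool[perm[:n_disc]])
    idx_e = np.sort(pool[perm[n_disc:]])
    assert not np.intersect1d(idx_d, idx_e).size
    ss_d = gwas_scan(dataset, phenotype, covariates, sample_index=idx_d)
    ss_e = gwas_scan(dataset, phenotype, covariates, sample_index=idx_e)
    return ss_d, ss_e, idx_d, idx_e


def _harmonize(
    a: pd.DataFrame, b: pd.DataFrame, sentinel_ids: list[str] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ai = a.set_index("SNP")
    bi = b.set_index("SNP")
    ids = [s for s in sentinel_ids if s in ai.index and s in bi.index]
    ba, sea, bb, seb = [], [], [], []
    for s in ids:
        ra, rb_ = ai.loc[s], bi.loc[s]
        if (ra["A1"], ra["A2"]) == (rb_["A1"], rb_["A2"]):
            sign = 1.0
        elif (ra["A1"], ra["A2"]) == (rb_["A2"], rb_["A1"]):
            sign = -1.0
        else:
            raise ValueError(f"sentinel {s}: alleles do not match between the two sets")
        ba.append(ra["b"])
        sea.append(ra["se"])
        bb.append(sign * rb_["b"])
        seb.append(rb_["se"])
    return (np.array(ba, float), np.array(sea, float),
            np.array(bb, float), np.array(seb, float))


def _rb(ba: np.ndarray, sea: np.ndarray, bb: np.ndarray, seb: np.ndarray) -> float:
    va = ba.var(ddof=1) - np.mean(sea**2)
    vb = bb.var(ddof=1) - np.mean(seb**2)
    if va <= 0 or vb <= 0:
        raise ValueError(
            "error-corrected effect variance is non-positive: estimation noise "
            "exceeds the effect-size signal, r_b is undefined"
        )
    cov = np.cov(ba, bb, ddof=1)[0, 1]
    return float(cov / np.sqrt(va * vb))


def rb_estimate(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    sentinel_ids: list[str] | np.ndarray,
    min_sentinels: int = 10,
) -> tuple[float, float]:
    """Error-corrected effect correlation at sentinel SNPs with jackknife SE.

    Effects are harmonized to a shared effect allele (signs flipped when the
    allele labels are swapped).  Returns ``(r_b, se_jackknife)`` where the
    SE is the delete-one jackknife over sentinels:
    SE^2 = (k-1)/k * sum_j (r_b(-j) - mean(r_b(-.)))^2.
    """
    ba, sea, bb, seb = _harmonize(sumstats_a, sumstats_b, sentinel_ids)
    k = len(ba)
    if k < min_sentinels:
        raise ValueError(f"only {k} shared sentinels; need >= {min_sentinels}")
    r = _rb(ba, sea, bb, seb)
    loo = np.empty(k)
    mask = np.ones(k, dtype=bool)
    for j in range(k):
        mask[j] = False
        loo[j] = _rb(ba[mask], sea[mask], bb[mask], seb[mask])
        mask[j] = True
    se = np.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2))
    return r, float(se)


def negative_control(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    sentinel_ids: list[str] | np.ndarray,
) -> tuple[float, float]:
    """r_b between two disjoint same-population samples; expected ~1.

    Passing the same estimates twice is rejected: the correction assumes
    independent errors, which identical inputs violate by construction.
    """
    ba, sea, bb, seb = _harmonize(sumstats_a, sumstats_b, sentinel_ids)
    if np.array_equal(ba, bb) and np.array_equal(sea, seb):
        raise ValueError(
            "the two summary-statistic sets are identical: the negative control "
            "requires disjoint samples with independent errors"
        )
    return rb_estimate(sumstats_a, sumstats_b, sentinel_ids)
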