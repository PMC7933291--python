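"""Per-SNP F_ST and LD-score differentiation, MAF-LD matched binning, and
the low/high split feeding the two-component GREML contrast.

The stratification protocol: SNPs are first placed into equal-count
frequency bins (MAF in population 1 crossed with the frequency of the same
allele in population 2), each frequency cell is then split into LD-score
bins per population (nested, so LD quantiles are computed within the cell),
and finally the SNPs of every joint bin are divided into a low and a high
group by the sorted differentiation metric (F_ST or LDCV).  Matching on
frequency and LD before splitting is what isolates the differentiation
signal from its confounders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import compute_grm
from .greml import BivariateModel, GREMLFit, reml_fit
from .simulate import GenotypeDataset

__all__ = [
    "SnpStrata",
    "fst_hudson",
    "fst_hudson_overall",
    "fst_weir_cockerham",
    "fst_per_snp",
    "ld_scores",
    "ldcv",
    "make_bins",
    "split_within_bins",
    "build_strata",
    "two_component_fit",
]


@dataclass
class SnpStrata:
    """Per-SNP differentiation metrics, bin assignment and group label."""

    table: pd.DataFrame  # snp, freq1, freq2, fst, ld1, ld2, ldcv, bin, group
    n_possible_bins: int

    def group_index(self, group: str) -> np.ndarray:
        return np.where(self.table["group"].to_numpy() == group)[0]

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fst_hudson(
    freq1: np.ndarray, n1: int | np.ndarray, freq2: np.ndarray, n2: int | np.ndarray
) -> np.ndarray:
    """Hudson's two-population per-SNP F_ST estimator.

    F = [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
        / [p1(1-p2) + p2(1-p1)]

    ``n1``/``n2`` count sampled allele copies (2x the diploid sample size),
    which is the scale on which the sampling-variance correction makes the
    estimator unbiased for the Balding-Nichols F.  Negative values are
    retained; SNPs with an undefined denominator (both frequencies 0 or
    both 1) come back as NaN for the caller to exclude.
    """
    p1, p2 = np.asarray(freq1, float), np.asarray(freq2, float)
    n1a, n2a = np.asarray(n1, float), np.asarray(n2, float)
    if np.any(n1a < 2) or np.any(n2a < 2):
        raise ValueError("need at least 2 sampled allele copies per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1a - 1) - p2 * (1 - p2) / (n2a - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def fst_hudson_overall(
    freq1: np.ndarray, n1: int | np.ndarray, freq2: np.ndarray, n2: int | np.ndarray
) -> float:
    """Genome-wide Hudson F_ST: ratio of summed numerators to summed
    denominators across SNPs.

    The ratio-of-averages combination is unbiased for the divergence
    parameter (E[num]/E[den] = F under the island model), whereas averaging
    the per-SNP ratios is biased downward because numerator and denominator
    are correlated.  Per-SNP values from :func:`fst_hudson` are for ranking;
    this is the summary to report.
    """
    p1, p2 = np.asarray(freq1, float), np.asarray(freq2, float)
    n1a, n2a = np.asarray(n1, float), np.asarray(n2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1a - 1) - p2 * (1 - p2) / (n2a - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


def fst_weir_cockerham(
    freq1: np.ndarray, n1: int | np.ndarray, freq2: np.ndarray, n2: int | np.ndarray
) -> np.ndarray:
    """Weir & Cockerham's theta for two populations from allele frequencies.

    The frequency-only form (random-mating within populations assumed), with
    ``n1``/``n2`` again counting allele copies.  Available as an alternative
    ranking metric; Hudson is the default.
    """
    p1, p2 = np.asarray(freq1, float), np.asarray(freq2, float)
    n1a, n2a = np.asarray(n1, float) / 2.0, np.asarray(n2, float) / 2.0  # diploids
    r = 2.0
    n_bar = (n1a + n2a) / r
    nc = (r * n_bar - (n1a**2 + n2a**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1a * p1 + n2a * p2) / (r * n_bar)
    s2 = (n1a * (p1 - p_bar) ** 2 + n2a * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1a * 2 * p1 * (1 - p1) + n2a * 2 * p2 * (1 - p2)) / (r * n_bar)
    a = n_bar / nc * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    return out


def fst_per_snp(
    freq1: np.ndarray,
    n1: int | np.ndarray,
    freq2: np.ndarray,
    n2: int | np.ndarray,
    estimator: str = "hudson",
) -> np.ndarray:
    """Per-SNP F_ST with the chosen estimator ('hudson' or 'weir-cockerham')."""
    if estimator == "hudson":
        return fst_hudson(freq1, n1, freq2, n2)
    if estimator == "weir-cockerham":
        return fst_weir_cockerham(freq1, n1, freq2, n2)
    raise ValueError(f"unknown estimator {estimator!r}")


def ld_scores(
    genotypes: np.ndarray,
    positions: np.ndarray,
    window_kb: float = 1000.0,
    adjust: bool = True,
) -> np.ndarray:
    """Per-SNP LD score: sum of (adjusted) r^2 with SNPs inside the window.

    The bias adjustment r2_adj = r2 - (1 - r2)/(n - 2) removes the E[r2]
    inflation of order 1/n under no LD, so independent SNPs have expected
    score ~1 (the unadjusted self term).  Positions must be sorted; the
    window is +/- ``window_kb`` kilobases.
    """
    g = np.asarray(genotypes, float)
    n, m = g.shape
    if n <= 2:
        raise ValueError("LD scores need more than 2 samples")
    pos = np.asarray(positions, float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    z = g - g.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: zero correlation with everything
    z = z / sd
    window = window_kb * 1000.0
    lo = np.searchsorted(pos, pos - window, side="left")
    hi = np.searchsorted(pos, pos + window, side="right")
    scores = np.empty(m)
    chunk = 256
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        span_lo, span_hi = lo[start], hi[stop - 1]
        r = (z[:, start:stop].T @ z[:, span_lo:span_hi]) / n
        r2 = r * r
        if adjust:
            r2 = r2 - (1.0 - r2) / (n - 2)
        for j in range(start, stop):
            # self term contributes exactly 1 either way: r2 = 1 and the
            # adjustment 1 - (1-1)/(n-2) leaves it at 1.
            scores[j] = r2[j - start, lo[j] - span_lo: hi[j] - span_lo].sum()
    return scores


def ldcv(ld_score_pop1: np.ndarray, ld_score_pop2: np.ndarray) -> np.ndarray:
    """Coefficient of variation of the two populations' LD scores per SNP.

    CV = sample SD of (l1, l2) / their mean = |l1 - l2| / (sqrt(2) * mean).
    Scale-invariant; zero when the scores agree.
    """
    l1, l2 = np.asarray(ld_score_pop1, float), np.asarray(ld_score_pop2, float)
    if np.any(l1 < 0) or np.any(l2 < 0):
        raise ValueError("LD scores must be non-negative")
    mean = (l1 + l2) / 2.0
    if np.any(mean <= 0):
        raise ValueError("mean LD score must be positive")
    return np.abs(l1 - l2) / (np.sqrt(2.0) * mean)


def _equal_count_bins(values: np.ndarray, k: int) -> np.ndarray:
    """Rank-based equal-count bin index in [0, k); ties broken by index."""
    n = len(values)
    k = min(k, n) if n else k
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    if len(np.unique(values)) < k:
        warnings.warn(
            f"fewer distinct values ({len(np.unique(values))}) than bins ({k}); "
            "tied values are split by index order",
            stacklevel=3,
        )
    return ranks * k // max(n, 1)


def make_bins(
    freq1: np.ndarray,
    freq2: np.ndarray,
    ld1: np.ndarray,
    ld2: np.ndarray,
    n_freq_bins: int = 125,
    n_ld_bins: int = 4,
) -> tuple[np.ndarray, int]:
    """Joint MAF-LD bin index per SNP.

    Frequency axes: equal-count bins of the population-1 MAF and of the
    population-2 frequency *of the same allele* (the population-1 minor
    allele), so a systematic frequency shift lands in different joint bins
    rather than being folded away.  LD axes are nested: within each
    frequency cell, equal-count bins of each population's LD score.  The
    joint index enumerates n_freq^2 * n_ld^2 possible bins; the count is
    returned alongside.
    """
    if n_freq_bins < 1 or n_ld_bins < 1:
        raise ValueError("bin counts must be >= 1")
    p1, p2 = np.asarray(freq1, float), np.asarray(freq2, float)
    maf1 = np.minimum(p1, 1.0 - p1)
    same_allele_f2 = np.where(p1 <= 0.5, p2, 1.0 - p2)
    b1 = _equal_count_bins(maf1, n_freq_bins)
    b2 = _equal_count_bins(same_allele_f2, n_freq_bins)
    freq_cell = b1 * n_freq_bins + b2
    l1b = np.zeros(len(p1), dtype=int)
    l2b = np.zeros(len(p1), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny cells routinely tie
        for cell in np.unique(freq_cell):
            idx = np.where(freq_cell == cell)[0]
            l1b[idx] = _equal_count_bins(np.asarray(ld1)[idx], n_ld_bins)
            l2b[idx] = _equal_count_bins(np.asarray(ld2)[idx], n_ld_bins)
    joint = (freq_cell * n_ld_bins + l1b) * n_ld_bins + l2b
    return joint, n_freq_bins * n_freq_bins * n_ld_bins * n_ld_bins


def split_within_bins(
    bin_index: np.ndarray,
    metric: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Low/high group label per SNP from the within-bin sorted metric.

    Within every joint bin the SNPs are sorted by the metric (ties broken by
    SNP index); the lower half goes to ``"low"``, the upper half to
    ``"high"``.  In odd bins the median SNP is assigned by a seeded coin
    flip — the randomisation rule for 3-SNP bins, generalised to any odd
    count — so the expected group sizes stay balanced.
    """
    bin_index = np.asarray(bin_index)
    metric = np.asarray(metric, float)
    if not np.all(np.isfinite(metric)):
        raise ValueError("metric must be finite for every SNP (exclude NaNs first)")
    rng = np.random.default_rng(seed)
    group = np.empty(len(metric), dtype=object)
    # deterministic bin traversal: sorted unique bins
    order = np.lexsort((np.arange(len(metric)), metric, bin_index))
    sorted_bins = bin_index[order]
    starts = np.r_[0, np.where(np.diff(sorted_bins) != 0)[0] + 1, len(order)]
    for a, b in zip(starts[:-1], starts[1:]):
        members = order[a:b]  # already metric-sorted within the bin
        size = len(members)
        half = size // 2
        group[members[:half]] = "low"
        group[members[size - half:]] = "high"
        if size % 2:
            group[members[half]] = "high" if rng.integers(2) else "low"
    return group.astype(str)


def build_strata(
    dataset: GenotypeDataset,
    metric: str = "fst",
    n_freq_bins: int = 125,
    n_ld_bins: int = 4,
    window_kb: float = 1000.0,
    estimator: str = "hudson",
    seed: int = 0,
) -> SnpStrata:
    """Compute F_ST / LD scores / LDCV, bin, and split a dataset's SNPs.

    ``metric`` chooses the ranking variable: ``"fst"`` (with the frequency
    and LD bin counts of the allele-frequency analysis, 125 and 4 by
    default) or ``"ldcv"`` (conventionally 20 frequency and 25 LD bins).
    SNPs whose F_ST is undefined are dropped from the table with a warning.
    """
    mask1, mask2 = dataset.population_mask(1), dataset.population_mask(2)
    p1 = dataset.allele_frequencies(1)
    p2 = dataset.allele_frequencies(2)
    fst = fst_per_snp(p1, 2 * mask1.sum(), p2, 2 * mask2.sum(), estimator=estimator)
    pos = dataset.snp_table["pos"].to_numpy()
    l1 = ld_scores(dataset.genotypes[mask1], pos, window_kb=window_kb)
    l2 = ld_scores(dataset.genotypes[mask2], pos, window_kb=window_kb)
    cv = ldcv(np.maximum(l1, 0), np.maximum(l2, 0))
    ok = np.isfinite(fst)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} SNPs with undefined F_ST")
    joint, n_possible = make_bins(
        p1[ok], p2[ok], l1[ok], l2[ok], n_freq_bins=n_freq_bins, n_ld_bins=n_ld_bins
    )
    values = fst if metric == "fst" else cv
    if metric not in ("fst", "ldcv"):
        raise ValueError(f"unknown metric {metric!r}")
    group = split_within_bins(joint, values[ok], seed)
    table = pd.DataFrame(
        {
            "snp": dataset.snp_table["snp"].to_numpy()[ok],
            "snp_index": np.where(ok)[0],
            "freq1": p1[ok],
            "freq2": p2[ok],
            "fst": fst[ok],
            "ld1": l1[ok],
            "ld2": l2[ok],
            "ldcv": cv[ok],
            "bin": joint,
            "group": group,
        }
    )
    return SnpStrata(table, n_possible)


def two_component_fit(
    dataset: GenotypeDataset,
    strata: SnpStrata,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    **reml_options,
) -> GREMLFit:
    """Joint bivariate GREML with one genetic component per SNP group.

    Builds a population-specific-standardization GRM from the low-group and
    the high-group SNPs, stacks the two populations, and fits both
    components jointly so the sampling covariance between the two groups'
    estimates — required by the difference test — is available.
    Component 1 is the low group, component 2 the high group.
    """
    grms = []
    for grp in ("low", "high"):
        idx = strata.table.loc[strata.table["group"] == grp, "snp_index"].to_numpy()
        if len(idx) == 0:
            raise ValueError(f"group {grp!r} is empty")
        grms.append(compute_grm(dataset.subset_snps(idx), mode="specific").matrix)
    pops = dataset.sample_table["population"].to_numpy()
    order = np.argsort(pops, kind="stable")
    n1 = int((pops == 1).sum())
    y = np.asarray(phenotype, float)[order]
    cols = [np.r_[np.ones(n1), np.zeros(len(y) - n1)],
            np.r_[np.zeros(n1), np.ones(len(y) - n1)]]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov[order].T)
    x = np.column_stack(cols)
    grms = [a[np.ix_(order, order)] for a in grms]
    model = BivariateModel(y=y, X=x, grms=grms, n1=n1)
    return reml_fit(model, **reml_options)
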