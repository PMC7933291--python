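"""Two-population genotype/phenotype simulator with known ground truth.

The generator produces the study conditions every downstream stage is tested
against: two populations whose allele frequencies diverge under the
Balding-Nichols model (Beta-distributed around a shared ancestral frequency,
parameterised directly by F_ST), within-population LD generated by a latent
Gaussian AR(1) threshold model in independent blocks, polygenic causal
effects that are bivariate-normal across populations with correlation
``rg_true``, and population-specific heritabilities.

All randomness flows through one :class:`numpy.random.Generator`.  The
convenience driver :func:`simulate_dataset` derives per-stage child
generators from the model seed in a fixed order (frequencies, genotypes,
effects, phenotypes, missingness), so stages are individually reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "PopulationModel",
    "TraitArchitecture",
    "GenotypeDataset",
    "draw_allele_frequencies",
    "simulate_genotypes",
    "draw_effects",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class PopulationModel:
    """Demographic / genotypic parameters of the two simulated cohorts.

    ``fst_target`` is the Balding-Nichols F: the expected per-SNP fixation
    index between the two populations.  ``ld_rho`` is the latent-Gaussian
    correlation between adjacent SNPs within an LD block; blocks are
    mutually independent.  ``admix_fraction`` (population 2 only) draws a
    per-individual probability that a haplotype block descends from the
    population-1 frequency set; ``None`` disables admixture.
    """

    n_pop1: int = 2000
    n_pop2: int = 2000
    m: int = 5000
    fst_target: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.5
    admix_fraction: Optional[tuple[float, float]] = None  # Beta(a, b) params
    missing_rate: float = 0.0
    bp_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pop1, self.n_pop2, self.m) < 1:
            raise ValueError("n_pop1, n_pop2 and m must all be >= 1")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError(f"fst_target must lie in (0, 1), got {self.fst_target}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TraitArchitecture:
    """Genetic architecture shared by the two populations.

    ``rg_true`` is the correlation of per-SNP causal effects across
    populations; ``h2_pop1``/``h2_pop2`` the narrow-sense SNP heritability
    realised in each cohort.  With ``effect_scale_model="standardized"``
    effects act on unit-variance genotypes (the implicit GREML scale); with
    ``"per-allele"`` they act on raw 0/1/2 dosages.
    """

    m_causal: int = 1000
    rg_true: float = 0.7
    h2_pop1: float = 0.5
    h2_pop2: float = 0.4
    effect_scale_model: str = "standardized"

    def __post_init__(self) -> None:
        if not -1.0 <= self.rg_true <= 1.0:
            raise ValueError("rg_true must lie in [-1, 1]")
        for h2 in (self.h2_pop1, self.h2_pop2):
            if not 0.0 <= h2 <= 1.0:
                raise ValueError("heritabilities must lie in [0, 1]")
        if self.effect_scale_model not in ("standardized", "per-allele"):
            raise ValueError("effect_scale_model must be 'standardized' or 'per-allele'")


@dataclass
class GenotypeDataset:
    """n x m dosage matrix plus SNP / sample metadata and optional truth.

    ``genotypes`` counts copies of allele A1 (0, 1, 2; ``MISSING`` = -1).
    ``snp_table`` columns: snp, chrom, pos, a1, a2.  ``sample_table``
    columns: fid, iid, population (1 or 2), sex, admix_fraction.  ``truth``
    optionally carries the simulated per-SNP effect pairs, causal indices
    and per-population generating frequencies.
    """

    genotypes: np.ndarray
    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_table) != n or len(self.snp_table) != m:
            raise ValueError("metadata tables do not match genotype dimensions")
        if self.sample_table["iid"].duplicated().any():
            raise ValueError("sample ids must be unique")
        pos = self.snp_table.groupby("chrom")["pos"].apply(
            lambda s: bool(np.all(np.diff(s.to_numpy()) > 0))
        )
        if not pos.all():
            raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def population_mask(self, pop: int) -> np.ndarray:
        return (self.sample_table["population"].to_numpy() == pop)

    def allele_frequencies(self, pop: Optional[int] = None) -> np.ndarray:
        """Sample A1 frequency per SNP, ignoring missing genotypes."""
        g = self.genotypes if pop is None else self.genotypes[self.population_mask(pop)]
        g = np.ma.masked_equal(g, MISSING)
        return np.asarray(g.mean(axis=0) / 2.0)

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        truth = None
        if self.truth is not None:
            truth = {
                k: (np.asarray(v)[index] if np.ndim(v) == 1 and len(v) == self.n_snps else v)
                for k, v in self.truth.items()
                if k != "causal_index"
            }
        return GenotypeDataset(
            self.genotypes[:, index],
            self.snp_table.iloc[index].reset_index(drop=True),
            self.sample_table,
            truth,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.genotypes[np.asarray(index)],
            self.snp_table,
            self.sample_table.iloc[index].reset_index(drop=True),
            self.truth,
        )


def draw_allele_frequencies(
    ancestral_maf_range: tuple[float, float],
    fst_target: float,
    m: int,
    rng: np.random.Generator,
    clip: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balding-Nichols frequency pairs for ``m`` SNPs.

    The ancestral frequency p is uniform on ``ancestral_maf_range``; each
    population's frequency is an independent draw from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_target``, so that
    E[p_k] = p and Var[p_k] = F p(1-p).  Draws are clipped to
    [clip, 1-clip] so downstream genotype simulation never sees a fixed
    allele; with the default ancestral range the clip is essentially never
    active.

    Returns ``(p_ancestral, p_pop1, p_pop2)``.
    """
    if not 0.0 < fst_target < 1.0:
        raise ValueError("fst_target must lie in (0, 1)")
    lo, hi = ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if np.any(p_anc <= 0.0) or np.any(p_anc >= 1.0):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    scale = (1.0 - fst_target) / fst_target
    p1 = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    p2 = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    p1 = np.clip(p1, clip, 1.0 - clip)
    p2 = np.clip(p2, clip, 1.0 - clip)
    return p_anc, p1, p2


def _haplotypes(
    freqs: np.ndarray,
    n_hap: int,
    block_size: int,
    rho: float,
    rng: np.random.Generator,
    freqs_alt: Optional[np.ndarray] = None,
    alt_block_prob: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Latent-Gaussian AR(1) haplotypes thresholded at per-SNP frequencies.

    Within a block z_j = rho * z_{j-1} + sqrt(1-rho^2) * eps_j; the allele is
    carried when z_j < Phi^{-1}(p_j), so the marginal frequency is exactly
    p_j while adjacent SNPs share latent correlation rho.  When admixture is
    on, each (haplotype, block) pair is thresholded at ``freqs_alt`` with the
    per-haplotype probability ``alt_block_prob`` — the latent field is
    shared, so LD is preserved across the source switch.
    """
    m = len(freqs)
    z = rng.standard_normal((n_hap, m))
    if rho > 0.0 and block_size > 1:
        # z_j = rho z_{j-1} + sqrt(1-rho^2) eps_j within a block; applied as
        # one triangular mixing matrix per block so the recursion is a GEMM
        w = np.sqrt(1.0 - rho * rho)
        bs = block_size
        jk = np.subtract.outer(np.arange(bs), np.arange(bs))
        mix = np.where(jk >= 0, rho ** np.maximum(jk, 0), 0.0)
        mix[:, 1:] *= w
        full = (m // bs) * bs
        if full:
            blocks = z[:, :full].reshape(n_hap, -1, bs)
            z[:, :full] = (blocks @ mix.T).reshape(n_hap, full)
        if m > full:
            rem = m - full
            z[:, full:] = z[:, full:] @ mix[:rem, :rem].T
    thr = norm.ppf(freqs)
    hap = z < thr[None, :]
    if freqs_alt is not None:
        n_blocks = -(-m // block_size)
        use_alt = rng.random((n_hap, n_blocks)) < alt_block_prob[:, None]
        use_alt = np.repeat(use_alt, block_size, axis=1)[:, :m]
        hap_alt = z < norm.ppf(freqs_alt)[None, :]
        hap = np.where(use_alt, hap_alt, hap)
    return hap


def simulate_genotypes(
    freqs: tuple[np.ndarray, np.ndarray],
    model: PopulationModel,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Simulate diploid genotypes for both populations.

    ``freqs`` is the (p_pop1, p_pop2) pair from
    :func:`draw_allele_frequencies`.  Genotypes are the sum of two
    independent haplotypes per individual.  Population-2 individuals may be
    admixed (see :class:`PopulationModel`).  The returned dataset's truth
    sidecar records the generating frequencies.
    """
    p1, p2 = (np.asarray(f, dtype=float) for f in freqs)
    if p1.shape != p2.shape or len(p1) != model.m:
        raise ValueError("frequency arrays must both have length model.m")
    for p in (p1, p2):
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("frequencies must lie strictly in (0, 1)")

    h1 = _haplotypes(p1, 2 * model.n_pop1, model.ld_block_size, model.ld_rho, rng)
    g1 = h1.reshape(model.n_pop1, 2, model.m).sum(axis=1)

    admix = np.zeros(model.n_pop2)
    if model.admix_fraction is not None:
        a, b = model.admix_fraction
        admix = rng.beta(a, b, size=model.n_pop2)
    h2 = _haplotypes(
        p2,
        2 * model.n_pop2,
        model.ld_block_size,
        model.ld_rho,
        rng,
        freqs_alt=p1 if model.admix_fraction is not None else None,
        alt_block_prob=np.repeat(admix, 2) if model.admix_fraction is not None else None,
    )
    g2 = h2.reshape(model.n_pop2, 2, model.m).sum(axis=1)

    genotypes = np.vstack([g1, g2]).astype(np.int8)
    if model.missing_rate > 0.0:
        mask = rng.random(genotypes.shape) < model.missing_rate
        genotypes[mask] = MISSING

    snp_table = pd.DataFrame(
        {
            "snp": [f"snp{j + 1}" for j in range(model.m)],
            "chrom": np.ones(model.m, dtype=int),
            "pos": (np.arange(model.m, dtype=int) + 1) * model.bp_spacing,
            "a1": "A",
            "a2": "G",
        }
    )
    n = model.n_pop1 + model.n_pop2
    pops = np.r_[np.ones(model.n_pop1, int), np.full(model.n_pop2, 2, int)]
    sample_table = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"I{i + 1}" for i in range(n)],
            "population": pops,
            "sex": (np.arange(n) % 2) + 1,
            "admix_fraction": np.r_[np.zeros(model.n_pop1), admix],
        }
    )
    truth = {"freq_pop1": p1, "freq_pop2": p2}
    return GenotypeDataset(genotypes, snp_table, sample_table, truth)


def draw_effects(
    arch: TraitArchitecture,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bivariate-normal causal effect pairs.

    ``m_causal`` SNPs are chosen uniformly without replacement; their effect
    pairs (b1_j, b2_j) have unit variances and correlation ``rg_true``
    (constructed as b2 = rg*b1 + sqrt(1-rg^2)*eta, exact in the |rg| = 1
    degenerate case).  Non-causal effects are zero.  Returns
    ``(beta_pop1, beta_pop2, causal_index)``.
    """
    if arch.m_causal > m:
        raise ValueError(f"m_causal ({arch.m_causal}) exceeds m ({m})")
    causal = np.sort(rng.choice(m, size=arch.m_causal, replace=False))
    b1 = rng.standard_normal(arch.m_causal)
    eta = rng.standard_normal(arch.m_causal)
    rg = arch.rg_true
    b2 = rg * b1 + np.sqrt(max(0.0, 1.0 - rg * rg)) * eta
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    beta1[causal] = b1
    beta2[causal] = b2
    return beta1, beta2, causal


def simulate_phenotypes(
    dataset: GenotypeDataset,
    effects: tuple[np.ndarray, np.ndarray],
    h2_pop1: float,
    h2_pop2: float,
    rng: np.random.Generator,
    effect_scale_model: str = "standardized",
) -> np.ndarray:
    """Phenotypes with the requested per-population heritabilities.

    Per population the genetic value g = X b (X standardized by the
    population's own sample frequencies, or raw centred dosages under the
    per-allele model) is rescaled so its sample variance equals h^2 exactly,
    and N(0, 1-h^2) environmental noise is added, so the phenotypic variance
    is ~1 in both cohorts.
    """
    beta1, beta2 = effects
    y = np.empty(dataset.n_samples)
    for pop, beta, h2 in ((1, beta1, h2_pop1), (2, beta2, h2_pop2)):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError("heritabilities must lie in [0, 1]")
        mask = dataset.population_mask(pop)
        g_raw = dataset.genotypes[mask].astype(float)
        g_raw[g_raw == MISSING] = np.nan
        p = np.nanmean(g_raw, axis=0) / 2.0
        x = g_raw - 2.0 * p
        if effect_scale_model == "standardized":
            sd = np.sqrt(2.0 * p * (1.0 - p))
            sd[sd == 0] = 1.0
            x = x / sd
        x[np.isnan(x)] = 0.0
        g = x @ beta
        vg = g.var(ddof=1)
        if h2 > 0.0:
            if vg <= 0.0:
                raise ValueError(f"population {pop}: zero genetic variance with h2 > 0")
            g = g * np.sqrt(h2 / vg)
        else:
            g = np.zeros_like(g)
        e = rng.standard_normal(mask.sum()) * np.sqrt(1.0 - h2)
        y[mask] = g + e
    return y


def simulate_dataset(
    model: PopulationModel,
    arch: TraitArchitecture,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Full simulation driver: genotypes + phenotypes + truth sidecar.

    Child generators are spawned from ``model.seed`` in a fixed order
    (frequencies, genotypes, effects, phenotypes) so each stage is
    independently reproducible.
    """
    streams = np.random.SeedSequence(model.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]
    p_anc, p1, p2 = draw_allele_frequencies(
        model.ancestral_maf_range, model.fst_target, model.m, rngs[0]
    )
    dataset = simulate_genotypes((p1, p2), model, rngs[1])
    beta1, beta2, causal = draw_effects(arch, model.m, rngs[2])
    y = simulate_phenotypes(
        dataset, (beta1, beta2), arch.h2_pop1, arch.h2_pop2, rngs[3],
        effect_scale_model=arch.effect_scale_model,
    )
    causal_mask = np.zeros(model.m, dtype=bool)
    causal_mask[causal] = True
    dataset.truth.update(
        {
            "freq_ancestral": p_anc,
            "beta_pop1": beta1,
            "beta_pop2": beta2,
            "causal_index": causal,
            "causal_mask": causal_mask,
            "rg_true": arch.rg_true,
            "h2_pop1": arch.h2_pop1,
            "h2_pop2": arch.h2_pop2,
        }
    )
    return dataset, y


def write_truth(dataset: GenotypeDataset, path: str) -> None:
    """Tab-delimited truth sidecar (per-SNP effects and frequencies)."""
    if dataset.truth is None:
        raise ValueError("dataset carries no truth sidecar")
    t = dataset.truth
    df = pd.DataFrame(
        {
            "snp": dataset.snp_table["snp"],
            "freq_pop1": t["freq_pop1"],
            "freq_pop2": t["freq_pop2"],
            "beta_pop1": t.get("beta_pop1", np.zeros(dataset.n_snps)),
            "beta_pop2": t.get("beta_pop2", np.zeros(dataset.n_snps)),
        }
    )
    df.to_csv(path, sep="\t", index=False)
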