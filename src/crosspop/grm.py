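"""Genomic relationship matrices, principal components, and GCTA GRM I/O.

Two standardization modes are supported.  ``mode="specific"`` standardizes
each individual's genotypes by the allele frequencies of its own population
(the cross-population GREML convention: within-population relatedness is
measured on each population's own scale, and the cross-population block
carries the genetic covariance signal).  ``mode="average"`` uses pooled
frequencies from the combined sample, in which allele-frequency divergence
shows up as positive within-population and negative cross-population
relatedness — the structure population PCs are computed from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeDataset

__all__ = [
    "GRM",
    "standardize_genotypes",
    "compute_grm",
    "compute_pcs",
    "write_pcs",
    "write_grm",
    "read_grm",
    "polymorphic_index",
]


def polymorphic_index(dataset: GenotypeDataset) -> np.ndarray:
    """Indices of SNPs polymorphic within every population present.

    Population-specific standardization is undefined for a SNP fixed in
    either cohort, so such SNPs must be dropped before :func:`compute_grm`
    with ``mode="specific"``.
    """
    pops = dataset.sample_table["population"].to_numpy()
    keep = np.ones(dataset.n_snps, dtype=bool)
    for pop in np.unique(pops):
        p = dataset.subset_samples(np.where(pops == pop)[0]).allele_frequencies()
        keep &= (p > 0.0) & (p < 1.0)
    return np.where(keep)[0]


@dataclass
class GRM:
    matrix: np.ndarray  # n x n symmetric
    sample_ids: pd.DataFrame  # columns fid, iid
    m_snps: np.ndarray | int  # scalar, or n x n pairwise-complete counts
    mode: str = "specific"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def standardize_genotypes(genotypes: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """z = (x - 2p) / sqrt(2p(1-p)); missing genotypes become 0 after centring.

    Setting a missing entry to the (standardized) mean leaves every pairwise
    product it enters equal to zero — the GCTA convention, paired with
    per-pair SNP counts in :func:`compute_grm`.
    """
    p = np.asarray(frequencies, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = int(np.argmax((p <= 0.0) | (p >= 1.0)))
        raise ValueError(f"SNP {bad} has frequency {p[bad]}: cannot standardize p in {{0, 1}}")
    x = genotypes.astype(float)
    x[genotypes == MISSING] = np.nan
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[np.isnan(z)] = 0.0
    return z


def compute_grm(
    dataset: GenotypeDataset,
    mode: str = "specific",
    frequencies: Optional[dict[int, np.ndarray]] = None,
) -> GRM:
    """A = Z Z' / m with population-specific or pooled standardization.

    With ``mode="specific"`` each individual's row of Z uses its own
    population's allele frequencies (estimated from the analysis sample
    unless ``frequencies`` maps population label -> per-SNP frequency).
    With missing genotypes present the divisor is the per-pair count of
    SNPs observed in both individuals.
    """
    if dataset.n_snps < 2:
        raise ValueError("need at least 2 SNPs to build a GRM")
    g = dataset.genotypes
    z = np.empty(g.shape, dtype=float)
    if mode == "average":
        p = dataset.allele_frequencies()
        _check_poly(p, "combined sample")
        z[:] = standardize_genotypes(g, p)
    elif mode == "specific":
        pops = dataset.sample_table["population"].to_numpy()
        for pop in np.unique(pops):
            mask = pops == pop
            if mask.sum() < 2:
                raise ValueError(f"population {pop} has fewer than 2 samples")
            if frequencies is not None and pop in frequencies:
                p = np.asarray(frequencies[pop], dtype=float)
            else:
                p = dataset.subset_samples(np.where(mask)[0]).allele_frequencies()
            _check_poly(p, f"population {pop}")
            z[mask] = standardize_genotypes(g[mask], p)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    from scipy.linalg.blas import dsyrk

    a = dsyrk(1.0, z, lower=1)
    a = a + np.tril(a, -1).T
    if np.any(g == MISSING):
        obs = (g != MISSING).astype(float)
        counts = obs @ obs.T
        counts[counts == 0] = 1.0
        a /= counts
        m_snps: np.ndarray | int = counts.astype(int)
    else:
        a /= dataset.n_snps
        m_snps = dataset.n_snps
    a = (a + a.T) / 2.0
    return GRM(a, dataset.sample_table[["fid", "iid"]].copy(), m_snps, mode)


def _check_poly(p: np.ndarray, where: str) -> None:
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = int(np.argmax((p <= 0.0) | (p >= 1.0)))
        raise ValueError(f"SNP index {bad} is monomorphic in {where}")


def compute_pcs(grm: GRM, k: int) -> np.ndarray:
    """Top-k eigenvectors of the GRM, each scaled by sqrt(eigenvalue).

    Components come in descending eigenvalue order; each column's sign is
    fixed so its largest-magnitude loading is positive, making covariate
    files reproducible across runs and platforms.
    """
    if k > grm.n:
        raise ValueError(f"k={k} exceeds n={grm.n}")
    if not np.all(np.isfinite(grm.matrix)):
        raise ValueError("GRM contains non-finite entries")
    from scipy.linalg import eigh

    n = grm.n
    vals, vecs = eigh(grm.matrix, subset_by_index=(n - k, n - 1))
    vals, vecs = vals[::-1], vecs[:, ::-1]
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs * np.sqrt(np.maximum(vals, 0.0))


def write_pcs(grm: GRM, pcs: np.ndarray, path: str) -> None:
    """Eigenvector covariate file: ``FID IID PC1 .. PCk`` (no header)."""
    df = grm.sample_ids.copy()
    for j in range(pcs.shape[1]):
        df[f"PC{j + 1}"] = pcs[:, j]
    df.to_csv(path, sep=" ", header=False, index=False)


def write_grm(grm: GRM, path_prefix: str) -> None:
    """GCTA binary triplet: .grm.bin, .grm.N.bin (float32), .grm.id.

    The .bin files hold the lower triangle including the diagonal, row by
    row, as little-endian 4-byte floats.
    """
    n = grm.n
    idx = np.tril_indices(n)
    grm.matrix[idx].astype("<f4").tofile(f"{path_prefix}.grm.bin")
    if np.isscalar(grm.m_snps):
        counts = np.full(len(idx[0]), grm.m_snps, dtype="<f4")
    else:
        counts = np.asarray(grm.m_snps)[idx].astype("<f4")
    counts.tofile(f"{path_prefix}.grm.N.bin")
    grm.sample_ids.to_csv(f"{path_prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm(path_prefix: str) -> GRM:
    ids = pd.read_csv(
        f"{path_prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    tri = np.fromfile(f"{path_prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if len(tri) != expected:
        raise ValueError(
            f"{path_prefix}.grm.bin holds {len(tri)} floats but .grm.id lists "
            f"{n} samples (expected {expected})"
        )
    a = np.zeros((n, n))
    idx = np.tril_indices(n)
    a[idx] = tri
    a = a + np.tril(a, -1).T
    counts = np.fromfile(f"{path_prefix}.grm.N.bin", dtype="<f4")
    if len(counts) != expected:
        raise ValueError(f"{path_prefix}.grm.N.bin size does not match .grm.id")
    nmat = np.zeros((n, n))
    nmat[idx] = counts
    nmat = nmat + np.tril(nmat, -1).T
    if np.allclose(nmat, nmat.flat[0]):
        m_snps: np.ndarray | int = int(round(float(nmat.flat[0])))
    else:
        m_snps = nmat.astype(int)
    return GRM(a, ids, m_snps, mode="specific")
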