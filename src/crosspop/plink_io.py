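"""PLINK 1.9 BED/BIM/FAM reader and writer (SNP-major, 2-bit encoding).

Byte layout: the BED file starts with the magic bytes 0x6C 0x1B followed by
0x01 (SNP-major).  Each SNP then occupies ceil(n/4) bytes; within a byte the
lowest-order pair of bits codes the first individual.  Bit pairs:
00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2.
Genotypes in memory count copies of the *second* BIM allele (A2), so
dosage 0 maps to 00 and dosage 2 to 11 — the convention of the common
Python BED readers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeDataset

__all__ = ["write_plink", "read_plink", "PlinkFormatError", "write_phenotype", "read_phenotype"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage of A2 -> 2-bit code, and inverse
_ENCODE = {0: 0b00, -1: 0b01, 1: 0b10, 2: 0b11}
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Raised for malformed BED/BIM/FAM input, with the specific defect named."""


def write_plink(dataset: GenotypeDataset, path_prefix: str) -> None:
    """Write ``path_prefix``.bed/.bim/.fam."""
    g = dataset.genotypes
    n, m = g.shape
    lookup = np.zeros(256, dtype=np.uint8)
    for dosage, code in _ENCODE.items():
        lookup[dosage & 0xFF] = code
    codes = lookup[g.astype(np.int8).view(np.uint8)]  # n x m, values 0..3
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, m), dtype=np.uint8)])
    quads = codes.T.reshape(m, -1, 4)  # SNP-major, 4 samples per byte
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(f"{path_prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    st = dataset.snp_table
    bim = pd.DataFrame(
        {
            "chrom": st["chrom"],
            "snp": st["snp"],
            "cm": 0,
            "pos": st["pos"],
            "a1": st["a1"],
            "a2": st["a2"],
        }
    )
    bim.to_csv(f"{path_prefix}.bim", sep="\t", header=False, index=False)

    st = dataset.sample_table
    fam = pd.DataFrame(
        {
            "fid": st["fid"],
            "iid": st["iid"],
            "father": 0,
            "mother": 0,
            "sex": st["sex"] if "sex" in st else 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{path_prefix}.fam", sep="\t", header=False, index=False)


def read_plink(path_prefix: str) -> GenotypeDataset:
    """Read a BED/BIM/FAM triplet back into a :class:`GenotypeDataset`.

    Malformed magic bytes, a truncated BED payload, and a BIM/BED SNP-count
    mismatch are reported as distinct :class:`PlinkFormatError` messages.
    """
    bim = pd.read_csv(
        f"{path_prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        f"{path_prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{path_prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _MAGIC:
        raise PlinkFormatError(
            f"{path_prefix}.bed: bad magic bytes {raw[:3]!r} (expected 6c 1b 01, SNP-major)"
        )
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if len(payload) % bytes_per_snp:
        raise PlinkFormatError(
            f"{path_prefix}.bed: truncated payload ({len(payload)} bytes is not a "
            f"multiple of {bytes_per_snp} bytes per SNP for n={n})"
        )
    m_bed = len(payload) // bytes_per_snp
    if m_bed != m:
        raise PlinkFormatError(
            f"{path_prefix}: BIM lists {m} SNPs but BED payload holds {m_bed}"
        )
    b = payload.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = b & 0b11
    codes[:, 1::4] = (b >> 2) & 0b11
    codes[:, 2::4] = (b >> 4) & 0b11
    codes[:, 3::4] = (b >> 6) & 0b11
    genotypes = _DECODE[codes[:, :n]].T.copy()

    snp_table = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    sample_table = fam[["fid", "iid", "sex"]].copy()
    sample_table["population"] = 0
    sample_table["admix_fraction"] = 0.0
    return GenotypeDataset(genotypes, snp_table, sample_table)


def write_phenotype(sample_table: pd.DataFrame, values: np.ndarray, path: str) -> None:
    """Whitespace-delimited ``FID IID value`` file (no header, GCTA style)."""
    df = pd.DataFrame(
        {"fid": sample_table["fid"], "iid": sample_table["iid"], "value": values}
    )
    df.to_csv(path, sep=" ", header=False, index=False)


def read_phenotype(path: str) -> pd.DataFrame:
    """Read ``FID IID value...`` (any number of trailing value columns)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str, 1: str})
    df = df.rename(columns={0: "fid", 1: "iid"})
    df.columns = ["fid", "iid"] + [f"v{i}" for i in range(1, df.shape[1] - 1)]
    return df
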