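"""Minimal PLINK1 binary (.bed/.bim/.fam) reader and writer.

The .bed format is SNP-major: per variant, each sample's genotype occupies two
bits (00 = hom allele1, 01 = missing, 10 = het, 11 = hom allele2), packed four
samples per byte, each variant padded to a whole byte.  Counted allele here is
allele1 (the .bim A1 column), matching the convention of
:class:`qcpop.data.GenotypeDataset`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import GenotypeDataset

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> allele1 dosage
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}

_SEX_TO_FAM = {"M": 1, "F": 2}
_FAM_TO_SEX = {1: "M", 2: "F"}


def write_bed(dataset: GenotypeDataset, prefix: str) -> None:
    """Write ``prefix``.bed/.bim/.fam from a :class:`GenotypeDataset`."""
    calls = dataset.calls
    n, m = calls.shape
    # map dosages to 2-bit codes, vectorised via lookup on (dosage + 1)
    lut = np.empty(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage + 1] = code
    codes = lut[(calls.T.astype(np.int16) + 1)]  # variant-major (m, n)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.ones((m, pad), dtype=np.uint8)], axis=1
        )  # pad with "missing"; ignored on read
    codes = codes.reshape(m, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)

    v = dataset.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": v["cm"] if "cm" in v.columns else 0.0,
            "pos": v["pos"],
            "a1": v["allele1"],
            "a2": v["allele2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    s = dataset.samples
    fam = pd.DataFrame(
        {
            "fid": s["family"] if "family" in s.columns else s["id"],
            "iid": s["id"],
            "pat": s["father"] if "father" in s.columns else 0,
            "mat": s["mother"] if "mother" in s.columns else 0,
            "sex": s["sex"].map(_SEX_TO_FAM).fillna(0).astype(int),
            "pheno": s["phenotype"] if "phenotype" in s.columns else -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_bed(prefix: str) -> GenotypeDataset:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeDataset`."""
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str, "pat": str, "mat": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
        raw = np.fromfile(fh, dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    if raw.size != m * bytes_per_variant:
        raise ValueError(
            f"{prefix}.bed has {raw.size} data bytes; expected {m * bytes_per_variant}"
        )
    raw = raw.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, little-endian within byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    calls = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele1": bim["a1"],
            "allele2": bim["a2"],
            "cm": bim["cm"],
        }
    )
    samples = pd.DataFrame(
        {
            "id": fam["iid"],
            "family": fam["fid"],
            "father": fam["pat"],
            "mother": fam["mat"],
            "sex": fam["sex"].map(_FAM_TO_SEX),
            "phenotype": fam["pheno"],
        }
    )
    return GenotypeDataset(calls=calls, variants=variants, samples=samples)


def write_fileset(dataset: GenotypeDataset, directory: str, prefix: str = "cohort") -> str:
    """Write bed/bim/fam plus the full sample manifest as samples.tsv."""
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, prefix)
    write_bed(dataset, path)
    dataset.samples.to_csv(os.path.join(directory, "samples.tsv"), sep="\t", index=False)
    return path
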