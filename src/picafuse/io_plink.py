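"""Minimal variant-major PLINK BED/BIM/FAM reader and writer.

The BED file stores genotypes 2 bits per sample, least-significant bits
first, one variant per record of ``ceil(n_samples / 4)`` bytes:

===== =========================== ==============
code  genotype                    dosage of A1
===== =========================== ==============
0b00  homozygous A1/A1            2
0b01  missing                     NaN
0b10  heterozygous                1
0b11  homozygous A2/A2            0
===== =========================== ==============

On write, allele A1 is the dosage-counted (minor) allele; on read, the
dosage counts A1 whatever it is — real-world BIM files vary in which
allele ends up in column 5.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BIM_COLUMNS, GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B])
_VARIANT_MAJOR = 0x01

# 2-bit code -> dosage of allele 1
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class PlinkFormatError(ValueError):
    pass


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a BED/BIM/FAM triple into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    snp_meta = pd.read_csv(bim, sep=r"\s+", header=None, names=BIM_COLUMNS)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None,
                         names=["fid", "iid", "father", "mother", "sex",
                                "phenotype"], dtype={"iid": str})
    n_subjects, n_snps = len(fam_df), len(snp_meta)

    raw = bed.read_bytes()
    if raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2] != _VARIANT_MAJOR:
        raise PlinkFormatError(
            f"{bed}: sample-major layout (mode byte {raw[2]:#04x}) is not "
            "supported; re-encode variant-major")
    bytes_per_variant = (n_subjects + 3) // 4
    expected = 3 + bytes_per_variant * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed}: {len(raw)} bytes, expected {expected} for "
            f"{n_subjects} samples x {n_snps} variants")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3)
    data = data.reshape(n_snps, bytes_per_variant)
    # unpack 2-bit fields, LSB first
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)],
                     axis=-1).reshape(n_snps, -1)[:, :n_subjects]
    dosages = _CODE_TO_DOSAGE[codes].T
    return GenotypeMatrix(dosages, snp_meta, list(fam_df["iid"]))


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a BED/BIM/FAM triple (variant-major, A1 = counted allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_subjects, geno.n_snps

    codes = np.full((m, n), 0b01, dtype=np.uint8)   # missing by default
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[(geno.dosages == dosage).T] = code
    padded = (n + 3) // 4 * 4
    if padded != n:
        codes = np.concatenate(
            [codes, np.zeros((m, padded - n), dtype=np.uint8)], axis=1)
    quads = codes.reshape(m, -1, 4)
    packed = (quads[..., 0] | (quads[..., 1] << 2)
              | (quads[..., 2] << 4) | (quads[..., 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([_VARIANT_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())

    geno.snp_meta[BIM_COLUMNS].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": geno.subject_ids, "iid": geno.subject_ids,
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False,
               index=False)
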