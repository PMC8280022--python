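"""PLINK 1 binary fileset (.bed/.bim/.fam) and delimited-text I/O.

The .bed layout is the SNP-major variant: a 3-byte magic (6C 1B 01)
followed by ceil(n_samples/4) bytes per variant, two bits per call,
sample 0 in the lowest-order bit pair.  Two-bit codes (counting A1):
00 = hom A1 (dosage 2), 01 = missing, 10 = het, 11 = hom A2 (dosage 0).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, SummaryStatistics

_MAGIC = bytes((0x6C, 0x1B, 0x01))

# dosage -> 2-bit code, and back
_CODE_FOR_DOSAGE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as prefix.bed/.bim/.fam."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.dosages.shape

    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    d = dataset.dosages.T
    for dosage, code in _CODE_FOR_DOSAGE.items():
        codes[d == dosage] = code

    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    quads = padded.reshape(m, n_bytes, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": dataset.variants["chrom"],
            "id": dataset.variants["id"],
            "cm": 0,
            "pos": dataset.variants["pos"],
            "a1": dataset.variants["a1"],
            "a2": dataset.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": dataset.samples["fid"],
            "iid": dataset.samples["iid"],
            "father": 0,
            "mother": 0,
            "sex": dataset.samples["sex"],
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a prefix.bed/.bim/.fam fileset into a GenotypeDataset."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 .bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if len(body) != m * n_bytes:
        raise ValueError(f"{prefix}.bed: expected {m * n_bytes} data bytes, found {len(body)}")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _DOSAGE_FOR_CODE[codes[:, :n]].T

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid", "sex"]].copy()
    return GenotypeDataset(dosages, variants, samples)


SUMSTAT_COLUMNS = {
    "SNP": "id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
}


def write_sumstats(sumstats: SummaryStatistics, path: str | Path) -> None:
    """Write summary statistics as tab-separated text with the
    SNP/CHR/BP/A1/A2/BETA/SE/P/N header dialect."""
    inv = {v: k for k, v in SUMSTAT_COLUMNS.items()}
    out = sumstats.table.rename(columns=inv)
    cols = [c for c in SUMSTAT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path, columns: dict[str, str] | None = None) -> SummaryStatistics:
    """Read delimited summary statistics.

    ``columns`` maps file headers to canonical names; defaults to the
    SNP/CHR/BP/A1/A2/BETA/SE/P/N dialect.
    """
    mapping = dict(SUMSTAT_COLUMNS if columns is None else columns)
    raw = pd.read_csv(path, sep=r"\s+")
    present = {k: v for k, v in mapping.items() if k in raw.columns}
    table = raw.rename(columns=present)[list(present.values())]
    return SummaryStatistics(table)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype/covariate table in the PLINK dialect (FID and
    IID leading columns, tab-separated)."""
    cols = list(phenotypes.columns)
    for lead in ("iid", "fid"):
        if lead in cols:
            cols.insert(0, cols.pop(cols.index(lead)))
    out = phenotypes[cols].rename(columns={"fid": "FID", "iid": "IID"})
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=r"\s+")
    return raw.rename(columns={"FID": "fid", "IID": "iid"})
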