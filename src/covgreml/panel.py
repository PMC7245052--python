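"""Genotype panel container and PLINK1 binary I/O.

A :class:`GenotypePanel` holds hard-call genotypes for ``n`` samples at ``m``
SNPs as an ``(n, m)`` int8 matrix counting copies of allele1 (0/1/2, with -1
for missing), together with per-SNP metadata: chromosome, 1-based position,
alleles, minor allele frequency, optional imputation info r^2 and the
Hardy-Weinberg exact-test p-value.

The binary genotype codec follows the PLINK1 bed format: a 3-byte header
(0x6C, 0x1B, then mode 0x01 for SNP-major order) followed by one record per
SNP, each packing 4 samples per byte in 2-bit fields, least-significant bits
first.  Field values: 00 = two copies of allele1, 01 = missing, 10 =
heterozygous, 11 = zero copies of allele1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# call value -> 2-bit code and back
_CALL_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2", "maf", "info_r2", "hwe_p"]


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK1 binary input."""


@dataclass
class GenotypePanel:
    """Hard-call genotypes plus per-SNP metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (one per row of ``calls``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, allele1, allele2,
        maf, info_r2, hwe_p``.  ``info_r2`` may be NaN, meaning the SNP was
        directly genotyped (no imputation quality available).
    calls : numpy.ndarray
        ``(n_samples, n_snps)`` int8 matrix of allele1 copy counts; -1 marks
        a missing call.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} call rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} call columns")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def allele1_frequency(self) -> np.ndarray:
        """Per-SNP allele1 frequency from non-missing calls (pairwise-complete)."""
        masked = np.ma.masked_equal(self.calls, MISSING)
        p = masked.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele1_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=self.snps.copy(),
            calls=self.calls[index, :].copy(),
        )

    def with_recomputed_metadata(self) -> "GenotypePanel":
        """Return a copy whose maf and hwe_p columns are recomputed from calls."""
        from .qc import hwe_exact_p  # local import to avoid a cycle

        snps = self.snps.copy()
        snps["maf"] = self.minor_allele_frequency()
        pvals = np.empty(self.n_snps)
        for j in range(self.n_snps):
            col = self.calls[:, j]
            col = col[col != MISSING]
            pvals[j] = hwe_exact_p(
                int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0))
            )
        snps["hwe_p"] = pvals
        return GenotypePanel(list(self.sample_ids), snps, self.calls.copy())


def _pack_snp(col: np.ndarray) -> np.ndarray:
    """Pack one SNP's calls (length n) into ceil(n/4) bytes, 2 bits per sample."""
    n = col.shape[0]
    codes = np.empty(n, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[col == call] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros(n_bytes * 4, dtype=np.uint8)
    padded[:n] = codes
    padded = padded.reshape(n_bytes, 4)
    return (
        padded[:, 0] | (padded[:, 1] << 2) | (padded[:, 2] << 4) | (padded[:, 3] << 6)
    ).astype(np.uint8)


def _unpack_snp(raw: np.ndarray, n: int) -> np.ndarray:
    codes = np.empty(raw.shape[0] * 4, dtype=np.uint8)
    codes[0::4] = raw & 0b11
    codes[1::4] = (raw >> 2) & 0b11
    codes[2::4] = (raw >> 4) & 0b11
    codes[3::4] = (raw >> 6) & 0b11
    return _CODE_TO_CALL[codes[:n]]


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam in PLINK1 SNP-major binary format."""
    prefix = str(prefix)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        for j in range(panel.n_snps):
            fh.write(_pack_snp(panel.calls[:, j]).tobytes())
    bim = panel.snps[["chrom", "snp_id", "pos", "allele1", "allele2"]].copy()
    bim.insert(2, "cm", 0)
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypePanel:
    """Read a PLINK1 bed/bim/fam triplet into a :class:`GenotypePanel`.

    MAF and HWE p-values are recomputed from the decoded calls; ``info_r2``
    is left absent (NaN) and may be attached afterwards with
    :func:`attach_info_scores`.
    """
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"snp_id": str, "allele1": str, "allele2": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: not a PLINK1 bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}"
        )
    calls = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        rec = body[j * bytes_per_snp : (j + 1) * bytes_per_snp]
        calls[:, j] = _unpack_snp(rec, n)
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
            "maf": np.nan,
            "info_r2": np.nan,
            "hwe_p": np.nan,
        }
    )
    panel = GenotypePanel(list(fam["iid"]), snps, calls)
    return panel.with_recomputed_metadata()


def attach_info_scores(panel: GenotypePanel, sidecar_path: str | Path) -> GenotypePanel:
    """Attach imputation info r^2 from a two-column TSV (snp_id, r2).

    SNPs absent from the sidecar keep ``info_r2 = NaN``, which downstream
    filtering treats as "directly genotyped" (the info filter is bypassed).
    """
    info = pd.read_csv(sidecar_path, sep="\t", dtype={"snp_id": str})
    if not {"snp_id", "r2"}.issubset(info.columns):
        raise ValueError("info sidecar must have columns snp_id and r2")
    snps = panel.snps.copy()
    snps["info_r2"] = snps["snp_id"].map(info.set_index("snp_id")["r2"])
    return GenotypePanel(list(panel.sample_ids), snps, panel.calls.copy())
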