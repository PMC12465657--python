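"""Genotype containers, PLINK 1 binary I/O, allele frequencies, and GRMs.

Genotype calls are stored as an ``int8`` individuals x markers matrix of
alternate-allele (allele2) dosages 0/1/2, with ``-1`` marking a missing call.
The genomic relationship matrix follows the standard construction
``G = W W' / m`` on centred, unit-variance marker columns, i.e. the covariance
of additive genetic values implied by equal per-marker effect variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

# PLINK 1 .bed: 2-bit codes, individual-within-byte little end first.
# 0b00 = hom allele1 (dosage 0), 0b10 = het (1), 0b11 = hom allele2 (2),
# 0b01 = missing.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_CALL = np.array([0, -1, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, -1: 0b01}


class PlinkFormatError(ValueError):
    """Raised for malformed .bed/.bim/.fam content."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive genotype calls plus marker metadata.

    ``markers`` columns: id, chrom, pos (1-based bp), a1, a2; rows are in
    matrix column order, sorted by (chrom, pos).
    """

    calls: np.ndarray
    individual_ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        if self.calls.shape != (len(self.individual_ids), len(self.markers)):
            raise ValueError("calls shape inconsistent with ids/markers")
        if len(set(self.markers["id"])) != len(self.markers):
            raise ValueError("duplicate marker ids")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def marker_index(self, ids) -> np.ndarray:
        """Column indices of the given marker ids (order preserved)."""
        lookup = pd.Index(self.markers["id"])
        idx = lookup.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0][:5]
            raise KeyError(f"markers not in genotype matrix: {list(missing)}")
        return idx

    def subset_markers(self, ids) -> "GenotypeMatrix":
        idx = self.marker_index(ids)
        return GenotypeMatrix(
            self.calls[:, idx],
            self.individual_ids,
            self.markers.iloc[idx].reset_index(drop=True),
        )


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with provenance marker count."""

    matrix: np.ndarray
    individual_ids: np.ndarray
    n_markers_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK 1 .bed (SNP-major) / .bim / .fam files."""
    n, m = geno.calls.shape
    codes = np.empty_like(geno.calls, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[geno.calls == call] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifted = padded.reshape(m, n_bytes, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    payload = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(payload.tobytes())
    bim = geno.markers
    pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "id": bim["id"],
            "cm": 0,
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    ).to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    ).to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK 1 .bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"bad .bed magic at byte 0: {raw[:3].hex()} (expected {_BED_MAGIC.hex()})"
        )
    n_bytes = (n + 3) // 4
    expected = 3 + m * n_bytes
    if len(raw) != expected:
        raise PlinkFormatError(
            f".bed truncated: {len(raw)} bytes, expected {expected} "
            f"(offset {min(len(raw), expected)})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    two_bit = (data[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
    calls = _CODE_TO_CALL[two_bit.reshape(m, -1)[:, :n]].T
    markers = bim[["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    return GenotypeMatrix(np.ascontiguousarray(calls), fam["iid"].to_numpy(object), markers)


def write_grm_gcta(grm: GRM, prefix: str) -> None:
    """Write a GRM in the GCTA binary layout.

    ``<prefix>.grm.bin``: float32 row-wise lower triangle (diagonal included);
    ``<prefix>.grm.N.bin``: float32 marker count per element;
    ``<prefix>.grm.id``: two-column id text file.
    """
    n = len(grm.individual_ids)
    tri = grm.matrix[np.tril_indices(n)].astype(np.float32)
    tri.tofile(f"{prefix}.grm.bin")
    np.full(len(tri), grm.n_markers_used, dtype=np.float32).tofile(
        f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str) -> GRM:
    """Read a GCTA binary-format GRM written by :func:`write_grm_gcta`."""
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)["iid"].to_numpy(object)
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError(f"GRM binary has {len(tri)} elements, expected "
                         f"{n * (n + 1) // 2} for {n} ids")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
    m = int(counts[0]) if len(counts) else 0
    return GRM(mat, ids, m)


def allele_freq_and_maf(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker allele2 frequency ``p`` and minor allele frequency.

    Frequencies are means over non-missing calls; markers with no observed
    calls are flagged ``all_missing`` and carry NaN frequencies.
    """
    calls = geno.calls
    obs = calls >= 0
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * n_obs), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {
            "id": geno.markers["id"].to_numpy(),
            "p": p,
            "maf": maf,
            "n_obs": n_obs,
            "all_missing": n_obs == 0,
        }
    )


def standardize(geno: GenotypeMatrix, freqs: pd.DataFrame | None = None) -> np.ndarray:
    """Centre and scale calls to unit variance; missing imputed to the mean.

    Column j becomes ``(x - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with missing
    entries set to 0 after centring. Monomorphic markers (p in {0, 1}) must be
    filtered beforehand.
    """
    if freqs is None:
        freqs = allele_freq_and_maf(geno)
    p = np.asarray(freqs["p"], dtype=np.float64)
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        bad = geno.markers["id"].to_numpy()[~((p > 0) & (p < 1))][:5]
        raise ValueError(f"monomorphic/all-missing markers must be pre-filtered: {list(bad)}")
    w = (geno.calls.astype(np.float64) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w[geno.calls == MISSING] = 0.0
    return w


def build_grm(geno: GenotypeMatrix, marker_set=None, yang_diagonal: bool = False) -> GRM:
    """GRM over the selected markers: ``G = W W' / m`` on standardized calls.

    With ``yang_diagonal=True`` the diagonal uses the within-individual
    bias-corrected estimator ``1 + (x^2 - (1+2p)x + 2p^2) / (2p(1-p)) / m``
    instead of the plain quadratic form.
    """
    if marker_set is not None:
        ids = getattr(marker_set, "ids", marker_set)
        if len(ids) == 0:
            raise ValueError("empty marker set")
        geno = geno.subset_markers(ids)
    if geno.n_markers == 0:
        raise ValueError("empty marker set")
    freqs = allele_freq_and_maf(geno)
    poly = (freqs["p"] > 0) & (freqs["p"] < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic markers from GRM")
        geno = geno.subset_markers(freqs.loc[poly, "id"])
        freqs = freqs[poly].reset_index(drop=True)
    w = standardize(geno, freqs)
    m = w.shape[1]
    g = w @ w.T / m
    if yang_diagonal:
        p = freqs["p"].to_numpy()
        x = geno.calls.astype(np.float64)
        x[geno.calls == MISSING] = 2.0 * np.broadcast_to(p, x.shape)[geno.calls == MISSING]
        diag_terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
        np.fill_diagonal(g, 1.0 + diag_terms.mean(axis=1))
    return GRM(g, geno.individual_ids, m)
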