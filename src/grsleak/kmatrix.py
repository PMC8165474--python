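"""The SNP co-occurrence matrix K = (1/M) Phi^T Phi and its estimators.

Under binary coding K is made of plain population statistics: the diagonal
and last row/column hold SNP frequencies, off-diagonals hold pairwise
co-occurrence frequencies, and the corner is 1.  Under allele-count coding
the entries are the corresponding combinations of heterozygous/homozygous
class frequencies.  K can be computed exactly from a cohort, estimated from
a disjoint public sample, assembled from published frequency tables, or
perturbed with Gaussian noise; the spectral-norm error bound translates the
estimation error into a bound on the reconstruction error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grs import build_design
from .synthdata import ALLELE_COUNT, BINARY, GenotypeMatrix

__all__ = [
    "KMatrix",
    "FrequencyTable",
    "build_K",
    "estimate_K",
    "frequencies_of",
    "k_from_frequencies",
    "perturb_K",
    "error_bound",
]


@dataclass
class KMatrix:
    """Symmetric (N+1)x(N+1) co-occurrence matrix with provenance."""

    values: np.ndarray
    snp_ids: list[str]
    provenance: str = "exact"   # exact | estimated | perturbed | from_frequencies
    source_size: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.snp_ids) + 1
        if self.values.shape != (p, p):
            raise ValueError(f"K must be {p}x{p} for {p - 1} SNPs, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        if not np.isclose(self.values[-1, -1], 1.0):
            raise ValueError("corner entry K[N+1,N+1] must equal 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        cols = list(self.snp_ids) + ["_intercept"]
        pd.DataFrame(self.values, index=cols, columns=cols).to_csv(path, sep="\t")
        sidecar = {"snp_ids": self.snp_ids, "provenance": self.provenance,
                   "source_size": self.source_size}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar), encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path) -> "KMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text(encoding="utf-8"))
        else:
            meta = {"snp_ids": [str(c) for c in df.columns[:-1]], "provenance": "exact",
                    "source_size": 0}
        return cls(df.to_numpy(dtype=float), list(meta["snp_ids"]), meta["provenance"],
                   int(meta["source_size"]))


@dataclass
class FrequencyTable:
    """Exact count-based SNP frequency summaries of a cohort of M individuals.

    Counts are kept as integers and divided by M only when a frequency or a K
    entry is produced, so assembling K from this table reproduces
    ``build_K`` bit for bit.

    Binary coding uses ``pair_counts`` (individuals carrying both SNPs; the
    diagonal is the per-SNP carrier count).  Allele-count coding additionally
    records the heterozygous/homozygous class counts per SNP and the pairwise
    class co-counts.
    """

    snp_ids: list[str]
    coding: str
    n_individuals: int
    pair_counts: np.ndarray | None = None          # binary: (N, N) ints
    het_counts: np.ndarray | None = None           # allele_count: (N,)
    hom_counts: np.ndarray | None = None           # allele_count: (N,)
    pair_het_het: np.ndarray | None = None         # both heterozygous
    pair_hom_het: np.ndarray | None = None         # one hom-rare, other het (symmetrized)
    pair_hom_hom: np.ndarray | None = None         # both homozygous rare

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.coding == BINARY:
            if self.pair_counts is None:
                raise ValueError("binary coding requires pair_counts")
            self.pair_counts = np.asarray(self.pair_counts)
            M = self.n_individuals
            diag = np.diag(self.pair_counts)
            if self.pair_counts.min() < 0 or diag.max() > M:
                raise ValueError("counts must lie in [0, M]")
            if np.any(self.pair_counts > np.minimum.outer(diag, diag)):
                raise ValueError("co-occurrence counts cannot exceed marginal counts")
        elif self.coding == ALLELE_COUNT:
            for name in ("het_counts", "hom_counts", "pair_het_het", "pair_hom_het", "pair_hom_hom"):
                if getattr(self, name) is None:
                    raise ValueError(f"allele_count coding requires {name}")
                setattr(self, name, np.asarray(getattr(self, name)))
            if np.any(self.het_counts + self.hom_counts > self.n_individuals):
                raise ValueError("genotype class counts exceed cohort size")
        else:
            raise ValueError(f"unknown coding {self.coding!r}")

    @property
    def frequencies(self) -> np.ndarray:
        """Per-SNP frequency: carrier frequency (binary) or P(genotype != 0)."""
        if self.coding == BINARY:
            return np.diag(self.pair_counts) / self.n_individuals
        return (self.het_counts + self.hom_counts) / self.n_individuals

    @property
    def mean_dosage(self) -> np.ndarray:
        """E[g_i]: equals the frequency under binary coding, p_Aa+2p_AA otherwise."""
        if self.coding == BINARY:
            return self.frequencies
        return (self.het_counts + 2 * self.hom_counts) / self.n_individuals


def build_K(G: GenotypeMatrix) -> KMatrix:
    """Exact K = (1/M) Phi^T Phi of a cohort (either coding)."""
    phi = build_design(G).astype(np.int64)
    K = (phi.T @ phi) / G.n_individuals
    return KMatrix(K, list(G.snp_ids), "exact", G.n_individuals)


def estimate_K(G_public: GenotypeMatrix, snp_ids: list[str]) -> KMatrix:
    """Plug-in estimate of K from a public sample, in the release's SNP order."""
    try:
        sub = G_public.select_snps(snp_ids)
    except KeyError as exc:
        raise KeyError(f"public genotypes missing required SNPs: {exc}") from exc
    K = build_K(sub)
    K.provenance = "estimated"
    return K


def frequencies_of(G: GenotypeMatrix) -> FrequencyTable:
    """Exact integer-count frequency table of a cohort."""
    X = G.values.astype(np.int64)
    if G.coding == BINARY:
        return FrequencyTable(list(G.snp_ids), BINARY, G.n_individuals, pair_counts=X.T @ X)
    het = (X == 1).astype(np.int64)
    hom = (X == 2).astype(np.int64)
    return FrequencyTable(
        list(G.snp_ids), ALLELE_COUNT, G.n_individuals,
        het_counts=het.sum(axis=0), hom_counts=hom.sum(axis=0),
        pair_het_het=het.T @ het,
        pair_hom_het=hom.T @ het + het.T @ hom,
        pair_hom_hom=hom.T @ hom,
    )


def k_from_frequencies(freqs: FrequencyTable) -> KMatrix:
    """Assemble K from frequency summaries alone.

    Binary: off-diagonals are co-occurrence frequencies, diagonal and last
    row/column are SNP frequencies, corner 1.  Allele-count: K_ii =
    p_Aa + 4 p_AA, K_ij = p_Aa/Bb + 2 p_AA/Bb + 4 p_AA/BB, last row/column
    p_Aa + 2 p_AA.
    """
    N = len(freqs.snp_ids)
    M = freqs.n_individuals
    counts = np.zeros((N + 1, N + 1), dtype=np.int64)
    if freqs.coding == BINARY:
        counts[:N, :N] = freqs.pair_counts
        marg = np.diag(freqs.pair_counts)
    else:
        counts[:N, :N] = freqs.pair_het_het + 2 * freqs.pair_hom_het + 4 * freqs.pair_hom_hom
        np.fill_diagonal(counts[:N, :N], freqs.het_counts + 4 * freqs.hom_counts)
        marg = freqs.het_counts + 2 * freqs.hom_counts
    counts[:N, N] = marg
    counts[N, :N] = marg
    counts[N, N] = M
    return KMatrix(counts / M, list(freqs.snp_ids), "from_frequencies", M)


def perturb_K(K: KMatrix, sigma: float, seed: int | np.random.SeedSequence = 0) -> KMatrix:
    """Add i.i.d. N(0, sigma^2) noise to the upper triangle and mirror it.

    Entrywise i.i.d. noise would break symmetry, and the attack algebra
    assumes a symmetric K with unit corner, so only the upper triangle
    (including the diagonal) is perturbed, the lower triangle mirrors it, and
    the corner is reset to 1.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    p = K.values.shape[0]
    noise = np.zeros((p, p))
    iu = np.triu_indices(p)
    noise[iu] = rng.normal(0.0, sigma, size=len(iu[0]))
    noise = noise + np.triu(noise, 1).T
    out = K.values + noise
    out[-1, -1] = 1.0
    return KMatrix(out, list(K.snp_ids), "perturbed", K.source_size)


def error_bound(K: KMatrix, K_hat: KMatrix, ridge_lambda: float = 0.0) -> float:
    """Upper bound ||K^-1|| * ||K - K_hat|| on the relative reconstruction error.

    Norms are spectral.  ||K^-1|| = 1/sigma_min(K); with a ridge penalty
    lambda > 0 the first factor is bounded by 1/lambda instead, since the
    regularized system replaces K by K + lambda I.
    """
    diff_norm = float(np.linalg.norm(K.values - K_hat.values, 2))
    if ridge_lambda > 0:
        return diff_norm / ridge_lambda
    smin = float(np.linalg.svd(K.values, compute_uv=False)[-1])
    if smin <= np.finfo(float).eps * max(K.values.shape):
        raise np.linalg.LinAlgError("K is singular; pass ridge_lambda > 0")
    return diff_norm / smin
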