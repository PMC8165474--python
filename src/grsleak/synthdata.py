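"""Synthetic cohorts for genotype-reconstruction experiments.

Simulates a population of binary (0/1 presence of the minor allele) or
allele-count (0/1/2) genotypes with optional linkage-disequilibrium blocks,
linear phenotypes with Gaussian noise, and disjoint private/added/public/test
cohort splits drawn from the one population.  Everything is a pure function of
its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "CohortSplit",
    "SimConfig",
    "simulate_genotypes",
    "population_frequencies",
    "simulate_phenotypes",
    "make_split",
    "subsample_snps",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
]

BINARY = "binary"
ALLELE_COUNT = "allele_count"
_CODING_RANGE = {BINARY: (0, 1), ALLELE_COUNT: (0, 2)}


class GenotypeFormatError(ValueError):
    """Raised when a genotype table violates its coding or shape contract."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs table of integer genotype calls.

    ``coding='binary'`` stores minor-allele presence indicators in {0,1};
    ``coding='allele_count'`` stores minor-allele counts in {0,1,2}.
    """

    values: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]
    coding: str = BINARY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GenotypeFormatError("genotype values must be a 2-D matrix")
        if self.coding not in _CODING_RANGE:
            raise GenotypeFormatError(f"unknown coding {self.coding!r}")
        n, p = self.values.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != p:
            raise GenotypeFormatError(
                f"id lists ({len(self.individual_ids)} x {len(self.snp_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if len(set(self.snp_ids)) != p:
            raise GenotypeFormatError("snp_ids must be unique")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise GenotypeFormatError("genotype entries must be integers")
            self.values = self.values.astype(np.int64)
        lo, hi = _CODING_RANGE[self.coding]
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise GenotypeFormatError(
                f"entries outside [{lo}, {hi}] for coding {self.coding!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def take(self, rows: Sequence[int], individual_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        rows = list(rows)
        ids = list(individual_ids) if individual_ids is not None else [self.individual_ids[i] for i in rows]
        return GenotypeMatrix(self.values[rows], list(self.snp_ids), ids, self.coding)

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict/reorder columns to ``snp_ids`` (errors on missing ids)."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNP ids not present: {missing}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(self.values[:, cols], list(snp_ids), list(self.individual_ids), self.coding)


@dataclass
class PhenotypeVector:
    """Real-valued trait measurements paired with a genotype matrix."""

    values: np.ndarray
    trait_name: str = "trait"
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")
        if self.individual_ids is not None and len(self.individual_ids) != len(self.values):
            raise ValueError("individual_ids length does not match values")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, rows: Sequence[int]) -> "PhenotypeVector":
        rows = list(rows)
        ids = [self.individual_ids[i] for i in rows] if self.individual_ids is not None else None
        return PhenotypeVector(self.values[rows], self.trait_name, ids)


@dataclass
class SimConfig:
    """Parameters of one synthetic-cohort study.

    Defaults mirror the study protocol the attacks are evaluated under:
    M=1000 private individuals, N=200 SNPs with population frequency drawn
    uniformly in (0.25, 0.75) — i.e. only common variants — and a linear
    phenotype with unit-variance Gaussian noise.
    """

    n_private: int = 1000
    n_added: int = 1
    n_public: int = 800
    n_test: int = 50
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.25, 0.75)
    ld_block_size: int = 1
    within_block_corr: float = 0.0
    beta_true: np.ndarray | None = None
    noise_sd: float = 1.0
    coding: str = BINARY
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < low <= high < 1, got {self.maf_range}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.beta_true is not None:
            self.beta_true = np.asarray(self.beta_true, dtype=float).ravel()
            if len(self.beta_true) != self.n_snps + 1:
                raise ValueError(
                    f"beta_true must have length n_snps+1={self.n_snps + 1}, got {len(self.beta_true)}"
                )

    @property
    def n_total(self) -> int:
        return self.n_private + self.n_added + self.n_public + self.n_test

    # Independent child streams so varying e.g. the phenotype noise seed never
    # perturbs the genotypes.
    def _streams(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("genotypes", "phenotypes", "assignment", "effects"), children))

    def resolve_beta(self) -> np.ndarray:
        """The true effect vector; drawn once (standard normal) when unset."""
        if self.beta_true is not None:
            return self.beta_true
        rng = np.random.default_rng(self._streams()["effects"])
        return rng.standard_normal(self.n_snps + 1)

    def to_dict(self) -> dict:
        d = {
            "n_private": self.n_private, "n_added": self.n_added,
            "n_public": self.n_public, "n_test": self.n_test,
            "n_snps": self.n_snps, "maf_range": list(self.maf_range),
            "ld_block_size": self.ld_block_size,
            "within_block_corr": self.within_block_corr,
            "noise_sd": self.noise_sd, "coding": self.coding, "seed": self.seed,
        }
        if self.beta_true is not None:
            d["beta_true"] = self.beta_true.tolist()
        return d


@dataclass
class CohortSplit:
    """Disjoint private / added / public / test cohorts from one population."""

    private_base: GenotypeMatrix
    private_phenotypes: PhenotypeVector
    added: GenotypeMatrix
    added_phenotypes: PhenotypeVector
    public: GenotypeMatrix
    test_pool: GenotypeMatrix
    test_phenotypes: PhenotypeVector
    config: SimConfig
    seed: int = 0

    def __post_init__(self) -> None:
        groups = [
            self.private_base.individual_ids,
            self.added.individual_ids,
            self.public.individual_ids,
            self.test_pool.individual_ids,
        ]
        seen: set[str] = set()
        for ids in groups:
            overlap = seen.intersection(ids)
            if overlap:
                raise ValueError(f"cohort id sets overlap: {sorted(overlap)[:5]}")
            seen.update(ids)


def _simulate_haplotype_layer(
    rng: np.random.Generator, n: int, freqs: np.ndarray, block_size: int, rho: float
) -> np.ndarray:
    """One Bernoulli layer with block-factor latent correlation.

    SNP j is 1 iff a standard-normal latent falls below Phi^{-1}(p_j); within a
    block the latents share a common factor with loading sqrt(rho), so the
    marginal frequency is exactly p_j while neighbouring SNPs correlate.
    """
    n_snps = len(freqs)
    eps = rng.standard_normal((n, n_snps))
    if rho > 0 and block_size > 1:
        n_blocks = -(-n_snps // block_size)
        factors = rng.standard_normal((n, n_blocks))
        block_of = np.arange(n_snps) // block_size
        latent = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * eps
    else:
        latent = eps
    return (latent < norm.ppf(freqs)).astype(np.int8)


def population_frequencies(config: SimConfig) -> np.ndarray:
    """The per-SNP population frequencies the generator will use for ``config``.

    Replays the frequency draw of :func:`simulate_genotypes` (the first draw on
    the genotype stream), so simulated cohorts can be checked against their
    generating truth.
    """
    rng = np.random.default_rng(config._streams()["genotypes"])
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def simulate_genotypes(config: SimConfig, n_individuals: int | None = None) -> GenotypeMatrix:
    """Simulate the full population genotype matrix for ``config``.

    Per-SNP frequencies are drawn uniformly in ``maf_range``; for allele-count
    coding two independent haplotype layers are summed, giving Binomial(2, p)
    marginals.  Deterministic given ``config.seed``.
    """
    n = config.n_total if n_individuals is None else n_individuals
    rng = np.random.default_rng(config._streams()["genotypes"])
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    layers = 2 if config.coding == ALLELE_COUNT else 1
    values = sum(
        _simulate_haplotype_layer(rng, n, freqs, config.ld_block_size, config.within_block_corr)
        for _ in range(layers)
    )
    snp_ids = [f"snp_{j}" for j in range(config.n_snps)]
    ind_ids = [f"ind_{i}" for i in range(n)]
    return GenotypeMatrix(np.asarray(values, dtype=np.int8), snp_ids, ind_ids, config.coding)


def simulate_phenotypes(
    G: GenotypeMatrix, beta_true: np.ndarray, noise_sd: float, seed: int | np.random.SeedSequence,
    trait_name: str = "trait",
) -> PhenotypeVector:
    """y = Phi beta + eps with eps ~ N(0, noise_sd^2) i.i.d."""
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    if len(beta_true) != G.n_snps + 1:
        raise ValueError(f"beta_true must have length N+1={G.n_snps + 1}, got {len(beta_true)}")
    phi = np.column_stack([G.values.astype(float), np.ones(G.n_individuals)])
    rng = np.random.default_rng(seed)
    y = phi @ beta_true + rng.normal(0.0, noise_sd, size=G.n_individuals)
    return PhenotypeVector(y, trait_name, list(G.individual_ids))


def make_split(config: SimConfig) -> CohortSplit:
    """Simulate one population and partition it into the four disjoint cohorts."""
    G = simulate_genotypes(config)
    streams = config._streams()
    beta = config.resolve_beta()
    y = simulate_phenotypes(G, beta, config.noise_sd, streams["phenotypes"])
    rng = np.random.default_rng(streams["assignment"])
    order = rng.permutation(config.n_total)
    bounds = np.cumsum([config.n_private, config.n_added, config.n_public, config.n_test])
    idx_priv, idx_add, idx_pub, idx_test = np.split(order, bounds[:-1])
    return CohortSplit(
        private_base=G.take(idx_priv),
        private_phenotypes=y.take(idx_priv),
        added=G.take(idx_add),
        added_phenotypes=y.take(idx_add),
        public=G.take(idx_pub),
        test_pool=G.take(idx_test),
        test_phenotypes=y.take(idx_test),
        config=config,
        seed=config.seed,
    )


def subsample_snps(
    G: GenotypeMatrix, n_snps: int, seed: int = 0, stratified: bool = True
) -> GenotypeMatrix:
    """Pick ``n_snps`` columns from a larger panel.

    With ``stratified=True`` (default) the panel is cut into ``n_snps``
    contiguous equal-width bins and one SNP is drawn per bin, keeping the
    selection spread along the panel; otherwise a simple random subset.
    """
    if n_snps > G.n_snps:
        raise ValueError(f"cannot subsample {n_snps} SNPs from a panel of {G.n_snps}")
    rng = np.random.default_rng(seed)
    if stratified:
        edges = np.linspace(0, G.n_snps, n_snps + 1)
        cols = [int(rng.integers(int(np.floor(edges[i])), max(int(np.floor(edges[i])) + 1, int(np.floor(edges[i + 1])))))
                for i in range(n_snps)]
        cols = sorted(set(min(c, G.n_snps - 1) for c in cols))
        # bin collisions are only possible at fractional edges; top up randomly
        while len(cols) < n_snps:
            extra = int(rng.integers(0, G.n_snps))
            if extra not in cols:
                cols.append(extra)
        cols = sorted(cols)
    else:
        cols = sorted(rng.choice(G.n_snps, size=n_snps, replace=False).tolist())
    return GenotypeMatrix(G.values[:, cols], [G.snp_ids[c] for c in cols],
                          list(G.individual_ids), G.coding)


# ---------------------------------------------------------------------------
# Delimited text I/O.  Tab-separated, UTF-8, header row of SNP ids, first
# column individual ids; genotype cells are bare integers, no missing values.

def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.values, index=G.individual_ids, columns=G.snp_ids)
    df.index.name = f"id:{G.coding}"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path, coding: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise GenotypeFormatError(f"{path} is empty")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise GenotypeFormatError(f"cannot parse genotype table {path}: {exc}") from exc
    header = str(df.index.name or "")
    if coding is None:
        coding = header.split(":", 1)[1] if ":" in header else BINARY
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise GenotypeFormatError(f"non-numeric genotype cell in {path}")
    if not np.all(values == np.round(values)):
        raise GenotypeFormatError(f"non-integer genotype cell in {path}")
    return GenotypeMatrix(values.astype(np.int64), [str(c) for c in df.columns],
                          [str(i) for i in df.index], coding)


def write_phenotypes(y: PhenotypeVector, path: str | Path) -> None:
    ids = y.individual_ids if y.individual_ids is not None else [f"ind_{i}" for i in range(len(y))]
    pd.DataFrame({y.trait_name: y.values}, index=ids).rename_axis("id").to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    path = Path(path)
    if not path.read_text(encoding="utf-8").strip():
        raise ValueError(f"{path} is empty")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"phenotype table {path} must have exactly one value column")
    col = df.columns[0]
    return PhenotypeVector(df[col].to_numpy(dtype=float), str(col), [str(i) for i in df.index])
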