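"""Baselines, evaluation metrics, and figure-level experiment protocols.

The protocols replicate, on synthetic cohorts, the experiments the attacks
are evaluated with: exact reconstruction with known K for one and three
added individuals, the EM attack across public-sample sizes, the stochastic
EM attack for three added individuals, and the stability of EM accuracy as
the private cohort grows.  Every protocol is a pure function of its
configuration and master seed and returns a per-replicate record table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .em import EMConfig, SEMConfig, em_attack, sem_attack
from .exact import assign_genotypes, compute_d, identify_Cm_simple, reconstruct_single
from .grs import GRSRelease, fit_grs
from .kmatrix import build_K, estimate_K
from .synthdata import BINARY, CohortSplit, GenotypeMatrix, PhenotypeVector, SimConfig, make_split

__all__ = [
    "ExperimentReport",
    "baseline_most_common",
    "accuracy",
    "atypicality",
    "run_protocol",
    "PROTOCOLS",
]


def baseline_most_common(G_public: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """Per-SNP majority call in the public sample (frequency > 0.5 -> 1).

    A frequency of exactly 0.5 calls 0: the tie goes to the reference class.
    Without the released models this is the best per-SNP guess an attacker
    can make, so it is the natural baseline for every attack.
    """
    sub = G_public.select_snps(snp_ids)
    if sub.coding != BINARY:
        raise ValueError("most-common-variant baseline requires binary coding")
    freqs = sub.values.mean(axis=0)
    return (freqs > 0.5).astype(np.int8)


def accuracy(estimated: np.ndarray | GenotypeMatrix, truth: np.ndarray | GenotypeMatrix) -> float:
    """Fraction of SNP entries recovered correctly, best over row permutations.

    Individual labels are arbitrary (the attack cannot know which recovered
    genotype is which added individual), so rows are matched by the
    assignment minimizing total disagreement before scoring.
    """
    est = estimated.values if isinstance(estimated, GenotypeMatrix) else np.asarray(estimated)
    tru = truth.values if isinstance(truth, GenotypeMatrix) else np.asarray(truth)
    est = np.atleast_2d(est)
    tru = np.atleast_2d(tru)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch {est.shape} vs {tru.shape}")
    m = est.shape[0]
    if m == 1:
        return float(np.mean(est == tru))
    cost = np.zeros((m, m))
    for i in range(m):
        cost[i] = np.sum(est[i][None, :] != tru, axis=1)
    rows, cols = linear_sum_assignment(cost)
    return 1.0 - float(cost[rows, cols].sum()) / est.size


def atypicality(x: np.ndarray | GenotypeMatrix, G_public: GenotypeMatrix,
                snp_ids: list[str] | None = None) -> float:
    """Fraction of SNPs where an individual differs from the public majority.

    High atypicality individuals are exactly the ones the most-common-variant
    baseline fails on, and the privacy-sensitive ones: uncommon variants
    identify individuals.
    """
    if isinstance(x, GenotypeMatrix):
        if x.coding != BINARY:
            raise ValueError("atypicality requires binary coding")
        snp_ids = snp_ids or x.snp_ids
        x = x.values
    x = np.asarray(x).ravel()
    if snp_ids is None:
        snp_ids = G_public.snp_ids
    if not set(np.unique(x)).issubset({0, 1}):
        raise ValueError("atypicality requires binary genotypes")
    majority = baseline_most_common(G_public, list(snp_ids))
    return float(np.mean(x != majority))


@dataclass
class ExperimentReport:
    """Per-replicate records and aggregate summaries of one protocol run."""

    protocol: str
    master_seed: int
    config: dict
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records) and "accuracy" in self.records:
            acc = self.records["accuracy"].dropna()
            if len(acc) and (acc.min() < 0 or acc.max() > 1):
                raise ValueError("accuracy values must lie in [0, 1]")

    def summary(self, by: list[str] | None = None) -> pd.DataFrame:
        cols = [c for c in ("accuracy", "baseline_accuracy") if c in self.records]
        group = by or [c for c in ("public_size", "private_size", "method") if c in self.records]
        if not group:
            return self.records[cols].agg(["mean", "std"]).T
        return self.records.groupby(group)[cols].agg(["mean", "std"])

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _refit_with(split: CohortSplit, G_extra: GenotypeMatrix, y_extra: PhenotypeVector) -> GRSRelease:
    """Second release: private base plus the given extra individuals."""
    joint = GenotypeMatrix(
        np.vstack([split.private_base.values, G_extra.values]),
        list(split.private_base.snp_ids),
        list(split.private_base.individual_ids) + list(G_extra.individual_ids),
        split.private_base.coding,
    )
    y = PhenotypeVector(
        np.concatenate([split.private_phenotypes.values, y_extra.values]),
        split.private_phenotypes.trait_name, joint.individual_ids,
    )
    return fit_grs(joint, y)


def _iterate_tests(split: CohortSplit, m: int, n_tests: int, rng: np.random.Generator):
    """Yield (test index, genotypes, phenotypes) groups of m pool individuals."""
    pool = split.test_pool.n_individuals
    for t in range(n_tests):
        idx = rng.choice(pool, size=m, replace=False)
        yield t, split.test_pool.take(idx), split.test_phenotypes.take(idx)


def _protocol_known_K(seed: int, m: int, n_splits: int, n_tests: int,
                      sim_kwargs: dict) -> pd.DataFrame:
    records = []
    for s in range(n_splits):
        cfg = SimConfig(seed=seed * 10_000 + s, n_added=0, **sim_kwargs)
        split = make_split(cfg)
        release_old = fit_grs(split.private_base, split.private_phenotypes)
        K = build_K(split.private_base)
        rng = np.random.default_rng(np.random.SeedSequence([seed, s, 7]))
        for t, G_add, y_add in _iterate_tests(split, m, n_tests, rng):
            release_new = _refit_with(split, G_add, y_add)
            d = compute_d(K, release_old, release_new)
            base = baseline_most_common(split.public, split.private_base.snp_ids)
            base_acc = accuracy(np.tile(base, (m, 1)), G_add.values)
            if m == 1:
                result = reconstruct_single(d)
                status = "ok"
            else:
                try:
                    C = identify_Cm_simple(d, m)
                    result = assign_genotypes(d, C)
                    status = "ok"
                except Exception as exc:  # infeasible seeds are recorded, not raised
                    records.append(dict(split=s, test=t, m=m, method="exact",
                                        accuracy=np.nan, baseline_accuracy=base_acc,
                                        status=type(exc).__name__))
                    continue
            records.append(dict(
                split=s, test=t, m=m, method="exact",
                accuracy=accuracy(result.genotypes, G_add),
                baseline_accuracy=base_acc,
                atypicality=float(np.mean([atypicality(G_add.values[i], split.public,
                                                       split.private_base.snp_ids)
                                           for i in range(m)])),
                status=status,
            ))
    return pd.DataFrame(records)


def _protocol_em_sweep(seed: int, public_sizes: tuple[int, ...], n_splits: int,
                       n_tests: int, sim_kwargs: dict,
                       em_cfg: EMConfig | None = None) -> pd.DataFrame:
    records = []
    for pub in public_sizes:
        for s in range(n_splits):
            cfg = SimConfig(seed=seed * 10_000 + s, n_added=0, n_public=pub, **sim_kwargs)
            split = make_split(cfg)
            release_old = fit_grs(split.private_base, split.private_phenotypes)
            K_hat = estimate_K(split.public, split.private_base.snp_ids)
            alphas = split.public.select_snps(split.private_base.snp_ids).values.mean(axis=0)
            base = baseline_most_common(split.public, split.private_base.snp_ids)
            rng = np.random.default_rng(np.random.SeedSequence([seed, pub, s, 11]))
            for t, G_add, y_add in _iterate_tests(split, 1, n_tests, rng):
                release_new = _refit_with(split, G_add, y_add)
                result = em_attack(K_hat, release_old, release_new, alphas,
                                   em_cfg or EMConfig())
                records.append(dict(
                    split=s, test=t, m=1, method="em", public_size=pub,
                    accuracy=accuracy(result.genotypes, G_add),
                    baseline_accuracy=accuracy(base[None, :], G_add.values),
                    atypicality=atypicality(G_add.values[0], split.public,
                                            split.private_base.snp_ids),
                    sigma2_hat=result.sigma2_hat,
                    converged=result.diagnostics["converged"],
                ))
    return pd.DataFrame(records)


def _protocol_sem(seed: int, m: int, n_splits: int, n_tests: int, sim_kwargs: dict,
                  sem_cfg: SEMConfig | None = None) -> pd.DataFrame:
    records = []
    for s in range(n_splits):
        cfg = SimConfig(seed=seed * 10_000 + s, n_added=0, **sim_kwargs)
        split = make_split(cfg)
        release_old = fit_grs(split.private_base, split.private_phenotypes)
        K_hat = estimate_K(split.public, split.private_base.snp_ids)
        alphas = split.public.select_snps(split.private_base.snp_ids).values.mean(axis=0)
        base = baseline_most_common(split.public, split.private_base.snp_ids)
        rng = np.random.default_rng(np.random.SeedSequence([seed, s, 13]))
        for t, G_add, y_add in _iterate_tests(split, m, n_tests, rng):
            release_new = _refit_with(split, G_add, y_add)
            run_cfg = sem_cfg or SEMConfig()
            run_cfg = SEMConfig(**{**run_cfg.__dict__, "seed": seed * 1_000_003 + s * 101 + t})
            result = sem_attack(K_hat, release_old, release_new, alphas, m, run_cfg)
            records.append(dict(
                split=s, test=t, m=m, method="sem",
                accuracy=accuracy(result.genotypes, G_add),
                baseline_accuracy=accuracy(np.tile(base, (m, 1)), G_add.values),
                atypicality=float(np.mean([atypicality(G_add.values[i], split.public,
                                                       split.private_base.snp_ids)
                                           for i in range(m)])),
                sigma2_hat=result.sigma2_hat,
            ))
    return pd.DataFrame(records)


def _protocol_private_scaling(seed: int, private_sizes: tuple[int, ...], n_snps: int,
                              n_public: int, n_tests: int,
                              em_cfg: EMConfig | None = None) -> pd.DataFrame:
    """EM accuracy as the private cohort grows, with a fixed public and test set.

    One large population is simulated; the public sample, test pool and a
    maximal private pool are carved out once, then nested private cohorts of
    increasing size are taken from the private pool.
    """
    records = []
    M_max = max(private_sizes)
    cfg = SimConfig(seed=seed, n_private=M_max, n_added=0, n_public=n_public,
                    n_test=n_tests, n_snps=n_snps)
    split = make_split(cfg)
    K_alphas = split.public.values.mean(axis=0)
    base = baseline_most_common(split.public, split.private_base.snp_ids)
    K_hat = estimate_K(split.public, split.private_base.snp_ids)
    for M in private_sizes:
        G_priv = split.private_base.take(range(M))
        y_priv = split.private_phenotypes.take(range(M))
        release_old = fit_grs(G_priv, y_priv)
        sub = CohortSplit(G_priv, y_priv,
                          split.added, split.added_phenotypes,
                          split.public, split.test_pool, split.test_phenotypes,
                          cfg, seed)
        for t in range(n_tests):
            G_add = split.test_pool.take([t])
            y_add = split.test_phenotypes.take([t])
            release_new = _refit_with(sub, G_add, y_add)
            result = em_attack(K_hat, release_old, release_new, K_alphas,
                               em_cfg or EMConfig())
            records.append(dict(
                private_size=M, test=t, m=1, method="em",
                accuracy=accuracy(result.genotypes, G_add),
                baseline_accuracy=accuracy(base[None, :], G_add.values),
            ))
    return pd.DataFrame(records)


def run_protocol(name: str, seed: int = 0, **overrides) -> ExperimentReport:
    """Run one named figure-level experiment and return its report.

    Protocols (defaults are desk-scale: 5 splits x 10 test draws):

    - ``known_K_single``: exact attack, m=1, M=1000, N=200 — accuracy 1.0.
    - ``known_K_multi``: exact attack, m=3 — accuracy 1.0 whenever all 2^3
      presence-combinations occur (infeasible draws are recorded, not raised).
    - ``em_single_sweep``: EM attack across public sizes 200/400/800.
    - ``sem_multi``: stochastic EM, m=3, public size 800.
    - ``private_size_scaling``: EM accuracy over growing private cohorts from
      one 50,000-individual population with 100 SNPs.
    """
    if name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; choose from {sorted(PROTOCOLS)}")
    fn, defaults = PROTOCOLS[name]
    params = {**defaults, **overrides}
    records = fn(seed, **params)
    return ExperimentReport(protocol=name, master_seed=seed, config=params, records=records)


_SIM_DEFAULTS = dict(n_private=1000, n_snps=200, n_public=800, n_test=50)

PROTOCOLS: dict[str, tuple[Callable, dict]] = {
    "known_K_single": (_protocol_known_K,
                       dict(m=1, n_splits=5, n_tests=10, sim_kwargs=dict(_SIM_DEFAULTS))),
    "known_K_multi": (_protocol_known_K,
                      dict(m=3, n_splits=5, n_tests=10, sim_kwargs=dict(_SIM_DEFAULTS))),
    "em_single_sweep": (_protocol_em_sweep,
                        dict(public_sizes=(200, 400, 800), n_splits=5, n_tests=10,
                             sim_kwargs=dict(n_private=1000, n_snps=200, n_test=50))),
    "sem_multi": (_protocol_sem,
                  dict(m=3, n_splits=5, n_tests=10, sim_kwargs=dict(_SIM_DEFAULTS),
                       sem_cfg=SEMConfig(max_iter=800, burn_in=200, averaging_window=600))),
    "private_size_scaling": (_protocol_private_scaling,
                             dict(private_sizes=(200, 500, 1000, 3000, 10000, 30000),
                                  n_snps=100, n_public=2000, n_tests=10)),
}
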