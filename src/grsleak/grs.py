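"""Linear genetic-risk-score (GRS) models.

A GRS is an ordinary least-squares fit of a continuous trait on N SNP columns
plus an intercept.  The released artifact is the coefficient vector beta-hat
of length N+1 together with the SNP identifiers and the cohort size M — the
exact inputs the reconstruction attacks consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .synthdata import BINARY, CohortSplit, GenotypeMatrix, PhenotypeVector

__all__ = ["GRSRelease", "RankDeficiencyError", "build_design", "fit_grs", "release_pair"]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Normal equations are singular and no ridge penalty was requested."""


@dataclass
class GRSRelease:
    """A published GRS model: coefficients, SNP ids, cohort size."""

    beta: np.ndarray            # length N+1, intercept last
    snp_ids: list[str]
    cohort_size: int
    coding: str = BINARY
    ridge_lambda: float = 0.0
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if len(self.beta) != len(self.snp_ids) + 1:
            raise ValueError(
                f"beta length {len(self.beta)} != len(snp_ids)+1 = {len(self.snp_ids) + 1}"
            )
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "beta": self.beta.tolist(),
                "snp_ids": self.snp_ids,
                "cohort_size": self.cohort_size,
                "coding": self.coding,
                "ridge_lambda": self.ridge_lambda,
                "trait_name": self.trait_name,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GRSRelease":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(
            beta=np.asarray(obj["beta"], dtype=float),
            snp_ids=list(obj["snp_ids"]),
            cohort_size=int(obj["cohort_size"]),
            coding=obj.get("coding", BINARY),
            ridge_lambda=float(obj.get("ridge_lambda", 0.0)),
            trait_name=obj.get("trait_name", "trait"),
        )


def build_design(G: GenotypeMatrix) -> np.ndarray:
    """M x (N+1) design matrix: genotype columns then an all-ones intercept."""
    if G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    return np.column_stack([G.values.astype(float), np.ones(G.n_individuals)])


def fit_grs(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    ridge_lambda: float = 0.0,
    trait_name: str | None = None,
) -> GRSRelease:
    """Fit the GRS by solving the normal equations.

    beta solves (Phi^T Phi + M*lambda*I_adj) beta = Phi^T y, where I_adj is
    the identity with a zero in the intercept position — the intercept is
    never penalized.  lambda=0 gives exact OLS; a singular system then raises
    :class:`RankDeficiencyError` rather than falling back to a pseudo-inverse.
    """
    if len(y) != G.n_individuals:
        raise ValueError(f"phenotype length {len(y)} != {G.n_individuals} individuals")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    phi = build_design(G)
    M, p = phi.shape
    A = phi.T @ phi
    if ridge_lambda > 0:
        penalty = np.full(p, M * ridge_lambda)
        penalty[-1] = 0.0
        A = A + np.diag(penalty)
    b = phi.T @ y.values
    try:
        c, low = scipy.linalg.cho_factor(A)
        beta = scipy.linalg.cho_solve((c, low), b)
    except np.linalg.LinAlgError as exc:
        if ridge_lambda == 0:
            raise RankDeficiencyError(
                f"normal equations singular (M={M}, N+1={p}); the design has "
                "rank-deficient columns — use ridge_lambda > 0 or more individuals"
            ) from exc
        raise
    return GRSRelease(
        beta=beta,
        snp_ids=list(G.snp_ids),
        cohort_size=M,
        coding=G.coding,
        ridge_lambda=ridge_lambda,
        trait_name=trait_name if trait_name is not None else y.trait_name,
    )


def release_pair(split: CohortSplit, ridge_lambda: float = 0.0) -> tuple[GRSRelease, GRSRelease]:
    """The two published models: fit on the private base, then base + added.

    Both releases share identical SNP ids and ordering, as they would when one
    study re-runs the same analysis on a slightly grown cohort.
    """
    first = fit_grs(split.private_base, split.private_phenotypes, ridge_lambda)
    joint = GenotypeMatrix(
        np.vstack([split.private_base.values, split.added.values]),
        list(split.private_base.snp_ids),
        list(split.private_base.individual_ids) + list(split.added.individual_ids),
        split.private_base.coding,
    )
    y_joint = PhenotypeVector(
        np.concatenate([split.private_phenotypes.values, split.added_phenotypes.values]),
        split.private_phenotypes.trait_name,
        joint.individual_ids,
    )
    second = fit_grs(joint, y_joint, ridge_lambda)
    return first, second
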