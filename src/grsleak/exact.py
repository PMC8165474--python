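"""Exact genotype reconstruction when the co-occurrence matrix K is known.

The attack vector d = K (beta_new - beta_old) computed from two released GRS
models is, with the exact K of the first cohort, a rescaled copy of the added
genotypes: with m added individuals each entry of d equals the sum of the
hidden per-individual scaling constants C_j over exactly the individuals
carrying that SNP.  So d takes at most 2^m distinct values, zero marks SNPs
nobody added carries, and identifying the C_j (a subset-sum problem over the
observed values) reads the genotypes straight off.

Variants handled here: a single added individual (read off directly), several
added individuals (simple and extended C identification), releases that share
only part of their SNP panels (restriction to the overlap), and two releases
that each contain individuals the other lacks (signed constants).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .grs import GRSRelease
from .kmatrix import FrequencyTable, KMatrix
from .synthdata import BINARY, GenotypeMatrix

__all__ = [
    "DVector",
    "CmSolution",
    "ReconstructionResult",
    "AttackError",
    "DegenerateScalingError",
    "NoisyDError",
    "SimplePreconditionError",
    "ReconstructionInfeasibleError",
    "compute_d",
    "cluster_values",
    "reconstruct_single",
    "identify_Cm_simple",
    "identify_Cm_extended",
    "assign_genotypes",
    "restrict_to_overlap",
    "symmetric_difference_d",
]

#: Relative tolerance (times max |d|) for treating two d entries as equal.
DEFAULT_REL_TOL = 1e-6


class AttackError(RuntimeError):
    """Base class for reconstruction failures."""


class DegenerateScalingError(AttackError):
    """The scaling constant C is indistinguishable from 0."""


class NoisyDError(AttackError):
    """d entries do not cluster on the exact-K value lattice; use the EM attack."""


class SimplePreconditionError(AttackError):
    """The 2^m-distinct-values precondition of the simple algorithm fails."""


class ReconstructionInfeasibleError(AttackError):
    """No consistent set of scaling constants exists within the search budget."""


@dataclass
class DVector:
    """Attack vector d = K (beta_new - beta_old), with the declared m."""

    values: np.ndarray
    m_declared: int
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.snp_ids) + 1:
            raise ValueError("d must have length len(snp_ids)+1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("d entries must be finite")
        if self.m_declared < 1:
            raise ValueError("m_declared must be >= 1")

    @property
    def intercept_value(self) -> float:
        return float(self.values[-1])


@dataclass
class CmSolution:
    """Identified scaling constants C_1 <= ... <= C_m.

    ``ambiguity`` lists alternative C vectors that also explain d, with their
    genotype log-likelihoods (the chosen solution first when scored).
    """

    C_values: np.ndarray
    method: str = "simple"      # simple | extended | single | em | sem
    ambiguity: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C_values = np.sort(np.asarray(self.C_values, dtype=float).ravel())

    @property
    def m(self) -> int:
        return len(self.C_values)


@dataclass
class ReconstructionResult:
    """Recovered genotypes plus the estimated nuisance parameters."""

    genotypes: GenotypeMatrix
    C: CmSolution
    posteriors: np.ndarray | None = None      # (N+1, m) when probabilistic
    sigma2_hat: float | None = None
    method: str = "exact"
    assignment: np.ndarray | None = None      # (N+1, m) subset indicators
    diagnostics: dict = field(default_factory=dict)


def compute_d(K: KMatrix, release_old: GRSRelease, release_new: GRSRelease) -> DVector:
    """d = K (beta_new - beta_old); m is the cohort-size difference."""
    if release_old.snp_ids != release_new.snp_ids:
        raise ValueError("releases use different SNP panels; use restrict_to_overlap")
    if K.snp_ids != release_old.snp_ids:
        raise ValueError("K SNP ordering does not match the releases")
    m = release_new.cohort_size - release_old.cohort_size
    if m < 1:
        raise ValueError(
            f"second release must contain more individuals (got sizes "
            f"{release_old.cohort_size} -> {release_new.cohort_size})"
        )
    d = K.values @ (release_new.beta - release_old.beta)
    return DVector(d, m, list(release_old.snp_ids))


def cluster_values(values: np.ndarray, rel_tol: float = DEFAULT_REL_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Group near-equal reals; returns (labels, cluster means).

    Values are sorted and split wherever the gap exceeds ``rel_tol * max|v|``.
    The tolerance scales with the data, so rescaling y (hence C and d) leaves
    the clustering unchanged.
    """
    values = np.asarray(values, dtype=float)
    scale = float(np.max(np.abs(values))) if values.size else 0.0
    tol = rel_tol * scale if scale > 0 else rel_tol
    order = np.argsort(values)
    labels = np.empty(len(values), dtype=int)
    reps: list[float] = []
    start = 0
    sorted_vals = values[order]
    for i in range(1, len(values) + 1):
        if i == len(values) or sorted_vals[i] - sorted_vals[i - 1] > tol:
            members = order[start:i]
            labels[members] = len(reps)
            reps.append(float(sorted_vals[start:i].mean()))
            start = i
    return labels, np.asarray(reps)


def _tol_of(d: DVector, rel_tol: float) -> float:
    scale = float(np.max(np.abs(d.values)))
    return rel_tol * scale if scale > 0 else rel_tol


def reconstruct_single(d: DVector, rel_tol: float = DEFAULT_REL_TOL) -> ReconstructionResult:
    """Read one added individual off d: entry i is 0 or C = d[N+1].

    The intercept row of the added design row is 1, so the last entry of d is
    exactly C; each SNP entry is assigned to whichever of {0, C} is nearer.
    Entries far from both raise :class:`NoisyDError` (estimated-K territory —
    use the EM attack); |C| below tolerance is degenerate.
    """
    if d.m_declared != 1:
        raise ValueError(f"reconstruct_single requires m=1, got m={d.m_declared}")
    tol = _tol_of(d, rel_tol)
    C = d.intercept_value
    if abs(C) <= tol:
        raise DegenerateScalingError(
            f"scaling constant C={C:.3e} is within tolerance of 0; "
            "presence and absence are indistinguishable"
        )
    snp_vals = d.values[:-1]
    dist0 = np.abs(snp_vals)
    dist1 = np.abs(snp_vals - C)
    worst = float(np.min(np.stack([dist0, dist1]), axis=0).max()) if len(snp_vals) else 0.0
    if worst > tol:
        raise NoisyDError(
            f"d entries deviate from {{0, C}} by up to {worst:.3e} (> tol {tol:.3e}); "
            "K appears to be estimated — use the EM attack"
        )
    calls = (dist1 < dist0).astype(np.int8)
    G = GenotypeMatrix(calls[None, :], list(d.snp_ids), ["recovered_1"], BINARY)
    assignment = np.ones((len(d.values), 1), dtype=np.int8)
    assignment[:-1, 0] = calls
    return ReconstructionResult(
        genotypes=G,
        C=CmSolution(np.array([C]), method="single"),
        method="exact",
        assignment=assignment,
        diagnostics={"max_deviation": worst, "tol": tol},
    )


def _unique_nonzero(d: DVector, rel_tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Cluster d entries; returns (labels, cluster reps, tol) with the cluster
    nearest zero treated as the zero class."""
    labels, reps = cluster_values(d.values, rel_tol)
    return labels, reps, _tol_of(d, rel_tol)


def _nonzero_reps(reps: np.ndarray, tol: float) -> np.ndarray:
    if len(reps) == 0:
        return reps
    zero_idx = int(np.argmin(np.abs(reps)))
    if abs(reps[zero_idx]) <= tol:
        return np.delete(reps, zero_idx)
    return reps.copy()


def identify_Cm_simple(d: DVector, m: int | None = None, rel_tol: float = DEFAULT_REL_TOL) -> CmSolution:
    """Identify C_m when all 2^m presence-combinations occur in d.

    Steps: take the unique nonzero values of d; form all pairwise sums of
    distinct values; the values not expressible as such a sum are the C_m.
    Validated by requiring exactly 2^m distinct values overall and that the
    identified constants sum to the intercept entry of d.
    """
    m = d.m_declared if m is None else m
    _, reps, tol = _unique_nonzero(d, rel_tol)
    nonzero = _nonzero_reps(reps, tol)
    n_clusters = len(reps)
    if n_clusters != 2 ** m or len(nonzero) != 2 ** m - 1:
        raise SimplePreconditionError(
            f"expected 2^{m}={2 ** m} distinct d values (zero included), found "
            f"{n_clusters}; fall back to identify_Cm_extended"
        )
    pair_sums = np.array([a + b for a, b in itertools.combinations(nonzero, 2)])
    is_sum = np.array([
        len(pair_sums) > 0 and np.min(np.abs(pair_sums - v)) <= tol for v in nonzero
    ])
    C = nonzero[~is_sum]
    if len(C) != m or abs(C.sum() - d.intercept_value) > max(tol, 1e-8 * abs(d.intercept_value)):
        raise SimplePreconditionError(
            f"pairwise-sum elimination left {len(C)} candidates summing to "
            f"{C.sum():.6g} vs intercept {d.intercept_value:.6g}; "
            "fall back to identify_Cm_extended"
        )
    return CmSolution(C, method="simple")


def _genotype_loglik(assignment: np.ndarray, freqs: np.ndarray) -> float:
    """Log-probability of recovered genotypes under independent per-SNP
    Bernoulli frequencies (marginal frequencies only)."""
    g = assignment[:-1, :]           # drop intercept row
    p = np.clip(np.asarray(freqs, dtype=float), 1e-12, 1 - 1e-12)[:, None]
    return float(np.sum(np.where(g == 1, np.log(p), np.log1p(-p))))


def identify_Cm_extended(
    d: DVector,
    m: int | None = None,
    snp_freqs: FrequencyTable | np.ndarray | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    max_subsets: int = 2 ** 20,
    max_rounds: int = 4,
) -> CmSolution:
    """Identify C_m even when some presence-combinations are missing from d.

    Starts from the pairwise-sum elimination of the simple algorithm; if that
    does not yield exactly m constants summing to d's intercept entry, the
    candidate pool is augmented with pairwise differences and searched for an
    m-subset that (a) sums to the intercept entry and (b) explains every d
    value as one of its subset-sums.  Competing subsets are ranked by the
    likelihood of the genotypes they imply under the per-SNP frequencies.
    """
    m = d.m_declared if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    _, reps, tol = _unique_nonzero(d, rel_tol)
    nonzero = _nonzero_reps(reps, tol)
    target = d.intercept_value

    if 2 ** m > len(d.values):
        raise ReconstructionInfeasibleError(
            f"2^m = {2 ** m} exceeds the {len(d.values)} observed d entries; "
            "exact multi-individual reconstruction requires N > 2^m"
        )

    # Steps 1-3: values not expressible as a pairwise sum of observed values.
    pair_sums = np.array([a + b for a, b in itertools.combinations(nonzero, 2)]) \
        if len(nonzero) > 1 else np.empty(0)
    primary = [v for v in nonzero
               if len(pair_sums) == 0 or np.min(np.abs(pair_sums - v)) > tol]

    # Step 4: accept immediately when the elimination already worked.
    if len(primary) == m and abs(sum(primary) - target) <= max(tol, 1e-8 * abs(target)):
        sol = CmSolution(np.asarray(primary), method="extended")
        try:
            assign_genotypes(d, sol, rel_tol)
            return sol
        except NoisyDError:
            pass  # inconsistent despite matching sum; fall through to search

    def _dedupe(vals: list[float]) -> list[float]:
        out: list[float] = []
        for v in sorted(vals):
            if not out or v - out[-1] > tol:
                out.append(v)
        return out

    pool = _dedupe(primary)
    freq_arr = None
    if snp_freqs is not None:
        freq_arr = snp_freqs.frequencies if isinstance(snp_freqs, FrequencyTable) else np.asarray(snp_freqs)

    for _ in range(max_rounds):
        # Step 6: pairwise differences are also potential constants.
        diffs = [a - b for a, b in itertools.permutations(pool, 2)]
        new_pool = _dedupe([v for v in pool + diffs if abs(v) > tol])
        # Step 7: search m-subsets of the pool summing to the intercept entry.
        if math.comb(len(new_pool), m) > max_subsets:
            raise ReconstructionInfeasibleError(
                f"candidate pool of {len(new_pool)} values exceeds the subset "
                f"search budget ({max_subsets} subsets) for m={m}"
            )
        scored: list[tuple[np.ndarray, float]] = []
        for combo in itertools.combinations(new_pool, m):
            if abs(sum(combo) - target) > max(tol, 1e-8 * abs(target)):
                continue
            cand = CmSolution(np.asarray(combo), method="extended")
            try:
                result = assign_genotypes(d, cand, rel_tol)
            except NoisyDError:
                continue
            ll = _genotype_loglik(result.assignment, freq_arr) if freq_arr is not None else 0.0
            scored.append((cand.C_values, ll))
        if scored:
            scored.sort(key=lambda t: -t[1])
            best_C, best_ll = scored[0]
            ambiguity = [(c, ll) for c, ll in scored
                         if not np.allclose(c, best_C, atol=tol)]
            return CmSolution(best_C, method="extended", ambiguity=ambiguity)
        if len(new_pool) == len(pool):
            break  # step 8: pool stopped growing, repeating cannot help
        pool = new_pool

    raise ReconstructionInfeasibleError(
        f"no set of {m} constants consistent with d was found within the search budget"
    )


def assign_genotypes(d: DVector, C: CmSolution, rel_tol: float = DEFAULT_REL_TOL) -> ReconstructionResult:
    """Match every d entry to the nearest subset-sum of C and read off genotypes.

    Entry i matching the subset S means exactly the individuals in S carry
    SNP i; the indicator of S becomes column i of Phi_m^T.  An entry matching
    no subset-sum within tolerance raises :class:`NoisyDError`.
    """
    m = C.m
    if m > 20:
        raise ValueError("subset-sum enumeration limited to m <= 20")
    tol = _tol_of(d, rel_tol)
    subsets = np.array(list(itertools.product((0, 1), repeat=m)), dtype=np.int8)  # (2^m, m)
    sums = subsets @ C.C_values
    dist = np.abs(d.values[:, None] - sums[None, :])
    nearest = np.argmin(dist, axis=1)
    worst = float(dist[np.arange(len(d.values)), nearest].max())
    if worst > tol:
        bad = int(np.argmax(dist[np.arange(len(d.values)), nearest]))
        raise NoisyDError(
            f"d entry {bad} = {d.values[bad]:.6g} is {worst:.3e} from the nearest "
            f"subset-sum (tol {tol:.3e}); use the EM attack"
        )
    assignment = subsets[nearest]                 # (N+1, m)
    genotypes = assignment[:-1, :].T.copy()       # (m, N)
    G = GenotypeMatrix(genotypes, list(d.snp_ids),
                       [f"recovered_{j + 1}" for j in range(m)], BINARY)
    return ReconstructionResult(
        genotypes=G, C=C, method="exact", assignment=assignment,
        diagnostics={"max_deviation": worst, "tol": tol},
    )


def restrict_to_overlap(
    release_old: GRSRelease,
    release_new: GRSRelease,
    K_old_full: KMatrix,
    K_new_full: KMatrix | None = None,
) -> DVector:
    """Attack vector over the SNPs shared by two releases with different panels.

    Each study's normal equations give K beta-hat = (1/M) Phi^T y over its own
    panel, with the added individuals contributing a low-rank correction to the
    second study.  Restricting the *rows* of those products to the shared SNPs
    (plus intercept) cancels the shared cohort's contribution exactly, leaving
    [K' beta'] - [K beta] = C [phi_0]: the usual attack vector, now over the
    shared SNPs only.  The restriction applies to the full matrix-vector
    products, so the co-occurrence rows of the shared SNPs against *each*
    study's full panel are needed — ``K_old_full`` over the first panel and
    ``K_new_full`` over the second (both taken over the shared cohort; they
    coincide when the panels coincide, in which case ``K_new_full`` may be
    omitted and the result equals :func:`compute_d`).
    """
    if K_old_full.snp_ids != release_old.snp_ids:
        raise ValueError("K_old_full must be indexed by the first release's SNP panel")
    if K_new_full is None:
        if release_new.snp_ids != release_old.snp_ids:
            raise ValueError(
                "releases use different SNP panels: the second panel's "
                "co-occurrence matrix K_new_full is required"
            )
        K_new_full = K_old_full
    elif K_new_full.snp_ids != release_new.snp_ids:
        raise ValueError("K_new_full must be indexed by the second release's SNP panel")
    new_set = set(release_new.snp_ids)
    shared = [s for s in release_old.snp_ids if s in new_set]
    if not shared:
        raise ValueError("releases share no SNPs; the overlap attack needs >= 1")
    old_pos = {s: i for i, s in enumerate(release_old.snp_ids)}
    new_pos = {s: i for i, s in enumerate(release_new.snp_ids)}
    idx_old = [old_pos[s] for s in shared] + [len(release_old.snp_ids)]
    idx_new = [new_pos[s] for s in shared] + [len(release_new.snp_ids)]
    d = (K_new_full.values @ release_new.beta)[idx_new] \
        - (K_old_full.values @ release_old.beta)[idx_old]
    m = max(release_new.cohort_size - release_old.cohort_size, 1)
    return DVector(d, m, shared)


def symmetric_difference_d(
    K: KMatrix,
    release_A: GRSRelease,
    release_B: GRSRelease,
    a: int | None = None,
    b: int | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
) -> DVector:
    """Attack vector when each study has individuals the other lacks.

    Study A has M+a participants and study B has M+b, sharing the M core.
    d = K (beta_A - beta_B) equals (1/M) Phi_{a+b} r_{a+b} where the columns
    of Phi_{a+b} stack the a+b distinct individuals and r carries
    +(y - Phi beta_A) residuals for A-only individuals and the negated
    residuals for B-only ones — the problem reduces to an (a+b)-individual
    reconstruction whose constants may take either sign.
    """
    if release_A.snp_ids != release_B.snp_ids:
        raise ValueError("releases use different SNP panels; use restrict_to_overlap")
    if K.snp_ids != release_A.snp_ids:
        raise ValueError("K SNP ordering does not match the releases")
    if a is None or b is None:
        raise ValueError("symmetric-difference attack needs the counts a and b")
    d = K.values @ (release_A.beta - release_B.beta)
    if a + b == 0:
        if np.max(np.abs(d)) > rel_tol * max(np.max(np.abs(K.values @ release_A.beta)), 1.0):
            raise AttackError("a=b=0 declared but the releases differ")
        raise ValueError("a + b must be >= 1 for a reconstruction target to exist")
    return DVector(d, a + b, list(release_A.snp_ids))
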