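"""Probabilistic reconstruction when K is only estimated.

With an estimated K-hat the attack vector x = K-hat * Delta (Delta the
difference of the two released coefficient vectors) is modelled as Gaussian
around the exact-K lattice: x ~ N(Phi_m^T c_m, sigma^2 Delta^T Delta I), with
the unknown genotype entries z_ij Bernoulli under public SNP frequencies
alpha_i.  For one added individual the posterior is available in closed form
and an exact EM alternates responsibilities with updates of C and sigma^2.
For several individuals the E-step is replaced by Gibbs sampling over the
z_ij (stochastic EM): the C update is a least-squares solve against the
sampled indicator matrix, sigma^2 is the mean squared error, and C is kept
sorted ascending to break the permutation symmetry between individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exact import CmSolution, DVector, ReconstructionResult
from .grs import GRSRelease
from .kmatrix import KMatrix
from .synthdata import BINARY, GenotypeMatrix

__all__ = [
    "EMConfig",
    "SEMConfig",
    "EMState",
    "em_single",
    "em_attack",
    "gibbs_conditional",
    "sem_multiple",
    "sem_attack",
    "call_genotypes",
]

_SIGMA2_REL_FLOOR = 1e-12


class SEMDivergenceError(RuntimeError):
    """The sigma^2 trace of the stochastic EM run diverged."""


@dataclass
class EMConfig:
    """Controls for the exact (m=1) EM attack."""

    max_iter: int = 500
    convergence_tol: float = 1e-8
    init_mode: str = "prior_probs"       # prior_probs | zeros
    call_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not (0.0 < self.call_threshold < 1.0):
            raise ValueError("call_threshold must lie in (0, 1)")
        if self.init_mode not in ("prior_probs", "zeros"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class SEMConfig(EMConfig):
    """Controls for the stochastic EM (m>1) attack.

    The run has fixed length ``max_iter``; after ``burn_in`` iterations the C
    vector, sigma^2 and the sampled indicators are averaged over the final
    ``averaging_window`` iterations to form point estimates and posteriors.
    """

    max_iter: int = 2000
    burn_in: int = 500
    averaging_window: int = 1000
    gibbs_sweeps_per_iter: int = 1
    n_restarts: int = 3

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.burn_in < 0 or self.averaging_window < 1 or self.gibbs_sweeps_per_iter < 1:
            raise ValueError("burn_in >= 0, averaging_window >= 1, sweeps >= 1 required")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.averaging_window > self.max_iter - self.burn_in:
            raise ValueError("averaging_window must fit after burn_in within max_iter")


@dataclass
class EMState:
    """Snapshot of the latent posteriors and parameters during a run."""

    pi: np.ndarray               # (N+1, m) posterior P(z_ij = 1)
    C: np.ndarray                # length m, sorted ascending
    sigma2: float
    loglik_trace: list[float] = field(default_factory=list)


def _prepare_alphas(alphas: np.ndarray, n_entries: int) -> np.ndarray:
    """Priors for each coordinate of x: public frequencies, then 1 for the
    intercept (an added design row always ends in 1)."""
    alphas = np.asarray(alphas, dtype=float).ravel()
    if len(alphas) == n_entries:          # caller already appended the intercept
        full = alphas.copy()
    elif len(alphas) == n_entries - 1:
        full = np.append(alphas, 1.0)
    else:
        raise ValueError(f"expected {n_entries - 1} SNP priors, got {len(alphas)}")
    if np.any((full < 0) | (full > 1)):
        raise ValueError("prior frequencies must lie in [0, 1]")
    full[-1] = 1.0
    return full


def _sigma2_floor(x: np.ndarray) -> float:
    return _SIGMA2_REL_FLOOR * max(float(np.mean(x ** 2)), np.finfo(float).tiny)


def _bernoulli_logodds(alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log alpha, log(1-alpha)) with degenerate priors mapped to -inf safely."""
    with np.errstate(divide="ignore"):
        return np.log(alpha), np.log1p(-alpha)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def em_single(
    d_hat: DVector,
    alphas: np.ndarray,
    cfg: EMConfig | None = None,
    delta_ss: float = 1.0,
) -> ReconstructionResult:
    """Exact EM reconstruction of one added individual from a noisy d.

    ``d_hat`` is K-hat * Delta; ``alphas`` are the public per-SNP frequencies;
    ``delta_ss`` is Delta^T Delta, the factor relating the model variance
    sigma^2 to the observed scatter (pass 1.0 to estimate on the combined
    scale).  The E-step computes the per-entry posterior of carrying the SNP,
    the M-step re-estimates C (responsibility-weighted mean of x) and sigma^2
    (responsibility-weighted mean squared residual).
    """
    cfg = cfg or EMConfig()
    x = d_hat.values
    n = len(x)
    alpha = _prepare_alphas(alphas, n)
    la, lb = _bernoulli_logodds(alpha)

    if cfg.init_mode == "prior_probs":
        pi = alpha.copy()
    else:
        pi = np.zeros(n)
    pi[-1] = 1.0

    def m_step(pi: np.ndarray) -> tuple[float, float]:
        denom = pi.sum()
        C = float(np.sum(pi * x) / denom)            # denom >= 1: intercept pi is 1
        s2 = float(np.sum(pi * (x - C) ** 2 + (1 - pi) * x ** 2) / n)
        return C, max(s2, _sigma2_floor(x))

    def e_step(C: float, s2: float) -> np.ndarray:
        ll1 = la - (x - C) ** 2 / (2 * s2)
        ll0 = lb - x ** 2 / (2 * s2)
        pi = _sigmoid(ll1 - ll0)
        pi = np.where(alpha >= 1.0, 1.0, np.where(alpha <= 0.0, 0.0, pi))
        return pi

    def observed_loglik(C: float, s2: float) -> float:
        norm_const = -0.5 * np.log(2 * np.pi * s2)
        l1 = la + norm_const - (x - C) ** 2 / (2 * s2)
        l0 = lb + norm_const - x ** 2 / (2 * s2)
        return float(np.sum(np.logaddexp(l1, l0)))

    C, s2 = m_step(pi)
    trace = [observed_loglik(C, s2)]
    converged = False
    for it in range(cfg.max_iter):
        pi = e_step(C, s2)
        C_new, s2_new = m_step(pi)
        trace.append(observed_loglik(C_new, s2_new))
        dC = abs(C_new - C) / max(abs(C), 1e-300)
        ds = abs(s2_new - s2) / max(s2, 1e-300)
        C, s2 = C_new, s2_new
        if max(dC, ds) < cfg.convergence_tol:
            converged = True
            break

    sigma2_hat = s2 / delta_ss
    calls = (pi[:-1] >= cfg.call_threshold).astype(np.int8)
    G = GenotypeMatrix(calls[None, :], list(d_hat.snp_ids), ["recovered_1"], BINARY)
    return ReconstructionResult(
        genotypes=G,
        C=CmSolution(np.array([C]), method="em"),
        posteriors=pi[:, None],
        sigma2_hat=sigma2_hat,
        method="em",
        diagnostics={
            "converged": converged,
            "n_iter": it + 1,
            "loglik_trace": trace,
            "sigma2_combined": s2,
            "at_sigma2_floor": s2 <= _sigma2_floor(x) * (1 + 1e-9),
        },
    )


def em_attack(
    K_hat: KMatrix,
    release_old: GRSRelease,
    release_new: GRSRelease,
    alphas: np.ndarray,
    cfg: EMConfig | None = None,
) -> ReconstructionResult:
    """Convenience wrapper: build x = K-hat Delta and Delta^T Delta, run EM."""
    delta = release_new.beta - release_old.beta
    d_hat = DVector(K_hat.values @ delta,
                    max(release_new.cohort_size - release_old.cohort_size, 1),
                    list(release_old.snp_ids))
    return em_single(d_hat, alphas, cfg, delta_ss=float(delta @ delta))


def gibbs_conditional(
    x_i: float,
    alpha_i: float,
    C: np.ndarray,
    z_others: np.ndarray,
    j: int,
    sigma2: float,
    delta_ss: float = 1.0,
) -> float:
    """P(z_ij = 1 | x_i, z_ik for k != j, C, sigma^2) for one site and individual.

    Two-term Bernoulli posterior: the Gaussian likelihood of x_i with and
    without C_j added to the contribution of the other individuals, weighted
    by the prior alpha_i.  Computed in log space.  Sites are independent;
    only the m individuals interact.
    """
    if alpha_i >= 1.0:
        return 1.0
    if alpha_i <= 0.0:
        return 0.0
    C = np.asarray(C, dtype=float)
    z = np.asarray(z_others, dtype=float)
    base = float(np.dot(C, z) - C[j] * z[j])
    s2 = sigma2 * delta_ss
    ll1 = np.log(alpha_i) - (x_i - C[j] - base) ** 2 / (2 * s2)
    ll0 = np.log1p(-alpha_i) - (x_i - base) ** 2 / (2 * s2)
    return float(_sigmoid(np.array([ll1 - ll0]))[0])


def _exact_site_posterior(
    x: np.ndarray, alpha: np.ndarray, C: np.ndarray, s2: float
) -> np.ndarray:
    """Exact marginal posteriors P(z_ij = 1 | x_i) given (C, sigma^2).

    Sites are independent given the parameters, so the joint over the m
    indicators at one site is enumerable: 2^m configurations with Bernoulli
    priors and a Gaussian likelihood on the subset-sum.  Returns (N+1, m).
    """
    import itertools as _it

    states = np.array(list(_it.product((0, 1), repeat=len(C))), dtype=float)
    w = _exact_site_posterior_weights(x, alpha, C, s2, states)
    pi = w @ states
    pi[-1, :] = 1.0
    return pi


def _exact_em_refine(
    x: np.ndarray, alpha: np.ndarray, C0: np.ndarray, s20: float, floor: float,
    max_iter: int = 200, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Deterministic EM polish of (C, sigma^2) using the enumerated E-step.

    Alternates the exact per-site posterior with weighted least-squares
    updates of C and the posterior-expected mean squared residual for
    sigma^2.  Started from the stochastic-EM averages this sharpens the
    estimates to a local maximum of the likelihood; in the noiseless limit it
    contracts to the exact-attack solution.
    """
    import itertools as _it

    m = len(C0)
    states = np.array(list(_it.product((0, 1), repeat=m)), dtype=float)
    C, s2 = C0.copy(), max(s20, floor)
    n = len(x)
    it = 0
    for it in range(max_iter):
        pi_full = _exact_site_posterior_weights(x, alpha, C, s2, states)  # (n, 2^m)
        w_state = pi_full.sum(axis=0)                                     # (2^m,)
        A = (states.T * w_state) @ states
        b = states.T @ (pi_full.T @ x)
        try:
            C_new = scipy.linalg.solve(A, b, assume_a="sym")
        except (np.linalg.LinAlgError, ValueError):
            C_new = scipy.linalg.solve(A + 1e-10 * np.eye(m) * (np.trace(A) / m + 1.0), b,
                                       assume_a="sym")
        resid2 = (x[:, None] - states @ C_new) ** 2
        s2_new = max(float(np.sum(pi_full * resid2) / n), floor)
        done = (np.max(np.abs(C_new - C)) <= tol * max(np.max(np.abs(C)), 1e-300)
                and abs(s2_new - s2) <= tol * s2)
        order = np.argsort(C_new)
        C, s2 = C_new[order], s2_new
        if done:
            break
    pi_full = _exact_site_posterior_weights(x, alpha, C, s2, states)
    pi = pi_full @ states
    pi[-1, :] = 1.0
    return pi, C, s2, it + 1


def _exact_site_posterior_weights(
    x: np.ndarray, alpha: np.ndarray, C: np.ndarray, s2: float, states: np.ndarray
) -> np.ndarray:
    """Posterior weights over the 2^m per-site states; rows sum to 1."""
    m = states.shape[1]
    sums = states @ C
    ones = states.sum(axis=1)
    la, lb = _bernoulli_logodds(alpha)
    la = np.where(np.isfinite(la), la, -1e300)
    lb = np.where(np.isfinite(lb), lb, -1e300)
    log_post = (la[:, None] * ones[None, :] + lb[:, None] * (m - ones)[None, :]
                - (x[:, None] - sums[None, :]) ** 2 / (2 * s2))
    log_post -= log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _gibbs_sweep(
    Z: np.ndarray, x: np.ndarray, la: np.ndarray, lb: np.ndarray, alpha: np.ndarray,
    C: np.ndarray, s2: float, rng: np.random.Generator,
) -> None:
    """One systematic sweep updating every z_ij in place, vectorized over sites."""
    m = Z.shape[1]
    for j in range(m):
        base = Z @ C - C[j] * Z[:, j]
        ll1 = la - (x - C[j] - base) ** 2 / (2 * s2)
        ll0 = lb - (x - base) ** 2 / (2 * s2)
        p = _sigmoid(ll1 - ll0)
        p = np.where(alpha >= 1.0, 1.0, np.where(alpha <= 0.0, 0.0, p))
        Z[:, j] = rng.random(len(x)) < p
    Z[-1, :] = 1.0   # intercept row of every added design row is 1


def sem_multiple(
    d_hat: DVector,
    m: int | None = None,
    alphas: np.ndarray | None = None,
    cfg: SEMConfig | None = None,
    delta_ss: float = 1.0,
) -> ReconstructionResult:
    """Stochastic EM reconstruction of m >= 2 added individuals.

    Each iteration: (a) Gibbs sweeps over all z_ij; (b) least-squares update
    of C against the sampled indicator matrix and sigma^2 as the mean squared
    error; (c) ascending sort of C with the matching column permutation of Z.
    Posteriors are the post-burn-in indicator frequencies; C and sigma^2 are
    averaged over the same window.
    """
    cfg = cfg or SEMConfig()
    m = d_hat.m_declared if m is None else m
    if m < 2:
        raise ValueError("sem_multiple requires m >= 2; use em_single for m=1")
    if alphas is None:
        raise ValueError("public SNP frequencies (alphas) are required")
    x = d_hat.values
    n = len(x)
    alpha = _prepare_alphas(alphas, n)

    best = None
    for chain_seed in np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts):
        result = _sem_chain(x, n, m, alpha, cfg, np.random.default_rng(chain_seed))
        if best is None or result["loglik"] > best["loglik"]:
            best = result

    pi, C_bar, s2_bar = best["pi"], best["C"], best["s2"]
    calls = (pi[:-1, :] >= cfg.call_threshold).astype(np.int8).T    # (m, N)
    G = GenotypeMatrix(calls, list(d_hat.snp_ids),
                       [f"recovered_{j + 1}" for j in range(m)], BINARY)
    return ReconstructionResult(
        genotypes=G,
        C=CmSolution(C_bar, method="sem"),
        posteriors=pi,
        sigma2_hat=s2_bar / delta_ss,
        method="sem",
        diagnostics={
            "n_iter": cfg.max_iter,
            "n_averaged": best["n_avg"],
            "n_restarts": cfg.n_restarts,
            "ridge_stabilized_updates": best["ridge_warnings"],
            "sigma2_combined": s2_bar,
            "refine_iters": best["refine_iters"],
            "pi_sampled": best["pi_sampled"],
            "loglik": best["loglik"],
        },
    )


def _multi_observed_loglik(x: np.ndarray, alpha: np.ndarray, C: np.ndarray, s2: float) -> float:
    """Observed-data log-likelihood, marginalizing the 2^m per-site states."""
    import itertools as _it

    states = np.array(list(_it.product((0, 1), repeat=len(C))), dtype=float)
    sums = states @ C
    ones = states.sum(axis=1)
    la, lb = _bernoulli_logodds(alpha)
    la = np.where(np.isfinite(la), la, -1e300)
    lb = np.where(np.isfinite(lb), lb, -1e300)
    lp = (la[:, None] * ones[None, :] + lb[:, None] * (len(C) - ones)[None, :]
          - (x[:, None] - sums[None, :]) ** 2 / (2 * s2)
          - 0.5 * np.log(2 * np.pi * s2))
    from scipy.special import logsumexp
    return float(logsumexp(lp, axis=1).sum())


def _sem_chain(
    x: np.ndarray, n: int, m: int, alpha: np.ndarray, cfg: SEMConfig,
    rng: np.random.Generator,
) -> dict:
    """One stochastic-EM chain plus deterministic polish; returns its scored state."""
    la, lb = _bernoulli_logodds(alpha)
    floor = _sigma2_floor(x)

    Z = np.zeros((n, m))
    if cfg.init_mode == "prior_probs":
        Z[:] = rng.random((n, m)) < alpha[:, None]
    Z[-1, :] = 1.0

    def update_params(Z: np.ndarray) -> tuple[np.ndarray, float, bool]:
        A = Z.T @ Z
        b = Z.T @ x
        ridged = False
        try:
            C = scipy.linalg.solve(A, b, assume_a="sym")
            if not np.all(np.isfinite(C)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            C = scipy.linalg.solve(A + 1e-8 * (np.trace(A) / m + 1.0) * np.eye(m), b,
                                   assume_a="sym")
            ridged = True
        resid = x - Z @ C
        s2 = max(float(np.mean(resid ** 2)), floor)
        return C, s2, ridged

    C, s2, _ = update_params(Z)
    order = np.argsort(C)
    C, Z = C[order], Z[:, order]

    C_sum = np.zeros(m)
    s2_sum = 0.0
    Z_sum = np.zeros((n, m))
    n_avg = 0
    ridge_warnings = 0
    s2_scale = max(float(np.mean(x ** 2)), np.finfo(float).tiny)
    avg_start = cfg.max_iter - cfg.averaging_window

    for it in range(cfg.max_iter):
        for _ in range(cfg.gibbs_sweeps_per_iter):
            _gibbs_sweep(Z, x, la, lb, alpha, C, s2, rng)
        C, s2, ridged = update_params(Z)
        ridge_warnings += ridged
        if s2 > 1e12 * s2_scale:
            raise SEMDivergenceError(f"sigma^2 trace diverged at iteration {it}")
        order = np.argsort(C)              # symmetry-breaking projection
        C, Z = C[order], Z[:, order]
        if it >= max(cfg.burn_in, avg_start):
            C_sum += C
            s2_sum += s2
            Z_sum += Z
            n_avg += 1

    C_bar = C_sum / n_avg
    s2_bar = s2_sum / n_avg
    pi_sampled = Z_sum / n_avg
    pi_sampled[-1, :] = 1.0
    # The sampler's stationary noise limits both the indicator frequencies and
    # the averaged parameters.  For small m the per-site posterior factorizes
    # and is enumerable over 2^m states, so a deterministic EM polish from the
    # stochastic averages sharpens (C, sigma^2) to a likelihood optimum and
    # yields exact posteriors; in the noiseless limit this contracts to the
    # exact-attack answer.
    refine_iters = 0
    if m <= 12:
        pi, C_bar, s2_bar, refine_iters = _exact_em_refine(x, alpha, C_bar, s2_bar, floor)
        loglik = _multi_observed_loglik(x, alpha, C_bar, s2_bar)
    else:
        pi = pi_sampled
        loglik = -s2_bar   # restart selection falls back to the lowest noise level
    return dict(pi=pi, C=C_bar, s2=s2_bar, pi_sampled=pi_sampled, n_avg=n_avg,
                ridge_warnings=ridge_warnings, refine_iters=refine_iters, loglik=loglik)


def sem_attack(
    K_hat: KMatrix,
    release_old: GRSRelease,
    release_new: GRSRelease,
    alphas: np.ndarray,
    m: int | None = None,
    cfg: SEMConfig | None = None,
) -> ReconstructionResult:
    """Convenience wrapper: build x = K-hat Delta and Delta^T Delta, run SEM."""
    delta = release_new.beta - release_old.beta
    m = m if m is not None else max(release_new.cohort_size - release_old.cohort_size, 1)
    d_hat = DVector(K_hat.values @ delta, m, list(release_old.snp_ids))
    return sem_multiple(d_hat, m, alphas, cfg, delta_ss=float(delta @ delta))


def call_genotypes(
    pi: np.ndarray, threshold: float = 0.5, snp_ids: list[str] | None = None
) -> GenotypeMatrix:
    """Hard calls 1[pi >= threshold] (ties call 1); intercept row dropped."""
    pi = np.asarray(pi, dtype=float)
    if pi.ndim == 1:
        pi = pi[:, None]
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    calls = (pi[:-1, :] >= threshold).astype(np.int8).T
    ids = snp_ids if snp_ids is not None else [f"snp_{i}" for i in range(calls.shape[1])]
    return GenotypeMatrix(calls, list(ids),
                          [f"recovered_{j + 1}" for j in range(calls.shape[0])], BINARY)
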