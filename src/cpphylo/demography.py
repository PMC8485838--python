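"""Neutrality tests and mismatch-distribution expansion fitting.

Per-lineage historical demography from a non-recombining locus:

* Tajima's D (1989), Fu's Fs (1997) and the Ramos-Onsins & Rozas (2002)
  R2 statistic, with p-values from seeded neutral coalescent simulations
  conditioned on the sample size and the observed number of segregating
  sites (the practice behind "permutation" p-values for these tests).
* The pairwise-difference (mismatch) distribution with a sudden-expansion
  fit: expected class probabilities follow the finite-size
  Rogers-Harpending model with parameters tau (scaled expansion time),
  theta0 and theta1 (mutation-scaled sizes before/after expansion), fitted
  by bounded multistart SSD minimisation; goodness of fit via SSD and
  Harpending's raggedness index with parametric-bootstrap p-values.

Sign conventions: strongly negative D and Fs, and small R2, indicate an
excess of rare variants and hence demographic expansion; the simulation
p-values for D are two-tailed, those for Fs and R2 lower-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .coalescent import (
    Event,
    constant_size_tree,
    fixed_s_patterns,
    pairwise_difference_matrix,
    poisson_branch_mutations,
    simulate_genealogy,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# summaries of an alignment (gap-free sequences)


def site_base_counts(sequences: Sequence[str]) -> list[dict[str, int]]:
    """Base counts for each polymorphic column."""
    mat = np.array([list(s) for s in sequences], dtype="U1")
    out = []
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        if vals.size >= 2:
            out.append(dict(zip(vals.tolist(), counts.tolist())))
    return out


def segregating_sites(sequences: Sequence[str]) -> int:
    return len(site_base_counts(sequences))


def mean_pairwise_differences(sequences: Sequence[str]) -> float:
    n = len(sequences)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    pairs = n * (n - 1) / 2.0
    total = 0.0
    for counts in site_base_counts(sequences):
        same = sum(c * (c - 1) / 2.0 for c in counts.values())
        total += pairs - same
    return total / pairs


def _singleton_loads(sequences: Sequence[str]) -> np.ndarray:
    """U_i: number of singleton sites whose minor base sequence i carries.

    At a site where the rarest base has count 1 and is a strict minority,
    its single carrier is counted.  When count-1 bases tie for the
    majority (only possible at very small n, e.g. two sequences), the
    carrier of the lexicographically smallest such base is counted.
    """
    mat = np.array([list(s) for s in sequences], dtype="U1")
    n = mat.shape[0]
    u = np.zeros(n, dtype=float)
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        if vals.size < 2:
            continue
        cmax = counts.max()
        single = [v for v, c in zip(vals, counts) if c == 1]
        if not single:
            continue
        if cmax > 1:
            for v in single:
                u[np.flatnonzero(mat[:, j] == v)[0]] += 1
        else:
            # all bases singletons: lexicographically smallest wins the tie
            u[np.flatnonzero(mat[:, j] == sorted(single)[0])[0]] += 1
    return u


# ---------------------------------------------------------------------------
# statistics


def tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d_value(n: int, S: int, k_bar: float) -> float:
    """Tajima's D from (n, S, mean pairwise differences)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    c = tajima_constants(n)
    return (k_bar - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))


@lru_cache(maxsize=16)
def _log_stirling_first(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n (unsigned, first kind), in log space."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |S1(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        cur[1: m + 1] = np.logaddexp(
            prev[0:m], np.log(m - 1) + prev[1: m + 1] if m > 1 else -np.inf
        )
        # note: |S1(m,k)| = |S1(m-1,k-1)| + (m-1)|S1(m-1,k)|
        prev = cur
    return prev


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_first(n)
    k = np.arange(n + 1)
    denom = np.sum(np.log(theta + np.arange(n)))
    with np.errstate(divide="ignore"):
        return ls + k * np.log(theta) - denom


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta, n).

    ``theta`` is conventionally the observed mean number of pairwise
    differences.  Raises for the degenerate cases S' = 1 (k_obs = 1 makes
    Fs = +inf) and S' = 0.
    """
    if n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("haplotype count must be in 1..n")
    log_pmf = ewens_log_pmf(n, theta)
    s_prime = float(np.exp(special.logsumexp(log_pmf[k_obs:])))
    s_prime = min(max(s_prime, 0.0), 1.0)
    if s_prime >= 1.0:
        raise ValueError("S' = 1 (every sample has >= k_obs haplotypes): Fs = +inf")
    if s_prime <= 0.0:
        raise ValueError("S' = 0: Fs = -inf")
    return float(np.log(s_prime / (1.0 - s_prime)))


def r2_value(n: int, S: int, k_bar: float, u: np.ndarray) -> float:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton loads."""
    if S < 1:
        raise ValueError("R2 is undefined when S = 0")
    return float(np.sqrt(np.mean((u - k_bar / 2.0) ** 2)) / S)


# ---------------------------------------------------------------------------
# simulation nulls


def simulate_neutral_null(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Joint null distributions of (D, Fs, R2) under constant size.

    Each replicate draws a Kingman genealogy and places exactly S
    mutations on branches with probability proportional to length
    (infinite sites), conditioning the null on the observed S.
    """
    ds, fss, r2s = [], [], []
    pairs = n * (n - 1) / 2.0
    for _ in range(reps):
        tree = constant_size_tree(n, 1.0, rng)
        patterns = fixed_s_patterns(tree, S, rng)
        counts = patterns.sum(axis=0)
        k_bar = float((counts * (n - counts)).sum() / pairs)
        ds.append(tajimas_d_value(n, S, k_bar) if n >= 4 else np.nan)
        u = np.zeros(n)
        for m in range(S):
            if counts[m] == 1:
                u[np.flatnonzero(patterns[:, m])[0]] += 1
            elif counts[m] == n - 1:
                u[np.flatnonzero(~patterns[:, m])[0]] += 1
        r2s.append(r2_value(n, S, k_bar, u))
        k_hap = np.unique(patterns, axis=0).shape[0]
        try:
            fss.append(fus_fs(n, k_hap, k_bar) if k_bar > 0 else np.nan)
        except ValueError:
            fss.append(np.nan)
    return {"D": np.asarray(ds), "Fs": np.asarray(fss), "R2": np.asarray(r2s)}


@dataclass
class NeutralityResult:
    n: int
    S: int
    k_bar: float
    n_haplotypes: int
    D: float | None = None
    p_D: float | None = None
    Fs: float | None = None
    p_Fs: float | None = None
    R2: float | None = None
    p_R2: float | None = None
    n_simulations: int = 0


def neutrality_tests(
    sequences: Sequence[str], n_sim: int = 1000, seed: int | None = None
) -> NeutralityResult:
    """Tajima's D, Fu's Fs and R2 for one lineage, with simulation p-values.

    The three statistics share one set of neutral simulations conditioned
    on (n, S).  S = 0 raises: the statistics are undefined, not zero.
    """
    seqs = list(sequences)
    n = len(seqs)
    S = segregating_sites(seqs)
    if S < 1:
        raise ValueError("neutrality tests are undefined when S = 0")
    k_bar = mean_pairwise_differences(seqs)
    k_hap = len(set(seqs))
    d_obs = tajimas_d_value(n, S, k_bar) if n >= 4 else None
    fs_obs = fus_fs(n, k_hap, k_bar) if k_bar > 0 else None
    r2_obs = r2_value(n, S, k_bar, _singleton_loads(seqs))

    rng = np.random.default_rng(seed)
    null = simulate_neutral_null(n, S, n_sim, rng)
    res = NeutralityResult(n, S, k_bar, k_hap, n_simulations=n_sim)
    if d_obs is not None:
        lo = (np.sum(null["D"] <= d_obs) + 1) / (n_sim + 1)
        hi = (np.sum(null["D"] >= d_obs) + 1) / (n_sim + 1)
        res.D, res.p_D = float(d_obs), float(min(1.0, 2.0 * min(lo, hi)))
    if fs_obs is not None:
        valid = null["Fs"][~np.isnan(null["Fs"])]
        res.Fs = float(fs_obs)
        res.p_Fs = float((np.sum(valid <= fs_obs) + 1) / (valid.size + 1))
    res.R2 = float(r2_obs)
    res.p_R2 = float((np.sum(null["R2"] <= r2_obs) + 1) / (n_sim + 1))
    return res


# ---------------------------------------------------------------------------
# mismatch distribution


def mismatch_observed(sequences: Sequence[str]) -> np.ndarray:
    """Relative frequencies of pairwise difference counts, classes 0..max."""
    seqs = list(sequences)
    n = len(seqs)
    if n < 2:
        raise ValueError("mismatch distribution needs >= 2 sequences")
    mat = np.array([list(s) for s in seqs], dtype="U1")
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((mat[i] != mat[j]).sum()))
    counts = np.bincount(diffs)
    return counts / counts.sum()


def _equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """F_i(theta) = theta^i / (1+theta)^(i+1), the geometric equilibrium."""
    i = np.arange(d_max + 1, dtype=float)
    theta = max(theta, 1e-12)
    return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))


def sudden_expansion_expected(
    tau: float, theta0: float, theta1: float, d_max: int, normalise: bool = True
) -> np.ndarray:
    """Expected mismatch probabilities under a sudden expansion.

    A pair of lineages coalesces at rate 1/theta1 (mutational time units)
    until tau, and at rate 1/theta0 before the expansion; differences are
    Poisson along the pair path.  The closed form is

        F_i = F_i(theta1) P[Gamma(i+1) <= tau (1+theta1)/theta1]
              + exp(-tau (1+theta1)/theta1) sum_j tau^(i-j)/(i-j)! F_j(theta0)

    which reduces to the equilibrium geometric at theta0 when tau -> 0 and
    at theta1 when tau -> infinity.  The vector is renormalised over the
    observed support 0..d_max so both distributions sum to one.
    """
    theta1 = max(theta1, 1e-9)
    tau = max(tau, 0.0)
    i = np.arange(d_max + 1)
    rate = (1.0 + theta1) / theta1
    term1 = _equilibrium_mismatch(theta1, d_max) * special.gammainc(i + 1, tau * rate)
    # w_k = exp(-tau*rate) tau^k / k!
    with np.errstate(divide="ignore"):
        log_w = -tau * rate + np.where(
            i > 0, i * np.log(max(tau, 1e-300)), 0.0
        ) - special.gammaln(i + 1)
    w = np.exp(log_w)
    eq0 = _equilibrium_mismatch(theta0, d_max)
    term2 = np.convolve(w, eq0)[: d_max + 1]
    f = term1 + term2
    if normalise:
        total = f.sum()
        if total <= 0:
            raise FloatingPointError("degenerate expected mismatch distribution")
        f = f / total
    return f


def harpending_raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness on mismatch class frequencies.

    Boundary convention: classes below 0 and above the last observed class
    have frequency 0, so the squared-difference sum includes the first and
    last class against zero.
    """
    x = np.concatenate([[0.0], np.asarray(freqs, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchResult:
    observed: np.ndarray
    expected: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    hri: float
    p_ssd: float | None = None
    p_hri: float | None = None
    n_boot: int = 0
    #: refitted tau of each parametric-bootstrap replicate
    boot_tau: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


_THETA1_MAX = 1e4


def _fit_ssd(observed: np.ndarray, starts: Sequence[tuple[float, float, float]]) -> tuple[np.ndarray, float]:
    d_max = observed.size - 1
    bounds = [(0.0, 3.0 * max(d_max, 1)), (0.0, 2.0 * max(d_max, 1)), (1e-3, _THETA1_MAX)]

    def ssd(params: np.ndarray) -> float:
        exp = sudden_expansion_expected(params[0], params[1], params[2], d_max)
        return float(np.sum((observed - exp) ** 2))

    best: tuple[np.ndarray, float] | None = None
    for start in starts:
        res = optimize.minimize(ssd, np.asarray(start, float), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best[1]:
            best = (res.x, float(res.fun))
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(f"sudden-expansion optimiser failed; starts tried: {list(starts)}")
    return best


def _default_starts(observed: np.ndarray) -> list[tuple[float, float, float]]:
    d_max = observed.size - 1
    mean_d = float(np.arange(d_max + 1) @ observed)
    taus = sorted({max(0.1, 0.5 * mean_d), max(0.5, mean_d), max(1.0, 2.0 * mean_d)})
    return [(t, th0, th1) for t in taus for th0 in (0.1, 1.0) for th1 in (10.0, 1000.0)]


def fit_sudden_expansion(
    observed: np.ndarray,
    n: int,
    n_boot: int = 1000,
    seed: int | None = None,
    min_n: int = 8,
) -> MismatchResult:
    """Fit the sudden-expansion model and bootstrap SSD / raggedness p-values.

    ``observed`` are relative frequencies over difference classes 0..d_max
    for a lineage of ``n`` sequences.  Lineages with n below ``min_n`` are
    refused: their mismatch distributions are too sparse to constrain the
    three parameters.  The parametric bootstrap simulates coalescent
    samples of size n under the fitted expansion (theta1 now, theta0
    before tau, infinite sites), refits each, and reports
    p = P(statistic >= observed).
    """
    observed = np.asarray(observed, dtype=float)
    if n < min_n:
        raise ValueError(f"n = {n} below the minimum of {min_n} for mismatch fitting")
    if (observed > 0).sum() < 2:
        raise ValueError("need at least two mismatch classes with mass")
    warnings: list[str] = []
    params, ssd_obs = _fit_ssd(observed, _default_starts(observed))
    tau, th0, th1 = (float(v) for v in params)
    if th1 >= 0.99 * _THETA1_MAX:
        warnings.append("theta1 estimate at the upper bound (near-infinite size)")
        logger.warning("theta1 hit its upper bound %.3g", _THETA1_MAX)
    d_max = observed.size - 1
    expected = sudden_expansion_expected(tau, th0, th1, d_max)
    hri_obs = harpending_raggedness(observed)

    p_ssd = p_hri = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        # mutational time units: locus mutation rate u = 1/2 per unit time,
        # so a haploid size of theta gives E[pair differences] = theta.
        events = [Event("size", time=tau, dest="pop", size=max(th0, 1e-6))]
        hit_ssd = hit_hri = 0
        boot_tau = np.full(n_boot, np.nan)
        for b in range(n_boot):
            tree = simulate_genealogy({"pop": n}, {"pop": max(th1, 1e-6)}, events, rng)
            muts = poisson_branch_mutations(tree, 0.5, rng)
            d = pairwise_difference_matrix(tree, muts)
            iu = np.triu_indices(n, k=1)
            counts = np.bincount(d[iu])
            freqs = counts / counts.sum()
            starts = [(tau, th0, th1)] + _default_starts(freqs)[:2]
            try:
                params_sim, ssd_sim = _fit_ssd(freqs, starts)
                boot_tau[b] = params_sim[0]
            except RuntimeError:
                ssd_sim = np.inf
            hit_ssd += ssd_sim >= ssd_obs
            hit_hri += harpending_raggedness(freqs) >= hri_obs
        p_ssd = (hit_ssd + 1) / (n_boot + 1)
        p_hri = (hit_hri + 1) / (n_boot + 1)
    else:
        boot_tau = None
    return MismatchResult(
        observed, expected, tau, th0, th1, ssd_obs, hri_obs, p_ssd, p_hri, n_boot,
        boot_tau, warnings
    )
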