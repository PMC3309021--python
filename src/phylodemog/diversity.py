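"""Haplotype-level diversity statistics and neutrality tests.

Covers haplotype diversity h, nucleotide diversity pi, Watterson's theta,
the theta -> Ne conversion for mtDNA (theta = 2*Ne*mu), Tajima's D and
Fu's F_S with coalescent-simulation P-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alignment import HaplotypeAlignment, segregating_sites
from .neutral import neutral_summaries

__all__ = [
    "DiversityStats",
    "RateParams",
    "diversity_stats",
    "ne_from_theta",
    "tajimas_d",
    "fu_fs",
    "ewens_k_pmf",
    "mean_pairwise_differences",
    "TajimaResult",
    "FuFsResult",
]


@dataclass(frozen=True)
class RateParams:
    """Substitution rate (subs/site/Myr), generation time (years), sites."""

    subs_rate: float = 0.036
    generation_time: float = 2.5
    L: int = 1248

    def __post_init__(self):
        if self.subs_rate <= 0 or self.generation_time <= 0 or self.L <= 0:
            raise ValueError("rate parameters must be strictly positive")

    @property
    def mu_per_site_per_generation(self) -> float:
        return self.subs_rate * 1e-6 * self.generation_time

    @property
    def u_per_sequence_per_year(self) -> float:
        return self.subs_rate * 1e-6 * self.L


@dataclass(frozen=True)
class DiversityStats:
    n: int
    k: int
    h: float
    pi: float  # per site
    theta_w: float  # per site
    S: int


@dataclass(frozen=True)
class TajimaResult:
    d: float
    p_low: float  # Pr(D_sim <= D_obs), one-sided low tail
    p_two: float  # doubled smaller tail (two-sided convention)
    n_sims: int


@dataclass(frozen=True)
class FuFsResult:
    fs: float
    s_prime: float  # Pr(K >= k_obs | theta_pi, n) from the Ewens distribution
    p_value: float  # Pr(F_S,sim <= F_S,obs)
    n_sims: int

    @property
    def significant_arlequin(self) -> bool:
        """Arlequin convention: F_S called significant at P < 0.02."""
        return self.p_value < 0.02

    @property
    def significant_nominal(self) -> bool:
        return self.p_value < 0.05


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def mean_pairwise_differences(aln: HaplotypeAlignment) -> float:
    """Mean pairwise differences per sequence over all individual pairs."""
    n = aln.n
    if n < 2:
        raise ValueError("need at least two sequences")
    c = aln.haplotype_counts().astype(float)
    d = aln.pairwise_differences()
    total = 0.5 * float(c @ d @ c)  # within-haplotype pairs contribute 0
    return total / (n * (n - 1) / 2.0)


def diversity_stats(aln: HaplotypeAlignment) -> DiversityStats:
    n = aln.n
    if n < 2:
        raise ValueError("need at least two sequences")
    p = aln.frequencies()
    h = n / (n - 1) * (1.0 - float((p**2).sum()))
    s = segregating_sites(aln)
    pi_seq = mean_pairwise_differences(aln)
    theta_w = s / (harmonic(n) * aln.L)
    return DiversityStats(n=n, k=aln.k, h=h, pi=pi_seq / aln.L, theta_w=theta_w, S=s)


def ne_from_theta(theta_w: float, rates: RateParams) -> int:
    """Haploid effective size from per-site theta via theta = 2*Ne*mu.

    mu is per site per generation; the result is rounded half-up to an
    integer for reporting.
    """
    if theta_w < 0:
        raise ValueError("theta must be non-negative")
    ne = theta_w / (2.0 * rates.mu_per_site_per_generation)
    return int(math.floor(ne + 0.5))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_d_from_summaries(s: float, pi_seq: float, n: int, const: dict) -> float:
    if s == 0:
        return math.nan
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    return (pi_seq - s / const["a1"]) / math.sqrt(var)


def tajimas_d(
    aln: HaplotypeAlignment,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> TajimaResult:
    """Tajima's D with a simulation P-value.

    The null is the constant-size neutral coalescent conditioned on the
    sample size with theta fixed at the Watterson estimate; the reported
    one-sided P is the fraction of simulated D at or below the observed
    value (expansion pushes D negative), and p_two doubles the smaller tail.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    s_obs = segregating_sites(aln)
    if s_obs == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    const = tajima_constants(n)
    d_obs = _tajima_d_from_summaries(s_obs, mean_pairwise_differences(aln), n, const)

    theta_hat = s_obs / const["a1"]  # per sequence
    s_sim, pi_sim, _ = neutral_summaries(n, theta_hat, n_sims, rng)
    d_sim = np.array(
        [_tajima_d_from_summaries(s, p, n, const) for s, p in zip(s_sim, pi_sim)]
    )
    d_sim = d_sim[~np.isnan(d_sim)]
    m = len(d_sim)
    p_low = ((d_sim <= d_obs).sum() + 1) / (m + 1)
    p_high = ((d_sim >= d_obs).sum() + 1) / (m + 1)
    return TajimaResult(
        d=d_obs, p_low=float(p_low), p_two=float(min(1.0, 2 * min(p_low, p_high))),
        n_sims=n_sims,
    )


# ---------------------------------------------------------------------------
# Fu's F_S via the Ewens sampling distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    The row is built in exact integer arithmetic (Python bigints, so no
    overflow at any n) and converted to logs only at the end; math.log
    handles arbitrary-precision integers, which covers the n > 170 range
    where floats would overflow.
    """
    row = [1]  # n = 0
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k < m else 0)
    return tuple(-math.inf if v == 0 else math.log(v) for v in row)


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        out = np.zeros(n + 1)
        out[1] = 1.0
        return out
    logs = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logp = logs + k * math.log(theta) - log_rising
    logp[0] = -math.inf
    p = np.exp(logp - logp[np.isfinite(logp)].max())
    return p / p.sum()


def _ewens_tail(n: int, theta: float, k_obs: int) -> float:
    """S' = P(K >= k_obs | theta, n)."""
    p = ewens_k_pmf(n, theta)
    return float(p[k_obs:].sum())


def fs_statistic(n: int, theta_pi: float, k_obs: int) -> float:
    """F_S = ln(S'/(1-S')) with S' = P(K >= k_obs) under Ewens(theta_pi, n)."""
    if k_obs < 1:
        raise ValueError("need at least one haplotype")
    sp = _ewens_tail(n, theta_pi, k_obs)
    if sp >= 1.0:
        return math.inf  # S' = 1: log-odds diverges (e.g. k_obs = 1, theta -> 0)
    if sp <= 0.0:
        return -math.inf
    return math.log(sp / (1.0 - sp))


def fu_fs(
    aln: HaplotypeAlignment,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> FuFsResult:
    """Fu's F_S with a simulation P-value.

    theta is estimated by the mean pairwise difference per sequence (the
    usual plug-in for this test); the null distribution of F_S comes from
    constant-size neutral coalescent samples at that theta, each evaluated
    with its own pairwise-difference estimate, and P is the fraction of
    simulated values at or below the observed statistic.
    """
    n = aln.n
    if n < 3:
        raise ValueError("Fu's F_S needs n >= 3")
    theta_pi = mean_pairwise_differences(aln)
    fs_obs = fs_statistic(n, theta_pi, aln.k)
    sp_obs = _ewens_tail(n, theta_pi, aln.k)

    _, pi_sim, k_sim = neutral_summaries(n, theta_pi, n_sims, rng)
    fs_sim = np.array([fs_statistic(n, p, k) for p, k in zip(pi_sim, k_sim)])
    # +inf replicates (single haplotype, zero diversity) sit above any finite
    # observed value and never count toward the low tail
    n_le = int((fs_sim <= fs_obs).sum())
    p = (n_le + 1) / (len(fs_sim) + 1)
    return FuFsResult(fs=fs_obs, s_prime=sp_obs, p_value=float(p), n_sims=n_sims)
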