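"""Mismatch distributions and the sudden-expansion demographic model.

The observed mismatch distribution is the histogram of pairwise nucleotide
differences over all unordered sequence pairs. Under a sudden expansion
(theta0 -> theta1 at tau mutational units before present, infinite sites),
the probability that a random pair differs at j sites is

    F_j(tau, theta0, theta1) =
        Feq_j(theta1)
        + exp(-tau (theta1 + 1)/theta1)
          * sum_{i<=j} tau^(j-i)/(j-i)! * (Feq_i(theta0) - Feq_i(theta1))

with the equilibrium geometric law Feq_j(theta) = theta^j/(1+theta)^(j+1).
Parameters are fitted by minimizing the sum of squared deviations (SSD)
between observed and expected frequencies, and goodness of fit is assessed
with SSD and Harpending's raggedness index via a parametric bootstrap.
Expansion time in years follows tau = 2*u*t with u the per-sequence
mutation rate per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .alignment import HaplotypeAlignment, collapse_haplotypes
from .coalescent import MutationModel, overlay_mutations, simulate_piecewise_genealogy
from .diversity import RateParams

__all__ = [
    "MismatchDistribution",
    "MismatchFit",
    "mismatch_distribution",
    "expected_mismatch",
    "raggedness",
    "fit_sudden_expansion",
    "bootstrap_fit_pvalues",
    "expansion_time",
]


@dataclass(frozen=True)
class MismatchDistribution:
    counts: np.ndarray  # index = number of pairwise differences, 0..d_max
    total_pairs: int

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.total_pairs

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.counts)) @ self.freqs)


@dataclass(frozen=True)
class MismatchFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: Optional[float] = None
    p_rag: Optional[float] = None
    n_boot: int = 0


def mismatch_distribution(aln: HaplotypeAlignment) -> MismatchDistribution:
    """Histogram of pairwise differences over all individual pairs."""
    n = aln.n
    if n < 2:
        raise ValueError("need at least two sequences")
    c = aln.haplotype_counts()
    d = aln.pairwise_differences()
    d_max = int(d.max()) if aln.k > 1 else 0
    counts = np.zeros(d_max + 1, dtype=np.int64)
    # within-haplotype pairs are identical
    counts[0] += int((c * (c - 1) // 2).sum())
    for i in range(aln.k):
        for j in range(i + 1, aln.k):
            counts[d[i, j]] += int(c[i] * c[j])
    return MismatchDistribution(counts=counts, total_pairs=n * (n - 1) // 2)


def _equilibrium(theta: float, j_max: int) -> np.ndarray:
    """Geometric equilibrium mismatch law, stable for large theta."""
    j = np.arange(j_max + 1)
    if theta <= 0:
        out = np.zeros(j_max + 1)
        out[0] = 1.0
        return out
    r = theta / (1.0 + theta)
    return r**j / (1.0 + theta)


def expected_mismatch(
    j_max: int, tau: float, theta0: float, theta1: float
) -> np.ndarray:
    """Sudden-expansion probabilities F_j for j = 0..j_max."""
    f1 = _equilibrium(theta1, j_max)
    f0 = _equilibrium(theta0, j_max)
    if tau == 0:
        return f0
    j = np.arange(j_max + 1)
    log_pois = j * math.log(tau) - gammaln(j + 1) - tau
    pois = np.exp(log_pois)
    conv = np.convolve(pois, f0 - f1)[: j_max + 1]
    decay = math.exp(-tau / theta1) if theta1 > 0 else 0.0
    return f1 + decay * conv


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness index with the trailing zero-class convention.

    r = sum_{j=1}^{d+1} (x_j - x_{j-1})^2 with x_{d+1} = 0.
    """
    x = np.concatenate([np.asarray(freqs, dtype=float), [0.0]])
    return float(((x[1:] - x[:-1]) ** 2).sum())


def _ssd(obs: np.ndarray, tau: float, th0: float, th1: float) -> float:
    exp = expected_mismatch(len(obs) - 1, tau, th0, th1)
    return float(((obs - exp) ** 2).sum())


def fit_sudden_expansion(
    mm: MismatchDistribution,
    tau_step: float = 0.05,
    n_theta0: int = 11,
    n_theta1: int = 8,
    theta1_cap_factor: float = 10.0,
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed distribution.

    A coarse grid (tau in [0, 2*d_max] at ``tau_step``; theta0 from 0 up to
    the observed mean; theta1 log-spaced up to ``theta1_cap_factor * d_max``,
    a proxy for an effectively infinite post-expansion size) is scanned and
    the best cell refined by Nelder-Mead. Grid ties resolve to the smallest
    tau. Raggedness is a property of the observed distribution and is
    reported alongside the fit.
    """
    obs = mm.freqs
    d_max = max(mm.d_max, 1)
    if mm.counts[1:].sum() == 0:
        raise ValueError("all pairs identical: nothing to fit")
    th1_cap = theta1_cap_factor * d_max
    # cap the grid at 800 tau points so extreme distributions stay tractable
    step = max(tau_step, 2.0 * d_max / 800)
    taus = np.arange(0.0, 2.0 * d_max + step / 2, step)
    th0s = np.linspace(0.0, mm.mean, n_theta0)
    th1s = np.concatenate([np.geomspace(max(mm.mean, 1.0), th1_cap, n_theta1)])

    j = np.arange(d_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_tau = np.where(taus > 0, np.log(taus), -np.inf)
        pois = np.exp(
            np.nan_to_num(log_tau[:, None] * j[None, :], nan=-np.inf)
            - gammaln(j + 1)[None, :]
            - taus[:, None]
        )
    pois[taus == 0] = 0.0
    pois[taus == 0, 0] = 1.0

    best = (math.inf, 0.0, 0.0, 0.0)
    for th1 in th1s:
        f1 = _equilibrium(th1, d_max)
        decay = np.exp(-taus / th1)
        for th0 in th0s:
            if th0 > th1:
                continue
            f0 = _equilibrium(th0, d_max)
            delta = f0 - f1
            toep = np.zeros((d_max + 1, d_max + 1))
            for i in range(d_max + 1):
                toep[i, i:] = delta[: d_max + 1 - i]
            conv = pois @ toep  # (n_tau, d_max+1)
            fexp = f1[None, :] + decay[:, None] * conv
            fexp[taus == 0] = f0[None, :]
            ssd = ((fexp - obs[None, :]) ** 2).sum(axis=1)
            i_best = int(np.argmin(ssd))  # first index = smallest tau on ties
            if ssd[i_best] < best[0] - 1e-15:
                best = (float(ssd[i_best]), float(taus[i_best]), float(th0), float(th1))

    def objective(params: np.ndarray) -> float:
        tau, th0, th1 = params
        if tau < 0 or th0 < 0 or th1 < th0 or th1 > th1_cap or tau > 4 * d_max:
            return 1.0 + float(np.abs(params).sum())
        return _ssd(obs, tau, th0, max(th1, 1e-9))

    res = optimize.minimize(
        objective,
        x0=np.array(best[1:]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    if res.fun <= best[0]:
        ssd_opt, (tau, th0, th1) = float(res.fun), [float(v) for v in res.x]
    else:  # keep the grid optimum if polishing failed to improve
        ssd_opt, tau, th0, th1 = best
    return MismatchFit(
        tau=max(tau, 0.0),
        theta0=max(th0, 0.0),
        theta1=max(th1, th0, 0.0),
        ssd=ssd_opt,
        raggedness=raggedness(obs),
    )


def simulate_expansion_alignment(
    n: int,
    L: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator | int | None = None,
    mutation: MutationModel | None = None,
    mu_seq: float = 1e-3,
) -> HaplotypeAlignment:
    """Draw one sample of n sequences under the fitted sudden expansion.

    The mutational-unit parameters are mapped onto a single population with
    a stepwise size change (theta = 2*Ne*mu_seq per sequence, change at
    tau/(2*mu_seq) generations) and finite-sites mutations at L sites.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ne1 = max(theta1, 1e-4) / (2.0 * mu_seq)
    ne0 = max(theta0, 1e-4) / (2.0 * mu_seq)
    t_change = tau / (2.0 * mu_seq)
    gen = simulate_piecewise_genealogy(n, [(0.0, ne1), (t_change, ne0)], rng)
    mut = mutation or MutationModel(rate=mu_seq / L)
    seqs = overlay_mutations(gen, mut, L, rng)
    return collapse_haplotypes(seqs.items(), {k: "pop" for k in seqs})


def bootstrap_fit_pvalues(
    aln: HaplotypeAlignment,
    fit: MismatchFit,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    tau_step: float = 0.25,
) -> MismatchFit:
    """Parametric-bootstrap P-values for SSD and raggedness.

    ``n_boot`` coalescent samples (same n and L as the data) are simulated
    under the fitted expansion demography; each is refitted and P is the
    fraction of simulated statistics at or above the observed one, so small
    P rejects the sudden-expansion null.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_ssd = n_rag = 0
    for _ in range(n_boot):
        sim = simulate_expansion_alignment(
            aln.n, aln.L, fit.tau, fit.theta0, fit.theta1, rng
        )
        mm_sim = mismatch_distribution(sim)
        if mm_sim.counts[1:].sum() == 0:
            # degenerate monomorphic draw: SSD of a refit is 0
            if fit.ssd <= 0:
                n_ssd += 1
            if raggedness(mm_sim.freqs) >= fit.raggedness:
                n_rag += 1
            continue
        fit_sim = fit_sudden_expansion(mm_sim, tau_step=tau_step)
        if fit_sim.ssd >= fit.ssd:
            n_ssd += 1
        if fit_sim.raggedness >= fit.raggedness:
            n_rag += 1
    return replace(
        fit,
        p_ssd=n_ssd / n_boot,
        p_rag=n_rag / n_boot,
        n_boot=n_boot,
    )


def expansion_time(tau: float, rates: RateParams) -> tuple[float, float]:
    """Convert tau to an expansion time: returns (years, Mya rounded to 3 dp).

    tau = 2*u*t with u the mutation rate per sequence per year
    (subs/site/Myr * 1e-6 * L), so the conversion needs no generation time.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    u = rates.u_per_sequence_per_year
    years = tau / (2.0 * u)
    return years, round(years / 1e6, 3)
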