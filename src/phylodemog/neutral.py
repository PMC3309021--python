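"""Constant-size neutral coalescent samples under the infinite-sites model.

Used to build null distributions for Tajima's D and Fu's F_S: genealogies are
drawn from the standard Kingman coalescent conditioned on the sample size,
mutations are Poisson on branches with rate theta/2 per lineage per unit of
coalescent time (N generations, haploid scaling), and the summaries needed by
the tests (segregating sites, mean pairwise differences, number of distinct
haplotypes) are read off the mutated branches directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["neutral_summaries"]


def _one_replicate(n: int, theta: float, rng: np.random.Generator):
    lineages = [1 << i for i in range(n)]  # bitmask of subtended tips
    mutated: list[tuple[int, int]] = []  # (tip mask, number of mutations)
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        if theta > 0:
            hits = rng.poisson(t * theta / 2.0, size=k)
            for mask, m in zip(lineages, hits):
                if m:
                    mutated.append((mask, int(m)))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    s = sum(m for _, m in mutated)
    npairs = n * (n - 1) / 2.0
    pi = sum(m * bin(mask).count("1") * (n - bin(mask).count("1")) for mask, m in mutated)
    pi /= npairs
    # haplotype classes: tips identical iff separated by no mutated branch
    if mutated:
        sigs = {
            tuple((mask >> tip) & 1 for mask, _ in mutated) for tip in range(n)
        }
        k_hap = len(sigs)
    else:
        k_hap = 1
    return s, pi, k_hap


def neutral_summaries(
    n: int,
    theta: float,
    n_reps: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n_reps`` neutral samples; returns (S, pi_seq, K) arrays.

    ``theta`` is the population mutation parameter per sequence (2*Ne*mu_seq);
    ``pi_seq`` is the mean number of pairwise differences per sequence.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out_s = np.empty(n_reps, dtype=int)
    out_pi = np.empty(n_reps)
    out_k = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        out_s[r], out_pi[r], out_k[r] = _one_replicate(n, theta, rng)
    return out_s, out_pi, out_k
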