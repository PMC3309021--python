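"""Hierarchical analysis of molecular variance (AMOVA).

Three-level decomposition of pairwise-difference distances — among regional
groups, among populations within groups, and within populations — with the
fixation indices Phi_CT, Phi_SC, Phi_ST and permutation P-values. The
distance between two sequences is the raw count of differing sites, and
negative variance components are reported as-is (flagged, not truncated) so
the percentages stay additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment, SampleTable

__all__ = ["AmovaResult", "amova", "compare_groupings"]


@dataclass(frozen=True)
class AmovaResult:
    grouping_label: str
    var_among_groups: float
    var_among_pops_within: float
    var_within_pops: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    n_permutations: int
    degenerate: bool = False
    negative_components: bool = False

    @property
    def total_variance(self) -> float:
        return self.var_among_groups + self.var_among_pops_within + self.var_within_pops

    @property
    def pct_variation(self) -> tuple[float, float, float]:
        tot = self.total_variance
        if tot == 0:
            return (float("nan"),) * 3
        return (
            100.0 * self.var_among_groups / tot,
            100.0 * self.var_among_pops_within / tot,
            100.0 * self.var_within_pops / tot,
        )

    def as_row(self) -> dict:
        pct = self.pct_variation
        return {
            "grouping": self.grouping_label,
            "pct_among_groups": pct[0],
            "pct_among_pops_within_groups": pct[1],
            "pct_within_pops": pct[2],
            "phi_ct": self.phi_ct,
            "phi_sc": self.phi_sc,
            "phi_st": self.phi_st,
            "p_ct": self.p_ct,
            "p_sc": self.p_sc,
            "p_st": self.p_st,
        }


def _components(
    d_blocks: np.ndarray,  # (P, P) total distance sums between population pairs
    pop_sizes: np.ndarray,  # (P,)
    group_of_pop: np.ndarray,  # (P,) group index per population
    n_groups: int,
) -> tuple[float, float, float]:
    """Variance components (sigma_a, sigma_b, sigma_c) from block sums."""
    n_tot = int(pop_sizes.sum())
    n_pops = len(pop_sizes)
    ss_pop = np.diag(d_blocks) / (2.0 * pop_sizes)
    ssd_wp = float(ss_pop.sum())

    group_sizes = np.zeros(n_groups)
    ss_group = np.zeros(n_groups)
    sum_np2_over_ng = 0.0
    for g in range(n_groups):
        mask = group_of_pop == g
        group_sizes[g] = pop_sizes[mask].sum()
        ss_group[g] = d_blocks[np.ix_(mask, mask)].sum() / (2.0 * group_sizes[g])
        sum_np2_over_ng += (pop_sizes[mask] ** 2).sum() / group_sizes[g]
    ss_total = d_blocks.sum() / (2.0 * n_tot)
    ssd_ap = float(ss_group.sum() - ssd_wp)
    ssd_ag = float(ss_total - ss_group.sum())

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_tot - n_pops
    ms_wp = ssd_wp / df_wp if df_wp else 0.0
    ms_ap = ssd_ap / df_ap if df_ap else 0.0
    ms_ag = ssd_ag / df_ag if df_ag else 0.0

    n1 = (n_tot - sum_np2_over_ng) / df_ap if df_ap else 1.0
    n2 = (sum_np2_over_ng - (pop_sizes**2).sum() / n_tot) / df_ag if df_ag else 1.0
    n3 = (n_tot - (group_sizes**2).sum() / n_tot) / df_ag if df_ag else 1.0

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if n1 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 else 0.0
    return sigma_a, sigma_b, sigma_c


def _block_sums(dist: np.ndarray, pop_idx: np.ndarray, n_pops: int) -> np.ndarray:
    """(P, P) matrix of summed inter-individual distances between populations."""
    blocks = np.zeros((n_pops, n_pops))
    members = [np.flatnonzero(pop_idx == p) for p in range(n_pops)]
    for p in range(n_pops):
        for q in range(p, n_pops):
            s = dist[np.ix_(members[p], members[q])].sum()
            blocks[p, q] = s
            blocks[q, p] = s
    return blocks


def _phi(sigma: tuple[float, float, float]) -> tuple[float, float, float]:
    a, b, c = sigma
    tot = a + b + c
    phi_ct = a / tot if tot else float("nan")
    phi_sc = b / (b + c) if (b + c) else float("nan")
    phi_st = (a + b) / tot if tot else float("nan")
    return phi_ct, phi_sc, phi_st


def amova(
    aln: HaplotypeAlignment,
    samples: SampleTable,
    grouping: Mapping[str, str] | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    grouping_label: str | None = None,
) -> AmovaResult:
    """Three-level AMOVA with permutation tests.

    ``grouping`` maps population -> group and defaults to the sample table's
    group column. Permutation schemes: Phi_CT permutes whole populations
    among groups, Phi_SC permutes individuals among populations within their
    group, Phi_ST permutes individuals among all populations. P-values use
    (count{perm >= obs} + 1)/(n_perm + 1).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    group_of = dict(grouping) if grouping is not None else samples.group_of_population()
    label = grouping_label or "/".join(
        sorted({str(g) for g in group_of.values()})
    )

    hap_idx, ind_pops = aln.expand_individuals()
    pops = sorted(set(ind_pops))
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    missing = [p for p in pops if p not in group_of]
    if missing:
        raise ValueError(f"grouping missing populations: {missing}")
    groups = sorted(set(group_of[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("Phi_CT needs at least two groups")
    pop_index = {p: i for i, p in enumerate(pops)}
    group_index = {g: i for i, g in enumerate(groups)}
    pop_idx = np.array([pop_index[p] for p in ind_pops])
    group_of_pop = np.array([group_index[group_of[p]] for p in pops])
    pop_sizes = np.bincount(pop_idx, minlength=len(pops)).astype(float)

    hap_d = aln.pairwise_differences().astype(float)
    dist = hap_d[np.ix_(hap_idx, hap_idx)]
    if not dist.any():
        return AmovaResult(
            grouping_label=label,
            var_among_groups=0.0, var_among_pops_within=0.0, var_within_pops=0.0,
            phi_ct=float("nan"), phi_sc=float("nan"), phi_st=float("nan"),
            p_ct=float("nan"), p_sc=float("nan"), p_st=float("nan"),
            n_permutations=0, degenerate=True,
        )

    blocks = _block_sums(dist, pop_idx, len(pops))
    sigma = _components(blocks, pop_sizes, group_of_pop, len(groups))
    phi_ct, phi_sc, phi_st = _phi(sigma)

    # --- permutations ---
    ge_ct = ge_sc = ge_st = 0
    ind_group = np.array([group_index[group_of[p]] for p in ind_pops])
    for _ in range(n_perm):
        # CT: shuffle population units among groups (group sizes in #pops kept)
        perm_gop = rng.permutation(group_of_pop)
        s = _components(blocks, pop_sizes, perm_gop, len(groups))
        if _phi(s)[0] >= phi_ct - 1e-12:
            ge_ct += 1
        # SC: shuffle individuals among populations within their group
        perm_pop = pop_idx.copy()
        for g in range(len(groups)):
            members = np.flatnonzero(ind_group == g)
            perm_pop[members] = pop_idx[members][rng.permutation(len(members))]
        b = _block_sums(dist, perm_pop, len(pops))
        s = _components(b, pop_sizes, group_of_pop, len(groups))
        if _phi(s)[1] >= phi_sc - 1e-12:
            ge_sc += 1
        # ST: shuffle individuals among all populations
        perm_pop = pop_idx[rng.permutation(len(pop_idx))]
        b = _block_sums(dist, perm_pop, len(pops))
        s = _components(b, pop_sizes, group_of_pop, len(groups))
        if _phi(s)[2] >= phi_st - 1e-12:
            ge_st += 1

    return AmovaResult(
        grouping_label=label,
        var_among_groups=sigma[0],
        var_among_pops_within=sigma[1],
        var_within_pops=sigma[2],
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_ct=(ge_ct + 1) / (n_perm + 1),
        p_sc=(ge_sc + 1) / (n_perm + 1),
        p_st=(ge_st + 1) / (n_perm + 1),
        n_permutations=n_perm,
        negative_components=any(v < 0 for v in sigma),
    )


def compare_groupings(
    aln: HaplotypeAlignment,
    samples: SampleTable,
    groupings: Sequence[tuple[str, Mapping[str, str]]],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """AMOVA for several candidate groupings, ranked by Phi_CT (descending).

    The arg-max grouping is the inferred most probable geographical
    subdivision (flagged in the ``best`` column).
    """
    if len(groupings) < 2:
        raise ValueError("need at least two groupings to compare")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for lab, grouping in groupings:
        res = amova(
            aln, samples, grouping, n_perm=n_perm, rng=rng, grouping_label=lab
        )
        rows.append(res.as_row())
    df = pd.DataFrame(rows).sort_values("phi_ct", ascending=False, kind="stable")
    df = df.reset_index(drop=True)
    df["best"] = False
    df.loc[0, "best"] = True
    return df
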