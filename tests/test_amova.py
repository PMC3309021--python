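import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from phylodemog.alignment import SampleTable, collapse_haplotypes
from phylodemog.amova import amova, compare_groupings


def _exact_decomposition(seqs, pops, groups):
    """Brute-force SSD decomposition in rational arithmetic."""
    def d(a, b):
        return sum(x != y for x, y in zip(seqs[a], seqs[b]))

    inds = [i for p in pops.values() for i in p]
    N, P, G = len(inds), len(pops), len(groups)

    def ss(members):
        return Fraction(
            sum(d(a, b) for a, b in itertools.combinations(members, 2)), len(members)
        )

    ss_total = ss(inds)
    ss_pops = sum(ss(m) for m in pops.values())
    ss_groups = sum(
        ss([i for p in groups[g] for i in pops[p]]) for g in groups
    )
    ms_wp = ss_pops / (N - P)
    ms_ap = (ss_groups - ss_pops) / (P - G)
    ms_ag = (ss_total - ss_groups) / (G - 1)
    sum_np2_ng = sum(
        Fraction(
            sum(len(pops[p]) ** 2 for p in groups[g]),
            sum(len(pops[p]) for p in groups[g]),
        )
        for g in groups
    )
    n1 = (N - sum_np2_ng) / (P - G)
    n2 = (sum_np2_ng - Fraction(sum(len(m) ** 2 for m in pops.values()), N)) / (G - 1)
    n3 = (
        N
        - Fraction(
            sum(sum(len(pops[p]) for p in groups[g]) ** 2 for g in groups), N
        )
    ) / (G - 1)
    sc = ms_wp
    sb = (ms_ap - sc) / n1
    sa = (ms_ag - sc - n2 * sb) / n3
    return float(sa), float(sb), float(sc)


def test_components_match_exact_decomposition(six_sequence_fixture):
    seqs, pop, aln, table = six_sequence_fixture
    res = amova(aln, table, n_perm=50, rng=0)
    sa, sb, sc = _exact_decomposition(
        seqs,
        {"p1": ["i1", "i2"], "p2": ["i3", "i4"], "p3": ["i5", "i6"]},
        {"g1": ["p1", "p2"], "g2": ["p3"]},
    )
    assert res.var_among_groups == pytest.approx(sa, abs=1e-12)
    assert res.var_among_pops_within == pytest.approx(sb, abs=1e-12)
    assert res.var_within_pops == pytest.approx(sc, abs=1e-12)
    assert sum(res.pct_variation) == pytest.approx(100.0, abs=0.01)
    assert res.phi_st == pytest.approx(1 - sc / (sa + sb + sc), abs=1e-12)


def test_all_identical_individuals_flagged_degenerate():
    seqs = {f"i{k}": "ACGT" for k in range(8)}
    pop = {f"i{k}": f"p{k % 4}" for k in range(8)}
    aln = collapse_haplotypes(seqs.items(), pop)
    table = SampleTable(
        pd.DataFrame(
            {
                "individual": list(pop),
                "population": list(pop.values()),
                "group": ["g1", "g2"] * 4,
            }
        )
    )
    # population->group must be consistent
    table = SampleTable(
        pd.DataFrame(
            {
                "individual": list(pop),
                "population": list(pop.values()),
                "group": ["g1" if pop[i] in ("p0", "p1") else "g2" for i in pop],
            }
        )
    )
    res = amova(aln, table, n_perm=10, rng=0)
    assert res.degenerate
    assert np.isnan(res.phi_ct)


def _private_haplotype_dataset(between_group_distance=40):
    """2 groups x 2 populations, each population fixed for a private haplotype."""
    L = 100
    base = ["A"] * L

    def seq(changes):
        s = list(base)
        for pos in changes:
            s[pos] = "T"
        return "".join(s)

    pop_seqs = {
        "p1": seq([0]),
        "p2": seq([1]),
        "p3": seq(range(10, 10 + between_group_distance)),
        "p4": seq(list(range(10, 10 + between_group_distance)) + [99]),
    }
    seqs, pop = {}, {}
    for p, s in pop_seqs.items():
        for r in range(4):
            seqs[f"{p}_{r}"] = s
            pop[f"{p}_{r}"] = p
    aln = collapse_haplotypes(seqs.items(), pop)
    table = SampleTable(
        pd.DataFrame(
            {
                "individual": list(pop),
                "population": list(pop.values()),
                "group": ["g1" if pop[i] in ("p1", "p2") else "g2" for i in pop],
            }
        )
    )
    return aln, table


def test_deep_group_structure_pushes_phi_ct_toward_one():
    aln, table = _private_haplotype_dataset()
    res = amova(aln, table, n_perm=100, rng=1)
    assert res.phi_ct > 0.9
    assert res.phi_st > res.phi_ct


def test_permutation_pvalues_reproducible_and_relabel_invariant():
    aln, table = _private_haplotype_dataset()
    r1 = amova(aln, table, n_perm=100, rng=123)
    r2 = amova(aln, table, n_perm=100, rng=123)
    assert (r1.p_ct, r1.p_sc, r1.p_st) == (r2.p_ct, r2.p_sc, r2.p_st)
    assert (r1.phi_ct, r1.phi_sc, r1.phi_st) == (r2.phi_ct, r2.phi_sc, r2.phi_st)


def test_true_grouping_outranks_scrambled(study_dataset):
    aln = study_dataset.alignment
    table = study_dataset.samples
    true_grouping = table.group_of_population()
    pops = sorted(true_grouping)
    rng = np.random.default_rng(9)
    scrambled = dict(zip(pops, rng.permutation([true_grouping[p] for p in pops])))
    merged = {p: ("DE" if g in ("D", "E") else g) for p, g in true_grouping.items()}
    df = compare_groupings(
        aln, table,
        [("true", true_grouping), ("scrambled", scrambled), ("merged_DE", merged)],
        n_perm=50, rng=7,
    )
    assert df.loc[0, "grouping"] == "true"
    assert bool(df.loc[0, "best"])
    phi = dict(zip(df["grouping"], df["phi_ct"]))
    # merging two deeply split lineages strictly lowers Phi_CT
    assert phi["merged_DE"] < phi["true"]


def test_identical_groupings_give_identical_phi(six_sequence_fixture):
    _, _, aln, table = six_sequence_fixture
    g = {"p1": "g1", "p2": "g1", "p3": "g2"}
    df = compare_groupings(aln, table, [("a", g), ("b", dict(g))], n_perm=30, rng=0)
    assert df["phi_ct"].nunique() == 1


def test_single_population_is_a_structure_error():
    seqs = {"a": "AAAA", "b": "AATA", "c": "ATAA"}
    pop = {k: "p1" for k in seqs}
    aln = collapse_haplotypes(seqs.items(), pop)
    table = SampleTable(
        pd.DataFrame({"individual": list(pop), "population": list(pop.values())})
    )
    with pytest.raises(ValueError):
        amova(aln, table, n_perm=10, rng=0)
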