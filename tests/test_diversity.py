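import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylodemog.alignment import collapse_haplotypes
from phylodemog.diversity import (
    RateParams,
    diversity_stats,
    ewens_k_pmf,
    fs_statistic,
    fu_fs,
    mean_pairwise_differences,
    ne_from_theta,
    tajima_constants,
    tajimas_d,
)
from phylodemog.mismatch import simulate_expansion_alignment


def _aln(seqs):
    pop = {k: "p" for k in seqs}
    return collapse_haplotypes(seqs.items(), pop)


def test_identical_pair_has_zero_diversity():
    aln = _aln({"a": "ACGT" * 25, "b": "ACGT" * 25})
    st_ = diversity_stats(aln)
    assert st_.h == 0.0
    assert st_.pi == 0.0
    assert st_.theta_w == 0.0


def test_watterson_theta_hand_value():
    # n=4, S=3, L=100: theta = 3 / (1.8333 * 100)
    seqs = {
        "a": "A" * 100,
        "b": "T" + "A" * 99,
        "c": "TT" + "A" * 98,
        "d": "TTT" + "A" * 97,
    }
    st_ = diversity_stats(_aln(seqs))
    assert st_.S == 3
    assert st_.theta_w == pytest.approx(3 / ((1 + 1 / 2 + 1 / 3) * 100), rel=1e-9)


def test_haplotype_diversity_matches_nei_formula():
    seqs = {"a": "AA", "b": "AA", "c": "AT", "d": "TT"}
    st_ = diversity_stats(_aln(seqs))
    p = np.array([2, 1, 1]) / 4
    assert st_.h == pytest.approx(4 / 3 * (1 - (p**2).sum()))


@pytest.mark.parametrize(
    "theta,expected",
    [(0.01361, 75611), (0.00582, 32333), (0.00268, 14889), (0.00503, 27944), (0.0, 0)],
)
def test_ne_conversion_reproduces_reported_values(theta, expected):
    assert ne_from_theta(theta, RateParams(0.036, 2.5, 1248)) == expected


def test_ne_conversion_scaling_properties():
    rates = RateParams(0.036, 2.5, 1248)
    half_gen = RateParams(0.036, 5.0, 1248)
    assert ne_from_theta(0.02, rates) == pytest.approx(2 * ne_from_theta(0.01, rates), abs=1)
    assert ne_from_theta(0.01, half_gen) == pytest.approx(
        ne_from_theta(0.01, rates) / 2, abs=1
    )


def test_tajimas_d_matches_textbook_formula():
    """Independent evaluation of the 1989 constants on a small alignment."""
    seqs = {
        f"s{i}": seq
        for i, seq in enumerate(
            [
                "AAAAA" + "C" * 15,
                "TAAAA" + "C" * 15,
                "TTAAA" + "C" * 15,
                "TTTAA" + "C" * 15,
                "TTTTA" + "C" * 15,
                "AAAAA" + "C" * 15,
                "AAAAT" + "C" * 15,
                "AAAAT" + "C" * 15,
                "TAAAA" + "C" * 15,
                "AAAAA" + "C" * 15,
            ]
        )
    }
    aln = _aln(seqs)
    n, s = 10, 5
    assert aln.n == n
    assert diversity_stats(aln).S == s
    # oracle: direct textbook constants
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    pi = mean_pairwise_differences(aln)
    expected = (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))
    got = tajimas_d(aln, n_sims=50, rng=0)
    assert got.d == pytest.approx(expected, rel=1e-12)
    const = tajima_constants(n)
    for key, val in zip("a1 a2 b1 b2 c1 c2 e1 e2".split(), (a1, a2, b1, b2, c1, c2, e1, e2)):
        assert const[key] == pytest.approx(val, rel=1e-12)


def test_expansion_pushes_d_and_fs_negative():
    aln = simulate_expansion_alignment(
        40, 1248, 6.0, 0.5, 80.0, rng=np.random.default_rng(7)
    )
    assert tajimas_d(aln, n_sims=200, rng=1).d < 0
    fs = fu_fs(aln, n_sims=200, rng=2)
    assert fs.fs < 0
    assert fs.p_value < 0.05


def test_divergent_sublineage_mixture_elevates_pi():
    """Two deeply divergent sub-lineages mixed in one sample raise pi."""
    single = simulate_expansion_alignment(
        20, 1248, 0.0, 2.0, 2.0, rng=np.random.default_rng(3)
    )
    # mimic deep divergence: flip 20 fixed sites in half the individuals
    hap_idx, _ = single.expand_individuals()
    strings = [single.sequence_strings()[i] for i in hap_idx]
    seqs = {}
    for i, s in enumerate(strings):
        if i < 10:
            seqs[f"a{i}"] = s
        else:
            seqs[f"b{i}"] = "".join(
                ("T" if c == "A" else "A") if j < 20 else c for j, c in enumerate(s)
            )
    mixed = _aln(seqs)
    assert diversity_stats(mixed).pi > diversity_stats(single).pi


def test_ewens_pmf_normalizes_on_grid():
    for n in (2, 5, 10, 20):
        for theta in (0.1, 1.0, 5.0, 10.0):
            assert ewens_k_pmf(n, theta).sum() == pytest.approx(1.0, abs=1e-12)


def test_ewens_tail_matches_exact_rational_arithmetic():
    def stirling(n, k, memo={}):
        if (n, k) in memo:
            return memo[(n, k)]
        if n == 0 and k == 0:
            return 1
        if n == 0 or k == 0:
            return 0
        v = stirling(n - 1, k - 1) + (n - 1) * stirling(n - 1, k)
        memo[(n, k)] = v
        return v

    for n in range(3, 9):
        for theta in (Fraction(1, 2), Fraction(2), Fraction(5)):
            rising = 1
            for i in range(n):
                rising *= theta + i
            exact = [
                Fraction(stirling(n, k)) * theta**k / rising for k in range(n + 1)
            ]
            assert sum(exact) == 1
            pmf = ewens_k_pmf(n, float(theta))
            for k in range(n + 1):
                assert pmf[k] == pytest.approx(float(exact[k]), abs=1e-12)
            for k_obs in range(1, n + 1):
                sp_exact = float(sum(exact[k_obs:]))
                if 0 < sp_exact < 1:
                    assert fs_statistic(n, float(theta), k_obs) == pytest.approx(
                        math.log(sp_exact / (1 - sp_exact)), abs=1e-9
                    )


def test_fs_infinite_sentinel_when_tail_saturates():
    assert fs_statistic(5, 0.0, 1) == math.inf


def test_sample_size_guards():
    aln = _aln({"a": "ACGT"})
    with pytest.raises(ValueError):
        diversity_stats(aln)
    pair = _aln({"a": "AAAA", "b": "AAAT"})
    with pytest.raises(ValueError):
        tajimas_d(pair)
    mono = _aln({c: "AAAA" for c in "abcde"})
    with pytest.raises(ValueError):
        tajimas_d(mono)


@given(st.integers(min_value=2, max_value=15), st.floats(0.1, 8.0))
def test_ewens_pmf_is_a_distribution(n, theta):
    p = ewens_k_pmf(n, theta)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
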