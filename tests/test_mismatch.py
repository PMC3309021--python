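import numpy as np
import pytest

from phylodemog.alignment import collapse_haplotypes
from phylodemog.diversity import RateParams
from phylodemog.mismatch import (
    MismatchDistribution,
    bootstrap_fit_pvalues,
    expansion_time,
    expected_mismatch,
    fit_sudden_expansion,
    mismatch_distribution,
    raggedness,
    simulate_expansion_alignment,
)


def _aln(seqs):
    return collapse_haplotypes(seqs.items(), {k: "p" for k in seqs})


def test_identical_sequences_put_all_mass_at_zero():
    mm = mismatch_distribution(_aln({c: "ACGT" for c in "abcd"}))
    assert mm.counts.tolist() == [6]
    assert mm.freqs[0] == 1.0


def test_two_haplotypes_hand_enumeration():
    # counts 2 and 2, differing at 5 sites: 2 within-pairs at 0, 4 cross at 5
    seqs = {"a": "AAAAA", "b": "AAAAA", "c": "TTTTT", "d": "TTTTT"}
    mm = mismatch_distribution(_aln(seqs))
    assert mm.counts[0] == 2
    assert mm.counts[5] == 4
    assert mm.counts.sum() == 6  # C(4,2)


def test_counts_sum_to_all_pairs(expansion_aln):
    mm = mismatch_distribution(expansion_aln)
    n = expansion_aln.n
    assert mm.counts.sum() == n * (n - 1) // 2
    assert mm.freqs.sum() == pytest.approx(1.0)


def test_raggedness_hand_evaluation():
    assert raggedness(np.array([0.2, 0.5, 0.3])) == pytest.approx(0.22)


def test_expected_mismatch_limits():
    # tau=0 collapses to the pre-expansion equilibrium law
    f = expected_mismatch(10, 0.0, 1.0, 50.0)
    geo = np.array([1.0**j / 2.0 ** (j + 1) for j in range(11)])
    assert np.allclose(f, geo)
    # equal theta0=theta1 stays at equilibrium regardless of tau
    f = expected_mismatch(15, 3.0, 2.0, 2.0)
    geo = np.array([2.0**j / 3.0 ** (j + 1) for j in range(16)])
    assert np.allclose(f, geo)


def test_expected_mismatch_matches_numerical_integration():
    """Closed form vs direct quadrature of the coalescent-mixture integral."""
    from scipy import integrate
    from scipy.stats import poisson

    tau, th0, th1 = 4.0, 0.8, 30.0
    for j in (0, 2, 5, 9):
        recent, _ = integrate.quad(
            lambda s: (1 / th1) * np.exp(-s / th1) * poisson.pmf(j, s), 0, tau
        )
        ancient, _ = integrate.quad(
            lambda v: (1 / th0) * np.exp(-v / th0) * poisson.pmf(j, tau + v),
            0, np.inf,
        )
        direct = recent + np.exp(-tau / th1) * ancient
        assert expected_mismatch(j, tau, th0, th1)[j] == pytest.approx(direct, rel=1e-6)


def test_fit_recovers_zero_ssd_on_model_data():
    exp = expected_mismatch(20, 4.0, 0.5, 50.0)
    exp = exp / exp.sum()
    mm = MismatchDistribution(counts=(exp * 1e9).astype(np.int64), total_pairs=int(1e9))
    fit = fit_sudden_expansion(mm)
    assert fit.ssd < 1e-8
    assert fit.tau == pytest.approx(4.0, abs=0.1)


def test_fit_optimum_not_worse_than_grid():
    aln = simulate_expansion_alignment(30, 800, 4.0, 0.5, 50.0, rng=1)
    mm = mismatch_distribution(aln)
    fit = fit_sudden_expansion(mm)
    obs = mm.freqs
    rng = np.random.default_rng(0)
    for _ in range(200):
        tau = rng.uniform(0, 2 * mm.d_max)
        th0 = rng.uniform(0, mm.mean)
        th1 = th0 + rng.uniform(0, 10 * mm.d_max)
        ssd = ((obs - expected_mismatch(mm.d_max, tau, th0, th1)) ** 2).sum()
        assert fit.ssd <= ssd + 1e-12
    assert fit.theta1 >= fit.theta0 >= 0
    assert fit.tau >= 0


def _two_lineage_mixture(n_per_side, n_flip, rng_seed, L=1248, theta=1.0):
    """One population split into two blocks separated by n_flip fixed sites."""
    base = simulate_expansion_alignment(
        2 * n_per_side, L, 0.0, theta, theta, rng=rng_seed
    )
    strings = []
    hap_idx, _ = base.expand_individuals()
    for i in hap_idx:
        strings.append(base.sequence_strings()[i])
    seqs = {}
    for i, s in enumerate(strings):
        if i < n_per_side:
            seqs[f"a{i}"] = s
        else:
            seqs[f"b{i}"] = "".join(
                ("T" if c == "A" else "A") if j < n_flip else c
                for j, c in enumerate(s)
            )
    return _aln(seqs)


def test_expansion_data_smoother_than_two_lineage_mixture():
    expanded = simulate_expansion_alignment(40, 1248, 5.0, 0.2, 60.0, rng=11)
    mixture = _two_lineage_mixture(20, 25, 12)
    r_exp = raggedness(mismatch_distribution(expanded).freqs)
    r_mix = raggedness(mismatch_distribution(mixture).freqs)
    assert r_exp < r_mix


def test_bootstrap_pvalues_deterministic_under_seed(expansion_aln):
    mm = mismatch_distribution(expansion_aln)
    fit = fit_sudden_expansion(mm)
    b1 = bootstrap_fit_pvalues(expansion_aln, fit, n_boot=15, rng=42)
    b2 = bootstrap_fit_pvalues(expansion_aln, fit, n_boot=15, rng=42)
    assert (b1.p_ssd, b1.p_rag) == (b2.p_ssd, b2.p_rag)
    assert 0.0 <= b1.p_ssd <= 1.0 and 0.0 <= b1.p_rag <= 1.0


def test_bimodal_mixture_rejected_by_bootstrap():
    """A deep two-lineage mixture violates the sudden-expansion null."""
    aln = _two_lineage_mixture(15, 30, 21, theta=0.5)
    mm = mismatch_distribution(aln)
    fit = fit_sudden_expansion(mm)
    fit = bootstrap_fit_pvalues(aln, fit, n_boot=60, rng=5)
    assert fit.p_ssd < 0.05
    assert fit.raggedness > 0.1  # strongly multimodal observed distribution


@pytest.mark.parametrize(
    "tau,mya",
    [(4.738, 0.053), (4.375, 0.049), (2.209, 0.025), (0.0, 0.0)],
)
def test_expansion_time_reproduces_reported_conversions(tau, mya):
    years, got = expansion_time(tau, RateParams(0.036, 2.5, 1248))
    assert got == mya
    assert years == pytest.approx(tau / (2 * 0.036e-6 * 1248))


def test_expansion_time_scaling():
    r = RateParams(0.036, 2.5, 1248)
    y1, _ = expansion_time(1.0, r)
    y2, _ = expansion_time(2.0, r)
    assert y2 == pytest.approx(2 * y1)
    half_L = RateParams(0.036, 2.5, 624)
    y3, _ = expansion_time(1.0, half_L)
    assert y3 == pytest.approx(2 * y1)
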