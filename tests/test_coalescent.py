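import numpy as np
import pytest
from scipy import stats

from phylodemog.coalescent import (
    Branch,
    DemographicModel,
    MutationModel,
    overlay_mutations,
    refugial_models,
    simulate_genealogy,
    simulate_piecewise_genealogy,
)
from phylodemog.genealogy import Genealogy, GNode
from phylodemog.synthetic import LINEAGE_THETAS


def _single_pop(ne=10000.0, n=2):
    return DemographicModel(
        branches={"p": Branch("p", ne)},
        split_times={},
        generation_time=2.5,
        sample_sizes={"p": n},
    )


def test_pairwise_tmrca_mean_matches_haploid_expectation():
    rng = np.random.default_rng(1)
    model = _single_pop()
    times = [simulate_genealogy(model, rng)[0].tmrca() for _ in range(2000)]
    assert np.mean(times) == pytest.approx(10000.0, rel=0.05)


def test_two_population_split_bounds_tmrca():
    model = DemographicModel(
        branches={
            "anc": Branch("anc", 5000.0),
            "x": Branch("x", 1000.0, "anc"),
            "y": Branch("y", 1000.0, "anc"),
        },
        split_times={"anc": 25_000.0},  # 10 000 generations
        generation_time=2.5,
        sample_sizes={"x": 1, "y": 1},
    )
    rng = np.random.default_rng(2)
    for _ in range(50):
        gen, _ = simulate_genealogy(model, rng)
        assert gen.tmrca() >= 10_000.0


def test_tree_shape_invariants():
    model = _single_pop(n=12)
    gen, tip_pop = simulate_genealogy(model, 3)
    gen.validate()
    assert gen.n_tips == 12
    assert len(tip_pop) == 12
    internal = sum(1 for nd in gen.postorder() if not nd.is_tip)
    assert internal == 11
    # node times strictly decrease tipward along every edge
    for node in gen.postorder():
        for child in node.children:
            assert child.time < node.time


def test_zero_rate_gives_identical_sequences():
    gen, _ = simulate_genealogy(_single_pop(n=6), 4)
    seqs = overlay_mutations(gen, MutationModel(rate=0.0), 100, 5)
    assert len(set(seqs.values())) == 1


def test_fixed_seed_reproduces_alignment():
    gen, _ = simulate_genealogy(_single_pop(n=6), 11)
    s1 = overlay_mutations(gen, MutationModel(rate=1e-4), 500, 42)
    s2 = overlay_mutations(gen, MutationModel(rate=1e-4), 500, 42)
    assert s1 == s2


def test_divergence_matches_jukes_cantor_closed_form():
    """HKY with kappa=1 and equal frequencies is Jukes-Cantor."""
    a, b = GNode(0, "a"), GNode(0, "b")
    gen = Genealogy(GNode(500.0, children=[a, b]))
    mut = MutationModel(rate=1e-3, kappa=1.0, gamma_shape=1e9)
    L = 40000
    seqs = overlay_mutations(gen, mut, L, 7)
    observed = sum(x != y for x, y in zip(seqs["a"], seqs["b"])) / L
    expected = 0.75 * (1 - np.exp(-4 / 3 * 1e-3 * 1000))
    assert observed == pytest.approx(expected, rel=0.05)


def test_hky_rate_matrix_properties():
    mut = MutationModel(rate=1e-8, kappa=3.0, base_freqs=(0.3, 0.2, 0.3, 0.2))
    q = mut.rate_matrix()
    pi = np.array(mut.base_freqs)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
    assert np.allclose(pi @ q, 0.0, atol=1e-12)  # stationarity
    assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)  # unit mean rate
    # detailed balance (reversibility)
    for i in range(4):
        for j in range(4):
            assert pi[i] * q[i, j] == pytest.approx(pi[j] * q[j, i], abs=1e-12)


def test_within_population_diversity_closes_loop_with_theta():
    """Mean pairwise difference per site approximates theta = 2*Ne*mu."""
    ne, mu, L = 5000.0, 9e-8, 1248
    theta = 2 * ne * mu
    rng = np.random.default_rng(13)
    model = _single_pop(ne=ne, n=2)
    diffs = []
    for _ in range(500):
        gen, _ = simulate_genealogy(model, rng)
        seqs = overlay_mutations(gen, MutationModel(rate=mu), L, rng)
        a, b = seqs.values()
        diffs.append(sum(x != y for x, y in zip(a, b)) / L)
    assert np.mean(diffs) == pytest.approx(theta, rel=0.10)


def test_tmrca_distribution_agrees_with_msprime():
    """Independent-simulator cross-check on a two-epoch single population."""
    msprime = pytest.importorskip("msprime")
    n, ne1, ne0, t_change = 8, 20000.0, 500.0, 4000.0
    rng = np.random.default_rng(17)
    mine = np.array(
        [
            simulate_piecewise_genealogy(n, [(0.0, ne1), (t_change, ne0)], rng).tmrca()
            for _ in range(1000)
        ]
    )
    demography = msprime.Demography()
    demography.add_population(name="p", initial_size=ne1)
    demography.add_population_parameters_change(time=t_change, initial_size=ne0)
    theirs = np.array(
        [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples={"p": n}, demography=demography, ploidy=1,
                num_replicates=1000, random_seed=99,
            )
        ]
    )
    ks = stats.ks_2samp(mine, theirs)
    assert ks.pvalue > 0.01


def test_sampling_on_internal_branch_is_an_error():
    model = DemographicModel(
        branches={
            "anc": Branch("anc", 1000.0),
            "x": Branch("x", 1000.0, "anc"),
            "y": Branch("y", 1000.0, "anc"),
        },
        split_times={"anc": 1000.0},
        generation_time=1.0,
        sample_sizes={"x": 2, "y": 2},
    )
    with pytest.raises(ValueError):
        simulate_genealogy(model, 0, sample_sizes={"anc": 2})


def test_model_validation_rejects_inverted_split_times():
    with pytest.raises(ValueError):
        DemographicModel(
            branches={
                "root": Branch("root", 1000.0),
                "mid": Branch("mid", 1000.0, "root"),
                "a": Branch("a", 1000.0, "mid"),
                "b": Branch("b", 1000.0, "mid"),
                "c": Branch("c", 1000.0, "root"),
            },
            split_times={"root": 100.0, "mid": 200.0},  # mid older than root
            generation_time=1.0,
        )


def test_refugial_models_structure_and_conversions():
    single, multiple = refugial_models(LINEAGE_THETAS)
    # branch sizes derive from the reported thetas
    assert round(single.branches["C"].ne) == 32333
    assert round(single.branches["D"].ne) == 14889
    assert round(single.branches["E"].ne) == 27944
    assert round(single.branches["ancestral"].ne) == 75611
    # daughters sum close to the pooled empirical size
    total_daughters = sum(single.branches[x].ne for x in "CDE")
    assert total_daughters == pytest.approx(75611, rel=0.01)
    # 640 000 years at 2.5 yr/generation = 256 000 generations
    assert multiple.start_generations("root") == pytest.approx(256_000.0)
    assert single.start_generations("ancestral") == pytest.approx(7_200.0)
    # the multiple-refugia root is older than the single-refugium one
    assert multiple.split_times["root"] > single.split_times["ancestral"]


def test_genealogy_newick_roundtrip():
    gen, tip_pop = simulate_genealogy(_single_pop(n=6), 21)
    back = Genealogy.from_newick(gen.to_newick())
    assert back.n_tips == 6
    assert back.tmrca() == pytest.approx(gen.tmrca(), rel=1e-6)
    assert {t.label for t in back.tips()} == {t.label for t in gen.tips()}
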