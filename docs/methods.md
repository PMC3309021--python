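# Methods

This package re-implements, as tested reusable code, the inference chain of
a mitochondrial-DNA phylogeography study of a pond frog from southwestern
China: haplotype-level diversity statistics, neutrality tests,
mismatch-distribution expansion inference, hierarchical AMOVA,
statistical-parsimony haplotype networks, and a coalescent-simulation test
of single- versus multiple-refugia demographic histories based on the
minimum number of sorting events on a genealogy. This note records the
models, the parameter conventions, and the design decisions taken where the
design was genuinely open.

## Data model

All statistics operate on a `HaplotypeAlignment`: distinct sequences
("haplotypes") over the retained sites with per-population counts.
Individuals with identical retained-site sequences are collapsed; haplotype
ids `H1..Hk` follow order of first appearance. Sites containing `N` or a
gap in *any* individual are removed globally before analysis (complete
deletion). The motivating dataset has no indels, so a single unambiguous
effective length `L` applies to every per-site quantity; with gappy data
this convention is conservative and can discard information. Expanding each
haplotype by its count recovers the individual-level data exactly, so the
collapse is information-preserving for every statistic computed here.

## Diversity and neutrality tests

- Haplotype diversity: `h = n/(n-1) * (1 - sum p_i^2)` over haplotype
  frequencies (Nei's small-sample-corrected heterozygosity analogue).
- Nucleotide diversity `pi`: mean pairwise differences over all individual
  pairs, divided by `L`.
- Watterson's `theta_W = S / (a_n * L)` with `a_n = sum_{i<n} 1/i` and `S`
  the number of segregating (polymorphic) sites.
- Effective size: mtDNA is haploid and maternally inherited, so
  `theta = 2 * Ne * mu` with `mu` per site per generation. With the study's
  rate of 0.036 substitutions/site/Myr and a 2.5-year generation,
  `mu = 9e-8` and `Ne = theta_W / (2 mu)`, reported rounded half-up to an
  integer. The haploid-Ne convention is used *everywhere* in this package
  (the coalescent engine included); diploid conventions differ by a factor
  of two.
- Tajima's D uses the 1989 variance constants with `pi` and `S` per
  sequence. Its P-value comes from 1000 (default) constant-size neutral
  coalescent simulations conditioned on the sample size with theta fixed at
  the Watterson estimate. The reported one-sided P is
  `Pr(D_sim <= D_obs)` (expansion drives D negative); a two-sided value
  (doubled smaller tail) is also reported.
- Fu's F_S: `F_S = ln(S'/(1-S'))` with `S' = Pr(K >= k_obs)` under the
  Ewens sampling distribution at `theta_pi` (mean pairwise differences per
  sequence), the usual plug-in for this test. `Pr(K = k)` uses unsigned
  Stirling numbers of the first kind computed by the exact integer
  recurrence (Python bigints; probabilities are assembled in log space, so
  sample sizes beyond the float range of the raw Stirling numbers — roughly
  n > 170 — remain stable). P-values again come from neutral simulations,
  each replicate evaluated with its own `theta_pi`; `Pr(F_sim <= F_obs)` is
  reported. Significance conventions differ between tools: the result
  object exposes both the nominal P < 0.05 verdict and the stricter
  P < 0.02 convention used by Arlequin for this statistic. Degenerate
  replicates with a single haplotype give `S' = 1` and are reported as a
  `+inf` sentinel; they can never fall in the low (expansion) tail.

## Mismatch distributions and the sudden-expansion model

The mismatch distribution counts unordered sequence pairs by their number
of pairwise differences. Under a sudden expansion `theta0 -> theta1` at
`tau` mutational units before present (infinite-sites), the pair-difference
law is the standard equilibrium-geometric/Poisson mixture

    F_j(tau, theta0, theta1) = Feq_j(theta1)
      + exp(-tau (theta1+1)/theta1)
        * sum_{i<=j} tau^(j-i)/(j-i)! (Feq_i(theta0) - Feq_i(theta1)),

with `Feq_j(theta) = theta^j / (1+theta)^(j+1)`. A unit test checks this
closed form against direct numerical integration of the underlying
coalescent mixture.

Fitting minimizes the sum of squared deviations (SSD) between observed and
expected frequencies over `j = 0..d_max` (the observed range): a coarse
grid — `tau` in `[0, 2 d_max]` at step 0.05 (capped at 800 grid points for
pathological, e.g. strongly bimodal, distributions), `theta0` from 0 to the
observed mean, `theta1` log-spaced up to `10 * d_max` as a proxy for the
effectively infinite post-expansion size (unbounded `theta1` is not
identifiable) — refined by Nelder–Mead. Grid ties resolve to the smallest
`tau`.

Goodness of fit uses SSD and Harpending's raggedness
`r = sum_{j=1}^{d+1} (x_j - x_{j-1})^2` with the convention `x_{d+1} = 0`.
P-values come from a parametric bootstrap: samples of the same `n` and `L`
are simulated under the fitted expansion demography (a single population
with a stepwise size change, finite-sites mutation at `L` sites so the null
matches how real and synthetic data arise, even though the fitted model is
infinite-sites), refitted, and `P = Pr(stat_sim >= stat_obs)`; small P
rejects sudden expansion. Calibration tests confirm near-uniform P under
the null at the 5% level. Note that for very low-diversity nulls the
raggedness of a monomorphic bootstrap replicate is 1.0 by convention, which
makes `P_rag` conservative there; SSD is the more reliable statistic in
that regime.

Expansion time uses `tau = 2 u t` with `u` per sequence per *year*
(`0.036e-6 * L`); no generation time enters this conversion, which
reproduces the published expansion times (0.053, 0.049, 0.025 Mya) from the
published `tau` values exactly at 3-decimal rounding. On strongly
multimodal pooled samples (deeply structured data) the fitted `tau` is
reported as-is and should not be interpreted as an expansion age.

## AMOVA

Three-level analysis of molecular variance on raw pairwise-difference
distances (the default distance for haplotypic data; no substitution
correction). Sums of squared deviations at total, group and population
levels give mean squares, and the unbalanced-design coefficients
(`n1, n2, n3`) convert these to variance components sigma_a (among groups),
sigma_b (among populations within groups), sigma_c (within populations);
`Phi_CT = a/(a+b+c)`, `Phi_SC = b/(b+c)`, `Phi_ST = (a+b)/(a+b+c)`. An
exact brute-force decomposition in rational arithmetic pins the
implementation on a small fixture. Negative components are reported as-is
with a flag so percentages stay additive. Permutation schemes: Phi_CT
permutes whole populations among groups; Phi_SC permutes individuals among
populations within their group; Phi_ST permutes individuals among all
populations; `P = (count{perm >= obs} + 1)/(n_perm + 1)`, so P is never 0.
With few population units the CT permutation space is coarse and the
smallest attainable P is limited accordingly (e.g. six populations in two
groups cannot reach P < 0.05); the type-I calibration test therefore uses
twelve units in three groups. `compare_groupings` ranks candidate
groupings by Phi_CT and flags the arg-max as the most probable
geographical subdivision, mirroring the grouping-search procedure used with
Arlequin.

## Statistical-parsimony networks

The connection limit is the largest step count `j` whose cumulative
probability of parsimony reaches the confidence level (default 95%). The
probability that a `j`-step connection over `L` sites involves no
superimposed change is computed multiplicatively as
`P_j = prod_{i=1..j} (1 - i/(2L))`, the no-collision (birthday-style)
probability of the accumulating changes over the `2L` site copies of the
two connected lineages. The exact source of the TCS program is not
distributed with its publications; this parameterization is pinned to the
program lineage's published behaviour — most directly the 15-step limit at
95% for `L = 1248` — and matches the square-root-of-length scaling of
published TCS limits across studies. An exact rational-arithmetic oracle
freezes the `L = 400 -> 8` case as a regression fixture.

Network assembly is agglomerative in increasing distance `d = 1..limit`:
within a round, haplotype pairs at distance `d` whose components were
already distinct at the start of the round are joined; `d > 1` connections
insert `d-1` synthetic "missing" intermediate nodes (ids `m1, m2, ...`,
numbered in insertion order within each component). Within a round, pairs
are processed by descending summed haplotype frequency (an
ancestral-weighting heuristic approximating TCS's tie-breaking, pinned by
tests but approximate), then lexically. An edge that closes a cycle formed
within the same round is recorded as a *loop* (an alternative,
equal-length connection) and retained, so "no loops observed" is a
checkable output property. The modal haplotype per component is the
highest-frequency haplotype, ties broken by network degree then id.

## Coalescent engine

The demographic model is a rooted population tree: per-branch haploid Ne,
split times in years (converted at the model's generation time), samples on
leaf branches. Within a branch, `k` lineages coalesce at rate
`k(k-1)/2 / Ne` per generation with exponential waiting times
(continuous-time; no discrete-generation approximation); at a split time
the daughters' surviving lineages enter the parent; the root branch extends
indefinitely. Sequences evolve by HKY with gamma rate multipliers (mean 1,
shape alpha) per site: per-branch transition matrices come from the
spectral decomposition of the reversible rate matrix (symmetrized with
sqrt-stationary weights), evaluated per site, so no event-level simulation
is needed. The per-pair TMRCA expectation (`E[T2] = Ne` generations,
haploid), the Jukes–Cantor divergence limit (kappa = 1, equal frequencies),
the `theta = 2 Ne mu` diversity loop, and a Kolmogorov–Smirnov comparison
of TMRCA distributions against msprime on a two-epoch model validate the
engine; msprime is used only as an independent oracle, never as the
implementation.

The two refugial hypotheses are built from the published per-lineage
Watterson estimates (C: 0.00582, D: 0.00268, E: 0.00503, pooled 0.01361
per site), converted to Ne as above: (a) a single ancestral population at
the pooled size splitting into C, D and E at 18 000 years BP (the end of
the last glacial maximum); (b) C isolated from (D,E) at 640 000 years BP
and D from E at 360 000 years BP. Ancestral branch sizes are not
identified by the data; by default they conserve the sum of their
daughters (the pooled empirical size is available as an alternative). HKY
parameters (kappa = 4, alpha = 0.5, uniform frequencies) are package
defaults of realistic magnitude — the hypothesis test depends only on tree
shapes, not on the mutation overlay.

## Minimum-sorting-events test

The Slatkin–Maddison statistic `s` is the minimum number of population-
state changes on the genealogy: a Fitch small-parsimony count with the
population as an unordered multistate character, validated against a
Sankoff dynamic-programming oracle on random trees. Counting deep
coalescences instead of state changes is a documented alternative the
package does not implement; for the fixed population-to-tip association
used here the Fitch count is the cited statistic. Polytomies are refused —
inputs are binary by construction (coalescent output) or must be resolved
upstream. The observed genealogy is an *input* (newick); inferring it is
out of scope, and users with only sequences should estimate a tree with an
external phylogenetics tool first.

For each candidate model, 1000 (default) simulated genealogies give the
null distribution of `s`; the 95% band is the empirical 2.5–97.5 percentile
interval with linear interpolation (numpy's default, pinned by tests), and
a model is rejected when the observed `s` falls strictly outside. Both
tail fractions are reported. Self-consistency tests confirm ~95% coverage
of `s` under its own generating model and that genealogies simulated under
the deep-split history reject the shallow single-refugium model while
retaining the generating one in well over 80% of replicates.

## Synthetic data

The generator emulates the study's design: 262 individuals, 22 populations
in five regional lineages (A–E), one concatenated 1248-bp region (the study
concatenated 525-bp and 723-bp gene fragments; all analyses treat the
concatenation as a single locus), HKY+G mutation at 9e-8
subs/site/generation. Lineage splits follow the dated history (A 2.44 Mya,
B 2.01 Mya, C 0.64 Mya, D/E 0.36 Mya); populations within a lineage
radiate in a star at 50 kya (a package choice — the real within-lineage
topology is unknown); Ne for C, D, E follow the published thetas, while A
(30 000) and B (5 000, a single isolated site) are package choices of
realistic magnitude. The real per-site sample sizes are not public, so a
fixed allocation summing to 262 is used for determinism. Presets:
`study_shape`, `single_refugium`, `multiple_refugia` (the two hypothesis
models with C/D/E sampling), and `expansion` (a 100-fold sudden growth at
50 kya). Every dataset carries a truth record (true genealogy, per-lineage
TMRCAs, distinct-haplotype count) for oracle-style testing.

What the generator does *not* emulate: recombination (appropriate for
mtDNA), migration after splits, selection, sequencing error, base
composition bias, and the study's actual haplotype frequencies. Passing
tests on this data therefore validate the *inference machinery* under the
stated models, not the biological conclusions for any real dataset.

## Reproducibility and problem sizes

Every stochastic routine takes a numpy `Generator` or integer seed; the
pipeline derives independent per-stage streams from one top-level seed via
`SeedSequence` and records them in a manifest, so a single number
reproduces the full report bundle bit-for-bit. Default replicate counts
follow the study's conventions (1000 permutations, 1000 bootstrap
replicates, 1000 simulated genealogies). The test suite and the analysis
drivers run at deliberately reduced scales chosen as the package's own
trade-off between statistical resolution and turnaround (e.g. 200-replicate
null distributions, 50-replicate power checks, 200 bootstrap replicates per
lineage); the defaults remain the full study-scale counts.

## Known limitations

- The ParsProb parameterization reproduces the TCS lineage's published
  limits but is a reconstruction, not a port of the (unavailable) original
  source; behaviour is pinned by fixtures at L = 1248 and L = 400.
- TCS's exact tie-breaking among equal-distance alternative connections is
  not fully documented; the frequency-based heuristic here is deterministic
  and tested, but approximate.
- The sudden-expansion fit can degenerate on strongly structured pooled
  samples (large tau, SSD-flat surface); such fits are reported, not
  suppressed, and their expansion times are not meaningful.
- Standard errors for h and pi beyond the point estimates are not
  computed, and no multi-locus estimators are provided.
- The AMOVA distance is the raw difference count; distances with
  substitution corrections are out of scope.
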