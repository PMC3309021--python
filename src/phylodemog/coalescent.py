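"""Structured coalescent simulation on a population tree, with HKY+G mutations.

The demographic model is a rooted tree of populations: each branch carries a
haploid effective size Ne (mtDNA convention, consistent with theta = 2*Ne*mu),
and each internal branch a split time in years before present at which its
daughter branches merge into it. Within a branch, lineages coalesce at the
standard pairwise rate k(k-1)/2 per Ne generations with exponential waiting
times; the root branch extends indefinitely into the past.

Sequences are realised by overlaying a continuous-time HKY substitution
process with gamma-distributed site-rate multipliers down each branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .genealogy import Genealogy, GNode

__all__ = [
    "Branch",
    "DemographicModel",
    "MutationModel",
    "simulate_genealogy",
    "simulate_piecewise_genealogy",
    "overlay_mutations",
    "refugial_models",
]


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class Branch:
    name: str
    ne: float
    parent: Optional[str] = None

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError(f"branch {self.name!r}: Ne must be positive")


@dataclass
class DemographicModel:
    """Population tree with split times (years) and per-branch haploid Ne."""

    branches: dict[str, Branch]
    split_times: dict[str, float]  # internal branch -> years BP daughters merge
    generation_time: float
    sample_sizes: dict[str, int] = field(default_factory=dict)
    label: str = "model"

    def __post_init__(self):
        roots = [b for b in self.branches.values() if b.parent is None]
        if len(roots) != 1:
            raise ValueError("model must have exactly one root branch")
        for b in self.branches.values():
            if b.parent is not None and b.parent not in self.branches:
                raise ValueError(f"unknown parent {b.parent!r} of {b.name!r}")
        for name in self.split_times:
            if name not in self.branches:
                raise ValueError(f"split time given for unknown branch {name!r}")
        for name, t in self.split_times.items():
            parent = self.branches[name].parent
            if parent is not None:
                if t >= self.split_times[parent]:
                    raise ValueError(
                        "split times must strictly increase toward the root"
                    )
        for pop in self.sample_sizes:
            if pop not in self.branches or self.children(pop):
                raise ValueError(f"samples must sit on leaf branches, not {pop!r}")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")

    def children(self, name: str) -> list[str]:
        return [b.name for b in self.branches.values() if b.parent == name]

    @property
    def root(self) -> str:
        return next(b.name for b in self.branches.values() if b.parent is None)

    def leaves(self) -> list[str]:
        return [n for n in self.branches if not self.children(n)]

    def start_generations(self, name: str) -> float:
        """Time (generations BP) at which this branch begins, looking backward."""
        if not self.children(name):
            return 0.0
        return self.split_times[name] / self.generation_time

    def end_generations(self, name: str) -> float:
        b = self.branches[name]
        if b.parent is None:
            return math.inf
        return self.split_times[b.parent] / self.generation_time

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "generation_time": self.generation_time,
            "branches": [
                {"name": b.name, "ne": b.ne, "parent": b.parent}
                for b in self.branches.values()
            ],
            "split_times": dict(self.split_times),
            "sample_sizes": dict(self.sample_sizes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        return cls(
            branches={
                b["name"]: Branch(b["name"], float(b["ne"]), b.get("parent"))
                for b in d["branches"]
            },
            split_times={k: float(v) for k, v in d.get("split_times", {}).items()},
            generation_time=float(d["generation_time"]),
            sample_sizes={k: int(v) for k, v in d.get("sample_sizes", {}).items()},
            label=d.get("label", "model"),
        )


@dataclass(frozen=True)
class MutationModel:
    """HKY substitution model with gamma rate heterogeneity across sites.

    ``rate`` is in substitutions/site/generation (expected, at stationarity);
    gamma multipliers have mean 1 and shape ``gamma_shape``.
    """

    rate: float
    kappa: float = 4.0
    gamma_shape: float = 0.5
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if abs(sum(self.base_freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape <= 0 or self.kappa <= 0 or self.rate < 0:
            raise ValueError("kappa and gamma shape must be positive, rate >= 0")

    def rate_matrix(self) -> np.ndarray:
        """HKY Q normalized to one expected substitution per unit time."""
        pi = np.asarray(self.base_freqs)
        # order A C G T; transitions: A<->G (0,2), C<->T (1,3)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = {i, j} in ({0, 2}, {1, 3})
                q[i, j] = (self.kappa if transition else 1.0) * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

def _coalesce(
    lineages: list[GNode],
    ne: float,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> list[GNode]:
    """Coalesce a pool of lineages between t_start and t_end (generations)."""
    t = t_start
    pool = list(lineages)
    while len(pool) > 1:
        k = len(pool)
        rate = k * (k - 1) / 2.0 / ne
        t = t + rng.exponential(1.0 / rate)
        if t > t_end:
            return pool
        i, j = rng.choice(k, size=2, replace=False)
        a, b = pool[i], pool[j]
        merged = GNode(time=t, children=[a, b])
        pool = [x for idx, x in enumerate(pool) if idx not in (i, j)]
        pool.append(merged)
    return pool


def simulate_genealogy(
    model: DemographicModel,
    rng: np.random.Generator | int | None = None,
    sample_sizes: Mapping[str, int] | None = None,
) -> tuple[Genealogy, dict[str, str]]:
    """Simulate one genealogy under the structured coalescent.

    Returns the genealogy (branch lengths in generations) and the mapping
    from tip label to population id.
    """
    rng = as_rng(rng)
    sizes = dict(sample_sizes if sample_sizes is not None else model.sample_sizes)
    if not sizes or sum(sizes.values()) < 2:
        raise ValueError("need at least two sampled lineages in total")
    for pop in sizes:
        if pop not in model.branches or model.children(pop):
            raise ValueError(f"samples must be placed on leaf branches, not {pop!r}")

    tip_pop: dict[str, str] = {}

    def process(name: str) -> list[GNode]:
        pool: list[GNode] = []
        for child in sorted(model.children(name)):
            pool.extend(process(child))
        if not model.children(name):
            for i in range(sizes.get(name, 0)):
                label = f"{name}.{i + 1}"
                tip_pop[label] = name
                pool.append(GNode(time=0.0, label=label))
        t0 = model.start_generations(name)
        t1 = model.end_generations(name)
        return _coalesce(pool, model.branches[name].ne, t0, t1, rng)

    out = process(model.root)
    assert len(out) == 1, "root branch must fully coalesce"
    gen = Genealogy(out[0])
    return gen, tip_pop


def simulate_piecewise_genealogy(
    n: int,
    epochs: Iterable[tuple[float, float]],
    rng: np.random.Generator | int | None = None,
) -> Genealogy:
    """Single-population coalescent with stepwise Ne changes.

    ``epochs`` is a sequence of ``(start_generation, ne)`` looking backward in
    time, starting at 0; the last epoch extends indefinitely.
    """
    rng = as_rng(rng)
    epochs = sorted((float(t), float(ne)) for t, ne in epochs)
    if not epochs or epochs[0][0] != 0.0:
        raise ValueError("first epoch must start at generation 0")
    pool = [GNode(time=0.0, label=f"s{i + 1}") for i in range(n)]
    t = 0.0
    for idx, (t0, ne) in enumerate(epochs):
        t_end = epochs[idx + 1][0] if idx + 1 < len(epochs) else math.inf
        pool = _coalesce(pool, ne, max(t, t0), t_end, rng)
        t = t_end
        if len(pool) == 1:
            break
    assert len(pool) == 1
    return Genealogy(pool[0])


# ---------------------------------------------------------------------------
# mutation overlay
# ---------------------------------------------------------------------------

def overlay_mutations(
    gen: Genealogy,
    mut: MutationModel,
    L: int,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Evolve sequences of length L down the genealogy; returns tip sequences.

    Branch-specific HKY transition matrices are computed in closed form from
    the spectral decomposition of Q, site by site (each site has its own
    gamma rate multiplier), so no event-level simulation is needed.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = as_rng(rng)
    pi = np.asarray(mut.base_freqs)
    q = mut.rate_matrix()
    # reversible Q: symmetrize with sqrt(pi) to use a stable eigh decomposition
    d = np.sqrt(pi)
    sym = (q * d[None, :]) / d[:, None]
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    a_mat = u / d[:, None]          # rows scaled: A = D^{-1/2} U
    b_mat = (u * d[:, None]).T      # B = U^T D^{1/2}

    site_rate = (
        rng.gamma(mut.gamma_shape, 1.0 / mut.gamma_shape, size=L)
        if mut.gamma_shape != math.inf
        else np.ones(L)
    )

    decode = np.array(list("ACGT"))
    root_state = rng.choice(4, size=L, p=pi)
    seqs: dict[str, str] = {}

    stack: list[tuple[GNode, np.ndarray]] = [(gen.root, root_state)]
    while stack:
        node, state = stack.pop()
        if node.is_tip:
            seqs[node.label] = "".join(decode[state])
            continue
        for child in node.children:
            blen = node.time - child.time
            t_site = mut.rate * blen * site_rate  # expected subs per site
            if mut.rate == 0 or blen == 0:
                stack.append((child, state.copy()))
                continue
            e_mat = np.exp(np.outer(t_site, lam))          # (L, 4)
            rows = a_mat[state]                            # (L, 4)
            probs = np.einsum("sj,sj,jk->sk", rows, e_mat, b_mat)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            uvar = rng.random(L)
            child_state = (probs.cumsum(axis=1) < uvar[:, None]).sum(axis=1)
            stack.append((child, np.minimum(child_state, 3).astype(np.int64)))
    return seqs


# ---------------------------------------------------------------------------
# the two refugial hypotheses
# ---------------------------------------------------------------------------

def refugial_models(
    thetas: Mapping[str, float],
    subs_rate_per_myr: float = 0.036,
    generation_time: float = 2.5,
    expansion_years: float = 18_000.0,
    deep_split_years: float = 640_000.0,
    shallow_split_years: float = 360_000.0,
    sample_sizes: Mapping[str, int] | None = None,
    ancestral_ne: str = "sum",
) -> tuple[DemographicModel, DemographicModel]:
    """Build the single-refugium and multiple-refugia demographic models.

    ``thetas`` carries per-site Watterson estimates for lineages ``C``, ``D``,
    ``E`` and their pooled ``total``; effective sizes follow theta = 2*Ne*mu
    with mu per site per generation. The single-refugium model derives all
    three lineages from one ancestral population at the end of the last
    glacial maximum; the multiple-refugia model isolates C at the deep
    middle-Pleistocene split and D from E at the shallow one. Ancestral
    branch sizes are not identified by the data; by default they conserve
    the sum of their daughters (``ancestral_ne="sum"``), or use the pooled
    empirical size (``"total"``).
    """
    mu = subs_rate_per_myr * 1e-6 * generation_time  # per site per generation
    ne = {k: thetas[k] / (2 * mu) for k in ("C", "D", "E", "total")}
    sizes = dict(sample_sizes or {})

    single = DemographicModel(
        branches={
            "ancestral": Branch("ancestral", ne["total"]),
            "C": Branch("C", ne["C"], "ancestral"),
            "D": Branch("D", ne["D"], "ancestral"),
            "E": Branch("E", ne["E"], "ancestral"),
        },
        split_times={"ancestral": expansion_years},
        generation_time=generation_time,
        sample_sizes=sizes,
        label="single_refugium",
    )

    ne_de = ne["D"] + ne["E"] if ancestral_ne == "sum" else ne["total"]
    ne_root = ne["C"] + ne_de if ancestral_ne == "sum" else ne["total"]
    multiple = DemographicModel(
        branches={
            "root": Branch("root", ne_root),
            "C": Branch("C", ne["C"], "root"),
            "DE": Branch("DE", ne_de, "root"),
            "D": Branch("D", ne["D"], "DE"),
            "E": Branch("E", ne["E"], "DE"),
        },
        split_times={"root": deep_split_years, "DE": shallow_split_years},
        generation_time=generation_time,
        sample_sizes=sizes,
        label="multiple_refugia",
    )
    return single, multiple
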