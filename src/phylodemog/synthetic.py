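"""Study-shaped synthetic datasets with known ground truth.

Generates alignments, sample tables and genealogies that mirror the design
of the mtDNA survey this package models: five regional lineages (A-E), 22
populations, 262 individuals, and a 1248-bp concatenated two-gene alignment
evolving under HKY+G. Lineage divergence times follow the dated history
(A ~2.44 Mya, B ~2.01 Mya, C ~0.64 Mya, D/E ~0.36 Mya); effective sizes for
C, D and E derive from the study's Watterson estimates, and the remaining
sizes are package choices of realistic magnitude. Every dataset carries a
truth record (true genealogy, lineage TMRCAs, haplotype count) so pipeline
stages can be tested without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment, SampleTable, collapse_haplotypes, write_fasta
from .coalescent import (
    Branch,
    DemographicModel,
    MutationModel,
    overlay_mutations,
    refugial_models,
    simulate_genealogy,
)
from .genealogy import Genealogy

__all__ = [
    "ScenarioPreset",
    "SyntheticDataset",
    "get_preset",
    "generate",
    "truth_report",
    "read_truth",
    "PRESET_NAMES",
    "LINEAGE_THETAS",
    "STUDY_ALLOCATION",
]

# Watterson theta per site for the three refugial-candidate lineages and
# their pooled total, as estimated in the study this design emulates.
LINEAGE_THETAS: dict[str, float] = {
    "C": 0.00582,
    "D": 0.00268,
    "E": 0.00503,
    "total": 0.01361,
}

SUBS_RATE_PER_MYR = 0.036
GENERATION_TIME = 2.5
SEQ_LENGTH = 1248
MU_PER_SITE_PER_GEN = SUBS_RATE_PER_MYR * 1e-6 * GENERATION_TIME  # 9e-8

# Fixed allocation of 262 individuals over 22 populations in 5 regional
# groups (the real per-site sample sizes are not reproduced; totals are).
STUDY_ALLOCATION: dict[str, dict[str, int]] = {
    "A": {"MG": 12, "A2": 12, "A3": 12, "A4": 12, "A5": 12},
    "B": {"HL": 10},
    "C": {"WN": 12, "ZY": 12, "LuL": 12},
    "D": {"LSH": 12, "LGH": 12},
    "E": {
        "KM": 12, "DL": 12, "E3": 12, "E4": 12, "E5": 12, "E6": 12,
        "E7": 12, "E8": 12, "E9": 12, "E10": 12, "E11": 12,
    },
}

# Haploid effective sizes per regional lineage; C, D, E follow the empirical
# thetas via theta = 2*Ne*mu, A and B are unconstrained package choices.
GROUP_NE: dict[str, float] = {
    "A": 30_000.0,
    "B": 5_000.0,
    "C": LINEAGE_THETAS["C"] / (2 * MU_PER_SITE_PER_GEN),
    "D": LINEAGE_THETAS["D"] / (2 * MU_PER_SITE_PER_GEN),
    "E": LINEAGE_THETAS["E"] / (2 * MU_PER_SITE_PER_GEN),
}

# Lineage split times (years BP) from the dated phylogeny, plus a recent
# within-lineage radiation time for the population-level star splits.
SPLIT_A = 2_440_000.0
SPLIT_B = 2_010_000.0
SPLIT_C = 640_000.0
SPLIT_DE = 360_000.0
WITHIN_GROUP_SPLIT = 50_000.0

PRESET_NAMES = ("study_shape", "multiple_refugia", "single_refugium", "expansion")


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    model: DemographicModel
    mutation: MutationModel
    L: int
    seed: int = 0


@dataclass
class SyntheticDataset:
    preset: ScenarioPreset
    alignment: HaplotypeAlignment
    samples: SampleTable
    genealogy: Genealogy
    tip_populations: dict[str, str]
    truth: dict

    def group_of_tip(self) -> dict[str, str]:
        g_of_pop = self.samples.group_of_population()
        return {t: g_of_pop[p] for t, p in self.tip_populations.items()}


def _study_shape_model() -> DemographicModel:
    """Five-lineage history with population-level leaves (22 populations)."""
    branches: dict[str, Branch] = {"rootA": Branch("rootA", GROUP_NE["A"] + 40_000.0)}
    split_times: dict[str, float] = {"rootA": SPLIT_A}
    # lineage backbone: (((C,(D,E)),B),A)
    branches["grpA"] = Branch("grpA", GROUP_NE["A"], "rootA")
    branches["BCDE"] = Branch("BCDE", 40_000.0, "rootA")
    split_times["BCDE"] = SPLIT_B
    branches["grpB"] = Branch("grpB", GROUP_NE["B"], "BCDE")
    branches["CDE"] = Branch("CDE", 35_000.0, "BCDE")
    split_times["CDE"] = SPLIT_C
    branches["grpC"] = Branch("grpC", GROUP_NE["C"], "CDE")
    branches["DE"] = Branch("DE", GROUP_NE["D"] + GROUP_NE["E"], "CDE")
    split_times["DE"] = SPLIT_DE
    branches["grpD"] = Branch("grpD", GROUP_NE["D"], "DE")
    branches["grpE"] = Branch("grpE", GROUP_NE["E"], "DE")

    sample_sizes: dict[str, int] = {}
    for group, pops in STUDY_ALLOCATION.items():
        anchor = f"grp{group}"
        split_times[anchor] = WITHIN_GROUP_SPLIT
        if len(pops) == 1:
            (pop, n), = pops.items()
            branches[pop] = Branch(pop, GROUP_NE[group], anchor)
            sample_sizes[pop] = n
            continue
        per_pop_ne = GROUP_NE[group] / len(pops)
        for pop, n in pops.items():
            branches[pop] = Branch(pop, per_pop_ne, anchor)
            sample_sizes[pop] = n
    return DemographicModel(
        branches=branches,
        split_times=split_times,
        generation_time=GENERATION_TIME,
        sample_sizes=sample_sizes,
        label="study_shape",
    )


def _expansion_model() -> DemographicModel:
    """Single population after a 100-fold sudden expansion ~50 kya."""
    return DemographicModel(
        branches={
            "ancestral": Branch("ancestral", 500.0),
            "pop": Branch("pop", 50_000.0, "ancestral"),
        },
        split_times={"ancestral": WITHIN_GROUP_SPLIT},
        generation_time=GENERATION_TIME,
        sample_sizes={"pop": 50},
        label="expansion",
    )


def get_preset(name: str, seed: int = 0) -> ScenarioPreset:
    mutation = MutationModel(rate=MU_PER_SITE_PER_GEN)
    if name == "study_shape":
        model = _study_shape_model()
    elif name in ("multiple_refugia", "single_refugium"):
        single, multiple = refugial_models(
            LINEAGE_THETAS,
            subs_rate_per_myr=SUBS_RATE_PER_MYR,
            generation_time=GENERATION_TIME,
            sample_sizes={"C": 36, "D": 24, "E": 132},
        )
        model = multiple if name == "multiple_refugia" else single
    elif name == "expansion":
        model = _expansion_model()
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return ScenarioPreset(name=name, model=model, mutation=mutation, L=SEQ_LENGTH, seed=seed)


def _group_of_population(preset: ScenarioPreset) -> dict[str, str]:
    if preset.name == "study_shape":
        return {
            pop: grp for grp, pops in STUDY_ALLOCATION.items() for pop in pops
        }
    return {pop: pop for pop in preset.model.sample_sizes}


def _lineage_tmrcas(
    gen: Genealogy, tip_group: Mapping[str, str]
) -> dict[str, float]:
    """TMRCA (generations) of the tips of each group on the true genealogy."""
    groups = sorted(set(tip_group.values()))
    tipsets: dict[int, frozenset] = {}
    best: dict[str, float] = {}
    want = {g: frozenset(t for t, gg in tip_group.items() if gg == g) for g in groups}
    for node in gen.postorder():
        if node.is_tip:
            tipsets[id(node)] = frozenset({node.label})
        else:
            tipsets[id(node)] = frozenset().union(
                *(tipsets[id(c)] for c in node.children)
            )
        for g in groups:
            if g not in best and want[g] <= tipsets[id(node)]:
                best[g] = node.time if len(want[g]) > 1 else 0.0
    return best


def generate(
    preset: ScenarioPreset,
    rng: np.random.Generator | int | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Simulate one dataset under the preset's demographic and mutation model.

    Uses the preset's seed unless an explicit rng/seed is supplied. With
    ``out_dir``, writes FASTA, sample TSV, true-genealogy newick and the
    truth TSV; identical seeds give byte-identical files.
    """
    if rng is None:
        rng = np.random.default_rng(preset.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    gen, tip_pop = simulate_genealogy(preset.model, rng)
    seqs = overlay_mutations(gen, preset.mutation, preset.L, rng)
    aln = collapse_haplotypes(sorted(seqs.items()), tip_pop)

    g_of_pop = _group_of_population(preset)
    table = pd.DataFrame(
        {
            "individual": sorted(tip_pop),
            "population": [tip_pop[t] for t in sorted(tip_pop)],
        }
    )
    table["group"] = table["population"].map(g_of_pop)
    samples = SampleTable(table)

    tip_group = {t: g_of_pop[p] for t, p in tip_pop.items()}
    tmrcas = _lineage_tmrcas(gen, tip_group)
    truth = {
        "preset": preset.name,
        "model_label": preset.model.label,
        "seed": preset.seed,
        "n_individuals": len(tip_pop),
        "n_populations": len(set(tip_pop.values())),
        "n_groups": len(set(tip_group.values())),
        "L": preset.L,
        "n_haplotypes": len(set(seqs.values())),
        "root_tmrca_generations": gen.tmrca(),
        **{f"tmrca_{g}_generations": t for g, t in sorted(tmrcas.items())},
    }
    ds = SyntheticDataset(
        preset=preset,
        alignment=aln,
        samples=samples,
        genealogy=gen,
        tip_populations=tip_pop,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "alignment.fasta", sorted(seqs.items()))
        samples.write_tsv(out / "samples.tsv")
        gen.write_newick(out / "genealogy.nwk")
        truth_report(truth, out / "truth.tsv")
    return ds


def truth_report(truth: Mapping, path: str | Path) -> None:
    """Serialize a truth record as a two-column key/value TSV."""
    df = pd.DataFrame(
        {"key": list(truth.keys()), "value": [str(v) for v in truth.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for key, value in zip(df["key"], df["value"]):
        try:
            num = float(value)
            out[key] = int(num) if num.is_integer() and "." not in value else num
        except ValueError:
            out[key] = value
    return out
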