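"""End-to-end analysis pipeline: diversity -> mismatch -> AMOVA -> network
-> refugia test, from one configuration, with a reproducibility manifest.

A single top-level seed deterministically derives independent per-stage
seeds (via numpy's SeedSequence), so one number reproduces every stochastic
quantity in the report bundle. Tables are written as TSV with a JSON twin.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import HaplotypeAlignment, SampleTable, read_alignment
from .amova import amova, compare_groupings
from .coalescent import refugial_models
from .diversity import RateParams, diversity_stats, fu_fs, ne_from_theta, tajimas_d
from .genealogy import Genealogy
from .mismatch import (
    bootstrap_fit_pvalues,
    expansion_time,
    fit_sudden_expansion,
    mismatch_distribution,
)
from .network import build_network, connection_limit, modal_haplotype
from .refugia import null_distribution, slatkin_s, test_hypothesis

__all__ = ["RunConfig", "run_pipeline", "stage_rngs", "diversity_table", "mismatch_table"]

_STAGES = ("stats", "mismatch", "amova", "network", "refugia")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-stage generators derived from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


@dataclass
class RunConfig:
    fasta: str
    samples: str
    out_dir: str
    tree: Optional[str] = None  # observed genealogy (newick) for the s test
    subs_rate: float = 0.036
    generation_time: float = 2.5
    n_perm: int = 1000
    n_boot: int = 1000
    n_sims: int = 1000
    seed: int = 1
    groupings: Sequence[tuple[str, Mapping[str, str]]] = field(default_factory=list)
    refugia_thetas: Optional[Mapping[str, float]] = None
    refugia_groups: tuple[str, ...] = ("C", "D", "E")

    def __post_init__(self):
        if min(self.n_perm, self.n_boot, self.n_sims) < 1:
            raise ValueError("replicate counts must be >= 1")

    def digest(self) -> str:
        blob = json.dumps(
            {k: (dict(v) if isinstance(v, Mapping) else v)
             for k, v in asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def diversity_table(
    aln: HaplotypeAlignment,
    samples: SampleTable,
    rates: RateParams,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-lineage (and total) diversity, Ne and neutrality tests."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g_of_pop = samples.group_of_population()
    units = [
        (g, [p for p, gg in g_of_pop.items() if gg == g]) for g in samples.groups
    ]
    units.append(("Total", list(samples.populations)))
    rows = []
    for label, pops in units:
        sub = aln.subset_populations([p for p in pops if p in aln.populations])
        if sub.n < 4:
            continue
        stats = diversity_stats(sub)
        row = {
            "lineage": label,
            "n": stats.n,
            "n_haplotypes": stats.k,
            "h": stats.h,
            "pi": stats.pi,
            "theta_w": stats.theta_w,
            "S": stats.S,
            "Ne": ne_from_theta(stats.theta_w, rates),
        }
        if stats.S > 0:
            taj = tajimas_d(sub, n_sims=n_sims, rng=rng)
            fs = fu_fs(sub, n_sims=n_sims, rng=rng)
            row.update(
                tajimas_d=taj.d, p_tajima=taj.p_low, fu_fs=fs.fs, p_fs=fs.p_value
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mismatch_table(
    aln: HaplotypeAlignment,
    samples: SampleTable,
    rates: RateParams,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sudden-expansion fits with bootstrap P-values and expansion times."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g_of_pop = samples.group_of_population()
    units = [
        (g, [p for p, gg in g_of_pop.items() if gg == g]) for g in samples.groups
    ]
    units.append(("Total", list(samples.populations)))
    rows = []
    for label, pops in units:
        sub = aln.subset_populations([p for p in pops if p in aln.populations])
        if sub.n < 4:
            continue
        mm = mismatch_distribution(sub)
        if mm.counts[1:].sum() == 0:
            continue
        fit = fit_sudden_expansion(mm)
        fit = bootstrap_fit_pvalues(sub, fit, n_boot=n_boot, rng=rng)
        _, mya = expansion_time(fit.tau, rates)
        rows.append(
            {
                "lineage": label,
                "tau": fit.tau,
                "theta0": fit.theta0,
                "theta1": fit.theta1,
                "ssd": fit.ssd,
                "p_ssd": fit.p_ssd,
                "raggedness": fit.raggedness,
                "p_rag": fit.p_rag,
                "expansion_time_mya": mya,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(config.seed)
    aln, samples = read_alignment(config.fasta, config.samples)
    rates = RateParams(config.subs_rate, config.generation_time, aln.L)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_individuals": aln.n,
        "n_haplotypes": aln.k,
        "effective_length": aln.L,
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - stage-tagged diagnostics
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    div = _stage(
        "stats",
        lambda: diversity_table(aln, samples, rates, config.n_sims, rngs["stats"]),
    )
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    manifest["stages"]["stats"] = {"rows": len(div)}

    mis = _stage(
        "mismatch",
        lambda: mismatch_table(aln, samples, rates, config.n_boot, rngs["mismatch"]),
    )
    mis.to_csv(out / "mismatch.tsv", sep="\t", index=False)
    manifest["stages"]["mismatch"] = {"rows": len(mis)}

    def _amova():
        if config.groupings:
            return compare_groupings(
                aln, samples, list(config.groupings),
                n_perm=config.n_perm, rng=rngs["amova"],
            )
        res = amova(aln, samples, n_perm=config.n_perm, rng=rngs["amova"])
        return pd.DataFrame([res.as_row()])

    amv = _stage("amova", _amova)
    amv.to_csv(out / "amova.tsv", sep="\t", index=False)
    manifest["stages"]["amova"] = {"rows": len(amv)}

    def _network():
        limit = connection_limit(aln.L)
        net = build_network(aln, limit)
        net.write_edge_tsv(out / "network_edges.tsv")
        summary = net.component_summary()
        modal = modal_haplotype(net, aln)
        summary["modal_haplotype"] = summary["component"].map(modal)
        summary.to_csv(out / "network_components.tsv", sep="\t", index=False)
        return {
            "connection_limit": limit,
            "n_components": len(net.components),
            "n_loops": len(net.loops),
        }

    manifest["stages"]["network"] = _stage("network", _network)

    if config.tree is not None and config.refugia_thetas is not None:
        def _refugia():
            gen = Genealogy.from_newick(config.tree, is_path=True)
            g_of_pop = samples.group_of_population()
            pop_of = samples.population_of()
            labels = {t.label: g_of_pop[pop_of[t.label]] for t in gen.tips()}
            keep = set(config.refugia_groups)
            extra = set(labels.values()) - keep
            if extra:
                raise ValueError(
                    f"observed tree contains tips outside {sorted(keep)}: "
                    f"{sorted(extra)}; prune the genealogy to the tested lineages"
                )
            sizes = {
                g: sum(1 for v in labels.values() if v == g) for g in keep
            }
            single, multiple = refugial_models(
                config.refugia_thetas,
                subs_rate_per_myr=config.subs_rate,
                generation_time=config.generation_time,
                sample_sizes=sizes,
            )
            s_obs = slatkin_s(gen, labels)
            results = {}
            for model in (single, multiple):
                null = null_distribution(
                    model, n_sims=config.n_sims, rng=rngs["refugia"]
                )
                res = test_hypothesis(s_obs, null, model_label=model.label)
                results[model.label] = {
                    "observed_s": res.observed_s,
                    "ci95": list(res.ci95),
                    "decision": res.decision,
                }
                pd.DataFrame(
                    sorted(res.histogram().items()), columns=["s", "count"]
                ).to_csv(out / f"refugia_null_{model.label}.tsv", sep="\t", index=False)
            return results

        manifest["stages"]["refugia"] = _stage("refugia", _refugia)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
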