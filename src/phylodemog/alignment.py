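"""Alignment and sample-table handling.

Reads a pre-aligned FASTA of mtDNA sequences together with a TSV sample
table (individual -> population -> regional group), collapses identical
sequences into haplotypes, and exposes the haplotype-level view that every
downstream statistic in this package consumes.

Sites containing an ``N`` or a gap in *any* individual are excluded from
all analyses (complete deletion), so a single unambiguous effective length
``L`` applies to every per-site quantity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "MetadataError",
    "SampleTable",
    "HaplotypeAlignment",
    "read_alignment",
    "collapse_haplotypes",
    "segregating_sites",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"))
_MISSING = {"N", "-", "?"}


class AlignmentError(ValueError):
    """Raised for malformed alignments (e.g. unequal sequence lengths)."""


class MetadataError(ValueError):
    """Raised when sequences and the sample table are inconsistent."""


@dataclass(frozen=True)
class SampleTable:
    """Individual -> population -> regional group mapping.

    The group column is optional in the TSV; absent a grouping, each
    population forms its own group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"individual", "population"}
        if not required.issubset(df.columns):
            raise MetadataError(
                f"sample table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if "group" not in df.columns:
            df = df.assign(group=df["population"])
            object.__setattr__(self, "table", df)
        if df["individual"].duplicated().any():
            dups = df.loc[df["individual"].duplicated(), "individual"].tolist()
            raise MetadataError(f"duplicate individual ids: {dups}")
        pop_groups = df.groupby("population")["group"].nunique()
        bad = pop_groups[pop_groups > 1]
        if len(bad):
            raise MetadataError(
                f"populations mapped to more than one group: {list(bad.index)}"
            )

    @classmethod
    def read_tsv(cls, path: str | Path | io.IOBase) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def individuals(self) -> list[str]:
        return self.table["individual"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual"], self.table["population"]))

    def group_of_population(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("population")[["population", "group"]].values
        )


@dataclass
class HaplotypeAlignment:
    """Distinct haplotype sequences with per-population counts.

    Attributes
    ----------
    haplotype_ids:
        ``H1..Hk`` in order of first appearance in the input.
    sequences:
        ``(k, L)`` uint8 matrix over the retained sites, coded A=0 C=1 G=2 T=3.
    counts:
        DataFrame indexed by haplotype id, one integer column per population.
    excluded_sites:
        Original 0-based column indices removed by complete deletion.
    original_length:
        Number of columns in the input alignment before deletion.
    """

    haplotype_ids: list[str]
    sequences: np.ndarray
    counts: pd.DataFrame
    excluded_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    original_length: int | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.uint8)
        if self.sequences.ndim != 2:
            raise AlignmentError("sequences must be a 2-D haplotype x site matrix")
        if len(self.haplotype_ids) != self.sequences.shape[0]:
            raise AlignmentError("haplotype_ids and sequence rows disagree")
        k = len(self.haplotype_ids)
        if k > 1:
            # no two haplotypes may share the retained-site sequence
            seen = {self.sequences[i].tobytes() for i in range(k)}
            if len(seen) != k:
                raise AlignmentError("duplicate haplotype sequences after collapse")
        if self.original_length is None:
            self.original_length = self.sequences.shape[1] + len(self.excluded_sites)

    # -- basic dimensions -------------------------------------------------
    @property
    def k(self) -> int:
        """Number of distinct haplotypes."""
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        """Retained (analysed) sites."""
        return self.sequences.shape[1]

    @property
    def n(self) -> int:
        """Number of individuals (sum of counts)."""
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def haplotype_counts(self) -> np.ndarray:
        """Total count per haplotype, aligned with ``haplotype_ids``."""
        return self.counts.to_numpy().sum(axis=1).astype(int)

    def frequencies(self) -> np.ndarray:
        c = self.haplotype_counts()
        return c / c.sum()

    # -- derived matrices -------------------------------------------------
    def pairwise_differences(self) -> np.ndarray:
        """(k, k) matrix of raw nucleotide differences between haplotypes."""
        a = self.sequences
        return (a[:, None, :] != a[None, :, :]).sum(axis=2).astype(int)

    def sequence_strings(self) -> list[str]:
        return ["".join(_DECODE[row]) for row in self.sequences]

    # -- restriction ------------------------------------------------------
    def subset_populations(self, pops: Sequence[str]) -> "HaplotypeAlignment":
        """Alignment restricted to individuals of the given populations.

        Haplotypes absent from the subset are dropped; ids are preserved.
        """
        missing = [p for p in pops if p not in self.counts.columns]
        if missing:
            raise MetadataError(f"unknown populations: {missing}")
        sub = self.counts[list(pops)]
        keep = sub.to_numpy().sum(axis=1) > 0
        return HaplotypeAlignment(
            haplotype_ids=[h for h, f in zip(self.haplotype_ids, keep) if f],
            sequences=self.sequences[keep],
            counts=sub.loc[keep],
            excluded_sites=self.excluded_sites,
            original_length=self.original_length,
        )

    def expand_individuals(self) -> tuple[np.ndarray, list[str]]:
        """Individual-level view: (n,) haplotype row index and population labels."""
        hap_idx: list[int] = []
        pops: list[str] = []
        mat = self.counts.to_numpy()
        for i in range(self.k):
            for j, pop in enumerate(self.counts.columns):
                c = int(mat[i, j])
                hap_idx.extend([i] * c)
                pops.extend([pop] * c)
        return np.array(hap_idx, dtype=int), pops

    # -- IO ---------------------------------------------------------------
    def write_haplotype_table(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "sequence", self.sequence_strings())
        df.index.name = "haplotype"
        df.to_csv(path, sep="\t")


def _encode(seq: str, sid: str) -> np.ndarray:
    s = seq.upper()
    out = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = np.full(out.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[out == ord(base)] = code
    for base in _MISSING:
        codes[out == ord(base)] = 254
    if (codes == 255).any():
        bad = {chr(c) for c in out[codes == 255]}
        raise AlignmentError(f"sequence {sid!r} contains invalid characters {bad}")
    return codes


def collapse_haplotypes(
    records: Iterable[tuple[str, str]],
    population_of: Mapping[str, str],
) -> HaplotypeAlignment:
    """Collapse individual sequences into a :class:`HaplotypeAlignment`.

    ``records`` yields ``(individual_id, sequence)``; every id must be a key
    of ``population_of``. Columns with missing data anywhere are removed
    before the identity comparison, so two individuals are one haplotype iff
    they agree at all retained sites.
    """
    ids, rows = [], []
    for sid, seq in records:
        if sid not in population_of:
            raise MetadataError(f"sequence id {sid!r} missing from sample table")
        ids.append(sid)
        rows.append(_encode(seq, sid))
    if not ids:
        raise AlignmentError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences are not aligned: lengths {sorted(lengths)}")
    mat = np.vstack(rows)
    bad_cols = (mat == 254).any(axis=0)
    excluded = np.flatnonzero(bad_cols)
    mat = mat[:, ~bad_cols]

    pops = sorted({population_of[i] for i in ids})
    hap_of_key: dict[bytes, int] = {}
    hap_ids: list[str] = []
    hap_rows: list[np.ndarray] = []
    counts: list[dict[str, int]] = []
    for sid, row in zip(ids, mat):
        key = row.tobytes()
        if key not in hap_of_key:
            hap_of_key[key] = len(hap_ids)
            hap_ids.append(f"H{len(hap_ids) + 1}")
            hap_rows.append(row)
            counts.append({p: 0 for p in pops})
        counts[hap_of_key[key]][population_of[sid]] += 1
    count_df = pd.DataFrame(counts, index=hap_ids, columns=pops).astype(int)
    return HaplotypeAlignment(
        haplotype_ids=hap_ids,
        sequences=np.vstack(hap_rows),
        counts=count_df,
        excluded_sites=excluded,
        original_length=len(bad_cols),
    )


def read_alignment(
    fasta_path: str | Path,
    sample_table_path: str | Path | SampleTable,
) -> tuple[HaplotypeAlignment, SampleTable]:
    """Read a FASTA alignment plus sample TSV and collapse to haplotypes."""
    samples = (
        sample_table_path
        if isinstance(sample_table_path, SampleTable)
        else SampleTable.read_tsv(sample_table_path)
    )
    pop_of = samples.population_of()
    records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta"))
    aln = collapse_haplotypes(records, pop_of)
    return aln, samples


def segregating_sites(aln: HaplotypeAlignment) -> int:
    """Number of retained columns with two or more observed states.

    Haplotypes are weighted by presence only, so the count is invariant to
    haplotype frequencies.
    """
    if aln.k == 0:
        raise AlignmentError("empty alignment")
    if aln.k == 1:
        return 0
    return int((aln.sequences != aln.sequences[0]).any(axis=0).sum())


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")
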