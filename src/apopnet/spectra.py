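"""Somatic mutation tables, Boolean spectra, and Hamming-distance comparison.

Per-gene point-mutation counts (missense / synonymous / nonsense) are binarized
("mutated in at least one sample" -> 1), optionally combined across mutation
types, mapped onto the model's kinetic-parameter order through a
gene<->parameter table, and compared against a parameter-sensitivity spectrum
by Hamming distance.  Parameters tied to protein *production* are excluded
from the mapping: production rates reflect gene amplification/deletion rather
than point mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_TYPES = ("missense", "synonymous", "nonsense")

__all__ = [
    "MUTATION_TYPES",
    "MutationTable",
    "GeneParameterMap",
    "BooleanSpectrum",
    "SpectrumComparison",
    "SpectrumAlignmentError",
    "parse_mutation_table",
    "binarize",
    "combine",
    "project_to_parameters",
    "hamming",
    "read_gene_parameter_map",
    "write_gene_parameter_map",
]


class SpectrumAlignmentError(ValueError):
    """Two spectra had different id sequences; comparison refused."""


@dataclass
class MutationTable:
    """Integer mutation counts per gene and mutation type for one cancer."""

    cancer_type: str
    counts: pd.DataFrame  # index: gene; columns: MUTATION_TYPES; int counts

    def __post_init__(self):
        for t in MUTATION_TYPES:
            if t not in self.counts.columns:
                self.counts[t] = 0
        self.counts = self.counts[list(MUTATION_TYPES)].astype(int)
        if (self.counts < 0).any().any():
            raise ValueError("mutation counts must be >= 0")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class GeneParameterMap:
    """parameter id -> gene id(s); production parameters are excluded entirely."""

    entries: dict[str, list[str]]
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.entries = {
            p: ([g] if isinstance(g, str) else list(g)) for p, g in self.entries.items()
        }
        overlap = self.excluded & set(self.entries)
        if overlap:
            raise ValueError(f"excluded parameters must not be mapped: {sorted(overlap)}")


@dataclass
class BooleanSpectrum:
    ids: list[str]
    bits: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if len(self.ids) != self.bits.shape[0]:
            raise ValueError("ids and bits must have the same length")

    def restrict(self, ids: list[str]) -> "BooleanSpectrum":
        """Subset to the given ids, in the given order."""
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise SpectrumAlignmentError(f"ids absent from spectrum: {missing}")
        return BooleanSpectrum(list(ids), self.bits[[pos[i] for i in ids]],
                               self.provenance)


@dataclass
class SpectrumComparison:
    hd: int
    n: int
    mismatches: list[str]


def parse_mutation_table(path: str | Path, cancer_type: str) -> MutationTable:
    """Read a TSV mutation table in either of two dialects.

    Dialect A (pre-aggregated): columns ``gene, missense, synonymous, nonsense``
    with integer counts; repeated genes are summed.
    Dialect B (per-sample rows): columns ``gene, mutation_type`` with one row
    per mutated sample; rows are counted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["gene", *MUTATION_TYPES])
    if df.empty and "gene" not in df.columns:
        df = pd.DataFrame(columns=["gene", *MUTATION_TYPES])
    cols = set(df.columns)
    if "gene" not in cols:
        raise ValueError(f"{path}: expected a 'gene' column, found {sorted(cols)}")

    if "mutation_type" in cols:  # dialect B
        bad = ~df["mutation_type"].isin(MUTATION_TYPES)
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # 1-based incl. header
            raise ValueError(
                f"{path}:{line}: unknown mutation type "
                f"{df['mutation_type'][bad].iloc[0]!r}"
            )
        counts = (
            df.groupby(["gene", "mutation_type"]).size().unstack(fill_value=0)
        )
        counts = counts.reindex(columns=list(MUTATION_TYPES), fill_value=0)
        counts.columns.name = None
    else:  # dialect A
        missing = [t for t in MUTATION_TYPES if t not in cols]
        if missing:
            raise ValueError(f"{path}: missing count columns {missing}")
        for i, row in df.iterrows():
            for t in MUTATION_TYPES:
                try:
                    v = int(row[t])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}:{i + 2}: non-integer count {row[t]!r} in {t}"
                    ) from None
                if v < 0:
                    raise ValueError(f"{path}:{i + 2}: negative count in {t}")
        counts = (
            df.assign(**{t: df[t].astype(int) for t in MUTATION_TYPES})
            .groupby("gene")[list(MUTATION_TYPES)]
            .sum()
        )
    counts.index.name = "gene"
    return MutationTable(cancer_type=cancer_type, counts=counts)


def binarize(table: MutationTable, mutation_type: str) -> BooleanSpectrum:
    """Per-gene bit: 1 iff at least one sample carries this mutation type."""
    if mutation_type not in MUTATION_TYPES:
        raise ValueError(f"unknown mutation type {mutation_type!r}")
    bits = (table.counts[mutation_type] >= 1).to_numpy()
    return BooleanSpectrum(table.genes, bits, provenance=f"mutation-type:{mutation_type}")


def _parse_rule(rule: str) -> tuple[str, tuple[str, ...]]:
    if rule.startswith("two_of:"):
        types = tuple(t.strip() for t in rule.split(":", 1)[1].split(","))
        if len(types) != 2 or any(t not in MUTATION_TYPES for t in types):
            raise ValueError(f"two_of rule needs two known types, got {rule!r}")
        return "two_of", types
    if rule in ("three_at_least_2", "three_at_least_1"):
        return rule, MUTATION_TYPES
    raise ValueError(f"unknown combination rule {rule!r}")


def combine(table: MutationTable, rule: str) -> BooleanSpectrum:
    """Combined-action Boolean spectrum over genes.

    ``two_of:typeA,typeB``   — 1 if at least one of the two types is mutated;
    ``three_at_least_2``     — 1 if at least two of the three types are mutated;
    ``three_at_least_1``     — 1 if at least one of the three types is mutated.
    """
    kind, types = _parse_rule(rule)
    per_type = np.stack([(table.counts[t] >= 1).to_numpy() for t in types])
    if kind == "two_of":
        bits = per_type.any(axis=0)
    elif kind == "three_at_least_2":
        bits = per_type.sum(axis=0) >= 2
    else:
        bits = per_type.any(axis=0)
    return BooleanSpectrum(table.genes, bits, provenance=f"combined-rule:{rule}")


def project_to_parameters(
    gene_spectrum: BooleanSpectrum,
    gmap: GeneParameterMap,
    parameter_order: list[str],
    allow_multi: bool = False,
) -> BooleanSpectrum:
    """Map a gene spectrum onto parameter order; excluded parameters are dropped.

    A parameter mapped to several genes (requires ``allow_multi``) takes the OR
    of their bits.
    """
    gene_bit = dict(zip(gene_spectrum.ids, gene_spectrum.bits))
    out_ids, out_bits, unmapped = [], [], []
    for pid in parameter_order:
        if pid in gmap.excluded:
            continue
        genes = gmap.entries.get(pid)
        if not genes:
            unmapped.append(pid)
            continue
        if len(genes) > 1 and not allow_multi:
            raise ValueError(
                f"parameter {pid} maps to multiple genes {genes}; "
                "pass allow_multi=True to OR their bits"
            )
        missing = [g for g in genes if g not in gene_bit]
        if missing:
            unmapped.append(pid)
            continue
        out_ids.append(pid)
        out_bits.append(any(gene_bit[g] for g in genes))
    if unmapped:
        raise ValueError(f"unmapped non-excluded parameters: {unmapped}")
    return BooleanSpectrum(out_ids, np.array(out_bits, dtype=bool),
                           provenance=gene_spectrum.provenance)


def hamming(a: BooleanSpectrum, b: BooleanSpectrum) -> SpectrumComparison:
    """Number of positions at which two equal-length, identically-ordered
    Boolean spectra differ."""
    if a.ids != b.ids:
        raise SpectrumAlignmentError(
            "spectra have different id sequences; align explicitly before comparing"
        )
    diff = a.bits != b.bits
    return SpectrumComparison(
        hd=int(diff.sum()), n=len(a.ids),
        mismatches=[i for i, d in zip(a.ids, diff) if d],
    )


def read_gene_parameter_map(path: str | Path) -> GeneParameterMap:
    """TSV with columns ``parameter, gene``; gene ``-`` marks an excluded
    (production-process) parameter.  A parameter may appear on several rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    entries: dict[str, list[str]] = {}
    excluded: set[str] = set()
    for _, row in df.iterrows():
        p, g = row["parameter"], row["gene"]
        if g == "-" or (isinstance(g, float) and pd.isna(g)):
            excluded.add(p)
        else:
            entries.setdefault(p, []).append(g)
    return GeneParameterMap(entries=entries, excluded=excluded)


def write_gene_parameter_map(gmap: GeneParameterMap, path: str | Path) -> None:
    rows = [(p, g) for p, genes in gmap.entries.items() for g in genes]
    rows += [(p, "-") for p in sorted(gmap.excluded)]
    pd.DataFrame(rows, columns=["parameter", "gene"]).to_csv(
        path, sep="\t", index=False
    )
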