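"""Ortholog-group tables, fragmentation-correction filtering, and copy-number
divergence.

The comparison unit throughout the package is the orthology group (OG): a
cluster of genes across species descended from one ancestral gene, as
produced by standard orthology inference. Copy-number divergence between a
focal species group and a comparator group is summarised per OG by the mean
copy-number difference

    MDelta(OG) = mean(copies over group A) - mean(copies over group B),

and OGs are classified three ways: duplicated (MDelta >= dup_threshold,
default 1, i.e. at least one extra copy on average in the focal lineage),
background (MDelta <= bg_threshold, default 0) and intermediate (excluded
from two-class association tests).

Fragmented genome assemblies inflate copy counts because partial gene models
are counted as extra copies; the coverage filter removes genes whose protein
covers less than a minimum fraction (default 60%) of the reference-species
ortholog before any copy counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologyTable",
    "read_orthology",
    "read_coverage",
    "apply_coverage_filter",
    "copy_number_matrix",
    "mean_delta",
    "classify_duplication",
    "DuplicationClass",
]


class OrthologyTable:
    """OG identifiers mapped to per-species gene lists.

    Parameters
    ----------
    groups:
        Mapping ``og_id -> {species: [gene ids]}``. Missing species mean
        zero copies.
    species:
        The full species universe. Defaults to the union seen in ``groups``;
        passing it explicitly preserves species that lost all genes.
    """

    def __init__(self, groups: dict[str, dict[str, list[str]]], species=None):
        self.groups = {og: {sp: list(gs) for sp, gs in d.items()} for og, d in groups.items()}
        seen = sorted({sp for d in self.groups.values() for sp in d})
        self.species = list(species) if species is not None else seen
        missing = set(seen) - set(self.species)
        if missing:
            raise ValueError(f"species in table but not in species list: {sorted(missing)}")
        self._validate()

    def _validate(self) -> None:
        owner: dict[str, str] = {}
        for og, d in self.groups.items():
            for sp, genes in d.items():
                for g in genes:
                    if g in owner:
                        raise ValueError(
                            f"gene {g!r} appears in both {owner[g]!r} and {og!r}"
                        )
                    owner[g] = og

    @property
    def og_ids(self) -> list[str]:
        return list(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def genes_of(self, species: str) -> list[str]:
        return [g for d in self.groups.values() for g in d.get(species, [])]

    def gene_to_og(self) -> pd.Series:
        """Flat gene -> OG map covering every species."""
        idx, vals = [], []
        for og, d in self.groups.items():
            for genes in d.values():
                idx.extend(genes)
                vals.extend([og] * len(genes))
        return pd.Series(vals, index=idx, name="og_id")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def read_tsv(cls, path) -> "OrthologyTable":
        """Read the long TSV dialect: columns og_id, species, genes
        (comma-separated; an empty cell means zero copies)."""
        groups: dict[str, dict[str, list[str]]] = {}
        species: list[str] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["og_id", "species", "genes"]:
                raise ValueError(
                    f"{path}: expected header og_id<TAB>species<TAB>genes, got {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
                og, sp, cell = parts
                genes = [g for g in cell.split(",") if g]
                groups.setdefault(og, {})[sp] = genes
                if sp not in species:
                    species.append(sp)
        return cls(groups, species=species)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("og_id\tspecies\tgenes\n")
            for og in self.groups:
                for sp in self.species:
                    genes = self.groups[og].get(sp, [])
                    fh.write(f"{og}\t{sp}\t{','.join(genes)}\n")


def read_orthology(path) -> OrthologyTable:
    """Read an orthology table (see :meth:`OrthologyTable.read_tsv`)."""
    return OrthologyTable.read_tsv(path)


def read_coverage(path) -> pd.Series:
    """Read a gene -> coverage-fraction table (TSV: gene, coverage)."""
    df = pd.read_csv(path, sep="\t")
    cov = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    _check_coverage(cov)
    return cov


def _check_coverage(cov: pd.Series) -> None:
    if cov.index.has_duplicates:
        dups = cov.index[cov.index.duplicated()].tolist()
        raise ValueError(f"duplicate genes in coverage table: {dups[:5]}")
    if ((cov < 0) | (cov > 1)).any():
        raise ValueError("coverage fractions must lie in [0, 1]")


@dataclass
class CoverageFilterReport:
    removed_low_coverage: list[str]
    removed_no_record: list[str]
    dropped_ogs: list[str]


def apply_coverage_filter(
    table: OrthologyTable,
    coverage: pd.Series,
    min_cov: float = 0.60,
    species=None,
) -> tuple[OrthologyTable, CoverageFilterReport]:
    """Drop genes whose protein covers less than ``min_cov`` of the
    reference ortholog (boundary inclusive: coverage == min_cov is kept).

    ``species`` limits filtering to those species (default: all). Genes of a
    filtered species with no coverage record are treated as unalignable and
    removed, with a warning. OGs emptied in every species are dropped.
    """
    if not 0 < min_cov <= 1:
        raise ValueError(f"min_cov must lie in (0, 1], got {min_cov}")
    _check_coverage(coverage)
    filt_sp = set(species) if species is not None else set(table.species)
    removed_low, removed_norec, dropped = [], [], []
    groups: dict[str, dict[str, list[str]]] = {}
    for og, d in table.groups.items():
        new_d: dict[str, list[str]] = {}
        for sp, genes in d.items():
            if sp not in filt_sp:
                new_d[sp] = list(genes)
                continue
            kept = []
            for g in genes:
                if g not in coverage.index:
                    removed_norec.append(g)
                elif coverage[g] >= min_cov:
                    kept.append(g)
                else:
                    removed_low.append(g)
            new_d[sp] = kept
        if any(new_d.values()):
            groups[og] = new_d
        else:
            dropped.append(og)
    if removed_norec:
        logger.warning(
            "%d genes had no coverage record and were removed as unalignable",
            len(removed_norec),
        )
    report = CoverageFilterReport(removed_low, removed_norec, dropped)
    return OrthologyTable(groups, species=table.species), report


def copy_number_matrix(table: OrthologyTable) -> pd.DataFrame:
    """OG x species matrix of gene copy counts (list lengths)."""
    data = {
        sp: [len(table.groups[og].get(sp, ())) for og in table.groups]
        for sp in table.species
    }
    return pd.DataFrame(data, index=pd.Index(table.og_ids, name="og_id"), dtype=np.int64)


def mean_delta(copies: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Per-OG mean copy-number difference, group A minus group B.

    Means are taken over all group members; a species absent from an OG
    contributes zero copies. Antisymmetric under a group swap.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    missing = (set(group_a) | set(group_b)) - set(copies.columns)
    if missing:
        raise ValueError(f"species not in copy matrix: {sorted(missing)}")
    md = copies[group_a].mean(axis=1) - copies[group_b].mean(axis=1)
    md.name = "mdelta"
    return md


@dataclass
class DuplicationClass:
    """Three-way duplication classification of OGs by MDelta."""

    labels: pd.Series  # og_id -> {"duplicated", "background", "intermediate"}
    dup_threshold: float
    bg_threshold: float

    def ogs(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in ("duplicated", "background", "intermediate")}


def classify_duplication(
    mdelta: pd.Series, dup_threshold: float = 1.0, bg_threshold: float = 0.0
) -> DuplicationClass:
    """Classify OGs as duplicated (MDelta >= dup_threshold), background
    (MDelta <= bg_threshold) or intermediate (excluded from two-class
    tests)."""
    if not dup_threshold > bg_threshold:
        raise ValueError("dup_threshold must exceed bg_threshold")
    labels = pd.Series("intermediate", index=mdelta.index)
    labels[mdelta >= dup_threshold] = "duplicated"
    labels[mdelta <= bg_threshold] = "background"
    return DuplicationClass(labels, dup_threshold, bg_threshold)
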