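"""Comparison of 2-3 candidate site lists from any detection methods.

Candidate lists (e.g. the gap/masking detector vs. Wilcoxon vs. limma
output) are partitioned into the 2^k - 1 exact-membership cells of their
Venn diagram, both at the site level and — after mapping sites to genes
through the array annotation — at the gene level. A median-difference
post-filter (default 0.2 beta units, the conventional threshold for
bisulfite-sequencing verifiability) can be applied to any list before
comparison, and a median-vs-median scatterplot visualises where each
cell's sites fall.

Gene-level cells are computed from per-list gene sets (the genes hit by
any site of a list), not by mapping each site cell separately: two lists
sharing no sites can still share a gene.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import BetaDataset, GroupDesign, NimblError, ProbeAnnotation

__all__ = [
    "ComparisonPartition",
    "partition_sites",
    "partition_genes",
    "median_diff_filter",
    "scatter_medians",
]

CellKey = tuple[str, ...]


def _cells_of(names: Sequence[str]) -> list[CellKey]:
    """All nonempty subsets of ``names``, each in input order."""
    keys: list[CellKey] = []
    for r in range(1, len(names) + 1):
        keys.extend(itertools.combinations(names, r))
    return keys


def _exact_partition(sets: Mapping[str, set[str]]) -> dict[CellKey, set[str]]:
    names = list(sets)
    cells: dict[CellKey, set[str]] = {key: set() for key in _cells_of(names)}
    for item in set().union(*sets.values()):
        key = tuple(n for n in names if item in sets[n])
        cells[key].add(item)
    return cells


@dataclass
class ComparisonPartition:
    """Exact-membership partition of 2-3 named site lists.

    ``site_cells`` maps each nonempty subset of list names (as a tuple in
    input order) to the site IDs belonging to exactly those lists; cells
    are pairwise disjoint and cover the union of the inputs.
    ``gene_cells`` holds the same structure for genes once
    :func:`partition_genes` has run.
    """

    list_names: tuple[str, ...]
    site_cells: dict[CellKey, set[str]]
    gene_cells: dict[CellKey, set[str]] | None = None

    def list_sites(self, name: str) -> set[str]:
        """Reconstruct one input list from the cells containing it."""
        return set().union(
            *(ids for key, ids in self.site_cells.items() if name in key)
        ) if self.site_cells else set()

    def counts(self, level: str = "site") -> dict[CellKey, int]:
        cells = self.site_cells if level == "site" else self.gene_cells
        if cells is None:
            raise NimblError("gene cells not computed yet; run partition_genes")
        return {key: len(ids) for key, ids in cells.items()}

    def to_frame(self, level: str = "site") -> pd.DataFrame:
        """Tabular view: one row per cell with its count and members."""
        cells = self.site_cells if level == "site" else self.gene_cells
        if cells is None:
            raise NimblError("gene cells not computed yet; run partition_genes")
        rows = [
            {"cell": "+".join(key), "n": len(ids), "members": ";".join(sorted(ids))}
            for key, ids in cells.items()
        ]
        return pd.DataFrame(rows)


def partition_sites(lists: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]]) -> ComparisonPartition:
    """Partition 2-3 named site-ID lists into exact-membership cells."""
    if not isinstance(lists, Mapping):
        names = [name for name, _ in lists]
        if len(set(names)) != len(names):
            raise NimblError(f"duplicate list name among {names}")
        lists = dict(lists)
    if not 2 <= len(lists) <= 3:
        raise NimblError(f"need 2 or 3 lists, got {len(lists)}")
    sets = {name: set(ids) for name, ids in lists.items()}
    return ComparisonPartition(
        list_names=tuple(sets),
        site_cells=_exact_partition(sets),
    )


def partition_genes(partition: ComparisonPartition, ann: ProbeAnnotation) -> ComparisonPartition:
    """Fill ``gene_cells``: per-list gene sets, then exact-membership cells.

    A list's gene set contains every gene annotated to any of its sites.
    Sites absent from the annotation contribute no genes; their count is
    reported in a warning.
    """
    gene_sets: dict[str, set[str]] = {}
    unannotated: set[str] = set()
    for name in partition.list_names:
        genes: set[str] = set()
        for site_id in partition.list_sites(name):
            if site_id not in ann:
                unannotated.add(site_id)
                continue
            genes.update(g for g in ann.genes_of(site_id) if g)
        gene_sets[name] = genes
    if unannotated:
        warnings.warn(f"{len(unannotated)} site(s) had no annotation and map to no gene")
    partition.gene_cells = _exact_partition(gene_sets)
    return partition


def median_diff_filter(
    site_ids: Iterable[str],
    ds: BetaDataset,
    design: GroupDesign,
    min_diff: float = 0.2,
) -> set[str]:
    """Keep sites whose absolute group-median beta difference >= ``min_diff``.

    Medians are taken over all non-missing samples of each group (no
    masking information is assumed — lists from any method are treated
    uniformly). Sites absent from the dataset are dropped with a warning.
    The default 0.2 is the difference generally verifiable by bisulfite
    sequencing.
    """
    if not (0.0 <= min_diff <= 1.0):
        raise NimblError(f"min_diff must be in [0, 1], got {min_diff}")
    design.validate_against(ds)
    site_ids = list(site_ids)
    known = [s for s in site_ids if s in ds.beta.index]
    if len(known) < len(site_ids):
        warnings.warn(f"{len(site_ids) - len(known)} site(s) not in dataset were dropped")
    if not known:
        return set()
    sub = ds.beta.loc[known]
    med1 = sub[design.samples_in(design.group_names[0])].median(axis=1, skipna=True)
    med2 = sub[design.samples_in(design.group_names[1])].median(axis=1, skipna=True)
    diff = (med2 - med1).abs()
    return set(diff.index[diff >= min_diff])


def scatter_medians(
    ds: BetaDataset,
    design: GroupDesign,
    partition: ComparisonPartition,
    path: str | Path,
) -> None:
    """Scatter group-1 vs group-2 median beta per site, coloured by cell.

    Sites on the diagonal have zero median difference; the legend gives the
    per-cell counts. Sites in the partition but absent from the dataset are
    silently omitted from the plot.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    design.validate_against(ds)
    g1 = design.samples_in(design.group_names[0])
    g2 = design.samples_in(design.group_names[1])
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10")
    for i, (key, ids) in enumerate(partition.site_cells.items()):
        present = [s for s in ids if s in ds.beta.index]
        label = f"{'+'.join(key)} ({len(ids)})"
        if present:
            sub = ds.beta.loc[present]
            x = sub[g1].median(axis=1, skipna=True)
            y = sub[g2].median(axis=1, skipna=True)
            ax.scatter(x, y, s=8, alpha=0.6, color=cmap(i % 10), label=label)
        else:
            ax.scatter([], [], s=8, color=cmap(i % 10), label=label)
    ax.plot([0, 1], [0, 1], color="grey", linewidth=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"median beta, {design.group_names[0]}")
    ax.set_ylabel(f"median beta, {design.group_names[1]}")
    ax.set_title("Group medians by comparison cell")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
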