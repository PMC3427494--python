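"""Core data containers shared by every module.

The central objects are:

* :class:`BetaDataset` — a sites × samples matrix of beta values (proportion
  methylated, in [0, 1]) with a parallel matrix of detection p-values.
* :class:`SignalDataset` — raw methylated/unmethylated hybridization
  intensities, convertible to beta values.
* :class:`ProbeAnnotation` — per-site genomic context from an Infinium
  manifest: chromosome, position, (gene, region) assignments, CpG-island
  relation, probe design type and probe sequence.
* :class:`GroupDesign` — a two-group sample design with per-group masking
  limits and optional beta-range constraints.
* :class:`DMRecord` — one detected differentially methylated site.

Matrices are stored as pandas DataFrames indexed by probe ID with sample
names as columns; missing measurements are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NimblError",
    "DimensionMismatchError",
    "GroupExhaustedError",
    "REGION_LABELS",
    "ISLAND_RELATIONS",
    "AUTOSOMES",
    "BetaDataset",
    "SignalDataset",
    "ProbeAnnotation",
    "GroupDesign",
    "DMRecord",
]


class NimblError(Exception):
    """Base class for structured errors raised by this package."""


class DimensionMismatchError(NimblError):
    """Two parallel matrices disagree in shape or labelling."""


class GroupExhaustedError(NimblError):
    """Masking or missing values removed every sample of a group at a site."""


#: Gene-region vocabulary used on Infinium 450k manifests.
REGION_LABELS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

#: Relation of a probe to the nearest CpG island.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Human autosome labels as used in manifests.
AUTOSOMES = tuple(str(i) for i in range(1, 23))


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dup = labels[labels.duplicated()][0]
        raise NimblError(f"duplicate {what} {dup!r}")


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame, name_a: str, name_b: str) -> None:
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"{name_a} is {a.shape[0]}x{a.shape[1]} but {name_b} is "
            f"{b.shape[0]}x{b.shape[1]}"
        )
    if not a.index.equals(b.index):
        off = a.index.symmetric_difference(b.index)
        bad = off[0] if len(off) else a.index[(a.index != b.index).argmax()]
        raise DimensionMismatchError(
            f"site IDs of {name_a} and {name_b} differ (first offender: {bad!r})"
        )
    if not a.columns.equals(b.columns):
        off = a.columns.symmetric_difference(b.columns)
        bad = off[0] if len(off) else a.columns[(a.columns != b.columns).argmax()]
        raise DimensionMismatchError(
            f"sample names of {name_a} and {name_b} differ (first offender: {bad!r})"
        )


@dataclass
class BetaDataset:
    """Beta values and detection p-values for a set of sites and samples.

    Parameters
    ----------
    beta
        Sites × samples matrix of methylation proportions in [0, 1];
        NaN marks a missing measurement.
    detection_p
        Matrix of detection p-values with the same index and columns;
        all-NaN when the input carried no p-values.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        self.detection_p = self.detection_p.astype(float)
        _check_unique(self.beta.index, "site ID")
        _check_unique(self.beta.columns, "sample name")
        _check_aligned(self.beta, self.detection_p, "beta", "detection_p")
        vals = self.beta.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise NimblError(
                f"beta value {vals[i, j]!r} outside [0, 1] at site "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        pv = self.detection_p.to_numpy()
        with np.errstate(invalid="ignore"):
            badp = (pv < 0.0) | (pv > 1.0)
        if badp.any():
            i, j = np.argwhere(badp)[0]
            raise NimblError(
                f"detection p-value {pv[i, j]!r} outside [0, 1] at site "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )

    @property
    def site_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_sites(self, site_ids: Sequence[str]) -> "BetaDataset":
        """Return a new dataset restricted to ``site_ids`` (order as given)."""
        return BetaDataset(self.beta.loc[list(site_ids)], self.detection_p.loc[list(site_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaDataset":
        """Return a new dataset restricted to ``sample_ids`` (order as given)."""
        cols = list(sample_ids)
        return BetaDataset(self.beta[cols], self.detection_p[cols])

    def copy(self) -> "BetaDataset":
        return BetaDataset(self.beta.copy(), self.detection_p.copy())


@dataclass
class SignalDataset:
    """Raw per-site methylated/unmethylated intensities plus detection p-values."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        self.methylated = self.methylated.astype(float)
        self.unmethylated = self.unmethylated.astype(float)
        self.detection_p = self.detection_p.astype(float)
        _check_unique(self.methylated.index, "site ID")
        _check_unique(self.methylated.columns, "sample name")
        _check_aligned(self.methylated, self.unmethylated, "methylated", "unmethylated")
        _check_aligned(self.methylated, self.detection_p, "methylated", "detection_p")
        for name, frame in (("methylated", self.methylated), ("unmethylated", self.unmethylated)):
            vals = frame.to_numpy()
            finite = np.isfinite(vals)
            with np.errstate(invalid="ignore"):
                if (vals[finite] < 0).any() or np.isinf(vals).any():
                    raise NimblError(f"{name} intensities must be finite and >= 0")

    @property
    def site_ids(self) -> list[str]:
        return list(self.methylated.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylated.columns)


class ProbeAnnotation:
    """Per-site genomic context, indexed by probe ID.

    Wraps a DataFrame with columns ``chromosome`` (str), ``position``
    (1-based int), ``gene_assignments`` (list of deduplicated
    ``(gene, region)`` tuples), ``island_relation``, ``design_type`` and
    ``probe_sequence`` (50-mer or None).
    """

    COLUMNS = (
        "chromosome",
        "position",
        "gene_assignments",
        "island_relation",
        "design_type",
        "probe_sequence",
    )

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise NimblError(f"annotation table lacks columns {missing}")
        self.table = table
        if validate:
            self._validate()
        self._gene_index: dict[str, set[str]] | None = None

    def _validate(self) -> None:
        _check_unique(self.table.index, "site ID")
        valid_regions = set(REGION_LABELS)
        for site_id, pairs in self.table["gene_assignments"].items():
            seen = set()
            for pair in pairs:
                if pair in seen:
                    raise NimblError(f"duplicate (gene, region) pair {pair} at site {site_id!r}")
                seen.add(pair)
                if pair[1] not in valid_regions:
                    raise NimblError(
                        f"unknown gene-region label {pair[1]!r} at site {site_id!r}"
                    )
        bad_rel = set(self.table["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_rel:
            raise NimblError(f"unknown CpG-island relation label(s) {sorted(bad_rel)}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.table.index

    def site(self, site_id: str) -> pd.Series:
        """Annotation row for one probe."""
        return self.table.loc[site_id]

    def genes_of(self, site_id: str) -> list[str]:
        """Distinct gene symbols assigned to a probe (annotation order)."""
        seen: dict[str, None] = {}
        for gene, _region in self.table.at[site_id, "gene_assignments"]:
            seen.setdefault(gene, None)
        return list(seen)

    def gene_to_sites(self) -> Mapping[str, set[str]]:
        """Map each gene symbol to the set of probes annotated to it (cached)."""
        if self._gene_index is None:
            index: dict[str, set[str]] = {}
            for site_id, pairs in self.table["gene_assignments"].items():
                for gene, _region in pairs:
                    index.setdefault(gene, set()).add(site_id)
            self._gene_index = index
        return self._gene_index

    def genes(self) -> list[str]:
        return sorted(self.gene_to_sites())

    def subset(self, site_ids: Iterable[str]) -> "ProbeAnnotation":
        ids = [s for s in site_ids if s in self.table.index]
        return ProbeAnnotation(self.table.loc[ids], validate=False)


@dataclass
class GroupDesign:
    """Assignment of samples to exactly two named groups.

    ``mask_limits`` gives the maximum number of samples that may be masked
    per group (one value per group, in ``group_names`` order), and
    ``range_constraints`` optionally restricts the unmasked beta values of a
    group to a closed interval ``[lo, hi]`` — e.g. requiring the normal
    group to stay hypomethylated.
    """

    group_names: tuple[str, str]
    assignment: Mapping[str, str]
    mask_limits: tuple[int, int] = (0, 0)
    range_constraints: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.group_names = tuple(self.group_names)  # type: ignore[assignment]
        if len(self.group_names) != 2 or len(set(self.group_names)) != 2:
            raise NimblError("a design needs exactly two distinct group names")
        extra = set(self.assignment.values()) - set(self.group_names)
        if extra:
            raise NimblError(f"sample(s) assigned to unknown group(s) {sorted(extra)}")
        for g in self.group_names:
            if not self.samples_in(g):
                raise NimblError(f"group {g!r} has no samples")
        if len(self.mask_limits) != 2 or any(m < 0 for m in self.mask_limits):
            raise NimblError("mask_limits must be two non-negative integers")
        for g, m in zip(self.group_names, self.mask_limits):
            if m >= len(self.samples_in(g)):
                raise NimblError(
                    f"mask limit {m} for group {g!r} would allow masking the "
                    f"entire group of {len(self.samples_in(g))} samples"
                )
        if self.range_constraints:
            for g, (lo, hi) in self.range_constraints.items():
                if g not in self.group_names:
                    raise NimblError(f"range constraint for unknown group {g!r}")
                if not (0.0 <= lo <= hi <= 1.0):
                    raise NimblError(
                        f"range constraint [{lo}, {hi}] for group {g!r} is not a "
                        "sub-interval of [0, 1]"
                    )

    def samples_in(self, group: str) -> list[str]:
        """Sample IDs assigned to ``group`` in assignment order."""
        return [s for s, g in self.assignment.items() if g == group]

    def mask_limit(self, group: str) -> int:
        return self.mask_limits[self.group_names.index(group)]

    def with_mask_limits(self, m1: int, m2: int) -> "GroupDesign":
        return replace(self, mask_limits=(m1, m2))

    def validate_against(self, ds: BetaDataset) -> None:
        missing = [s for s in self.assignment if s not in ds.beta.columns]
        if missing:
            raise NimblError(f"design sample(s) absent from dataset: {missing[:5]}")


@dataclass
class DMRecord:
    """One differentially methylated site as detected by the core module.

    ``beta_val_dist`` is the gap between the nearest unmasked beta values of
    the two (non-overlapping) groups; ``median_diff`` the absolute
    difference of the unmasked group medians; ``score`` equals
    ``2 * beta_val_dist - median_diff``. ``masked`` lists the masked sample
    IDs per group; any masking flags the site as rescued rather than
    natively separated.
    """

    site_id: str
    beta_val_dist: float
    median_diff: float
    score: float
    masked: Mapping[str, list[str]]
    direction: str  # "hyper_in_group2" | "hypo_in_group2"
    rank: int = 0

    @property
    def n_masked(self) -> dict[str, int]:
        return {g: len(ids) for g, ids in self.masked.items()}

    @property
    def total_masked(self) -> int:
        return sum(len(ids) for ids in self.masked.values())

    @property
    def flagged(self) -> bool:
        """True when detection required masking (rescued site)."""
        return self.total_masked > 0
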