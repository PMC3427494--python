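"""Synthetic Infinium-like datasets with planted ground truth.

The generator emulates the features of a two-group 450k-style beta-value
matrix that the rest of the package exercises:

* sites fall into classes — null-unmethylated (mean ~0.10),
  null-methylated (~0.90), null-intermediate (~0.50) and a planted
  differentially methylated class whose group means are separated by an
  effect ``delta`` (alternating hyper/hypo direction);
* betas are drawn from Beta distributions parameterised by
  ``(mean, concentration)`` via ``a = mean*c``, ``b = (1-mean)*c``, which
  pins the planted medians directly;
* a configurable number of "heterogeneous" samples per group (the
  tumor-contamination scenario: e.g. a resected tumor carrying normal
  tissue) have their planted-class betas shifted toward the other group's
  mean by a fraction ``s``;
* missing betas and detection-p failures are injected at stated rates;
* a fabricated annotation assigns sites round-robin to genes, gene
  regions, CpG-island relations and chromosomes so that gene summaries,
  profiles and list comparisons are exercisable without any download.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    BetaDataset,
    GroupDesign,
    ISLAND_RELATIONS,
    NimblError,
    ProbeAnnotation,
    REGION_LABELS,
)

__all__ = ["SimConfig", "SimTruth", "simulate", "inject_low_quality", "worked_example_dataset"]

SITE_CLASSES = ("null_unmethylated", "null_methylated", "null_intermediate", "dm_planted")
_NULL_MEANS = {"null_unmethylated": 0.10, "null_methylated": 0.90, "null_intermediate": 0.50}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror a small clinical two-group 450k comparison: 8 + 8
    samples, 10,000 sites of which 10% carry a planted group-median
    difference of 0.5, tight within-class variation (Beta concentration
    200, i.e. s.d. ≈ 0.03 at the extremes), 1% missing cells and 0.5%
    detection failures; contamination off unless requested.
    """

    n_sites: int = 10_000
    n_per_group: tuple[int, int] = (8, 8)
    mixture: tuple[float, float, float, float] = (0.30, 0.30, 0.30, 0.10)
    effect: float = 0.5
    concentration: float = 200.0
    contamination_per_group: tuple[int, int] = (0, 0)
    contamination_shift: float = 1.0
    missing_rate: float = 0.01
    detection_fail_rate: float = 0.005
    group_names: tuple[str, str] = ("normal", "tumor")
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise NimblError(f"mixture proportions must sum to 1, got {self.mixture}")
        if not (0.0 < self.effect < 1.0):
            raise NimblError(f"effect must be in (0, 1), got {self.effect}")
        for rate in (self.missing_rate, self.detection_fail_rate, self.contamination_shift):
            if not (0.0 <= rate <= 1.0):
                raise NimblError(f"rates and shift must be in [0, 1], got {rate}")
        for k, n in zip(self.contamination_per_group, self.n_per_group):
            if k >= n:
                raise NimblError(
                    f"contamination count {k} must be below the group size {n}"
                )


@dataclass
class SimTruth:
    """Planted ground truth: per-site class/means/DM flag, per-sample flags."""

    site_table: pd.DataFrame  # class_label, mean_group1, mean_group2, is_dm
    sample_table: pd.DataFrame  # group, contaminated

    @property
    def dm_sites(self) -> set[str]:
        return set(self.site_table.index[self.site_table["is_dm"]])

    @property
    def null_sites(self) -> set[str]:
        return set(self.site_table.index[~self.site_table["is_dm"]])


def _class_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_dm = round(cfg.n_sites * cfg.mixture[3])
    n_rest = cfg.n_sites - n_dm
    null_props = np.array(cfg.mixture[:3], dtype=float)
    null_props /= null_props.sum() if null_props.sum() else 1.0
    counts = np.floor(null_props * n_rest).astype(int)
    # distribute the rounding remainder over the null classes in order
    for i in range(n_rest - counts.sum()):
        counts[i % 3] += 1
    labels = np.concatenate(
        [np.repeat(SITE_CLASSES[i], counts[i]) for i in range(3)]
        + [np.repeat("dm_planted", n_dm)]
    )
    return rng.permutation(labels)


def _synthetic_annotation(site_ids: Sequence[str], rng: np.random.Generator) -> ProbeAnnotation:
    chroms = list(AUTOSOMES) + ["X", "Y"]
    alphabet = np.array(list("ACGT"))
    records = []
    for i, site_id in enumerate(site_ids):
        gene = f"GENE{i // 5 + 1:05d}"  # 5 consecutive sites per gene
        region = REGION_LABELS[i % len(REGION_LABELS)]
        pairs = [(gene, region)]
        if i % 7 == 0:  # a sprinkle of multi-gene probes
            pairs.append((f"GENE{i // 5 + 2:05d}", REGION_LABELS[(i + 3) % len(REGION_LABELS)]))
        seq = "".join(alphabet[rng.integers(0, 4, size=50)])
        records.append(
            (
                site_id,
                chroms[i % len(chroms)],
                1_000 + 137 * i,
                pairs,
                ISLAND_RELATIONS[i % len(ISLAND_RELATIONS)],
                "I" if i % 2 == 0 else "II",
                seq,
            )
        )
    table = pd.DataFrame.from_records(
        records, columns=("site_id",) + ProbeAnnotation.COLUMNS
    ).set_index("site_id")
    return ProbeAnnotation(table, validate=False)


def simulate(config: SimConfig) -> tuple[BetaDataset, ProbeAnnotation, GroupDesign, SimTruth]:
    """Draw a dataset, fabricated annotation, design and ground truth.

    Deterministic for a fixed config (bit-identical across calls).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_per_group
    g1, g2 = cfg.group_names
    site_ids = [f"cg{i:08d}" for i in range(cfg.n_sites)]
    sample_ids = [f"{g1}_{j + 1:02d}" for j in range(n1)] + [
        f"{g2}_{j + 1:02d}" for j in range(n2)
    ]
    labels = _class_labels(cfg, rng)

    lo = (1.0 - cfg.effect) / 2.0
    hi = (1.0 + cfg.effect) / 2.0
    mean1 = np.empty(cfg.n_sites)
    mean2 = np.empty(cfg.n_sites)
    dm_counter = 0
    for i, lab in enumerate(labels):
        if lab == "dm_planted":
            # alternate hyper/hypo in group 2
            if dm_counter % 2 == 0:
                mean1[i], mean2[i] = lo, hi
            else:
                mean1[i], mean2[i] = hi, lo
            dm_counter += 1
        else:
            mean1[i] = mean2[i] = _NULL_MEANS[lab]

    contaminated: list[str] = []
    for (g, n, k, means_other) in (
        (g1, n1, cfg.contamination_per_group[0], None),
        (g2, n2, cfg.contamination_per_group[1], None),
    ):
        if k:
            group_samples = [s for s in sample_ids if s.startswith(f"{g}_")]
            contaminated.extend(rng.choice(group_samples, size=k, replace=False))

    s = cfg.contamination_shift
    mean_matrix = np.empty((cfg.n_sites, n1 + n2))
    for j, sample in enumerate(sample_ids):
        own, other = (mean1, mean2) if j < n1 else (mean2, mean1)
        if sample in contaminated:
            mean_matrix[:, j] = (1.0 - s) * own + s * other
        else:
            mean_matrix[:, j] = own

    c = cfg.concentration
    betas = rng.beta(mean_matrix * c, (1.0 - mean_matrix) * c)

    pvals = rng.uniform(0.0, 0.01, size=betas.shape)
    fail = rng.random(betas.shape) < cfg.detection_fail_rate
    pvals[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
    missing = rng.random(betas.shape) < cfg.missing_rate
    betas[missing] = np.nan

    beta_frame = pd.DataFrame(betas, index=site_ids, columns=sample_ids)
    pval_frame = pd.DataFrame(pvals, index=site_ids, columns=sample_ids)
    ds = BetaDataset(beta_frame, pval_frame)
    ann = _synthetic_annotation(site_ids, rng)
    design = GroupDesign(
        group_names=(g1, g2),
        assignment={sam: (g1 if j < n1 else g2) for j, sam in enumerate(sample_ids)},
        mask_limits=(0, 0),
    )
    truth = SimTruth(
        site_table=pd.DataFrame(
            {
                "class_label": labels,
                "mean_group1": mean1,
                "mean_group2": mean2,
                "is_dm": labels == "dm_planted",
            },
            index=site_ids,
        ),
        sample_table=pd.DataFrame(
            {
                "group": [g1 if j < n1 else g2 for j in range(n1 + n2)],
                "contaminated": [sam in contaminated for sam in sample_ids],
            },
            index=sample_ids,
        ),
    )
    return ds, ann, design, truth


def inject_low_quality(
    ds: BetaDataset,
    samples: Sequence[str],
    fraction: float = 0.4,
    seed: int = 0,
) -> BetaDataset:
    """Corrupt chosen samples: uniform-noise betas with failed detection.

    A random ``fraction`` of each chosen sample's sites get a beta drawn
    uniformly on [0, 1] and a detection p-value above 0.05 — the coupled
    degradation (noisy measurement together with low detection confidence)
    that an experimentally failed array shows. Returns a modified copy.
    """
    if not (0.0 < fraction <= 1.0):
        raise NimblError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    n_sites = out.n_sites
    n_corrupt = round(fraction * n_sites)
    for sample in samples:
        if sample not in out.beta.columns:
            raise NimblError(f"unknown sample {sample!r}")
        idx = rng.choice(n_sites, size=n_corrupt, replace=False)
        col = out.beta.columns.get_loc(sample)
        out.beta.iloc[idx, col] = rng.uniform(0.0, 1.0, size=n_corrupt)
        out.detection_p.iloc[idx, col] = rng.uniform(0.06, 1.0, size=n_corrupt)
    return out


def worked_example_dataset() -> tuple[BetaDataset, GroupDesign]:
    """Hand-sized fixture realizing the three canonical detection cases.

    Three sites, two groups ("normal", "tumor") of three samples each,
    evaluated at minimum gap d = 0.2 with mask limits (1, 1):

    * ``site_A`` — cleanly separated groups (normal 0.10/0.15/0.20 vs
      tumor 0.60/0.65/0.70): detected already at m = (0, 0) with gap 0.40,
      median_diff 0.50, score 0.30.
    * ``site_B`` — groups overlap because one normal sample (0.65) sits in
      the tumor range: fails at m = (0, 0) (gap -0.05); at m = (1, 1) that
      sample (distance 0.50 from the normal median 0.15) is masked and the
      site passes with gap 0.45, median_diff 0.525, score 0.375.
    * ``site_C`` — low discrimination (normal 0.30/0.35/0.50 vs tumor
      0.55/0.60/0.62): fails at m = (0, 0) (gap 0.05); masking the normal
      0.50 yields gap 0.20, median_diff 0.275, score 0.125 — detected but
      scoring below site_A.

    Detection p-values are uniformly confident (0.001).
    """
    normal = ["normal_1", "normal_2", "normal_3"]
    tumor = ["tumor_1", "tumor_2", "tumor_3"]
    beta = pd.DataFrame(
        [
            [0.10, 0.15, 0.20, 0.60, 0.65, 0.70],
            [0.10, 0.15, 0.65, 0.60, 0.65, 0.70],
            [0.30, 0.35, 0.50, 0.55, 0.60, 0.62],
        ],
        index=["site_A", "site_B", "site_C"],
        columns=normal + tumor,
    )
    pvals = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
    design = GroupDesign(
        group_names=("normal", "tumor"),
        assignment={s: "normal" for s in normal} | {s: "tumor" for s in tumor},
        mask_limits=(1, 1),
    )
    return BetaDataset(beta, pvals), design
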