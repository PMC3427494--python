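"""Core differential-methylation detector.

A site is called differentially methylated when, after masking at most
``m_g`` samples per group, the beta values of the two groups are separated
by a gap (``beta_val_dist``) of at least ``d``. Masking is greedy: at each
iteration the sample most distant from its current group median (among
groups below their mask limit) is removed, one sample per iteration
irrespective of group, and the gap is re-tested. Detected sites are ranked
by

    score = beta_val_dist - (median_diff - beta_val_dist)
          = 2 * beta_val_dist - median_diff

so that wide inter-group separation is rewarded and intra-group spread
(median_diff exceeding the gap) is penalised. Sites whose detection
required masking carry the masked sample IDs and are thereby flagged as
rescued rather than natively separated.

The module also provides detection-p / missingness / annotation site
filtering, a per-gene region summary of detections, and a standard
Wilcoxon rank-sum + Benjamini-Hochberg comparator used when benchmarking
candidate lists against conventional testing.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    BetaDataset,
    DMRecord,
    GroupDesign,
    GroupExhaustedError,
    NimblError,
    ProbeAnnotation,
    REGION_LABELS,
)

__all__ = [
    "filter_sites",
    "autosomes_only",
    "islands_only",
    "group_gap",
    "mask_and_test",
    "score",
    "detect_dm",
    "gene_summary",
    "wilcoxon_comparator",
]


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def autosomes_only(site: pd.Series) -> bool:
    """Annotation predicate keeping probes on chromosomes 1-22."""
    return str(site["chromosome"]) in AUTOSOMES


def islands_only(site: pd.Series) -> bool:
    """Annotation predicate keeping probes inside CpG islands."""
    return site["island_relation"] == "Island"


def filter_sites(
    ds: BetaDataset,
    p_cutoff: float = 0.05,
    max_fail_samples: int = 0,
    max_missing_samples: int = 0,
    ann: ProbeAnnotation | None = None,
    keep: Callable[[pd.Series], bool] | None = None,
) -> BetaDataset:
    """Remove sites with too many low-confidence or missing measurements.

    A measurement is low-confidence when its detection p-value exceeds
    ``p_cutoff``; a missing p-value counts as low-confidence. Sites with
    more than ``max_fail_samples`` low-confidence samples, more than
    ``max_missing_samples`` missing betas, or rejected by the annotation
    predicate ``keep`` are dropped; order of the survivors is preserved.

    When the detection-p matrix is entirely missing (beta-only input) the
    detection criterion is skipped with a warning rather than removing
    every site.
    """
    if max_fail_samples < 0 or max_missing_samples < 0:
        raise NimblError("thresholds must be >= 0")
    n_missing = ds.beta.isna().sum(axis=1)
    survive = n_missing <= max_missing_samples
    pvals = ds.detection_p
    if pvals.notna().any().any():
        n_fail = ((pvals > p_cutoff) | pvals.isna()).sum(axis=1)
        survive &= n_fail <= max_fail_samples
    else:
        warnings.warn("no detection p-values present; skipping the detection-p filter")
    if keep is not None:
        if ann is None:
            raise NimblError("an annotation is required for annotation-based filtering")
        decisions = []
        n_unannotated = 0
        for site_id in ds.beta.index:
            if site_id not in ann:
                decisions.append(False)
                n_unannotated += 1
            else:
                decisions.append(bool(keep(ann.site(site_id))))
        if n_unannotated:
            warnings.warn(f"{n_unannotated} site(s) missing from annotation were removed")
        survive &= pd.Series(decisions, index=ds.beta.index)
    kept = ds.beta.index[survive]
    return ds.subset_sites(list(kept))


# ---------------------------------------------------------------------------
# Gap, masking, score
# ---------------------------------------------------------------------------

def _gap(lo_candidates: np.ndarray, hi_candidates: np.ndarray) -> float:
    """Signed gap between two non-empty beta arrays, lo/hi by their medians."""
    if np.median(lo_candidates) <= np.median(hi_candidates):
        lo, hi = lo_candidates, hi_candidates
    else:
        lo, hi = hi_candidates, lo_candidates
    return float(hi.min() - lo.max())


def _site_arrays(
    site_betas: Mapping[str, float] | pd.Series,
    design: GroupDesign,
) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    """Split one site's betas into per-group (ids, values) with missing dropped."""
    series = pd.Series(site_betas, dtype=float)
    out: list = []
    for g in design.group_names:
        ids = [s for s in design.samples_in(g) if s in series.index and np.isfinite(series[s])]
        out.append(ids)
        out.append(series[ids].to_numpy(dtype=float))
    return out[0], out[1], out[2], out[3]


def group_gap(
    site_betas: Mapping[str, float] | pd.Series,
    design: GroupDesign,
    masked: Iterable[str] = (),
) -> float:
    """Signed distance between the nearest betas of the two groups.

    The group with the smaller median of unmasked betas is the low group;
    the gap is ``min(high group) - max(low group)``. Positive means the
    groups do not overlap; zero or negative means they do.
    """
    masked = set(masked)
    ids1, b1, ids2, b2 = _site_arrays(site_betas, design)
    u1 = b1[[s not in masked for s in ids1]]
    u2 = b2[[s not in masked for s in ids2]]
    if len(u1) == 0 or len(u2) == 0:
        empty = design.group_names[0] if len(u1) == 0 else design.group_names[1]
        raise GroupExhaustedError(f"group {empty!r} exhausted by masking/missing values")
    return _gap(u1, u2)


def score(beta_val_dist: float, median_diff: float) -> float:
    """Ranking score: ``beta_val_dist - (median_diff - beta_val_dist)``.

    Maximal (equal to the gap itself) when both groups are perfectly tight,
    so that the medians sit exactly one gap apart.
    """
    if beta_val_dist <= 0:
        raise NimblError(f"beta_val_dist must be > 0, got {beta_val_dist}")
    if median_diff < beta_val_dist - 1e-12:
        raise NimblError(
            f"median_diff ({median_diff}) < beta_val_dist ({beta_val_dist}): "
            "group medians cannot be closer than the gap between the groups"
        )
    return 2.0 * beta_val_dist - median_diff


def _mask_and_test_arrays(
    ids1: Sequence[str],
    b1: np.ndarray,
    ids2: Sequence[str],
    b2: np.ndarray,
    d: float,
    m1: int,
    m2: int,
) -> tuple[bool, list[str], list[str], float]:
    """Greedy masking loop on one site's per-group arrays.

    Returns (passed, masked ids group1, masked ids group2, last gap).
    """
    in1 = np.ones(len(b1), dtype=bool)
    in2 = np.ones(len(b2), dtype=bool)
    masked1: list[str] = []
    masked2: list[str] = []
    while True:
        u1 = b1[in1]
        u2 = b2[in2]
        if len(u1) == 0 or len(u2) == 0:
            raise GroupExhaustedError("group exhausted by masking/missing values")
        gap = _gap(u1, u2)
        if gap >= d:
            return True, masked1, masked2, gap
        # candidate groups: below their mask limit and more than one sample left
        candidates: list[tuple[float, int, str, int, int]] = []
        med1 = float(np.median(u1)) if len(u1) else np.nan
        med2 = float(np.median(u2)) if len(u2) else np.nan
        if len(masked1) < m1 and len(u1) > 1:
            for idx in np.flatnonzero(in1):
                candidates.append((abs(b1[idx] - med1), len(u1), ids1[idx], 0, idx))
        if len(masked2) < m2 and len(u2) > 1:
            for idx in np.flatnonzero(in2):
                candidates.append((abs(b2[idx] - med2), len(u2), ids2[idx], 1, idx))
        if not candidates:
            return False, masked1, masked2, gap
        # largest distance; ties -> larger unmasked group, then smallest ID
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        _dist, _size, sid, grp, idx = candidates[0]
        if grp == 0:
            in1[idx] = False
            masked1.append(sid)
        else:
            in2[idx] = False
            masked2.append(sid)


def mask_and_test(
    site_betas: Mapping[str, float] | pd.Series,
    design: GroupDesign,
    d: float,
) -> tuple[bool, dict[str, list[str]], float]:
    """Greedy per-site masking until the groups separate by at least ``d``.

    At each iteration the group medians are recomputed over the unmasked
    samples, the sample most distant from its own group median (among
    groups still below their mask limit) is masked — one sample per
    iteration irrespective of group — and the gap is re-tested. Stops with
    success as soon as the gap reaches ``d``, or with failure when no
    maskable sample remains.

    Ties in distance are broken toward the larger unmasked group, then the
    lexicographically smallest sample ID, so results are deterministic.
    """
    if not (0.0 < d <= 1.0):
        raise NimblError(f"minimum gap d must be in (0, 1], got {d}")
    ids1, b1, ids2, b2 = _site_arrays(site_betas, design)
    m1, m2 = design.mask_limits
    passed, masked1, masked2, gap = _mask_and_test_arrays(ids1, b1, ids2, b2, d, m1, m2)
    return passed, {design.group_names[0]: masked1, design.group_names[1]: masked2}, gap


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _range_ok(
    design: GroupDesign,
    group: str,
    unmasked_values: np.ndarray,
) -> bool:
    if not design.range_constraints or group not in design.range_constraints:
        return True
    lo, hi = design.range_constraints[group]
    return bool(((unmasked_values >= lo) & (unmasked_values <= hi)).all())


def detect_dm(
    ds: BetaDataset,
    design: GroupDesign,
    d: float,
    ann: ProbeAnnotation | None = None,
) -> list[DMRecord]:
    """Detect and rank differentially methylated sites.

    Per site: run the greedy mask-and-test; on success, enforce any
    per-group beta-range constraints on the unmasked samples, compute the
    absolute difference of the unmasked group medians, the score and the
    direction (``hyper_in_group2`` when the second group's median is the
    higher one). Records are sorted by score descending — ties by gap
    descending, then fewer masked samples, then site ID — and ranked 1..n.

    ``ann`` is unused here and accepted for interface symmetry with the
    filtering step; annotation joins happen at write-out.
    """
    if not (0.0 < d <= 1.0):
        raise NimblError(f"minimum gap d must be in (0, 1], got {d}")
    design.validate_against(ds)
    g1, g2 = design.group_names
    s1 = design.samples_in(g1)
    s2 = design.samples_in(g2)
    m1, m2 = design.mask_limits
    B1 = ds.beta[s1].to_numpy(dtype=float)
    B2 = ds.beta[s2].to_numpy(dtype=float)
    site_ids = ds.site_ids

    records: list[DMRecord] = []
    n_exhausted = 0

    # Vectorized unmasked gap over all sites; the per-site greedy loop only
    # runs for sites that fail it and have masking headroom.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med1 = np.nanmedian(B1, axis=1)
        med2 = np.nanmedian(B2, axis=1)
        min1, max1 = np.nanmin(B1, axis=1), np.nanmax(B1, axis=1)
        min2, max2 = np.nanmin(B2, axis=1), np.nanmax(B2, axis=1)
    lo_is_1 = med1 <= med2
    gap0 = np.where(lo_is_1, min2 - max1, min1 - max2)

    for i, site_id in enumerate(site_ids):
        if np.isnan(med1[i]) or np.isnan(med2[i]):
            n_exhausted += 1
            continue
        if gap0[i] >= d:
            passed = True
            masked = {g1: [], g2: []}
            gap = float(gap0[i])
        elif m1 == 0 and m2 == 0:
            continue
        else:
            row1 = B1[i]
            row2 = B2[i]
            keep1 = np.isfinite(row1)
            keep2 = np.isfinite(row2)
            ids1 = [s for s, k in zip(s1, keep1) if k]
            ids2 = [s for s, k in zip(s2, keep2) if k]
            try:
                passed, masked1, masked2, gap = _mask_and_test_arrays(
                    ids1, row1[keep1], ids2, row2[keep2], d, m1, m2
                )
            except GroupExhaustedError:
                n_exhausted += 1
                continue
            if not passed:
                continue
            masked = {g1: masked1, g2: masked2}
        # unmasked per-group values for constraints/medians
        row1 = B1[i]
        row2 = B2[i]
        u1 = np.array(
            [v for s, v in zip(s1, row1) if np.isfinite(v) and s not in masked[g1]]
        )
        u2 = np.array(
            [v for s, v in zip(s2, row2) if np.isfinite(v) and s not in masked[g2]]
        )
        if not (_range_ok(design, g1, u1) and _range_ok(design, g2, u2)):
            continue
        md1 = float(np.median(u1))
        md2 = float(np.median(u2))
        median_diff = abs(md2 - md1)
        records.append(
            DMRecord(
                site_id=site_id,
                beta_val_dist=float(gap),
                median_diff=median_diff,
                score=score(float(gap), median_diff),
                masked=masked,
                direction="hyper_in_group2" if md2 > md1 else "hypo_in_group2",
            )
        )
    if n_exhausted:
        warnings.warn(
            f"{n_exhausted} site(s) skipped: a group had no usable measurements"
        )
    records.sort(
        key=lambda r: (-r.score, -r.beta_val_dist, r.total_masked, r.site_id)
    )
    for rank, rec in enumerate(records, start=1):
        rec.rank = rank
    return records


# ---------------------------------------------------------------------------
# Gene-region summary
# ---------------------------------------------------------------------------

def gene_summary(
    records: Sequence[DMRecord],
    ann: ProbeAnnotation,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-gene counts of measured and detected sites by gene region.

    For every gene annotated to any site of ``universe`` (the filtered,
    analysed site set): per region label, the number of universe sites
    carrying that (gene, region) pair and how many of those are in
    ``records``; overall counts are the size of the union of the
    per-region site sets, not their sum. One site can contribute to
    several genes and several regions, but once per (gene, region) pair.
    """
    universe = list(universe)
    detected = {r.site_id for r in records}
    measured: dict[str, dict[str, set[str]]] = {}
    for site_id in universe:
        if site_id not in ann:
            continue
        for gene, region in ann.site(site_id)["gene_assignments"]:
            if not gene:
                continue
            measured.setdefault(gene, {}).setdefault(region, set()).add(site_id)
    rows = {}
    for gene in sorted(measured):
        row: dict[str, float] = {}
        all_measured: set[str] = set()
        all_dm: set[str] = set()
        for region in REGION_LABELS:
            sites = measured[gene].get(region, set())
            dm = sites & detected
            row[f"{region}_measured"] = len(sites)
            row[f"{region}_dm"] = len(dm)
            row[f"{region}_fraction_dm"] = (len(dm) / len(sites)) if sites else np.nan
            all_measured |= sites
            all_dm |= dm
        row["overall_measured"] = len(all_measured)
        row["overall_dm"] = len(all_dm)
        rows[gene] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gene"
    return frame


# ---------------------------------------------------------------------------
# Conventional-test comparator
# ---------------------------------------------------------------------------

def wilcoxon_comparator(
    ds: BetaDataset,
    design: GroupDesign,
    alpha: float = 0.05,
) -> list[str]:
    """Sites significant under a two-sided Wilcoxon rank-sum test with BH.

    Per-site rank-sum test of the two groups' betas (missing values
    omitted), Benjamini-Hochberg adjustment across all tested sites,
    returning the IDs with adjusted p < ``alpha``. A site constant across
    all samples, or with an empty group after omitting missing values,
    gets p = 1.
    """
    from scipy.stats import ranksums
    from statsmodels.stats.multitest import multipletests

    design.validate_against(ds)
    g1, g2 = design.group_names
    a = ds.beta[design.samples_in(g1)].to_numpy(dtype=float)
    b = ds.beta[design.samples_in(g2)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise NimblError("each group needs at least 2 samples for the rank-sum test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = ranksums(a, b, axis=1, nan_policy="omit")
        pvals = np.asarray(result.pvalue, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    _reject, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [sid for sid, p in zip(ds.site_ids, p_adj) if p < alpha]
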