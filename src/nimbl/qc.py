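"""Per-sample quality control from beta distributions and detection p-values.

Two complementary signals identify low-quality arrays: an elevated count of
measurements with low detection confidence (detection p-value above a
cutoff), and an aberrant beta-value distribution. The latter is assessed
with a two-sample Kolmogorov-Smirnov test of each sample's betas against
the pooled betas of all other samples — a leave-one-out empirical
reference, chosen because beta-value mixtures have no standard parametric
form. A sample is flagged when the KS p-value falls below ``alpha`` AND the
KS statistic D reaches ``min_d``; with hundreds of thousands of sites the
p-value alone is degenerate, so the effect-size guard matters.

Flagged samples are reported, never removed automatically — an aberrant
distribution can be biological (e.g. large chromosomal aberrations), so
exclusion is the user's call.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BetaDataset, NimblError

__all__ = [
    "detection_summary",
    "ks_flag_samples",
    "qc_report",
    "beta_distribution_plot",
]

#: Minimum number of non-missing betas for the KS test to be meaningful.
MIN_SITES_FOR_KS = 100


def detection_summary(ds: BetaDataset, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-sample counts of measured sites and low-confidence measurements.

    A detection p-value above ``p_cutoff`` marks a low-confidence
    measurement; a missing p-value counts as low-confidence. When the
    p-value matrix is entirely missing, counts are reported as missing
    (with a warning), not as zero.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise NimblError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    n_measured = ds.beta.notna().sum(axis=0)
    pvals = ds.detection_p
    if pvals.notna().any().any():
        n_low = ((pvals > p_cutoff) | pvals.isna()).sum(axis=0).astype(float)
    else:
        warnings.warn("detection p-values are entirely missing; counts reported as missing")
        n_low = pd.Series(np.nan, index=ds.beta.columns)
    return pd.DataFrame(
        {"n_measured": n_measured.astype(int), "n_low_confidence": n_low},
        index=ds.beta.columns,
    )


def ks_flag_samples(
    ds: BetaDataset,
    alpha: float = 0.01,
    min_d: float = 0.05,
) -> pd.DataFrame:
    """Flag samples whose beta distribution deviates from all others.

    Each sample's non-missing betas are compared by two-sample KS test
    against the pooled non-missing betas of every other sample. Flagged
    when ``ks_pvalue < alpha`` and ``ks_statistic >= min_d``. A sample with
    fewer than 100 non-missing betas is flagged with note
    ``"insufficient data"`` and no KS computed.
    """
    from scipy.stats import ks_2samp

    if ds.n_samples < 2:
        raise NimblError("KS flagging needs at least 2 samples")
    values = ds.beta.to_numpy(dtype=float)
    columns = list(ds.beta.columns)
    per_sample = [values[:, j][np.isfinite(values[:, j])] for j in range(len(columns))]
    rows = []
    for j, sample in enumerate(columns):
        own = per_sample[j]
        if len(own) < MIN_SITES_FOR_KS:
            rows.append((sample, np.nan, np.nan, True, "insufficient data"))
            continue
        rest = np.concatenate([per_sample[k] for k in range(len(columns)) if k != j])
        stat = ks_2samp(own, rest)
        flagged = bool(stat.pvalue < alpha and stat.statistic >= min_d)
        rows.append((sample, float(stat.statistic), float(stat.pvalue), flagged, ""))
    return pd.DataFrame(
        rows, columns=["sample", "ks_statistic", "ks_pvalue", "flagged", "note"]
    ).set_index("sample")


def qc_report(
    ds: BetaDataset,
    p_cutoff: float = 0.05,
    alpha: float = 0.01,
    min_d: float = 0.05,
) -> pd.DataFrame:
    """Full QC table: detection counts joined with KS flagging."""
    return detection_summary(ds, p_cutoff).join(ks_flag_samples(ds, alpha, min_d))


def beta_distribution_plot(
    ds: BetaDataset,
    path: str | Path,
    flagged: list[str] | None = None,
) -> None:
    """Plot each sample's beta-value density on a shared [0, 1] axis.

    Flagged samples are drawn in red dashed lines; a typical good Infinium
    sample shows a bimodal density with modes near 0 and 1.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flagged = set(flagged or [])
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if ds.n_sites == 0 or ds.n_samples == 0:
        warnings.warn("empty dataset: writing empty axes")
    grid = np.linspace(0.0, 1.0, 201)
    for sample in ds.beta.columns:
        vals = ds.beta[sample].dropna().to_numpy()
        if len(vals) == 0:
            continue
        # histogram-based density: robust for any n, no bandwidth failure modes
        hist, edges = np.histogram(vals, bins=40, range=(0.0, 1.0), density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        dens = np.interp(grid, centers, hist)
        if sample in flagged:
            ax.plot(grid, dens, color="crimson", linestyle="--", label=f"{sample} (flagged)")
        else:
            ax.plot(grid, dens, alpha=0.7, label=sample)
    ax.set_xlim(0, 1)
    ax.set_xlabel("beta value")
    ax.set_ylabel("density")
    ax.set_title("Per-sample beta-value distributions")
    if ds.n_samples <= 20:
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
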