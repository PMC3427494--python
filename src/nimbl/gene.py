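"""Gene-centric views: per-gene methylation profiles in genomic coordinates.

For a gene of interest this module collects every measured array site
annotated to the gene, orders them by genomic position, marks those
detected as differentially methylated, and renders the classic profile
plot: per-sample beta values against position, group-coded markers,
asterisks over detected sites, stems marking every annotated CpG position,
and vertical guides at transcript landmarks (txStart, cdsStart,
TSS200/TSS1500 boundaries) when a gene-coordinate table is supplied.

Probe sequences can be exported as a FASTA (optionally headed by the
gene's genomic sequence) so the exact sequence context of each
measurement is available for designing confirmatory assays.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import BetaDataset, DMRecord, GroupDesign, NimblError, ProbeAnnotation
from .io_formats import write_probe_fasta

__all__ = [
    "GeneProfile",
    "read_gene_coords",
    "build_gene_profile",
    "plot_gene_profile",
    "export_gene_fasta",
]


@dataclass
class GeneProfile:
    """Ordered methylation profile of one gene.

    ``table`` has one row per measured site, sorted by position ascending,
    with columns ``position``, ``regions`` (this gene's region labels at
    the site, ';'-joined), ``dm_flag`` and one column per sample.
    ``unmeasured_sites`` lists annotated sites absent from the dataset
    (e.g. removed by filtering). ``landmarks`` maps label -> position.
    """

    gene: str
    table: pd.DataFrame
    unmeasured_sites: list[str] = field(default_factory=list)
    landmarks: dict[str, int] = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list[str]:
        fixed = {"position", "regions", "dm_flag"}
        return [c for c in self.table.columns if c not in fixed]


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene coordinate table.

    Tab-separated with header: gene, chrom, txStart, cdsStart, strand.
    Coordinates are taken as given; no strand arithmetic beyond placing the
    TSS200/TSS1500 guides upstream of txStart.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "txStart", "cdsStart", "strand"}
    missing = required - set(frame.columns)
    if missing:
        raise NimblError(f"gene coordinate table lacks column(s) {sorted(missing)}")
    return frame.set_index("gene")


def _landmarks_for(gene: str, coords: pd.DataFrame | None) -> dict[str, int]:
    if coords is None or gene not in coords.index:
        return {}
    row = coords.loc[gene]
    tx = int(row["txStart"])
    upstream = -1 if row["strand"] == "+" else 1
    return {
        "txStart": tx,
        "cdsStart": int(row["cdsStart"]),
        "TSS200": tx + upstream * 200,
        "TSS1500": tx + upstream * 1500,
    }


def build_gene_profile(
    gene: str,
    ds: BetaDataset,
    ann: ProbeAnnotation,
    dm: Sequence[DMRecord] = (),
    coords: pd.DataFrame | None = None,
) -> GeneProfile:
    """Collect, order and flag all measured sites annotated to ``gene``.

    Raises a :class:`NimblError` listing near-matches when the gene symbol
    is not in the annotation. Sites annotated to the gene but absent from
    the dataset are recorded in ``unmeasured_sites``.
    """
    gene_index = ann.gene_to_sites()
    if gene not in gene_index:
        near = difflib.get_close_matches(gene, list(gene_index), n=5)
        hint = f"; close matches: {', '.join(near)}" if near else ""
        raise NimblError(f"gene {gene!r} not found in annotation{hint}")
    annotated = gene_index[gene]
    measured = [s for s in ds.site_ids if s in annotated]
    unmeasured = sorted(annotated - set(measured))
    detected = {r.site_id for r in dm}
    rows = []
    for site_id in measured:
        site = ann.site(site_id)
        regions = ";".join(r for g, r in site["gene_assignments"] if g == gene)
        row = {
            "position": int(site["position"]),
            "regions": regions,
            "dm_flag": site_id in detected,
        }
        row.update(ds.beta.loc[site_id].to_dict())
        rows.append((site_id, row))
    table = pd.DataFrame.from_dict(dict(rows), orient="index")
    if len(table):
        table = table.sort_values("position", kind="stable")
    table.index.name = "site_id"
    return GeneProfile(
        gene=gene,
        table=table,
        unmeasured_sites=unmeasured,
        landmarks=_landmarks_for(gene, coords),
    )


def plot_gene_profile(
    profile: GeneProfile,
    design: GroupDesign,
    path: str | Path,
    window: tuple[int, int] | None = None,
    ann: ProbeAnnotation | None = None,
) -> None:
    """Render the per-gene methylation overview plot.

    Beta values (y, in [0, 1]) against genomic position (x), per-sample
    markers styled by group, asterisks over detected sites, stems below
    the x-axis for every annotated CpG position of the gene (including
    unmeasured ones when ``ann`` is given), and labeled vertical guides at
    the landmarks.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = profile.table
    if window is not None:
        lo, hi = window
        table = table[(table["position"] >= lo) & (table["position"] <= hi)]
        if len(table) == 0:
            warnings.warn(f"window {window} excludes every site of {profile.gene}")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    markers = {design.group_names[0]: ("o", "tab:blue"), design.group_names[1]: ("s", "tab:red")}
    for group in design.group_names:
        marker, color = markers[group]
        for sample in design.samples_in(group):
            if sample not in table.columns:
                continue
            ax.scatter(
                table["position"],
                table[sample],
                marker=marker,
                facecolors="none",
                edgecolors=color,
                s=28,
                linewidths=0.8,
                label=group if sample == design.samples_in(group)[0] else None,
            )
    for _sid, row in table[table["dm_flag"]].iterrows():
        ax.annotate("*", (row["position"], 1.03), ha="center", fontsize=14, annotation_clip=False)
    # stems for all annotated CpG positions in view
    stem_positions = list(table["position"])
    if ann is not None:
        for sid in profile.unmeasured_sites:
            if sid in ann:
                pos = int(ann.site(sid)["position"])
                if window is None or (window[0] <= pos <= window[1]):
                    stem_positions.append(pos)
    for pos in stem_positions:
        ax.plot([pos, pos], [-0.08, -0.02], color="black", linewidth=0.8, clip_on=False)
    for label, pos in profile.landmarks.items():
        if window is None or (window[0] <= pos <= window[1]):
            ax.axvline(pos, color="grey", linestyle=":", linewidth=0.9)
            ax.annotate(label, (pos, 1.08), ha="center", fontsize=7, annotation_clip=False)
    ax.set_ylim(-0.1, 1.05)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("beta value")
    ax.set_title(f"Methylation profile of {profile.gene}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_gene_fasta(
    profile: GeneProfile,
    ann: ProbeAnnotation,
    path: str | Path,
    gene_sequence: str | None = None,
) -> None:
    """Write the profile's probe sequences (position-ordered) as FASTA.

    The gene's genomic sequence, when supplied, becomes the first record.
    Probe headers carry the genomic position so the records can be placed
    without re-alignment. Errors out when no probe sequence is available.
    """
    probes = []
    for site_id in profile.site_ids:  # already position-sorted
        seq = ann.site(site_id)["probe_sequence"] if site_id in ann else None
        if seq:
            pos = int(ann.site(site_id)["position"])
            probes.append((f"{site_id} pos={pos}", seq))
    if not probes:
        raise NimblError(
            f"no probe sequences available for {profile.gene}; "
            "use a manifest with an AlleleA_ProbeSeq column"
        )
    write_probe_fasta(gene_sequence, probes, path, gene_name=profile.gene)
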