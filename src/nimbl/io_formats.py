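"""Readers and writers for every external representation the tool touches.

Supported formats:

* tab-delimited beta-value and detection p-value matrices (first column =
  probe ID, header row of sample names; GEO series-matrix metadata lines
  starting with ``!`` are tolerated),
* GenomeStudio-style signal matrices (methylated / unmethylated
  intensities),
* the Illumina Infinium manifest CSV dialect (header preamble tolerated,
  semicolon-delimited gene/region columns),
* ranked differential-methylation TSVs, gene-summary TSVs, BED exports,
* probe-sequence FASTA (wrapped at 60 columns),
* plain-text site-ID lists and two-column group-design files.

Numeric output uses 6 decimal places throughout so that written tables
diff reproducibly.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    BetaDataset,
    DimensionMismatchError,
    DMRecord,
    GroupDesign,
    ISLAND_RELATIONS,
    NimblError,
    ProbeAnnotation,
    REGION_LABELS,
    SignalDataset,
)

__all__ = [
    "read_beta_matrix",
    "read_signal_matrices",
    "compute_beta",
    "read_manifest",
    "write_manifest",
    "write_dm_table",
    "read_dm_table",
    "write_gene_summary",
    "write_bed",
    "write_probe_fasta",
    "read_site_list",
    "write_site_list",
    "read_group_design",
    "write_group_design",
]

#: Tokens treated as a missing value (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

FLOAT_FMT = "%.6f"
_PRECISION = 6

# Default beta offset: the Illumina convention M / (M + U + 100).
DEFAULT_OFFSET = 100.0


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited matrix with probe IDs in the first column.

    Lines starting with ``!`` (GEO series-matrix metadata) are skipped.
    Missing-value tokens become NaN; any other non-numeric cell raises with
    its row/column location.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment="!",
    )
    raw.index = raw.index.astype(str).str.strip().str.strip('"')
    raw.columns = raw.columns.astype(str).str.strip().str.strip('"')
    stripped = raw.apply(lambda col: col.str.strip().str.strip('"'))
    missing = stripped.apply(lambda col: col.str.lower().isin(MISSING_TOKENS))
    cleaned = stripped.where(~missing)
    try:
        values = cleaned.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        for col in cleaned.columns:
            converted = pd.to_numeric(cleaned[col], errors="coerce")
            bad = converted.isna() & cleaned[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise NimblError(
                    f"non-numeric cell {cleaned.at[row, col]!r} at site {row!r}, "
                    f"sample {col!r} in {path}"
                ) from exc
        raise
    return values


def _align_parallel(primary: pd.DataFrame, other: pd.DataFrame, what: str) -> pd.DataFrame:
    """Align ``other`` to ``primary`` by site ID and sample name.

    Columns are matched by name and reordered; a name present in only one
    matrix is a hard error naming the first offender.
    """
    for kind, a, b in (("site ID", primary.index, other.index),
                       ("sample name", primary.columns, other.columns)):
        diff = a.symmetric_difference(b)
        if len(diff):
            raise DimensionMismatchError(
                f"{kind} {diff[0]!r} present in only one of the beta and {what} files"
            )
    return other.loc[primary.index, primary.columns]


def read_beta_matrix(beta_path: str | Path, pval_path: str | Path | None = None) -> BetaDataset:
    """Read a beta-value matrix and an optional parallel detection-p matrix.

    Betas outside [0, 1] raise with the offending site and sample. When no
    p-value file is given, ``detection_p`` is all-missing.
    """
    beta = _read_matrix(beta_path)
    vals = beta.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (vals < 0.0) | (vals > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise NimblError(
            f"beta value {vals[i, j]} outside [0, 1] at site {beta.index[i]!r}, "
            f"sample {beta.columns[j]!r} in {beta_path}"
        )
    if pval_path is None:
        pvals = pd.DataFrame(np.nan, index=beta.index, columns=beta.columns)
    else:
        pvals = _align_parallel(beta, _read_matrix(pval_path), "p-value")
    return BetaDataset(beta, pvals)


def read_signal_matrices(
    methylated_path: str | Path,
    unmethylated_path: str | Path,
    pval_path: str | Path | None = None,
) -> SignalDataset:
    """Read GenomeStudio-style methylated/unmethylated intensity matrices."""
    meth = _read_matrix(methylated_path)
    unmeth = _align_parallel(meth, _read_matrix(unmethylated_path), "unmethylated")
    if pval_path is None:
        pvals = pd.DataFrame(np.nan, index=meth.index, columns=meth.columns)
    else:
        pvals = _align_parallel(meth, _read_matrix(pval_path), "p-value")
    return SignalDataset(meth, unmeth, pvals)


def compute_beta(signals: SignalDataset, offset: float = DEFAULT_OFFSET) -> BetaDataset:
    """Convert intensities to beta values: ``M / (M + U + offset)``.

    The offset keeps betas from being overestimated when both signals are
    low; 100 is the convention for Illumina arrays. Missing intensities
    propagate; a zero denominator (possible only at offset 0) yields a
    missing beta. Detection p-values are carried through unchanged.
    """
    if offset < 0:
        raise NimblError(f"offset must be >= 0, got {offset}")
    m = signals.methylated.to_numpy(dtype=float)
    u = signals.unmethylated.to_numpy(dtype=float)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    frame = pd.DataFrame(beta, index=signals.methylated.index, columns=signals.methylated.columns)
    return BetaDataset(frame, signals.detection_p.copy())


# ---------------------------------------------------------------------------
# Illumina manifest
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = (
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
    "Infinium_Design_Type",
)


def _find_manifest_header(path: str | Path) -> int:
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh):
            first = line.split(",", 1)[0].strip().strip('"')
            if first == "IlmnID":
                return lineno
    raise NimblError(f"no manifest column header (IlmnID ...) found in {path}")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Parse an Illumina-manifest-dialect CSV into a :class:`ProbeAnnotation`.

    Preamble lines before the ``IlmnID`` header and a trailing ``[Controls]``
    section are tolerated. Semicolon-delimited gene and region columns are
    split positionally into parallel (gene, region) pairs and deduplicated;
    an empty island relation maps to ``OpenSea``.
    """
    header_line = _find_manifest_header(path)
    raw = pd.read_csv(
        path,
        skiprows=header_line,
        dtype=str,
        keep_default_na=False,
        low_memory=False,
    )
    missing = [c for c in _MANIFEST_REQUIRED if c not in raw.columns]
    if missing:
        raise NimblError(f"manifest {path} lacks mandatory column(s) {missing}")
    # drop a trailing controls section, marked by a "[Controls]"-style row
    section = raw["IlmnID"].str.startswith("[")
    if section.any():
        raw = raw.iloc[: section.idxmax()]
    has_seq = "AlleleA_ProbeSeq" in raw.columns

    records = []
    for row in raw.itertuples(index=False):
        site_id = row.IlmnID.strip()
        genes = row.UCSC_RefGene_Name.strip()
        regions = row.UCSC_RefGene_Group.strip()
        gene_list = genes.split(";") if genes else []
        region_list = regions.split(";") if regions else []
        if len(gene_list) != len(region_list):
            raise NimblError(
                f"site {site_id!r}: {len(gene_list)} gene(s) but "
                f"{len(region_list)} region label(s)"
            )
        pairs: list[tuple[str, str]] = []
        for pair in zip(gene_list, region_list):
            if pair not in pairs:
                pairs.append(pair)
        island = row.Relation_to_UCSC_CpG_Island.strip() or "OpenSea"
        seq = getattr(row, "AlleleA_ProbeSeq", "").strip() if has_seq else ""
        records.append(
            (
                site_id,
                row.CHR.strip(),
                int(float(row.MAPINFO)),
                pairs,
                island,
                row.Infinium_Design_Type.strip(),
                seq or None,
            )
        )
    table = pd.DataFrame.from_records(
        records,
        columns=("site_id",) + ProbeAnnotation.COLUMNS,
    ).set_index("site_id")
    return ProbeAnnotation(table)


def write_manifest(ann: ProbeAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to the manifest CSV dialect.

    Parsing the written file reproduces the annotation exactly, which makes
    fabricated (synthetic) manifests usable everywhere a real one is.
    """
    out = pd.DataFrame(
        {
            "IlmnID": ann.table.index,
            "Infinium_Design_Type": ann.table["design_type"].to_numpy(),
            "AlleleA_ProbeSeq": [s or "" for s in ann.table["probe_sequence"]],
            "CHR": ann.table["chromosome"].to_numpy(),
            "MAPINFO": ann.table["position"].to_numpy(),
            "UCSC_RefGene_Name": [
                ";".join(g for g, _r in pairs) for pairs in ann.table["gene_assignments"]
            ],
            "UCSC_RefGene_Group": [
                ";".join(r for _g, r in pairs) for pairs in ann.table["gene_assignments"]
            ],
            "Relation_to_UCSC_CpG_Island": [
                "" if rel == "OpenSea" else rel for rel in ann.table["island_relation"]
            ],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DM result tables
# ---------------------------------------------------------------------------

def _dm_header(group_names: Sequence[str]) -> list[str]:
    return [
        "rank",
        "site_id",
        "score",
        "beta_val_dist",
        "median_diff",
        "direction",
        f"masked_{group_names[0]}",
        f"masked_{group_names[1]}",
        "chromosome",
        "position",
        "gene_regions",
        "island_relation",
    ]


def write_dm_table(
    records: Sequence[DMRecord],
    annotation: ProbeAnnotation | None,
    path: str | Path,
) -> None:
    """Write ranked detections with annotation to a tab-delimited file.

    A site absent from the annotation is emitted with empty annotation
    fields and a warning. An empty record list yields a header-only file.
    """
    if records:
        group_names = list(records[0].masked)
    else:
        group_names = ["group1", "group2"]
    rows = []
    unannotated = 0
    for rec in records:
        if annotation is not None and rec.site_id in annotation:
            site = annotation.site(rec.site_id)
            chrom = site["chromosome"]
            pos = str(site["position"])
            gene_regions = ";".join(f"{g}:{r}" for g, r in site["gene_assignments"])
            island = site["island_relation"]
        else:
            if annotation is not None:
                unannotated += 1
            chrom = pos = gene_regions = island = ""
        rows.append(
            [
                rec.rank,
                rec.site_id,
                FLOAT_FMT % rec.score,
                FLOAT_FMT % rec.beta_val_dist,
                FLOAT_FMT % rec.median_diff,
                rec.direction,
                ";".join(rec.masked[group_names[0]]),
                ";".join(rec.masked[group_names[1]]),
                chrom,
                pos,
                gene_regions,
                island,
            ]
        )
    if unannotated:
        warnings.warn(f"{unannotated} site(s) had no annotation; emitted with empty fields")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_dm_header(group_names))
        writer.writerows(rows)


def read_dm_table(path: str | Path) -> list[DMRecord]:
    """Re-read a table written by :func:`write_dm_table` into records.

    Annotation columns are dropped; masked-sample columns are recovered from
    the ``masked_<group>`` headers.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mask_cols = [c for c in frame.columns if c.startswith("masked_")]
    if len(mask_cols) != 2:
        raise NimblError(f"{path} does not look like a detection table")
    group_names = [c[len("masked_"):] for c in mask_cols]
    records = []
    for row in frame.itertuples(index=False):
        masked = {
            g: (getattr(row, f"masked_{g}").split(";") if getattr(row, f"masked_{g}") else [])
            for g in group_names
        }
        records.append(
            DMRecord(
                site_id=row.site_id,
                beta_val_dist=float(row.beta_val_dist),
                median_diff=float(row.median_diff),
                score=float(row.score),
                masked=masked,
                direction=row.direction,
                rank=int(row.rank),
            )
        )
    return records


def write_gene_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene region summary table to TSV."""
    summary.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def write_bed(
    records: Sequence[DMRecord],
    annotation: ProbeAnnotation,
    path: str | Path,
) -> None:
    """Export detected sites as BED (0-based half-open).

    The BED score is the detection score scaled ×1000 and clamped to
    [0, 1000]. Sites without annotation are dropped with a warning.
    """
    lines = []
    dropped = 0
    for rec in records:
        if rec.site_id not in annotation:
            dropped += 1
            continue
        site = annotation.site(rec.site_id)
        pos = int(site["position"])
        bed_score = int(np.clip(round(rec.score * 1000), 0, 1000))
        chrom = site["chromosome"]
        chrom = chrom if str(chrom).startswith("chr") else f"chr{chrom}"
        lines.append(f"{chrom}\t{pos - 1}\t{pos}\t{rec.site_id}\t{bed_score}")
    if dropped:
        warnings.warn(f"{dropped} site(s) without annotation omitted from BED export")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_NUCLEOTIDES = frozenset("ACGTN")


def _validate_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise NimblError(f"{what} contains non-nucleotide character(s) {sorted(bad)}")
    return seq


def write_probe_fasta(
    gene_sequence: str | None,
    probes: Sequence[tuple[str, str]],
    path: str | Path,
    gene_name: str = "gene",
) -> None:
    """Write a FASTA of the gene sequence (first record, if given) and probes.

    Headers are site IDs; lines wrap at 60 columns. Sequences must be
    A/C/G/T/N. An empty call writes an empty file with a warning.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    if gene_sequence is not None:
        records.append(
            SeqRecord(Seq(_validate_sequence(gene_sequence, "gene sequence")),
                      id=gene_name, description="")
        )
    for site_id, seq in probes:
        records.append(
            SeqRecord(Seq(_validate_sequence(seq, f"probe {site_id!r}")),
                      id=str(site_id), description="")
        )
    if not records:
        warnings.warn(f"nothing to write: empty FASTA {path}")
        Path(path).write_text("")
        return
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site lists and designs
# ---------------------------------------------------------------------------

def read_site_list(path: str | Path) -> list[str]:
    """Read a plain-text site-ID list, one ID per line; blanks ignored."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_site_list(site_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(site_ids) + "\n")


def read_group_design(
    path: str | Path,
    mask_limits: tuple[int, int] = (0, 0),
    range_constraints: Mapping[str, tuple[float, float]] | None = None,
) -> GroupDesign:
    """Read a two-column (sample ID, group label) tab-separated design file.

    The file has no header; group names are ordered by first appearance and
    exactly two must occur.
    """
    assignment: dict[str, str] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise NimblError(f"design line {line!r} is not two tab-separated columns")
        sample, group = parts[0].strip(), parts[1].strip()
        if sample in assignment:
            raise NimblError(f"sample {sample!r} assigned twice in {path}")
        assignment[sample] = group
        if group not in order:
            order.append(group)
    if len(order) != 2:
        raise NimblError(f"design file {path} defines {len(order)} group(s); need exactly 2")
    return GroupDesign(
        group_names=(order[0], order[1]),
        assignment=assignment,
        mask_limits=mask_limits,
        range_constraints=range_constraints,
    )


def write_group_design(design: GroupDesign, path: str | Path) -> None:
    lines = [f"{s}\t{g}" for s, g in design.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")
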