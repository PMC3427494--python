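import numpy as np
import pandas as pd
import pytest

from nimbl import BetaDataset, GroupDesign, ProbeAnnotation


@pytest.fixture
def toy_dataset():
    """4 sites x 4 samples (2 per group), one missing beta, one failed p."""
    samples = ["n1", "n2", "t1", "t2"]
    beta = pd.DataFrame(
        [
            [0.10, 0.20, 0.50, 0.60],
            [0.10, 0.60, 0.50, 0.90],
            [0.30, np.nan, 0.70, 0.80],
            [0.40, 0.45, 0.50, 0.55],
        ],
        index=["cg01", "cg02", "cg03", "cg04"],
        columns=samples,
    )
    pvals = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
    pvals.loc["cg04", "t2"] = 0.30
    return BetaDataset(beta, pvals)


@pytest.fixture
def toy_design():
    return GroupDesign(
        group_names=("normal", "tumor"),
        assignment={"n1": "normal", "n2": "normal", "t1": "tumor", "t2": "tumor"},
        mask_limits=(1, 1),
    )


def make_annotation(rows):
    """rows: (site_id, chrom, pos, pairs, island, design, seq)."""
    table = pd.DataFrame.from_records(
        rows, columns=("site_id",) + ProbeAnnotation.COLUMNS
    ).set_index("site_id")
    return ProbeAnnotation(table)


@pytest.fixture
def toy_annotation():
    return make_annotation(
        [
            ("cg01", "1", 1000, [("CHAD", "TSS200")], "Island", "I", "ACGT" * 12 + "AC"),
            ("cg02", "2", 2000, [("CHAD", "Body"), ("OTH", "Body")], "N_Shore", "II", None),
            ("cg03", "X", 3000, [("OTH", "5'UTR")], "OpenSea", "II", "A" * 50),
            ("cg04", "3", 4000, [], "Island", "I", None),
        ]
    )


@pytest.fixture
def manifest_file(tmp_path):
    """Manifest-dialect CSV with preamble and a controls section."""
    text = (
        "Illumina, Inc.\n"
        "[Heading]\n"
        "Descriptor File Name,HumanMethylation450_15017482_v.1.1.bpm\n"
        "[Assay]\n"
        "IlmnID,Infinium_Design_Type,AlleleA_ProbeSeq,CHR,MAPINFO,"
        "UCSC_RefGene_Name,UCSC_RefGene_Group,Relation_to_UCSC_CpG_Island\n"
        'cg01,I,' + "ACGT" * 12 + 'AC,1,1000,CHAD;CHAD,TSS200;Body,Island\n'
        "cg02,II,,2,2000,,,N_Shore\n"
        "cg03,II," + "A" * 50 + ",X,3000,OTH,5'UTR,\n"
        "[Controls]\n"
        "ctrl1,negative,,,,\n"
    )
    path = tmp_path / "manifest.csv"
    path.write_text(text)
    return path
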