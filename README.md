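# nimbl

Numerical identification of methylation biomarker lists: a heuristic,
annotation-aware detector and ranker of differentially methylated CpG
sites between two sample groups on Infinium-style methylation arrays
(450k-class beta-value matrices), with per-sample quality control, greedy
sample masking for heterogeneous clinical samples, gene-region
summarization and multi-method candidate-list comparison.

It is aimed at researchers comparing small clinical groups — e.g. tumor
vs. normal tissue — where rank tests are underpowered and surgically
resected samples are often contaminated by histologically normal cells,
so that one or two samples of a group behave like the other group.

## The method

Methylation at a CpG site is quantified by the **beta value**
β = M / (M + U + offset) ∈ [0, 1], the proportion of the methylated
hybridization signal (offset 100 by convention, preventing overestimation
at low signal). Each measurement carries a **detection p-value**; sites
with too many low-confidence (p > 0.05) or missing measurements are
excluded, and analysis can be restricted by annotation (autosomes only,
CpG islands only).

A site is called **differentially methylated** when the beta values of
the two groups are separated by a gap of at least a user-chosen minimum
distance *d*:

    beta_val_dist = min(high group) − max(low group) ≥ d

where low/high are assigned by group medians. To cope with heterogeneous
samples, up to *m₁*/*m₂* samples per group may be **masked**: iteratively,
the sample most distant from its current group median (among groups below
their limit) is removed — one sample per iteration, irrespective of group
— and the gap is re-tested until *d* is reached or the limits are
exhausted. Sites rescued by masking stay flagged with the masked sample
IDs. Detected sites are ranked by

    score = beta_val_dist − (median_diff − beta_val_dist)
          = 2·beta_val_dist − median_diff

with median_diff the absolute difference of the (unmasked) group medians:
wide separation scores high, intra-group spread is penalised, and
score = beta_val_dist exactly when both groups are perfectly tight.
Optional per-group beta-range constraints express biological hypotheses
(e.g. "hypomethylated in normals": normal betas in [0, 0.3]).

Around the core detector the package provides: QC (low-confidence counts
plus leave-one-out two-sample Kolmogorov–Smirnov flagging of aberrant
beta distributions), per-gene region summaries (sites measured vs.
detected per TSS1500/TSS200/5'UTR/1stExon/Body/3'UTR), per-gene profile
plots in genomic coordinates with probe-sequence FASTA export, an
exact-membership partition of 2–3 candidate lists at site and gene level
with a median-difference post-filter (default 0.2, the threshold
verifiable by bisulfite sequencing), a standard Wilcoxon rank-sum + BH
comparator, and a synthetic-data generator with planted ground truth.

## Worked example

Three sites, two groups of three samples each, minimum gap `d = 0.2`,
mask limits `(1, 1)`:

```python
from nimbl import detect_dm, worked_example_dataset

ds, design = worked_example_dataset()
for r in detect_dm(ds, design, d=0.2):
    print(r.rank, r.site_id, f"score={r.score:.3f}", f"gap={r.beta_val_dist:.2f}",
          f"median_diff={r.median_diff:.3f}", r.masked)
```

prints

```
1 site_B score=0.375 gap=0.45 median_diff=0.525 {'normal': ['normal_3'], 'tumor': []}
2 site_A score=0.300 gap=0.40 median_diff=0.500 {'normal': [], 'tumor': []}
3 site_C score=0.125 gap=0.20 median_diff=0.275 {'normal': ['normal_3'], 'tumor': []}
```

`site_A` separates cleanly without masking (gap 0.40). `site_B`'s groups
overlap because one normal sample sits in the tumor range; masking that
sample (`normal_3`) yields a 0.45 gap — detected but flagged as rescued.
`site_C` has low discrimination and passes only after masking, with the
lowest score. At mask limits `(0, 0)` only `site_A` is detected.

The `examples/` directory walks through each capability (detection with
masking, QC, gene profiles, list comparison, signal-to-beta conversion);
every script builds its own input and prints what it computes. A thin
CLI mirrors the library: `nimbl qc|dm|gene|compare|simulate --help`.

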