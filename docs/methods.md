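# Methods

## Model and procedure

The detector treats differential methylation as a geometric separation
problem on beta values rather than a hypothesis test. For one CpG site
with beta values split into two groups, let the *low* group be the one
with the smaller median. The inter-group distance is

    beta_val_dist = min(high group) − max(low group),

positive exactly when the groups do not overlap. A site is detected when
`beta_val_dist ≥ d` after masking at most `m_g` samples from group *g*.

Masking is greedy and site-local: while the gap test fails, group medians
are recomputed over the currently unmasked samples, and the single sample
with the largest absolute distance to its own group median — considering
only groups still below their mask limit — is removed; one sample per
iteration, irrespective of group. The loop stops at success (gap ≥ d) or
when no maskable sample remains. Because the unmasked configuration is
tested first, the detected set grows monotonically in `(m₁, m₂)`, and
shrinks monotonically in `d`.

Detected sites are ranked by `score = 2·beta_val_dist − median_diff`,
where `median_diff` is the absolute difference of the unmasked group
medians. Geometrically `median_diff ≥ beta_val_dist` always (the medians
cannot be closer than the gap between non-overlapping groups), so
`score ≤ beta_val_dist`, with equality for perfectly tight groups; the
penalty term `median_diff − beta_val_dist` measures intra-group spread.
This precondition is enforced as an internal assertion — violating it
indicates a caller bug, not a data property.

Optional per-group range constraints (`[lo, hi] ⊆ [0, 1]`) are evaluated
on the unmasked samples only, after masking succeeds: masked samples have
been declared unrepresentative, so they are exempt from biological
constraints as well. `median_diff` and the direction label
(`hyper_in_group2` iff the second group's unmasked median is higher) are
likewise computed on unmasked samples, for consistency with the gap.

Greedy masking is a heuristic: every site it detects is also detected by
exhaustive enumeration of all maskings within the limits (verified by a
brute-force oracle in the tests), but the converse can fail — a greedy
step can mask a suboptimal sample. The exhaustive search is exponential
in the mask limits and is used only as a test oracle.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `d` | minimum beta gap between groups | 0.1 (CLI) | a 0.1 beta difference is near the platform's reliable resolution |
| `m₁, m₂` | mask limit per group | 0 | masking is opt-in; it weakens the statistical reading of a call |
| `offset` | beta denominator constant | 100 | the Illumina convention; only affects signal-mode input |
| `p_cutoff` | detection-p above which a measurement is low-confidence | 0.05 | platform convention |
| `max_fail_samples`, `max_missing_samples` | site-exclusion thresholds | 0 | strictest setting: any unreliable sample excludes the site |
| QC `alpha`, `min_d` | KS flagging thresholds | 0.01, 0.05 | with ~10⁵ sites the KS p-value is degenerate; the effect-size floor `min_d` stops trivially small distributional shifts from flagging |
| compare `min_diff` | median-difference post-filter | 0.2 | the difference generally confirmable by bisulfite sequencing |

Detection-p semantics: a measurement is low-confidence when its detection
p-value **exceeds** the cutoff (high p = signal indistinguishable from
background); a missing p-value counts as low-confidence. When the
p-value matrix is entirely absent (beta-only input), the detection
criterion is skipped with a warning instead of discarding every site.

## Quality control

No parametric reference exists for the mixture-shaped beta distribution
of a real sample, so each sample is compared by a two-sample
Kolmogorov–Smirnov test against the pooled betas of all other samples
(leave-one-out empirical reference — the least-assumption choice). A
sample is flagged when `p < alpha` **and** `D ≥ min_d`. Samples with
fewer than 100 non-missing betas are flagged as `insufficient data`
without a KS test. Flagged samples are never removed automatically: an
aberrant distribution can be biological (e.g. chromosomal aberrations),
and the recommended corroboration is a high count of low-confidence
measurements in the same sample. Note that with few samples a grossly
aberrant sample also contaminates everyone else's pooled reference by
roughly `D/(n−1)`; the aberrant sample still dominates by an order of
magnitude, which is why flagging uses both thresholds.

## Gene-level views

The per-gene summary counts, for every gene occurring in the analysed
site universe and each region label (TSS1500, TSS200, 5'UTR, 1stExon,
Body, 3'UTR), the sites measured and those detected; a site contributes
once per distinct (gene, region) pair, and the overall columns are the
size of the union of the per-region site sets, not their sum. Gene
profiles order a gene's measured sites by genomic position and mark
detections; transcript landmarks (txStart, cdsStart and TSS200/TSS1500
guides placed upstream of txStart by strand) come exclusively from a
user-supplied coordinate table — no genome build is bundled and no
coordinate arithmetic beyond those fixed offsets is performed. Probe
FASTA export writes the manifest's probe sequences position-ordered; the
probes are already placed by the manifest, so no alignment is run.

## List comparison

2–3 named site lists are partitioned into their 2^k − 1 exact-membership
cells. Gene-level cells are computed from **per-list gene sets** (every
gene hit by any site of the list), then partitioned — not by mapping each
site cell separately — so two lists sharing no sites can still share a
gene. The median-difference post-filter uses all samples of each group
(no masking information): lists from different methods must be treated
uniformly, with the documented consequence that sites detected only via
masking may fail the post-filter.

## Synthetic data

The generator emulates a two-group Infinium study: sites are assigned to
four classes (null-unmethylated mean 0.10, null-methylated 0.90,
null-intermediate 0.50, planted-DM with group means (1±Δ)/2 alternating
direction), betas drawn from Beta(mean·c, (1−mean)·c) so the mean — and
for tight concentrations the median — is pinned directly. Heterogeneous
("contaminated") samples have their planted-class means shifted toward
the other group by a fraction *s*; missing cells and detection failures
are injected independently at the configured rates, except in the
explicit low-quality corruption helper where noisy betas and failed
detection co-occur (the coupling a failed array shows, and the basis of
the QC cross-check). Defaults are chosen once as plausible study
conditions: 10,000 sites, 8 + 8 samples (a typical small clinical
comparison), 10% planted sites at Δ = 0.5, concentration 200
(s.d. ≈ 0.03 near the extremes), 1% missing, 0.5% detection failures.
Scenario tests that require *certifiably* non-overlapping classes use
concentration 1000, where the probability of any of ~10⁵ draws straying
0.1 from its mean is ~10⁻¹⁰.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real arrays: Infinium I/II chemistry
shifts, batch and color-bias effects, spatially correlated probe
failures, biological covariance between neighbouring CpGs, and realistic
annotation topology (genes are fabricated round-robin). Conclusions
about detector logic (masking, ranking, monotonicity, oracle agreement)
transfer; conclusions about error rates on real data do not.

## Numerical choices

- Masking ties (equal distance to the group median) are broken toward
  the larger unmasked group, then the lexicographically smallest sample
  ID — deterministic, and preserving the smaller group.
- Rank ties (equal score) order by gap descending, then fewer total
  masked samples, then site ID.
- Missing betas at a site act as absent samples: they do not count
  toward mask limits and never enter medians or gaps. A group with a
  single unmasked sample is never masked further, and a site whose group
  has no usable measurements is skipped with a warning rather than
  aborting the run.
- Equal group medians assign the first group as the low group; the gap
  is then non-positive and the site fails the test either way.
- All written tables use 6 decimal places; table round-trips preserve
  values to that precision.
- The Wilcoxon comparator assigns p = 1 to sites that are constant
  across all samples or lose a group to missing values; BH adjustment
  runs across all tested sites.

## Problem sizes

The self-contained verification suite runs at desk scale: 10,000
simulated sites for the m = 0 oracle and the planted-recovery scenario,
5,000 for monotonicity, 1,000 random sites (groups of 5 and 6, mask
limits 2) for the greedy-vs-exhaustive confirmation, 10,000 random pairs
for the score identity. These sizes give exact set-level assertions
(zero violations expected, not approximate rates) while completing in
seconds. The full-scale published-study replication (≈485k sites × 16
samples) is implemented and exercised by
`tests/test_acceptance.py::test_full_scale_study_replication` whenever
its inputs are present under `data/gse29290/`; those inputs are
redistributable only via GEO and the Illumina manifest, so the package
does not ship them.

## Known limitations

- The detector provides no error-rate control; masking in particular
  removes the usual statistical reading of a discovery list. Masked
  counts are reported per record precisely so users can rank
  conservatively.
- Greedy masking can miss maskings an exhaustive search would find
  (never the reverse).
- No normalization, Infinium II signal correction, M-values, paired
  designs, covariates or region-level statistics; inputs are assumed
  preprocessed beta values.
- QC flagging with very few samples (< ~6) is fragile because the
  leave-one-out reference is dominated by single samples.
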