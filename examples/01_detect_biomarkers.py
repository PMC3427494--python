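"""Detect and rank differentially methylated sites with sample masking.

Simulates a small two-group study in which one sample per group is
heterogeneous (its planted sites look like the other group), then runs
detection with and without masking to show how masking rescues sites
obscured by a single aberrant sample.
"""

from nimbl import detect_dm
from nimbl.synth import SimConfig, simulate

ds, ann, design, truth = simulate(
    SimConfig(
        n_sites=5_000,
        contamination_per_group=(1, 1),
        missing_rate=0.0,
        detection_fail_rate=0.0,
        seed=11,
    )
)

records_m0 = detect_dm(ds, design, d=0.3)
records_m1 = detect_dm(ds, design.with_mask_limits(1, 1), d=0.3)

planted = truth.dm_sites
hits_m1 = {r.site_id for r in records_m1}

print(f"planted DM sites: {len(planted)} of {ds.n_sites}")
print(f"detected at d=0.3, m=(0,0): {len(records_m0)}")
print(f"detected at d=0.3, m=(1,1): {len(records_m1)}  "
      f"(sensitivity {len(hits_m1 & planted) / len(planted):.3f}, "
      f"false positives {len(hits_m1 - planted)})")
print("\ntop 3 ranked sites (score = 2*gap - median_diff):")
for r in records_m1[:3]:
    print(f"  rank {r.rank}: {r.site_id}  score={r.score:.3f}  gap={r.beta_val_dist:.3f}  "
          f"median_diff={r.median_diff:.3f}  masked={sum(r.n_masked.values())}  {r.direction}")
print("\nWithout masking the contaminated samples hide nearly every planted")
print("site; allowing one masked sample per group recovers them, and each")
print("record reports which samples were masked so rescued sites stay flagged.")
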