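"""Per-patient analyses downstream of a mutation-blot labeling.

Starting from an SBS-level MB labeling, compute each patient's MB
composition (the proportion of their SBSs in each class), cluster
patients on those compositions, and compare survival between the
resulting patient classes with a log-rank test.
"""
from pathlib import Path
import tempfile

import numpy as np
import pandas as pd

from mutblot import (
    ScheduleConfig,
    cluster_patients,
    generate_cohort,
    generate_reference,
    load_encoded_dataset,
    logrank,
    mb_composition,
    read_clinical,
    run_schedule,
    survival_demo_spec,
    two_class_profiles,
)

outdir = Path(tempfile.mkdtemp(prefix="mutblot_demo_"))
spec = survival_demo_spec()
genome = generate_reference(220_000, gc=0.41, seed=11, path=outdir / "ref.fa",
                            flank_length=10)
from mutblot import make_profiles
paths = generate_cohort(spec, make_profiles(3, F=10), genome, outdir, seed=11)

records, _, encodings = load_encoded_dataset(paths["maf"], paths["reference"], F=10)

# a shallow schedule is enough for a demo: 2 rounds -> 4 MB classes
labeling = run_schedule(encodings, ScheduleConfig(rounds=2, extra_split_count=0, seed=0))
frame = labeling.to_frame(records)
print("MB class sizes:", dict(zip(labeling.label_names(), labeling.class_sizes())))

comp = mb_composition(frame)
print("\nper-patient composition (first rows):")
print(comp.head(3).round(3).to_string())

classing = cluster_patients(comp, K=3, seed=0)
clin = read_clinical(paths["clinical"])
clin_df = pd.DataFrame(
    {"survival_time": [c.survival_time for c in clin],
     "event": [c.event for c in clin]},
    index=pd.Index([c.sample_barcode for c in clin], name="sample_barcode"),
).loc[comp.index]

groups = {
    f"class {k}": (
        clin_df.loc[classing.classes == k, "survival_time"].to_numpy(),
        clin_df.loc[classing.classes == k, "event"].to_numpy(),
    )
    for k in sorted(set(classing.classes))
}
res = logrank(groups)
print(f"\nlog-rank across {len(groups)} patient classes: "
      f"statistic={res.statistic:.2f}, p={res.p_value:.3g}")
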