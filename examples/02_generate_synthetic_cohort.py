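"""Generate a synthetic cohort with planted sequence-context classes.

The generator writes a reference FASTA, a MAF of somatic SBSs whose
flanks carry class-specific base enrichments, a clinical table, and
separate hidden-truth tables that record which planted class produced
each SBS and which archetype each patient belongs to.  Everything is
derived from one seed, so reruns are byte-identical.
"""
from pathlib import Path
import tempfile

import pandas as pd

from mutblot import (
    generate_cohort,
    generate_reference,
    two_class_profiles,
    two_class_spec,
)

outdir = Path(tempfile.mkdtemp(prefix="mutblot_demo_"))
genome = generate_reference(60_000, gc=0.41, seed=7, path=outdir / "ref.fa",
                            flank_length=10)
paths = generate_cohort(two_class_spec(), two_class_profiles(), genome,
                        outdir, seed=7)

print("files written to", outdir)
for k, p in paths.items():
    print(f"  {k}: {p.name}")

maf = pd.read_csv(paths["maf"], sep="\t")
print("\nfirst MAF rows:")
print(maf.head(3).to_string(index=False))

truth = pd.read_csv(paths["truth_sbs"], sep="\t")
print("\nplanted class counts:", truth["hidden_class"].value_counts().to_dict())
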