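"""Consensus differential expression under two normalization strategies.

Each miRNA is tested per pairwise group comparison with a pooled-variance
Student's t on delta-Ct, once after global-mean normalization and once after
reference-miRNA normalization.  A call requires a >= 2.5-fold change and
p <= 0.05 under BOTH strategies (the consensus rule).  Eight 3-fold
DME-downregulated miRNAs are planted here.
"""

import numpy as np

from mirqpcr import generate, plant_recovery_report, profiling_spec
from mirqpcr.pipeline import profile_stage

spec = profiling_spec(
    baseline_ct_range=(22.0, 31.0),
    de_plan=tuple((3 + i, "DME", float(np.log2(3))) for i in range(8)),
)
ct, sheet, truth = generate(spec, seed=17)
bundle = profile_stage(ct, sheet)

print("references used:", ", ".join(bundle.references))
for comp in ("DME_vs_CTR", "DME_vs_D", "D_vs_CTR"):
    calls = bundle.de.consensus_set(comp)
    print(f"{comp}: {len(calls)} consensus calls -> {calls}")

report = plant_recovery_report(truth, bundle.stability, bundle.de)
de_rep = report["de"]["consensus"]
print(f"recall of planted 3-fold shifts: {de_rep['recall']:.2f}")
print(f"false calls among {de_rep['n_null_tested']} null miRNAs: "
      f"{de_rep['n_false_calls']}")
# fc ~ 1/3 for a planted +log2(3) Ct shift; the 2.5-fold gate plus the dual
# strategy keeps the false-positive rate near zero.
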