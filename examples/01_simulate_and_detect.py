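"""Generate a synthetic profiling card and apply the detection filter.

The generator emulates a 378-assay miRNA array profiled in three clinical
groups of five subjects; weak wells (true Ct above 35) are censored the way
an instrument reports "Undetermined".  The detection rule keeps a miRNA
when at least 4 of 5 subjects in at least one group have Ct <= 35.
"""

from mirqpcr import detect_flags, generate, profiling_spec, venn_partition

# Widen the abundance window beyond the default so that a realistic share of
# assays sits near or beyond the Ct-35 detection limit, as on a real card
# where many low-abundance miRNAs never amplify reliably.
ct, sheet, truth = generate(profiling_spec(baseline_ct_range=(24.0, 40.0)), seed=17)
print(f"Ct matrix: {ct.n_mirnas} miRNAs x {ct.n_samples} samples")
print(f"censored wells: {int(ct.values.isna().sum().sum())}")

detection = detect_flags(ct, sheet, ct_threshold=35.0, min_frac=0.8)
print(f"reliably detected miRNAs: {len(detection.detected_set)}")
print("per-group detected counts:", detection.per_group_counts)

regions = venn_partition(detection)
shared = regions[(True, True, True)]
print(f"detected in all three groups: {shared}")
# The region counts partition the detected set: each miRNA falls in exactly
# one of the 7 regions according to which groups it was detected in.
assert sum(regions.values()) == len(detection.detected_set)
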