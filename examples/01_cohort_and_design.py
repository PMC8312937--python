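"""Generate a study-sized cohort and build the 11-column design matrix.

The cohort template is 39 cocaine-use-disorder subjects and 18 controls
with the study's sex ratios, YCU range and SNP carrier frequencies; the
design holds the four base covariates plus all interactions.
"""

import voxelbma as vb

scenario = vb.SimulationScenario(seed=1)
cohort = vb.generate_cohort(scenario)

report = vb.validate_cohort(cohort)
print("group sizes:", report["group_sizes"])
print("carrier frequencies:", {k: round(v, 3) for k, v in report["carrier_frequencies"].items()})
print("YCU range:", tuple(round(v, 2) for v in report["ranges"]["ycu"]))

design = vb.build_design_matrix(cohort)
print(f"\ndesign matrix: {design.n} subjects x {design.k} covariates")
print("columns:", ", ".join(design.column_names))
print("first CUD row:", [float(round(v, 2)) for v in design.values[0]])
# interaction columns are exact products of the raw base columns, so a
# control subject (YCU = 0) is zero in all five YCU-bearing columns
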