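"""Classify homeolog expression divergence under one stress.

A triad whose three homeologs all respond the same way is
sub-functionalized; a triad where only some respond is
neo-functionalized; triads expressed below 1 FPKM everywhere are
removed from the analysis.
"""

import pandas as pd

from homeobias import ExpressionMatrix, HomeologComponent, call_deg, classify_bias, summarize_bias

samples = ["control_1", "control_2", "control_3",
           "treatment_1", "treatment_2", "treatment_3"]
design = {s: (s.rsplit("_", 1)[0], int(s.rsplit("_", 1)[1])) for s in samples}
values = pd.DataFrame(
    {
        "subA": [12, 11, 13, 55, 60, 52],   # all three up ~4-fold
        "subB": [20, 22, 19, 88, 95, 90],
        "subD": [8, 9, 8, 40, 37, 42],
        "neoA": [15, 14, 16, 70, 66, 73],   # only the A copy responds
        "neoB": [15, 16, 14, 15, 14, 16],
        "neoD": [22, 21, 23, 22, 23, 21],
        "lowA": [0.2, 0.3, 0.1, 0.4, 0.2, 0.3],  # below the 1-FPKM floor
        "lowB": [0.1, 0.2, 0.2, 0.1, 0.3, 0.2],
        "lowD": [0.3, 0.2, 0.2, 0.2, 0.1, 0.3],
    },
    index=samples,
).T
m = ExpressionMatrix(values=values, design=design)
degs = call_deg(m, fc_threshold=2.0, alpha=0.05)

components = [
    HomeologComponent(id="triad_sub", members=["subA", "subB", "subD"]),
    HomeologComponent(id="triad_neo", members=["neoA", "neoB", "neoD"]),
    HomeologComponent(id="triad_low", members=["lowA", "lowB", "lowD"]),
]
calls = [classify_bias(c, degs, m) for c in components]
for c in calls:
    print(f"{c.component_id}: {c.status}  (member calls {c.member_calls})")
print(summarize_bias({"heat": calls}).to_string(index=False))
# triad_sub -> subfunctionalization_up (shared response), triad_neo ->
# neofunctionalization (diverged response), triad_low -> removed.
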