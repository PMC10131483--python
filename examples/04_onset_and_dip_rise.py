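"""Transcript-origin classification and zygotic expression-onset calling.

Averaged FPKM trajectories on the 0, 6-30 hpf grid are classified as maternal
(FPKM > 3 already at fertilization), clearly zygotic (FPKM < 1 at 0 hpf,
onset = first crossing of 3), ambiguous at 0 hpf, or undetected. For maternal
genes a zygotic onset can still be inferred from a dip-then-rise pattern —
demonstrated here on the published Abcc5D excerpt.
"""

import pandas as pd

from effectoronset import (
    SimulationConfig,
    annotate_dip_rise,
    average_replicates,
    call_onset,
    infer_dip_rise_onset,
    simulate_dataset,
)
from effectoronset.onset import TIME_GRID

bundle = simulate_dataset(SimulationConfig(n_genes=500, seed=42))
avg = average_replicates(bundle.fpkm_replicates)
calls = annotate_dip_rise(avg, call_onset(avg))

print("origin classes:", calls["origin"].value_counts().to_dict())
zygotic = calls[calls["origin"] == "zygotic_clear"]
print("onset-hour distribution of clearly zygotic genes:")
print(zygotic["onset_hpf"].value_counts().sort_index().to_dict())
print("maternal genes with an inferred dip-rise onset:",
      int(calls["dip_rise_onset_hpf"].notna().sum()))

# The published worked example: maternal FPKM 3.23 at 0 hpf, early minimum
# 1.86 at 8 hpf, rise to 4.93 at 10 hpf => inferred onset 10 hpf.
fpkm = {0: 3.23, 6: 2.6, 8: 1.86, 10: 4.93}
for h in TIME_GRID:
    fpkm.setdefault(h, 5.0)
onset = infer_dip_rise_onset(pd.Series(fpkm))
print(f"\nAbcc5D-style trajectory -> inferred zygotic onset {onset:g} hpf")
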