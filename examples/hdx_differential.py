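"""Differential HDX on a simulated two-state experiment.

Builds a peptide state table for a 32-residue protein whose first ten
residues get a 5-fold protection-factor increase in the bound state,
then runs the full differential pipeline: ΔHDX per (peptide, exposure),
a replicate-derived global confidence threshold, one-tailed significance
tests, and per-peptide protection calls.
"""

import numpy as np

from hdxflex import HDXSimConfig, PeptideRecord, RunConfig, run_hdx_pipeline
from hdxflex.synthetic import simulate_state_table

SEQ = "AKLMNQRSTVWYAGHIDEFKLVMNQRSTAKLY"

peptides = [
    PeptideRecord(SEQ[0:10], 1, 10),
    PeptideRecord(SEQ[9:20], 10, 20),
    PeptideRecord(SEQ[19:32], 20, 32),
]

cfg_sim = HDXSimConfig(
    protein_sequence=SEQ,
    protection_factor=10.0,
    replicate_noise_sd=0.15,   # Da, triplicate scatter
    exposures=(60.0, 600.0),   # 1 min and 10 min labeling
    seed=0,
)
pf_bound = np.asarray(cfg_sim.protection_factor).copy()
pf_bound[0:10] *= 5.0  # residues 1-10 rigidify on binding

table = simulate_state_table(
    cfg_sim, peptides, states={"free": cfg_sim.protection_factor, "bound": pf_bound}
)

result = run_hdx_pipeline(RunConfig(out_dir="scratch/hdx_example"), table=table)

print(f"global confidence threshold: {result['threshold_da']:.3f} Da")
print(result["summary"][["start", "end", "call", "summed_fractional_diff_pct"]]
      .to_string(index=False))
print(
    "\nNegative summed fractional differences mean less deuterium uptake in\n"
    "the bound state (protection); the engineered region 1-10 is the only\n"
    "peptide called, the rest stay below the significance threshold (ND)."
)
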