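"""Connectome rule suite on a toy synapse table.

Builds a toy synapse table with planted partner classes, applies the
downstream-partner selection rule (10/50 synapses, 4%/0.5% boundary
line), the input-selectivity cascade, and the per-glomerulus
contra/ipsi ORN-input profile of a commissural inhibitory interneuron.
"""

import warnings

from pherospace.connectome import (classify_input_selectivity,
                                   contra_ipsi_profile,
                                   select_downstream_types)
from pherospace.synthetic import (default_toy_connectome_spec,
                                  generate_toy_connectome)

table = generate_toy_connectome(default_toy_connectome_spec())

sel = select_downstream_types(table, "DA1_lPN", roi_filter=("LH",))
print("downstream partner selection (seed type DA1_lPN, LH only):")
print(sel.table[["post_type", "n_synapses", "pct", "decision"]]
      .to_string(index=False))

labels = {"DA1_lPN": ("pn", "DA1"), "DL3_PN": ("pn", "DL3"),
          "MechanoSensory": ("sensory", "mechanosensory")}
print("\ninput-selectivity classes:")
for cell in ("TON_multi", "TON_da1", "TON_mixed"):
    out = classify_input_selectivity(table, cell, labels)
    print(f"  {cell}: {out.label} (olfactory {out.olfactory_pn_input:.0f}, "
          f"DA1 {out.da1_pn_input:.0f}, sensory {out.sensory_input:.0f})")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    prof = contra_ipsi_profile(table, "il3LN6")
print("\ncontra/ipsi ORN input to il3LN6 per glomerulus:")
print(prof.to_string(index=False))
# the DA1 row reproduces the planted 1901/359 = 5.30 contralateral bias,
# the anatomical basis of contralateral inhibition in the circuit model
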