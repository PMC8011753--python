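"""Simulate a pooled single-cell CRISPR screen with ground truth.

Builds a 10-guide screen (200 cells per guide) in which guide sg02 imposes
monoallelic loss on 25% and biallelic loss on 5% of its cells for one
high-expression target gene. Prints the shapes of the generated matrices
and the realised loss-state fractions, which should sit near the
configured (0.25, 0.05).
"""

import numpy as np

from pacseq import LossProfile, SimConfig
from pacseq.synthetic_data import make_screen

cfg = SimConfig(seed=1, loss=LossProfile(f_mono=0.25, f_full=0.05))
screen = make_screen(cfg, cells_per_guide=200, target_gene="Gene00985",
                     perturbed_guide=1)

expr = screen["expression"]
gc = screen["guide_counts"]
truth = screen["truth"]

print(f"expression matrix: {expr.shape[0]} cells x {expr.shape[1]} genes, "
      f"median {np.median(expr.row_totals()):.0f} UMIs/cell")
print(f"guide counts:      {gc.shape[0]} cells x {gc.shape[1]} guides, "
      f"median {np.median(gc.row_totals()):.0f} gRNA UMIs/cell")

perturbed = truth.true_guide == "sg02"
states = truth.loss_state[perturbed.to_numpy()].value_counts(normalize=True)
print("loss states in the sg02 population "
      "(fractions; 'mono' halves the target's counts, 'bi' zeroes them):")
for state in ("none", "mono", "bi"):
    print(f"  {state:>5}: {states.get(state, 0.0):.3f}")
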