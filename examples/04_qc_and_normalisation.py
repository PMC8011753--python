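"""Transcriptome QC: knee rule, 3-MAD outlier removal, log-normalisation.

Simulates a barcode-rank distribution with an ambient tail and a control
expression matrix, then (1) separates cell-containing droplets from
ambient barcodes with the knee rule, (2) removes cells that are 3 median
absolute deviations out on mitochondrial fraction, genes detected, or
total UMIs, and (3) depth-normalises to ln(1 + count * 1e4 / cell total).
"""

import pandas as pd

from pacseq import SimConfig, knee_filter, lognormalize, mad_outlier_filter, qc_metrics
from pacseq.synthetic_data import make_barcode_distribution, make_control_matrix

cfg = SimConfig(seed=4)

dist = make_barcode_distribution(cfg)
kept = knee_filter(dist["total"], expected_cells=cfg.n_cells)
real = dist.index[dist["is_real"]]
print(f"knee rule kept {len(kept)} of {len(dist)} barcodes "
      f"({len(set(kept) & set(real))} of {len(real)} true cells, "
      f"{len(set(kept) - set(real))} ambient)")

cm, _mu = make_control_matrix(cfg)
metrics = qc_metrics(cm, mito_prefix="mt-")
keep = mad_outlier_filter(metrics, n_mads=3)
print(f"3-MAD filter removed {int((~keep).sum())} of {len(keep)} cells "
      f"(median mito fraction {metrics['mito_frac'].median():.3f})")

norm = lognormalize(cm.subset_cells(keep.to_numpy()), scale_factor=1e4)
col = norm.gene_values(norm.features[-11])  # a high-expression gene
print(f"log-normalised values for {norm.features[-11]}: "
      f"mean {col.mean():.2f}, max {col.max():.2f} "
      f"(depth differences between cells are divided out before log1p)")
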