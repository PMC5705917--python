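"""Fold-change filtering of a starvation time-course transcriptome.

Generates a synthetic carbon-starvation RNA-seq course (log-phase baseline
plus 12/50/90/180 h post-arrest samples) in which 257 genes are strongly
repressed and 120 strongly induced, then normalises, forms ratios to the
logarithmic-growth baseline and applies the strict >10-fold filters.
"""

import pandas as pd

import tnscreen as tn

truth = tn.build_expression_truth(n_genes=4836, n_down=257, n_up=120, seed=5)
counts, truth, lengths = tn.generate_rnaseq_counts(truth, dispersion=0.05,
                                                   seed=5)

library_sizes = pd.Series(1.0, index=counts.columns)  # equal by design
expression = tn.normalize_counts(counts, lengths, library_sizes)
ratios = tn.ratio_to_baseline(expression, "log_phase")

down, n_down = tn.fold_filter(ratios, "180h", fold=10, direction="down")
up, n_up = tn.fold_filter(ratios, "180h", fold=10, direction="up")

true_down = set(truth.loc[truth["180h"] < 0.1, "gene_id"])
true_up = set(truth.loc[truth["180h"] > 10, "gene_id"])
print(f"at 180 h: {n_down} genes >10-fold down (planted {len(true_down)}), "
      f"{n_up} genes >10-fold up (planted {len(true_up)})")
print(f"down recall {len(set(down) & true_down) / len(true_down):.3f}, "
      f"up recall {len(set(up) & true_up) / len(true_up):.3f}")

# Counts land close to the planted 257/120 because every planted fold
# exceeds 12; the handful of misses are genes whose sampled counts happen
# to pull the observed ratio just inside the 10-fold threshold.
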