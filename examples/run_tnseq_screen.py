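"""Run the insertion-fitness screen on a synthetic mutant pool.

Builds a scaled-down saturating transposon library (1,000 genes, ~36
insertion sites per gene) in which 2% of genes are longevity-defective:
their mutants die off at 0.2/day once growth arrests, a >16-fold depletion
by day 14. Two replicate cultures are sequenced at 0/3/7/14/30 days and the
pipeline calls per-gene insertion fitness, forms replicate consensus and
assembles the longevity gene set from the 3-14 day window.
"""

import tnscreen as tn

pool = tn.build_pool(n_genes=1000, sites_per_gene=36, frac_defective=0.02,
                     death_rate=0.2, seed=42)
trajectory = tn.simulate_abundances(pool)
counts, manifest = tn.sample_reads(trajectory, depth=1_000_000, seed=42)

results = tn.run_fitness_pipeline(counts, manifest, pool.genes)

planted = set(pool.genes.loc[
    pool.genes.phenotype == "longevity_defective", "gene_id"])
found = set(results.longevity_genes)

print(f"pool: {pool.n_mutants} mutants across {len(pool.genes)} genes")
for sample_id in ("t0d_r1", "t14d_r1"):
    fit = results.fits[sample_id]
    print(f"{sample_id}: log2 RpK ~ N(mu={fit.mu:.2f}, sigma={fit.sigma:.2f})"
          f" over {fit.n_bins} bins (rmse {fit.rmse:.1f})")
print(f"longevity set: {len(found)} genes "
      f"({len(found & planted)}/{len(planted)} planted defective genes "
      f"recovered, {len(found - planted)} neutral false positives)")
print("earliest timepoints of recovered genes:")
hits = results.longevity[results.longevity.in_longevity_set]
print(hits.earliest_timepoint.value_counts().sort_index().to_string())

# The mu/sigma lines describe the fitted null distribution each sample's
# calls are made against; a defective gene is called when it falls below
# the 95% band of that Gaussian in both replicates. Most planted genes
# surface at day 7 or 14, when their mutants are 4- to 16-fold depleted.
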