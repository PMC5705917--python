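"""Fold overrepresentation of a functional category in a gene set.

The arithmetic behind 'transporters are twice overrepresented': 15 of a
117-gene longevity set versus 293 transporter genes among 4,836 genome
loci.
"""

import tnscreen as tn

annotation = {f"g{i}": ("transporters" if i < 293 else "other")
              for i in range(4836)}
longevity_set = [f"g{i}" for i in range(15)]          # 15 transporters
longevity_set += [f"g{i}" for i in range(300, 402)]   # 102 other genes

census = tn.category_census(longevity_set, annotation, "transporters")
print(f"set: {census.set_count}/{census.set_size} "
      f"= {100 * census.set_fraction:.1f} %")
print(f"genome: {census.genome_count}/{census.genome_size} "
      f"= {100 * census.genome_fraction:.1f} %")
print(f"fold overrepresentation: {census.fold:.2f}")

# 12.8% of the set vs 6.1% of the genome: transporters are ~2.1x enriched
# among longevity genes — the census reports the ratio of the two
# fractions, with no hypothesis test attached.
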