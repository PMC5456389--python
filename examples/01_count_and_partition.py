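"""Count regulation events and partition genes by DEN.

Builds a small synthetic fold-change matrix, counts how often each gene
crosses the two-fold-change thresholds across treated samples (its DEN),
and splits genes into the frequently regulated top 15% versus the rest.
"""

import denpipe
from denpipe.den_core import (
    aggregate_to_genes,
    count_regulation,
    den_distribution_summary,
    partition_genes,
    partition_overlap,
)
from denpipe.synthetic_data import fixture_config, generate_dataset

dataset = generate_dataset(fixture_config("tiny", seed=42))
print(f"matrix: {dataset.matrix.shape[0]} probes x {dataset.matrix.shape[1]} samples")

probe_counts = count_regulation(dataset.matrix)  # default cutoffs +/-0.69 lnFC
gene_counts = aggregate_to_genes(probe_counts, dataset.probe_map, policy="max")
print(f"genes scored: {len(gene_counts)}")

up = partition_genes(gene_counts, "up", fraction=0.15)
down = partition_genes(gene_counts, "down", fraction=0.15)
print(f"up_h size: {len(up.high_set)}  down_h size: {len(down.high_set)}")

summary = den_distribution_summary(gene_counts, "up")
# share of all up-regulation events carried by the top 15% of genes --
# close to 1 means a few genes absorb most drug responses
print(f"top-15% share of up events: {summary['top_share']:.3f}")

overlap = partition_overlap(up.high_set, down.high_set)
# genes can be frequently regulated in both directions
print(f"up_h/down_h overlap: {overlap['n_intersection']} genes "
      f"(Jaccard {overlap['jaccard']:.3f})")
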