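# denpipe

Some genes respond to almost any drug; most respond to almost none. Given a
large compendium of drug-perturbation transcriptome profiles — a probe ×
treated-sample matrix of natural-log fold changes (lnFC) against matched
controls — `denpipe` quantifies this with the **differential expression
number (DEN)**: for each gene and direction, the count of treated samples in
which the gene crosses a two-fold-change threshold,

```
up-DEN(g)   = #{ samples s : lnFC(g, s) >  0.69 }        (0.69 = round(ln 2, 2))
down-DEN(g) = #{ samples s : lnFC(g, s) < -0.69 }
```

Genes are ranked by DEN and split into the frequently regulated top 15%
(`up_h` / `down_h`) versus the rest (`up_l` / `down_l`), and the two sets are
then compared across every annotation axis relevant to drug-target triage:
intra-chromosomal clustering (pairwise midpoint distances), tissue expression
specificity (TES = max expression / summed expression across tissues),
earliest developmental expression stage, homolog counts and phyletic age, SNP
density and disease-SNP (ClinVar-style) fraction, protein-interaction degree,
and GO subcellular localisation. Comparisons use the field's nonparametric
workhorses — Wilcoxon rank-sum and signed-rank, Pearson chi-squared,
two-sample Kolmogorov–Smirnov, Fisher's exact test, Spearman correlation —
with exact enumeration-equivalent p-values for small tie-free samples and a
Benjamini–Hochberg column reported alongside every raw p.

The package is aimed at computational biologists doing drug-perturbation or
target-prioritisation analyses who need the whole chain — file parsing, DEN
counting, partitioning, feature derivation, statistics, reporting — as a
tested, seeded, reproducible library. A synthetic-data generator with
plantable effect sizes makes every stage verifiable without any external
download: it draws heavy-tailed per-gene regulation propensities (producing
the power-law-like DEN distributions seen in real compendia) and can link
each annotation axis to propensity with a configurable signed effect.

## Worked example

```python
from denpipe.den_core import (aggregate_to_genes, count_regulation,
                              den_distribution_summary, partition_genes)
from denpipe.synthetic_data import fixture_config, generate_dataset

dataset = generate_dataset(fixture_config("tiny", seed=42))
probe_counts = count_regulation(dataset.matrix)          # +/-0.69 lnFC cutoffs
gene_counts = aggregate_to_genes(probe_counts, dataset.probe_map, policy="max")
up = partition_genes(gene_counts, "up", fraction=0.15)
print(len(up.high_set), den_distribution_summary(gene_counts, "up")["top_share"])
```

prints `7 0.295...`: of 50 genes, the 7 in the top 15% carry 29.5% of all
up-regulation events in this small fixture. At realistic scale
(`fixture_config("planted_paper_like")`, 2000 genes × 100 samples, heavy
Pareto tail) the top 15% carry well over half of all events.

Running the full comparison suite on that planted dataset
(`examples/02_planted_effects.py`) prints, among others:

```
             feature group_high             test    statistic       p_value    direction
chromosomal_distance       up_h wilcoxon_ranksum 4.917449e+07  1.788837e-62  low_greater
                 tes       up_h wilcoxon_ranksum 3.565570e+05  3.322879e-28 high_greater
              degree       up_h wilcoxon_ranksum 1.430110e+05  2.136037e-09  low_greater
       dsnp_fraction       up_h     fisher_exact 1.824465e+00 9.313634e-120 high_greater
```

Read: frequently up-regulated genes sit closer together on their chromosomes
(`low_greater` — the high set has *smaller* pair distances), are more
tissue-specific, have fewer interaction partners, and carry a higher
disease-SNP fraction (odds ratio 1.82) than rarely up-regulated genes —
exactly the directions planted in the generator.

The `examples/` directory holds one short script per capability: DEN counting
and partitioning, planted-effect recovery, the statistical toolbox, and the
file-based pipeline (`den run` equivalent). The `den` command-line tool
(`den count`, `den simulate`, `den run`, `den report`) is a thin wrapper over
the same functions; every run writes a metadata record (config echo, seeds,
input checksums) sufficient to reproduce it exactly.

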