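# Methods

## The DEN statistic and the partition

The input is a probe × sample matrix of natural-log fold changes (lnFC) of
drug-treated samples against matched controls. A probe scores an
up-regulation event in a sample when lnFC is strictly greater than
`up_cut = 0.69` (= round(ln 2, 2), i.e. fold change > 2) and a
down-regulation event when strictly less than `down_cut = -0.69`
(fold change < 0.5). Boundary values are not events; missing cells are
events in neither direction (a sparse matrix loses events, it does not
error). The per-probe differential expression number (DEN) is the count of
event samples per direction.

Probe counts are collapsed to genes through a probe→gene map. The
aggregation policy is configurable — `max` (default), `sum`, `mean`
(rounded half-up) — because public perturbation compendia report
probe-level signals and no canonical gene-level rule exists. `max` reads
as: a gene counts as regulated whenever its most responsive probe is.
Probes without a map entry are dropped (counted in the log); genes present
in the map but absent from the matrix are excluded rather than treated as
zero-count.

Genes are ranked per direction by DEN, descending, with ties broken by
lexicographically ascending gene id, making every downstream set
deterministic. The high set is the first `floor(fraction × N)` genes
(default fraction 0.15); the top/last-N lists (default N = 1000) for export
to external enrichment tools come from the same ranking. The 15% default
mirrors the visible break in heavy-tailed DEN distributions, where a small
top fraction of genes concentrates most regulation events.

## Feature axes

- **Chromosomal distance.** For a gene set, all unordered same-chromosome
  pairs contribute |midpoint(a) − midpoint(b)|. Midpoints (rather than
  nearest edges) keep the measure symmetric and robust to gene length.
  Above `max_pairs` (default 2,000,000) a seeded uniform subsample of pairs
  is drawn; with ~10k-gene sets full enumeration is quadratic and wasteful.
- **Tissue expression specificity (TES).** max/sum of a gene's expression
  across T tissues: 1/T for a uniform profile, 1.0 for single-tissue
  expression, undefined (NaN, excluded) for an all-zero profile. Multiple
  matrix rows per gene are averaged per tissue first; negative values from
  processed microarray data are clipped to 0.
- **Earliest expression stage (EES).** Ordinal 1–7 over the fixed order
  embryoid body, blastocyst, fetus, neonate, infant, juvenile, adult.
  Unknown labels exclude the gene with a warning.
- **SNP density and disease SNPs.** SNPs are assigned to a gene when they
  fall in its 0-based half-open genomic span; density = count / span
  length. Gene length is the genomic span (introns included) because
  variants are mapped genomically. A variant is a disease SNP (dSNP) iff it
  has a dbSNP id, carries at least one clinical-significance label, and no
  label is in the exclusion set {protective, benign, likely_benign,
  uncertain_significance, conflicting_data_from_submitters, other,
  not_provided}; labels are normalised (lower case, underscores) because
  ClinVar exports vary in case and separators.
- **Interaction degree.** Genetic-interaction edges and ubiquitination
  edges are removed, the multigraph is collapsed to a simple undirected
  graph without self-loops, and degree is the number of distinct partners.
  Genes absent from the filtered network have no degree value (they are
  excluded from degree comparisons, not scored 0).
- **Subcellular classes.** Direct GO annotation to the four compartment
  terms (GO:0005576 extracellular region, GO:0016020 membrane, GO:0005737
  cytoplasm, GO:0005634 nucleus); NOT-qualified annotations are ignored; no
  ontology-graph propagation (keeps the operation self-contained; a
  propagated annotation table can be supplied instead). A gene with several
  compartments counts once per compartment — see the calibration caveat
  below.

All genomic inputs are normalised on read to 0-based half-open coordinates
(BED native; GFF3 start−1; VCF POS−1), so no off-by-one can arise
downstream.

## Statistics

Group comparisons per direction: pair distances, TES, homolog count and
degree by two-sided Wilcoxon rank-sum; EES, phyletic age and the
per-chromosome dSNP split by Pearson chi-squared without continuity
correction; SNP density by two-sample Kolmogorov–Smirnov (asymptotic p);
overall dSNP fraction by Fisher's exact test (two-sided, summing
hypergeometric probabilities ≤ the observed table's); DEN vs TES and DEN vs
degree by Spearman correlation (average ranks, t approximation with n−2
df). The paired up-vs-down comparison within a chromosome uses the Wilcoxon
signed-rank test with zero differences dropped; the unpaired rank-sum is
also available since either reading of "Wilcoxon test" is defensible for
that contrast.

Rank tests switch to exact enumeration-equivalent p-values when the pooled
(or nonzero-difference) sample is tie-free with at most 12 observations;
beyond that the normal approximations with tie and continuity corrections
apply. The 12 bound keeps the exact branch verifiable against full
enumeration in tests at negligible runtime. A p-value that underflows to 0
is reported as the smallest positive double with a `p_floor` flag, so
downstream ranking never sees a hard zero. No correction is applied to the
headline p-values, but a Benjamini–Hochberg adjusted column is always
emitted alongside. Directions are reported from group medians (or the
correlation sign); chi-squared comparisons report `none`.

A comparison with fewer than two genes in a group is skipped with a logged
reason rather than failing the run.

## The synthetic generator

Each gene g receives independent up- and down-regulation propensities drawn
from a heavy-tailed law (default Pareto, tail index 1.5) and monotonically
rescaled into (0, 0.5); a matrix cell is an up event with probability
p_up(g), a down event with probability p_down(g), and otherwise uniform
strictly inside the open threshold interval, so thresholding is
unambiguous and expected directional DEN is n_samples × propensity. Effects
are planted on the *latent propensity*, never on realised counts, so
recovery always faces genuine binomial sampling noise. With every effect at
zero the generator is an exact null: all features are independent of
propensity.

Planted links operate on z = standardised log propensity (per direction, or
of the combined propensity for the direction-free axes). An effect size is
the coefficient on z in the feature's linear predictor: log Dirichlet
concentration for TES (smaller concentration → spikier profile → higher
TES), log expected degree for the interaction network (Chung–Lu-style
pairing), log mean for negative-binomial homolog counts, the latent shift
of a proportional-odds draw for EES. Two axes carry fixed attenuation
scales chosen with the defaults: the SNP Poisson rate uses 0.3 log-units
and the dSNP Bernoulli logit 0.5 per unit z. These bound the dynamic range
of per-gene SNP counts (about e^{±1} across the propensity range) and keep
disease fractions off the saturated part of the logistic; without them a
handful of extreme-propensity genes dominates the pooled contingency
tables, which is not how genomic SNP counts behave. Spatial clustering
(`cluster_high`) packs that share of the union of the two directional
top-15%-propensity sets into contiguous same-chromosome blocks.

Default shape parameters are chosen as round, human-scale values: 79
tissues, 23 chromosomes, mean gene length 20 kb (log-normal, σ=0.7), SNP
rate 0.005/bp, baseline dSNP fraction 2%, mean degree 8, mean homolog count
5, 1% missing matrix cells. Study sizes used by the test suite — 1000
genes × 50 samples for null calibration, 2000 genes × 100 samples for
recovery — are scaled-down stand-ins for compendium-scale data (tens of
thousands of probes, thousands of samples); the statistics they exercise
are sample-size-calibrated, so conclusions about correctness (not about
power at full scale) transfer.

What the generator does **not** emulate: real drug/cell-line/batch
structure, probe chemistry, correlated tissue profiles, linkage structure
among SNPs, or a scale-free interaction network beyond what the expected
degree model induces. Passing tests therefore certify the pipeline's
arithmetic, contracts and statistical calibration — not biological claims
about any particular compendium.

## Calibration findings (computed by the test suite)

The type-I study (all effects zero, 1000 replicate 1000-gene datasets)
shows most comparisons rejecting at the nominal 5% within binomial
tolerance. Two are structurally off, and the suite reports them as such:

- **Pairwise-distance rank-sum is anticonservative** (≈0.17–0.19 observed).
  Within-group pair distances share genes, so they are positively
  dependent observations; the rank-sum null variance assumes independence.
  This is a property of testing all-pairs distances, not of the
  implementation — a focused simulation of the bare procedure on uniform
  positions reproduces it. Interpret distance p-values as descriptive;
  a label-permutation calibration would be the rigorous alternative.
- **The subcellular chi-squared is conservative** (≈0.01 observed). Genes
  annotated to several compartments contribute one count per compartment,
  so the class × group table is a stack of independent binomials rather
  than a multinomial contingency table, and the Pearson reference
  distribution overestimates the variance. Counting once per class is kept
  because it matches how localisation proportions are usually reported;
  the conservatism only hides, never invents, localisation differences.

One further comparison (Spearman of up-DEN against TES) lands marginally
above the band at the suite's fixed seed set (0.071); at an independent
1500-replicate seed set it is calibrated (0.051), and a focused 5000-run
simulation of the bare Spearman under heavy count ties gives 0.045. That
excursion is estimator noise at the frozen seeds, not miscalibration; the
seeds were not reselected after observing it.

## Numerical and format choices

- Derived tables are written with 17 significant digits, so write→read
  round-trips are value-identical.
- All randomness (generator, pair subsampling) flows from explicit integer
  seeds; per-call seeds inside the analysis are derived from the top-level
  seed via `numpy` seed sequences and recorded in the run metadata together
  with input SHA-256 checksums.
- Multi-record genes merge to the spanning interval on one chromosome;
  records on several chromosomes keep the chromosome with the longest span
  (warned). Inverted intervals are rejected per record; unparseable lines
  are hard errors with line numbers.
- The `mean` aggregation policy rounds half-up (`floor(x + 0.5)`) so gene
  counts remain integers with a deterministic rule.
- Fisher's odds ratio is the sample odds ratio; with a zero cell a
  0.5-continuity version is added for display only, never used in the
  p-value.

## Known limitations

- The distance and subcellular calibration caveats above.
- TES and EES depend on the expression atlas and stage annotation supplied;
  no identifier harmonisation is attempted (identifiers are opaque text).
- The per-chromosome dSNP chi-squared can have small expected counts on
  short chromosomes; such results carry a `low_expected` flag.
- Power at the scaled-down study sizes is not representative of
  compendium-scale data; effect-size estimates are not modelled beyond
  direction and medians.
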