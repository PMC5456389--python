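"""Per-gene features compared between frequently and rarely regulated genes.

Each operation produces one comparison axis: intra-chromosomal pair
distances, tissue expression specificity (TES), earliest expression stage
(EES), SNP density and disease-SNP status, protein-interaction degree, and
GO-based subcellular class membership.  Operations are vectorised over all
genes; thin single-record wrappers are provided where a scalar contract is
more natural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneLocus, InteractionEdge, VariantRecord

logger = logging.getLogger(__name__)

#: Developmental stages in order; the earliest expression stage of a gene is
#: reported as the ordinal of the first stage at which it is expressed.
STAGE_ORDER = (
    "embryoid body",
    "blastocyst",
    "fetus",
    "neonate",
    "infant",
    "juvenile",
    "adult",
)
STAGE_TO_ORDINAL = {
    name.replace(" ", "_"): i + 1 for i, name in enumerate(STAGE_ORDER)
}

#: GO terms defining the four subcellular classes (direct annotation only,
#: no ontology-graph propagation).
SUBCELLULAR_GO_TERMS = {
    "GO:0005576": "extracellular region",
    "GO:0016020": "membrane",
    "GO:0005737": "cytoplasm",
    "GO:0005634": "nucleus",
}
SUBCELLULAR_CLASSES = tuple(SUBCELLULAR_GO_TERMS.values())

#: Clinical-significance labels that disqualify a variant from disease-SNP
#: status (normalised form: lower case, underscores).
DSNP_EXCLUDED_LABELS = frozenset(
    {
        "protective",
        "benign",
        "likely_benign",
        "uncertain_significance",
        "conflicting_data_from_submitters",
        "other",
        "not_provided",
    }
)

__all__ = [
    "STAGE_ORDER",
    "STAGE_TO_ORDINAL",
    "SUBCELLULAR_GO_TERMS",
    "SUBCELLULAR_CLASSES",
    "DSNP_EXCLUDED_LABELS",
    "GeneVariantSummary",
    "chrom_pair_distances",
    "chromosome_den_table",
    "tissue_specificity",
    "tissue_specificity_scores",
    "earliest_stage",
    "earliest_stage_table",
    "is_disease_snp",
    "variant_summary",
    "variant_summaries",
    "ppi_degrees",
    "subcellular_classes",
    "subcellular_table",
]


@dataclass(frozen=True)
class GeneVariantSummary:
    """SNP content of one gene span."""

    gene_id: str
    snp_count: int
    dsnp_count: int
    gene_length: int

    def __post_init__(self) -> None:
        if self.dsnp_count > self.snp_count:
            raise ValueError("dsnp_count cannot exceed snp_count")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")

    @property
    def snp_density(self) -> float:
        return self.snp_count / self.gene_length


# ---------------------------------------------------------------------------
# chromosomal distances
# ---------------------------------------------------------------------------

def _locus_frame(loci) -> pd.DataFrame:
    if isinstance(loci, pd.DataFrame):
        return loci
    from .io_formats import loci_frame

    return loci_frame(loci)


def _triangular_pair(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode linear indices of the strict upper triangle of an n x n grid
    into (i, j) pairs with i < j."""
    # row i starts at offset i*n - i*(i+1)/2 - i - ... ; solve quadratically
    # using the count of pairs before row i: c(i) = i*(2n - i - 1)/2.
    i = (2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * idx)) // 2
    i = i.astype(np.int64)
    before = i * (2 * n - i - 1) // 2
    j = idx - before + i + 1
    return i, j.astype(np.int64)


def chrom_pair_distances(loci, genes: set[str] | frozenset[str],
                         max_pairs: int | None = 2_000_000,
                         seed: int = 0) -> np.ndarray:
    """Midpoint distances for all same-chromosome pairs of the given genes.

    Genes without a locus are skipped (logged).  When the total number of
    pairs exceeds ``max_pairs`` a uniform random subsample of that size is
    drawn with the given seed; identical seeds give identical subsamples.
    Returns an empty (flagged) array when no chromosome holds two genes.
    """
    frame = _locus_frame(loci)
    sub = frame[frame["gene_id"].isin(genes)]
    n_missing = len(genes) - len(sub)
    if n_missing:
        logger.info("chrom_pair_distances: %d genes without loci skipped", n_missing)

    per_chrom: list[tuple[np.ndarray, int]] = []
    total_pairs = 0
    for _, grp in sub.groupby("chromosome", sort=True):
        if len(grp) < 2:
            continue
        mids = ((grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0)
        mids = np.sort(mids)
        n = len(mids)
        per_chrom.append((mids, n))
        total_pairs += n * (n - 1) // 2
    if total_pairs == 0:
        logger.warning("chrom_pair_distances: no chromosome holds 2+ genes")
        return np.empty(0, dtype=float)

    if max_pairs is not None and total_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(total_pairs, size=max_pairs, replace=False)
        chosen.sort()
        out = np.empty(max_pairs, dtype=float)
        offset = 0
        filled = 0
        for mids, n in per_chrom:
            n_pairs = n * (n - 1) // 2
            in_block = chosen[(chosen >= offset) & (chosen < offset + n_pairs)] - offset
            if in_block.size:
                i, j = _triangular_pair(in_block, n)
                out[filled:filled + in_block.size] = mids[j] - mids[i]
                filled += in_block.size
            offset += n_pairs
        return out

    chunks = []
    for mids, n in per_chrom:
        diff = np.abs(mids[:, None] - mids[None, :])
        chunks.append(diff[np.triu_indices(n, k=1)])
    return np.concatenate(chunks)


def chromosome_den_table(gene_counts: pd.DataFrame, loci) -> pd.DataFrame:
    """Per-gene (chromosome, up_count, down_count) rows for genes with loci.

    The paired per-gene counts feed the per-chromosome up-vs-down
    comparison; genes without a locus are excluded and the exclusion count
    logged.  Column totals over chromosomes equal totals over the genes
    that have loci.
    """
    frame = _locus_frame(loci).set_index("gene_id")
    gene_ids = gene_counts.index.astype(str)
    present = gene_ids.isin(frame.index)
    n_excluded = int((~present).sum())
    if n_excluded:
        logger.info("chromosome_den_table: %d genes without loci excluded", n_excluded)
    sub = gene_counts.loc[present, ["up_count", "down_count"]].copy()
    sub["chromosome"] = frame.loc[sub.index.astype(str), "chromosome"].to_numpy()
    sub.index.name = "gene_id"
    return sub.reset_index()[["gene_id", "chromosome", "up_count", "down_count"]]


# ---------------------------------------------------------------------------
# tissue expression specificity
# ---------------------------------------------------------------------------

def tissue_specificity(expression: np.ndarray | list[float]) -> float:
    """TES of one profile: max expression over sum across tissues.

    1/T for a uniform positive profile of T tissues, 1.0 when a single
    tissue carries all expression; NaN (undefined) when the profile sums
    to zero.
    """
    values = np.clip(np.asarray(expression, dtype=float), 0.0, None)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("profile must be a 1-d vector of >= 2 tissues")
    total = values.sum()
    if total <= 0:
        return float("nan")
    return float(values.max() / total)


def tissue_specificity_scores(tissue_matrix: pd.DataFrame) -> pd.Series:
    """TES per gene for a gene x tissue matrix (NaN where the row sum is 0)."""
    if tissue_matrix.shape[1] < 2:
        raise ValueError("tissue matrix needs >= 2 tissues")
    values = np.clip(tissue_matrix.to_numpy(dtype=float), 0.0, None)
    totals = values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tes = np.where(totals > 0, values.max(axis=1) / totals, np.nan)
    return pd.Series(tes, index=tissue_matrix.index, name="tes")


# ---------------------------------------------------------------------------
# earliest expression stage
# ---------------------------------------------------------------------------

def _normalise_stage(label: str) -> str:
    return label.strip().lower().replace(" ", "_")


def earliest_stage(gene_id: str, stage_labels: pd.Series | dict) -> int | None:
    """Ordinal (1..7) of the gene's earliest expression stage label.

    Unknown labels exclude the gene (None, with a warning)."""
    label = stage_labels.get(gene_id) if hasattr(stage_labels, "get") else None
    if label is None:
        return None
    ordinal = STAGE_TO_ORDINAL.get(_normalise_stage(str(label)))
    if ordinal is None:
        logger.warning("unknown developmental stage %r for gene %s; excluded",
                       label, gene_id)
    return ordinal


def earliest_stage_table(stage_labels: pd.Series) -> pd.Series:
    """Map a gene -> stage-label series to ordinals, dropping unknown labels."""
    normalised = stage_labels.astype(str).map(_normalise_stage)
    ordinals = normalised.map(STAGE_TO_ORDINAL)
    unknown = ordinals.isna()
    if unknown.any():
        logger.warning("%d genes with unknown developmental stages excluded",
                       int(unknown.sum()))
    return ordinals[~unknown].astype(int).rename("ees")


# ---------------------------------------------------------------------------
# SNPs and disease SNPs
# ---------------------------------------------------------------------------

def is_disease_snp(variant: VariantRecord) -> bool:
    """Disease-SNP test: a dbSNP id is present, at least one clinical
    significance label is present, and no label is in the exclusion set
    (protective / (likely) benign / uncertain significance / conflicting /
    other / not provided)."""
    if variant.rs_id is None:
        return False
    labels = variant.clinical_significance
    if not labels:
        return False
    return not (labels & DSNP_EXCLUDED_LABELS)


def _variants_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    from .io_formats import variants_frame

    return variants_frame(variants)


def _dsnp_mask(frame: pd.DataFrame) -> np.ndarray:
    if "is_dsnp" in frame.columns:
        return frame["is_dsnp"].to_numpy(dtype=bool)
    has_rs = frame["rs_id"].notna().to_numpy()
    labels = frame["clinical_significance"]
    has_label = labels.map(lambda s: len(s) > 0).to_numpy(dtype=bool)
    excluded = labels.map(lambda s: bool(s & DSNP_EXCLUDED_LABELS)).to_numpy(dtype=bool)
    return has_rs & has_label & ~excluded


def variant_summary(locus: GeneLocus, variants,
                    dsnp_filter=is_disease_snp) -> GeneVariantSummary:
    """SNP and disease-SNP counts for a single gene span.

    A variant is counted iff it lies on the locus chromosome with
    start <= position < end (half-open); density = snp_count / length.
    """
    snp = 0
    dsnp = 0
    for v in variants:
        if v.chromosome == locus.chromosome and locus.start <= v.position < locus.end:
            snp += 1
            if dsnp_filter(v):
                dsnp += 1
    return GeneVariantSummary(locus.gene_id, snp, dsnp, locus.length)


def variant_summaries(loci, variants) -> pd.DataFrame:
    """Vectorised per-gene SNP summaries for all loci.

    Returns gene_id, chromosome, gene_length, snp_count, dsnp_count and
    snp_density.  Interval membership uses the same half-open convention
    as :func:`variant_summary`.
    """
    locus_frame = _locus_frame(loci)
    var_frame = _variants_frame(variants)
    if var_frame.empty:
        out = locus_frame[["gene_id", "chromosome"]].copy()
        out["gene_length"] = locus_frame["end"] - locus_frame["start"]
        out["snp_count"] = 0
        out["dsnp_count"] = 0
        out["snp_density"] = 0.0
        return out

    dsnp = _dsnp_mask(var_frame)
    rows = []
    for chrom, genes in locus_frame.groupby("chromosome", sort=True):
        on_chrom = var_frame["chromosome"].to_numpy() == chrom
        positions = np.sort(var_frame.loc[on_chrom, "position"].to_numpy())
        d_positions = np.sort(var_frame.loc[on_chrom][dsnp[on_chrom]]["position"].to_numpy())
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        snp_counts = np.searchsorted(positions, ends, side="left") - \
            np.searchsorted(positions, starts, side="left")
        dsnp_counts = np.searchsorted(d_positions, ends, side="left") - \
            np.searchsorted(d_positions, starts, side="left")
        lengths = ends - starts
        rows.append(pd.DataFrame({
            "gene_id": genes["gene_id"].to_numpy(),
            "chromosome": chrom,
            "gene_length": lengths,
            "snp_count": snp_counts,
            "dsnp_count": dsnp_counts,
            "snp_density": snp_counts / lengths,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# protein-interaction degree
# ---------------------------------------------------------------------------

def ppi_degrees(edges: list[InteractionEdge] | pd.DataFrame,
                drop_genetic: bool = True,
                drop_ubiquitination: bool = True) -> pd.Series:
    """Interaction-network degree (distinct partners) per gene.

    Genetic-interaction edges and ubiquitination edges are removed (both
    on by default), the remaining multigraph is collapsed to a simple
    undirected graph without self-loops, and degree is the number of
    distinct partners.  Sum of degrees equals twice the retained simple
    edge count.
    """
    if isinstance(edges, pd.DataFrame):
        frame = edges.copy()
    else:
        frame = pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "system_class": e.system_class,
                    "modification": e.modification,
                }
                for e in edges
            ],
            columns=["gene_a", "gene_b", "system_class", "modification"],
        )
    if frame.empty:
        return pd.Series(dtype=int, name="degree")
    if drop_genetic and "system_class" in frame.columns:
        frame = frame[frame["system_class"] != "genetic"]
    if drop_ubiquitination and "modification" in frame.columns:
        mods = frame["modification"].fillna("").astype(str).str.lower()
        frame = frame[mods != "ubiquitination"]
    a = frame["gene_a"].astype(str)
    b = frame["gene_b"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    simple = pd.DataFrame({"lo": lo, "hi": hi})
    simple = simple[simple["lo"] != simple["hi"]].drop_duplicates()
    if simple.empty:
        return pd.Series(dtype=int, name="degree")
    degrees = pd.concat([simple["lo"], simple["hi"]]).value_counts().sort_index()
    degrees.name = "degree"
    degrees.index.name = "gene_id"
    return degrees.astype(int)


# ---------------------------------------------------------------------------
# subcellular classes (GO)
# ---------------------------------------------------------------------------

def subcellular_classes(gaf: pd.DataFrame, gene_id: str) -> frozenset[str]:
    """Subset of the four target classes directly annotating one gene.

    Annotations with a NOT qualifier are ignored."""
    table = subcellular_table(gaf)
    if gene_id not in table.index:
        return frozenset()
    row = table.loc[gene_id]
    return frozenset(c for c in SUBCELLULAR_CLASSES if row[c])


def subcellular_table(gaf: pd.DataFrame) -> pd.DataFrame:
    """Gene x class boolean membership table from GAF annotations.

    Only the four compartment terms are considered (direct annotation, no
    graph propagation); NOT-qualified rows are dropped.  Genes appearing
    in the GAF but matching no target term get an all-False row
    (uncategorised).
    """
    if gaf.empty:
        return pd.DataFrame(columns=list(SUBCELLULAR_CLASSES))
    qualifiers = gaf["qualifier"].fillna("").astype(str)
    negated = qualifiers.str.contains(r"\bNOT\b", case=True, regex=True) | \
        qualifiers.str.startswith("NOT")
    positive = gaf[~negated]
    genes = pd.Index(sorted(gaf["gene_id"].unique()), name="gene_id")
    table = pd.DataFrame(False, index=genes, columns=list(SUBCELLULAR_CLASSES))
    for go_id, cls in SUBCELLULAR_GO_TERMS.items():
        annotated = positive.loc[positive["go_id"] == go_id, "gene_id"].unique()
        table.loc[table.index.isin(annotated), cls] = True
    return table
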