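"""Synthetic drug-perturbation datasets with configurable planted effects.

The generator emulates the statistical structure of a large
drug-perturbation fold-change compendium: each gene carries latent up- and
down-regulation *propensities* drawn from a heavy-tailed law (so realised
per-gene event counts follow a power-law-like distribution in which a
small top fraction of genes holds most regulation events), and every
annotation axis (tissue specificity, genomic clustering, SNP/disease-SNP
content, interaction degree, homolog counts, developmental stage) can be
linked to the propensities with a configurable signed effect size.

Effects are planted on the latent propensity, not on the realised counts,
so that recovery tests face realistic sampling noise.  With all effect
sizes at zero the generator is an exact null: every feature is independent
of regulation propensity.

Fold-change values outside events are drawn strictly inside the open
threshold interval, so threshold counting is unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .gene_features import STAGE_ORDER, SUBCELLULAR_GO_TERMS
from .io_formats import FoldChangeMatrix, GeneLocus, VariantRecord

logger = logging.getLogger(__name__)

EFFECT_KEYS = (
    "tes_up", "tes_down", "cluster_high", "snp_density_high",
    "dsnp_frac_high", "degree_up", "degree_down", "homolog_high",
    "ees_up", "ees_down",
)

# Effect sizes are link-scale coefficients on the standardised
# log-propensity z: an effect of 1.0 shifts the feature's linear predictor
# (log concentration, log rate, logit, log mean, or ordinal latent) by one
# unit per standard deviation of log propensity.

#: baseline distribution over the seven developmental stages
EES_BASE_PROBS = np.array([0.15, 0.15, 0.20, 0.10, 0.10, 0.10, 0.20])

#: baseline phyletic-age categories and frequencies (oldest first)
PHYLETIC_AGES = ("early_eukaryote", "metazoa", "vertebrate", "mammal_specific")
PHYLETIC_BASE_PROBS = np.array([0.45, 0.25, 0.20, 0.10])

#: baseline marginal membership probability per subcellular class
SUBCELL_BASE_PROBS = {
    "extracellular region": 0.15,
    "membrane": 0.35,
    "cytoplasm": 0.45,
    "nucleus": 0.40,
}

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "make_fixture",
    "EFFECT_KEYS",
]


@dataclass
class SyntheticConfig:
    """Shape and planted-effect parameters of one synthetic dataset.

    ``propensity_law`` is ("pareto", alpha, xmin) or
    ("lognormal", mu, sigma); the draws are rescaled into (0, 0.5) so a
    gene's expected directional DEN is n_samples x propensity.  The
    default Pareto tail index of 1.5 produces the strongly heavy-tailed
    count distribution seen in large perturbation compendia.
    """

    n_genes: int = 1000
    probes_per_gene: int = 1
    n_samples: int = 100
    propensity_law: tuple = ("pareto", 1.5, 1.0)
    effect_sizes: dict = field(default_factory=dict)
    n_tissues: int = 79
    n_chromosomes: int = 23
    seed: int = 0
    up_cut: float = 0.69
    down_cut: float = -0.69
    mean_gene_length: float = 20_000.0
    gene_length_sigma: float = 0.7
    snp_rate_per_bp: float = 0.005
    dsnp_base_fraction: float = 0.02
    mean_degree: float = 8.0
    mean_homolog: float = 5.0
    missing_rate: float = 0.01
    # link scales for the SNP axes: these cap the dynamic range of per-gene
    # SNP counts (a Poisson rate moving e^{+/-1} across the propensity
    # range) and keep the disease fraction off the saturated part of the
    # logistic; pooled-count tests are otherwise dominated by a handful of
    # extreme-propensity genes.
    snp_rate_link_scale: float = 0.3
    dsnp_logit_link_scale: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_genes", "probes_per_gene", "n_samples",
                     "n_tissues", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.effect_sizes) - set(EFFECT_KEYS)
        if unknown:
            raise ValueError(f"unknown effect keys: {sorted(unknown)}")
        if self.propensity_law[0] not in {"pareto", "lognormal"}:
            raise ValueError(f"unknown propensity law {self.propensity_law[0]!r}")

    def effect(self, key: str) -> float:
        return float(self.effect_sizes.get(key, 0.0))


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated dataset."""

    gene_ids: list[str]
    p_up: np.ndarray        # per-gene up propensity in (0, 0.5)
    p_down: np.ndarray
    z_up: np.ndarray        # standardised log propensities
    z_down: np.ndarray
    z_comb: np.ndarray      # standardised log combined propensity
    clustered_genes: frozenset[str]
    effect_sizes: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "p_up": self.p_up,
            "p_down": self.p_down,
            "z_up": self.z_up,
            "z_down": self.z_down,
            "z_comb": self.z_comb,
            "clustered": [g in self.clustered_genes for g in self.gene_ids],
        })


@dataclass
class SyntheticDataset:
    """All generated inputs plus the ground truth."""

    matrix: FoldChangeMatrix
    probe_map: dict[str, str]
    loci: pd.DataFrame                 # gene_id, chromosome, start, end, strand
    tissue_matrix: pd.DataFrame        # gene x tissue
    variants: pd.DataFrame             # chromosome, position, rs_id, labels, is_dsnp
    edges: pd.DataFrame                # gene_a, gene_b, system_class, modification
    homolog: pd.Series
    phyletic: pd.Series
    ees_labels: pd.Series              # stage label text per gene
    gaf: pd.DataFrame                  # gene_id, qualifier, go_id
    truth: SyntheticTruth
    config: SyntheticConfig


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _draw_propensity(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "pareto":
        alpha, xmin = float(law[1]), float(law[2])
        raw = xmin * (1.0 + rng.pareto(alpha, size=n))
    else:
        mu, sigma = float(law[1]), float(law[2])
        raw = rng.lognormal(mean=mu, sigma=sigma, size=n)
    # monotone rescale into (0, 0.5); the heaviest gene sits just below 0.5
    return 0.5 * raw / (raw.max() * (1.0 + 1e-9))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete dataset (matrix plus every annotation table).

    Deterministic for a fixed config (including seed): same config twice
    gives byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    p_up = _draw_propensity(rng, config.propensity_law, n)
    p_down = _draw_propensity(rng, config.propensity_law, n)
    z_up = _standardise(np.log(p_up))
    z_down = _standardise(np.log(p_down))
    z_comb = _standardise(np.log(p_up + p_down))

    matrix, probe_map = _make_matrix(rng, config, gene_ids, p_up, p_down)
    loci, clustered = _make_loci(rng, config, gene_ids, p_up, p_down)
    tissue_matrix = _make_tissues(rng, config, gene_ids, z_up, z_down)
    variants = _make_variants(rng, config, loci, z_comb)
    edges = _make_edges(rng, config, gene_ids, z_up, z_down)
    homolog = _make_homolog(rng, config, gene_ids, z_comb)
    phyletic = _make_phyletic(rng, gene_ids)
    ees_labels = _make_ees(rng, config, gene_ids, z_up, z_down)
    gaf = _make_gaf(rng, gene_ids)

    truth = SyntheticTruth(
        gene_ids=gene_ids, p_up=p_up, p_down=p_down,
        z_up=z_up, z_down=z_down, z_comb=z_comb,
        clustered_genes=clustered,
        effect_sizes={k: config.effect(k) for k in EFFECT_KEYS},
    )
    return SyntheticDataset(
        matrix=matrix, probe_map=probe_map, loci=loci,
        tissue_matrix=tissue_matrix, variants=variants, edges=edges,
        homolog=homolog, phyletic=phyletic, ees_labels=ees_labels,
        gaf=gaf, truth=truth, config=config,
    )


def _make_matrix(rng, config, gene_ids, p_up, p_down):
    ppg = config.probes_per_gene
    n_probes = config.n_genes * ppg
    probe_ids = [f"P{g:05d}_{k}" for g in range(config.n_genes) for k in range(ppg)]
    probe_map = {
        pid: gene_ids[g] for pid, g in zip(probe_ids, np.repeat(np.arange(config.n_genes), ppg))
    }
    pu = np.repeat(p_up, ppg)[:, None]
    pd_ = np.repeat(p_down, ppg)[:, None]
    u = rng.random((n_probes, config.n_samples))
    up_mask = u < pu
    down_mask = (~up_mask) & (u < pu + pd_)
    margin = 0.001
    values = rng.uniform(config.down_cut + margin, config.up_cut - margin,
                         size=(n_probes, config.n_samples))
    magnitudes = rng.exponential(scale=0.4, size=(n_probes, config.n_samples))
    values[up_mask] = config.up_cut + margin + magnitudes[up_mask]
    values[down_mask] = config.down_cut - margin - magnitudes[down_mask]
    if config.missing_rate > 0:
        missing = rng.random((n_probes, config.n_samples)) < config.missing_rate
        values[missing] = np.nan
    frame = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"),
        columns=[f"S{j:04d}" for j in range(config.n_samples)],
    )
    return FoldChangeMatrix(frame), probe_map


def _make_loci(rng, config, gene_ids, p_up, p_down):
    """Place genes on chromosomes; with cluster_high > 0, that share of the
    top-propensity genes (the union of the top 15% by up and by down
    propensity) is packed into contiguous same-chromosome blocks instead
    of being placed uniformly."""
    n = config.n_genes
    lengths = np.maximum(
        rng.lognormal(np.log(config.mean_gene_length), config.gene_length_sigma,
                      size=n),
        200.0,
    ).astype(np.int64)
    chrom_of = rng.integers(0, config.n_chromosomes, size=n)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    # chromosome span generous enough for uniform placement
    span = max(int(lengths.sum() / config.n_chromosomes * 10), 10_000_000)

    starts = np.empty(n, dtype=np.int64)
    for c in range(config.n_chromosomes):
        on_c = np.flatnonzero(chrom_of == c)
        starts[on_c] = rng.integers(0, span, size=on_c.size)

    clustered: set[str] = set()
    effect = config.effect("cluster_high")
    if effect > 0:
        k = int(np.floor(0.15 * n))
        top_up = np.argsort(-p_up, kind="stable")[:k]
        top_down = np.argsort(-p_down, kind="stable")[:k]
        candidates = np.unique(np.concatenate([top_up, top_down]))
        share = min(1.0, effect)
        n_clustered = int(round(share * candidates.size))
        chosen = rng.permutation(candidates)[:n_clustered]
        clustered = {gene_ids[i] for i in chosen}
        # pack chosen genes per chromosome into one tight block each
        for c in range(config.n_chromosomes):
            block = [i for i in chosen if chrom_of[i] == c]
            if not block:
                continue
            origin = int(rng.integers(0, max(span // 2, 1)))
            cursor = origin
            for i in block:
                starts[i] = cursor
                gap = int(lengths[i] * rng.uniform(0.1, 1.0))
                cursor += int(lengths[i]) + gap

    frame = pd.DataFrame({
        "gene_id": gene_ids,
        "chromosome": [chrom_names[c] for c in chrom_of],
        "start": starts,
        "end": starts + lengths,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
    })
    return frame, frozenset(clustered)


def _make_tissues(rng, config, gene_ids, z_up, z_down):
    """Dirichlet tissue profiles: smaller concentration => spikier profile
    => higher tissue expression specificity."""
    shift = (config.effect("tes_up") * z_up + config.effect("tes_down") * z_down)
    log_alpha = -shift + rng.normal(0.0, 0.5, size=config.n_genes)
    alpha = np.clip(np.exp(log_alpha), 1e-3, 1e3)
    gammas = rng.gamma(shape=alpha[:, None],
                       scale=1.0, size=(config.n_genes, config.n_tissues))
    totals = gammas.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    profiles = gammas / totals * rng.lognormal(np.log(500.0), 0.5,
                                               size=(config.n_genes, 1))
    return pd.DataFrame(
        profiles, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"tissue_{t + 1:02d}" for t in range(config.n_tissues)],
    )


def _make_variants(rng, config, loci, z_comb):
    rate = config.snp_rate_per_bp * np.exp(
        config.snp_rate_link_scale * config.effect("snp_density_high") * z_comb)
    lengths = (loci["end"] - loci["start"]).to_numpy()
    counts = rng.poisson(rate * lengths)
    total = int(counts.sum())
    gene_idx = np.repeat(np.arange(len(loci)), counts)
    offsets = rng.random(total) * lengths[gene_idx]
    positions = loci["start"].to_numpy()[gene_idx] + offsets.astype(np.int64)
    chromosomes = loci["chromosome"].to_numpy()[gene_idx]

    base_logit = np.log(config.dsnp_base_fraction / (1 - config.dsnp_base_fraction))
    logit = base_logit + config.dsnp_logit_link_scale * \
        config.effect("dsnp_frac_high") * z_comb[gene_idx]
    disease_intent = rng.random(total) < 1.0 / (1.0 + np.exp(-logit))

    # realistic imperfections: some records lack a dbSNP id, some carry an
    # excluded significance label, some carry none at all
    has_rs = rng.random(total) >= 0.02
    label_choice = rng.random(total)
    labels = np.empty(total, dtype=object)
    labels[disease_intent] = "pathogenic"
    benign = ~disease_intent & (label_choice < 0.4)
    uncertain = ~disease_intent & (label_choice >= 0.4) & (label_choice < 0.6)
    likely = ~disease_intent & (label_choice >= 0.6) & (label_choice < 0.7)
    none_lbl = ~disease_intent & (label_choice >= 0.7)
    labels[benign] = "benign"
    labels[uncertain] = "uncertain_significance"
    labels[likely] = "likely_benign"
    labels[none_lbl] = ""

    rs_ids = np.char.add("rs", (np.arange(total) + 1).astype(str)).astype(object)
    rs_ids[~has_rs] = None
    label_sets = {
        "pathogenic": frozenset({"pathogenic"}),
        "benign": frozenset({"benign"}),
        "uncertain_significance": frozenset({"uncertain_significance"}),
        "likely_benign": frozenset({"likely_benign"}),
        "": frozenset(),
    }
    frame = pd.DataFrame({
        "chromosome": chromosomes,
        "position": positions,
        "rs_id": rs_ids,
        "clinical_significance": pd.Series(labels).map(label_sets).to_numpy(),
    })
    frame["is_dsnp"] = has_rs & disease_intent
    return frame.sort_values(["chromosome", "position"], kind="mergesort",
                             ignore_index=True)


def _make_edges(rng, config, gene_ids, z_up, z_down):
    """Configuration-model-style pairing with log-linear expected degrees."""
    shift = (config.effect("degree_up") * z_up + config.effect("degree_down") * z_down)
    log_deg = np.log(config.mean_degree) + shift + \
        rng.normal(0.0, 0.3, size=config.n_genes)
    weights = np.clip(np.exp(log_deg), 0.2, config.n_genes / 4.0)
    m = int(round(weights.sum() / 2.0))
    prob = weights / weights.sum()
    a = rng.choice(config.n_genes, size=m, p=prob)
    b = rng.choice(config.n_genes, size=m, p=prob)
    keep = a != b
    a, b = a[keep], b[keep]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    frame = pd.DataFrame({
        "gene_a": [gene_ids[i] for i in lo],
        "gene_b": [gene_ids[i] for i in hi],
    }).drop_duplicates(ignore_index=True)
    n_edges = len(frame)
    system = np.where(rng.random(n_edges) < 0.05, "genetic", "physical")
    modification = np.where(
        (system == "physical") & (rng.random(n_edges) < 0.03),
        "Ubiquitination", None)
    frame["system_class"] = system
    frame["modification"] = modification
    return frame


def _make_homolog(rng, config, gene_ids, z_comb):
    mu = config.mean_homolog * np.exp(
        config.effect("homolog_high") * z_comb)
    r = 2.0
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.Series(counts, index=pd.Index(gene_ids, name="gene_id"),
                     name="homolog_count")


def _make_phyletic(rng, gene_ids):
    ages = rng.choice(PHYLETIC_AGES, size=len(gene_ids), p=PHYLETIC_BASE_PROBS)
    return pd.Series(ages, index=pd.Index(gene_ids, name="gene_id"),
                     name="phyletic_age")


def _make_ees(rng, config, gene_ids, z_up, z_down):
    """Proportional-odds draw over the seven developmental stages; a
    positive shift pushes genes toward later stages."""
    shift = (config.effect("ees_up") * z_up
             + config.effect("ees_down") * z_down)
    cum = np.cumsum(EES_BASE_PROBS)[:-1]
    cutpoints = np.log(cum / (1.0 - cum))
    latent = shift + rng.logistic(0.0, 1.0, size=config.n_genes)
    stage_idx = np.searchsorted(cutpoints, latent, side="left")
    labels = [STAGE_ORDER[i] for i in stage_idx]
    return pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="ees")


def _make_gaf(rng, gene_ids):
    rows = []
    for go_id, cls in SUBCELLULAR_GO_TERMS.items():
        member = rng.random(len(gene_ids)) < SUBCELL_BASE_PROBS[cls]
        for gid in np.asarray(gene_ids, dtype=object)[member]:
            rows.append({"gene_id": gid, "qualifier": "located_in", "go_id": go_id})
    frame = pd.DataFrame(rows, columns=["gene_id", "qualifier", "go_id"])
    return frame.sort_values(["gene_id", "go_id"], kind="mergesort",
                             ignore_index=True)


# ---------------------------------------------------------------------------
# disk fixtures
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generated table in the dialect the readers consume.

    Returns the mapping of logical names to file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "loci": outdir / "loci.bed",
        "tissues": outdir / "tissues.tsv",
        "variants": outdir / "variants.vcf",
        "interactions": outdir / "interactions.tsv",
        "annotations": outdir / "annotations.tsv",
        "gaf": outdir / "go_annotations.gaf",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.json",
    }
    io_formats.write_matrix(dataset.matrix, paths["matrix"])
    io_formats.write_probe_gene_map(dataset.probe_map, paths["probe_map"])
    loci = [
        GeneLocus(r.gene_id, r.chromosome, int(r.start), int(r.end), r.strand)
        for r in dataset.loci.itertuples(index=False)
    ]
    io_formats.write_gene_loci_bed(loci, paths["loci"])
    dataset.tissue_matrix.to_csv(paths["tissues"], sep="\t", float_format="%.17g")
    variants = [
        VariantRecord(r.chromosome, int(r.position), r.rs_id,
                      frozenset(r.clinical_significance))
        for r in dataset.variants.itertuples(index=False)
    ]
    io_formats.write_variants_vcf(variants, paths["variants"])
    dataset.edges.fillna({"modification": "-"}).rename(columns={
        "gene_a": "Official Symbol Interactor A",
        "gene_b": "Official Symbol Interactor B",
        "system_class": "Experimental System Type",
        "modification": "Modification",
    }).to_csv(paths["interactions"], sep="\t", index=False)
    annotations = pd.concat([
        pd.DataFrame({"gene_id": dataset.homolog.index,
                      "feature_name": "homolog_count",
                      "value": dataset.homolog.astype(str).to_numpy()}),
        pd.DataFrame({"gene_id": dataset.phyletic.index,
                      "feature_name": "phyletic_age",
                      "value": dataset.phyletic.to_numpy()}),
        pd.DataFrame({"gene_id": dataset.ees_labels.index,
                      "feature_name": "earliest_stage",
                      "value": dataset.ees_labels.to_numpy()}),
    ], ignore_index=True)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    io_formats.write_gaf(dataset.gaf, paths["gaf"])
    io_formats.write_table(dataset.truth.frame(), paths["truth"])
    with open(paths["config"], "w") as handle:
        json.dump(dataclasses.asdict(dataset.config), handle, indent=2, default=str)
    return paths


PLANTED_PAPER_LIKE_EFFECTS = {
    # signs of the associations the analysis is built to detect:
    # frequently up-regulated genes are tissue-specific, late-expressed,
    # low-degree; frequently down-regulated genes the reverse; high-DEN
    # genes cluster in the genome, carry more (disease) SNPs and have
    # fewer homologs.
    "tes_up": 1.0,
    "tes_down": -1.0,
    "degree_up": -1.0,
    "degree_down": 1.0,
    "cluster_high": 1.0,
    "snp_density_high": 1.0,
    "dsnp_frac_high": 1.0,
    "homolog_high": -1.0,
    "ees_up": 1.0,
    "ees_down": -1.0,
}


def fixture_config(name: str, seed: int = 0) -> SyntheticConfig:
    """Named configurations: tiny (unit-test scale), null (no effects),
    planted_paper_like (all planted signs at standardised size 1)."""
    if name == "tiny":
        return SyntheticConfig(
            n_genes=50, probes_per_gene=2, n_samples=20, n_chromosomes=5,
            seed=seed, mean_gene_length=5_000.0, snp_rate_per_bp=0.002,
        )
    if name == "null":
        return SyntheticConfig(n_genes=1000, n_samples=50, seed=seed)
    if name == "planted_paper_like":
        return SyntheticConfig(
            n_genes=2000, n_samples=100, seed=seed,
            effect_sizes=dict(PLANTED_PAPER_LIKE_EFFECTS),
        )
    raise ValueError(f"unknown fixture name {name!r}")


def make_fixture(name: str, outdir: str | Path | None = None,
                 seed: int = 0) -> SyntheticDataset:
    """Generate a named fixture; if ``outdir`` is given, also write it."""
    dataset = generate_dataset(fixture_config(name, seed=seed))
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset
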