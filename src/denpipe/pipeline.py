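"""End-to-end orchestration: configuration, staged execution, reporting.

``run_pipeline`` drives the whole chain -- count regulation events,
aggregate probes to genes, partition by DEN, derive every feature table,
run the comparison suite -- and writes all declared artifacts plus a run
metadata record (config echo, seeds, package versions, input checksums)
that suffices to reproduce the run exactly.

``analyze_dataset`` is the in-memory fast path over an already-loaded (or
synthetic) dataset; the file-based pipeline and the simulation studies
share it, so results never depend on which entry point was used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, den_core, gene_features, io_formats, stat_compare
from .den_core import GenePartition, Thresholds
from .stat_compare import AnalysisConfig, ComparisonResult, FeatureBundle
from .synthetic_data import SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_dataset", "summarize_report"]

_CONFIG_KEYS = {
    "matrix", "probe_map", "loci", "loci_format", "tissues", "variants",
    "variant_format", "interactions", "annotations", "gaf", "up_cut",
    "down_cut", "fraction", "aggregation", "max_pairs", "seed",
    "top_last_n", "enabled_comparisons", "outdir", "matrix_dialect",
    "plots",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are hard errors)."""

    matrix: str
    probe_map: str
    outdir: str
    loci: str | None = None
    loci_format: str = "bed"
    tissues: str | None = None
    variants: str | None = None
    variant_format: str = "vcf"
    interactions: str | None = None
    annotations: str | None = None
    gaf: str | None = None
    up_cut: float = den_core.DEFAULT_UP_CUT
    down_cut: float = den_core.DEFAULT_DOWN_CUT
    fraction: float = den_core.DEFAULT_FRACTION
    aggregation: str = "max"
    max_pairs: int = 2_000_000
    seed: int = 0
    top_last_n: int = 1000
    enabled_comparisons: list[str] | None = None
    matrix_dialect: str = "tsv"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("matrix", "probe_map"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {path}")
        for name in ("loci", "tissues", "variants", "interactions",
                     "annotations", "gaf"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"configured input {name!r} missing: {path}")
        Thresholds(self.up_cut, self.down_cut)
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def analyze_dataset(dataset: SyntheticDataset,
                    thresholds: Thresholds | None = None,
                    fraction: float = den_core.DEFAULT_FRACTION,
                    policy: str = "max",
                    analysis: AnalysisConfig | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, GenePartition],
                               list[ComparisonResult]]:
    """Run count -> aggregate -> partition -> features -> comparisons on an
    in-memory dataset; returns (gene counts, partitions, results)."""
    thresholds = thresholds or Thresholds()
    probe_counts = den_core.count_regulation(dataset.matrix, thresholds)
    gene_counts = den_core.aggregate_to_genes(probe_counts, dataset.probe_map,
                                              policy=policy)
    partitions = {
        d: den_core.partition_genes(gene_counts, d, fraction=fraction)
        for d in ("up", "down")
    }
    bundle = FeatureBundle(
        loci=dataset.loci,
        tes=gene_features.tissue_specificity_scores(dataset.tissue_matrix),
        ees=gene_features.earliest_stage_table(dataset.ees_labels),
        homolog=dataset.homolog.astype(float),
        phyletic=dataset.phyletic,
        variants=gene_features.variant_summaries(dataset.loci, dataset.variants),
        degree=gene_features.ppi_degrees(dataset.edges).astype(float),
        subcellular=gene_features.subcellular_table(dataset.gaf),
    )
    analysis = analysis or AnalysisConfig()
    results = stat_compare.run_full_analysis(gene_counts, partitions, bundle,
                                             analysis)
    return gene_counts, partitions, results


def _load_bundle(config: RunConfig) -> tuple[FeatureBundle, dict]:
    loci = None
    tes = ees = homolog = phyletic = degree = None
    variants = subcellular = None
    meta: dict = {}
    if config.loci:
        loci_list = io_formats.read_gene_loci(config.loci, format=config.loci_format)
        loci = io_formats.loci_frame(loci_list)
        meta["n_loci"] = len(loci)
    if config.tissues:
        tissue_matrix = io_formats.read_tissue_matrix(config.tissues)
        tes = gene_features.tissue_specificity_scores(tissue_matrix)
        meta["n_tissues"] = tissue_matrix.shape[1]
    if config.annotations:
        table = io_formats.read_annotation_table(config.annotations)
        wide = table.pivot(index="gene_id", columns="feature_name", values="value")
        if "homolog_count" in wide.columns:
            homolog = pd.to_numeric(wide["homolog_count"], errors="coerce").dropna()
        if "phyletic_age" in wide.columns:
            phyletic = wide["phyletic_age"].dropna()
        if "earliest_stage" in wide.columns:
            ees = gene_features.earliest_stage_table(wide["earliest_stage"].dropna())
    if config.variants and loci is not None:
        variant_records = io_formats.read_variants(config.variants,
                                                   format=config.variant_format)
        variants = gene_features.variant_summaries(loci, variant_records)
        meta["n_variants"] = len(variant_records)
    if config.interactions:
        edges = io_formats.read_interactions(config.interactions)
        degree = gene_features.ppi_degrees(edges).astype(float)
        meta["n_edges"] = len(edges)
    if config.gaf:
        gaf = io_formats.read_gaf(config.gaf)
        subcellular = gene_features.subcellular_table(gaf)
    return FeatureBundle(loci=loci, tes=tes, ees=ees, homolog=homolog,
                         phyletic=phyletic, variants=variants, degree=degree,
                         subcellular=subcellular), meta


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all artifacts to ``outdir``.

    On a stage failure a FAILED marker file naming the stage is written
    and the exception re-raised; partial outputs are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    stage = "setup"
    paths: dict[str, Path] = {}
    try:
        stage = "count"
        matrix = io_formats.read_foldchange_matrix(config.matrix,
                                                   dialect=config.matrix_dialect)
        probe_map = io_formats.read_probe_gene_map(config.probe_map)
        thresholds = Thresholds(config.up_cut, config.down_cut)
        probe_counts = den_core.count_regulation(matrix, thresholds)

        stage = "aggregate"
        gene_counts = den_core.aggregate_to_genes(probe_counts, probe_map,
                                                  policy=config.aggregation)

        stage = "partition"
        partitions = {
            d: den_core.partition_genes(gene_counts, d, fraction=config.fraction)
            for d in ("up", "down")
        }
        den = den_core.den_table(gene_counts, partitions["up"], partitions["down"])
        paths["den"] = outdir / "den.tsv"
        io_formats.write_table(den.reset_index(), paths["den"])
        _write_gene_lists(gene_counts, config, outdir, paths)

        stage = "features"
        bundle, feature_meta = _load_bundle(config)
        features = _feature_table(gene_counts, bundle)
        paths["features"] = outdir / "features.tsv"
        io_formats.write_table(features.reset_index(), paths["features"])

        stage = "compare"
        analysis = AnalysisConfig(max_pairs=config.max_pairs, seed=config.seed,
                                  top_last_n_size=config.top_last_n,
                                  enabled=(frozenset(config.enabled_comparisons)
                                           if config.enabled_comparisons else None))
        results = stat_compare.run_full_analysis(gene_counts, partitions, bundle,
                                                 analysis)
        if bundle.loci is not None:
            chrom_table = gene_features.chromosome_den_table(gene_counts,
                                                             bundle.loci)
            results.extend(stat_compare.chromosome_updown_tests(chrom_table))
        if results:
            frame = stat_compare.results_frame(results)
            paths["results"] = outdir / "results.tsv"
            io_formats.write_table(frame, paths["results"])
            paths["results_json"] = outdir / "results.json"
            frame.to_json(paths["results_json"], orient="records", indent=2)

        if config.plots:
            stage = "plots"
            from . import plots as _plots

            paths["plot_den_hist"] = outdir / "den_histogram.png"
            _plots.den_histogram(gene_counts, paths["plot_den_hist"])
            if bundle.tes is not None:
                paths["plot_tes_scatter"] = outdir / "tes_vs_den.png"
                _plots.den_feature_scatter(gene_counts, bundle.tes, "up",
                                           paths["plot_tes_scatter"],
                                           feature_name="TES")

        stage = "metadata"
        metadata = {
            "package": "denpipe",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "n_probes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_genes": len(gene_counts),
            **feature_meta,
            "input_checksums": {
                name: _sha256(path)
                for name, path in (
                    ("matrix", config.matrix), ("probe_map", config.probe_map),
                    ("loci", config.loci), ("tissues", config.tissues),
                    ("variants", config.variants),
                    ("interactions", config.interactions),
                    ("annotations", config.annotations), ("gaf", config.gaf),
                )
                if path
            },
        }
        paths["metadata"] = outdir / "run_metadata.json"
        with open(paths["metadata"], "w") as handle:
            json.dump(metadata, handle, indent=2, sort_keys=True)
        return paths
    except Exception as exc:
        marker.write_text(f"stage={stage}\nerror={exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _write_gene_lists(gene_counts: pd.DataFrame, config: RunConfig,
                      outdir: Path, paths: dict[str, Path]) -> None:
    n = config.top_last_n
    if 2 * n > len(gene_counts):
        logger.info("skipping top/last-%d gene lists: only %d genes",
                    n, len(gene_counts))
        return
    for direction in ("up", "down"):
        top, last = den_core.top_last_n_ordered(gene_counts, direction, n=n)
        letter = direction[0].upper()
        for tag, ids in ((f"T{n}{letter}", top), (f"L{n}{letter}", last)):
            path = outdir / f"{tag}.txt"
            path.write_text("\n".join(ids) + "\n")
            paths[tag] = path


def _feature_table(gene_counts: pd.DataFrame,
                   bundle: FeatureBundle) -> pd.DataFrame:
    frame = gene_counts[["up_count", "down_count"]].copy()
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    if bundle.tes is not None:
        frame["tes"] = bundle.tes.reindex(frame.index)
    if bundle.ees is not None:
        frame["ees"] = bundle.ees.reindex(frame.index)
    if bundle.homolog is not None:
        frame["homolog_count"] = bundle.homolog.reindex(frame.index)
    if bundle.phyletic is not None:
        frame["phyletic_age"] = bundle.phyletic.reindex(frame.index)
    if bundle.variants is not None:
        var = bundle.variants.set_index("gene_id") \
            if "gene_id" in bundle.variants.columns else bundle.variants
        for col in ("snp_count", "dsnp_count", "snp_density"):
            frame[col] = var[col].reindex(frame.index)
    if bundle.degree is not None:
        frame["degree"] = bundle.degree.reindex(frame.index)
    if bundle.subcellular is not None:
        joined = bundle.subcellular.reindex(frame.index)
        frame["subcellular"] = [
            ";".join(c for c in bundle.subcellular.columns if row[c])
            if not row.isna().all() else ""
            for _, row in joined.iterrows()
        ]
    return frame.sort_index()


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_REPORT_SECTIONS = (
    ("Chromosomal clustering", ("chromosomal_distance",)),
    ("Baseline expression", ("tes", "tes_vs_den", "ees")),
    ("Evolutionary characteristics", ("homolog_count", "phyletic_age")),
    ("SNPs and disease SNPs", ("snp_density", "dsnp_fraction")),
    ("Interaction network and localisation",
     ("degree", "degree_vs_den", "subcellular_class")),
    ("Per-chromosome up vs down", ("up_vs_down_den",)),
)


def summarize_report(results: pd.DataFrame | list[ComparisonResult]) -> str:
    """Render results as a deterministic markdown report.

    Every number shown is taken verbatim from the results table; nothing
    is recomputed in this layer."""
    if isinstance(results, list):
        if not results:
            raise ValueError("empty comparison set")
        frame = stat_compare.results_frame(results)
    else:
        frame = results
    if frame.empty:
        raise ValueError("empty comparison set")
    lines = ["# DEN comparison report", ""]
    seen = np.zeros(len(frame), dtype=bool)
    for title, prefixes in _REPORT_SECTIONS:
        mask = frame["feature"].str.startswith(prefixes).to_numpy()
        block = frame[mask & ~seen]
        seen |= mask
        if block.empty:
            continue
        lines.append(f"## {title}")
        lines.append("")
        for row in block.itertuples(index=False):
            p = f"{row.p_value:.4g}" if np.isfinite(row.p_value) else "NA"
            lines.append(
                f"- `{row.feature}` ({row.group_high} vs {row.group_low}, "
                f"{row.test}): statistic={row.statistic:.6g}, p={p}, "
                f"direction={row.direction}"
            )
        lines.append("")
    rest = frame[~seen]
    if not rest.empty:
        lines.append("## Other comparisons")
        lines.append("")
        for row in rest.itertuples(index=False):
            p = f"{row.p_value:.4g}" if np.isfinite(row.p_value) else "NA"
            lines.append(
                f"- `{row.feature}` ({row.test}): statistic={row.statistic:.6g}, "
                f"p={p}, direction={row.direction}"
            )
        lines.append("")
    return "\n".join(lines)
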