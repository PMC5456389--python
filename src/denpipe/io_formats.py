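"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are normalised to a single convention on read:
0-based, half-open intervals.  BED input passes through natively; GFF3
(1-based, closed) and VCF (1-based positions) are converted.  Identifiers
are opaque text -- no translation against external services is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_SENTINELS = {"", "NA", "NaN", "nan", "na", "N/A", "null", "NULL"}

__all__ = [
    "FoldChangeMatrix",
    "GeneLocus",
    "VariantRecord",
    "InteractionEdge",
    "read_foldchange_matrix",
    "write_matrix",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_gene_loci",
    "write_gene_loci_bed",
    "read_variants",
    "write_variants_vcf",
    "read_interactions",
    "write_interactions",
    "read_tissue_matrix",
    "read_annotation_table",
    "read_gaf",
    "write_gaf",
    "write_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeMatrix:
    """Probe x sample grid of natural-log fold changes (lnFC).

    Rows are probesets, columns are treated samples; each cell is the
    log-transformed expression fold change of that probe in that sample
    relative to its matched control.  Missing cells are NaN and are
    non-events for all downstream counting.
    """

    data: pd.DataFrame  # index = probe ids, columns = sample ids, float64

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values[~np.isnan(values)]).all():
            raise ValueError("fold-change matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class GeneLocus:
    """Genomic span of one gene: 0-based half-open [start, end)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid locus for {self.gene_id}: start={self.start} end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class VariantRecord:
    """One SNP with an optional dbSNP id and clinical-significance labels.

    Labels are stored lower-cased, trimmed, with internal spaces replaced
    by underscores, so that ClinVar's inconsistent casing/separators
    compare equal.
    """

    chromosome: str
    position: int  # 0-based
    rs_id: str | None = None
    clinical_significance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("variant position must be >= 0")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected interaction between two genes; (a, b) == (b, a)."""

    gene_a: str
    gene_b: str
    system_class: str = "physical"  # {physical, genetic}
    modification: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("interactor ids must be non-empty")

    def canonical(self) -> "InteractionEdge":
        a, b = sorted((self.gene_a, self.gene_b))
        if (a, b) == (self.gene_a, self.gene_b):
            return self
        return InteractionEdge(a, b, self.system_class, self.modification)


# ---------------------------------------------------------------------------
# fold-change matrix
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_foldchange_matrix(path: str | Path, dialect: str = "tsv") -> FoldChangeMatrix:
    """Read a probe x sample lnFC matrix from TSV/CSV.

    First row is the sample header, first column the probe ids.  Empty
    cells and the usual missing sentinels ("NA", "NaN", "") become NaN.
    Duplicate probe/sample ids and non-numeric cells are hard errors.
    """
    raw = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    def _parse(cell: str) -> float:
        s = cell.strip()
        if s in MISSING_SENTINELS:
            return np.nan
        return float(s)

    out = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        colvals = raw[col].to_numpy()
        for i, cell in enumerate(colvals):
            try:
                out[i, j] = _parse(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at probe {raw.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    frame = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return FoldChangeMatrix(frame)


def write_matrix(matrix: FoldChangeMatrix | pd.DataFrame, path: str | Path,
                 dialect: str = "tsv") -> None:
    """Write a matrix so that a subsequent read reproduces values exactly.

    Floats are rendered with 17 significant digits (full round-trip
    precision for IEEE doubles)."""
    frame = matrix.data if isinstance(matrix, FoldChangeMatrix) else matrix
    frame.to_csv(path, sep=_sep(dialect), float_format="%.17g", na_rep="NA")


# ---------------------------------------------------------------------------
# probe -> gene map
# ---------------------------------------------------------------------------

def read_probe_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (probe_id, gene_id); one gene per probe."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError("probe-gene map needs at least two columns")
    probes = frame.iloc[:, 0].astype(str)
    genes = frame.iloc[:, 1].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"probe mapped more than once: {dup!r}")
    if (genes.str.len() == 0).any():
        raise ValueError("empty gene_id in probe-gene map")
    return dict(zip(probes, genes))


def write_probe_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(mapping.keys()), "gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene loci (BED / GFF3)
# ---------------------------------------------------------------------------

def _merge_loci(records: list[GeneLocus]) -> list[GeneLocus]:
    """Collapse multiple records per gene to one locus.

    Same chromosome: spanning interval min(start)..max(end).  Multiple
    chromosomes: keep only the chromosome with the longest span (warn)."""
    by_gene: dict[str, list[GeneLocus]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    merged: list[GeneLocus] = []
    for gene_id, recs in by_gene.items():
        by_chrom: dict[str, list[GeneLocus]] = {}
        for r in recs:
            by_chrom.setdefault(r.chromosome, []).append(r)
        spans = {
            chrom: (min(r.start for r in rs), max(r.end for r in rs))
            for chrom, rs in by_chrom.items()
        }
        if len(spans) > 1:
            logger.warning(
                "gene %s has records on %d chromosomes; keeping longest span",
                gene_id, len(spans),
            )
        chrom = max(spans, key=lambda c: (spans[c][1] - spans[c][0], c))
        start, end = spans[chrom]
        strand = by_chrom[chrom][0].strand
        merged.append(GeneLocus(gene_id, chrom, start, end, strand))
    return merged


def read_gene_loci(path: str | Path, format: str = "bed") -> list[GeneLocus]:
    """Read gene loci from BED4+ (native 0-based half-open) or GFF3.

    GFF3 (1-based closed) is converted on read: internal start = start - 1.
    Multiple records per gene are merged to the spanning interval; records
    with start >= end after conversion are rejected with a warning.
    """
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unknown loci format {format!r}")
    records: list[GeneLocus] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "bed":
                if len(fields) < 4:
                    raise ValueError(f"unparseable BED line {lineno}: {line!r}")
                try:
                    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                except ValueError:
                    raise ValueError(f"unparseable BED line {lineno}: {line!r}") from None
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "unknown"
            else:
                if len(fields) < 9:
                    raise ValueError(f"unparseable GFF3 line {lineno}: {line!r}")
                chrom = fields[0]
                try:
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                except ValueError:
                    raise ValueError(f"unparseable GFF3 line {lineno}: {line!r}") from None
                strand = fields[6] if fields[6] in "+-" else "unknown"
                name = _gff3_gene_id(fields[8])
                if name is None:
                    raise ValueError(
                        f"GFF3 line {lineno} has no ID/gene_id attribute: {line!r}"
                    )
            if start >= end or start < 0:
                logger.warning("rejecting locus %s at line %d: start=%d end=%d",
                               name, lineno, start, end)
                continue
            records.append(GeneLocus(name, chrom, start, end, strand))
    return _merge_loci(records)


def _gff3_gene_id(attributes: str) -> str | None:
    attrs = {}
    for part in attributes.split(";"):
        part = part.strip()
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key] = value
    return attrs.get("gene_id") or attrs.get("ID") or attrs.get("Name")


def write_gene_loci_bed(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as handle:
        for locus in loci:
            strand = locus.strand if locus.strand in "+-" else "."
            handle.write(
                f"{locus.chromosome}\t{locus.start}\t{locus.end}\t{locus.gene_id}\t0\t{strand}\n"
            )


def loci_frame(loci: Iterable[GeneLocus]) -> pd.DataFrame:
    """Tabular view of loci used by the vectorised feature operations."""
    return pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "chromosome": l.chromosome,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
            }
            for l in loci
        ]
    )


# ---------------------------------------------------------------------------
# variants (VCF / ClinVar-style TSV)
# ---------------------------------------------------------------------------

_SIG_SPLIT = ",;/|"


def _parse_significance(text: str) -> frozenset[str]:
    for ch in _SIG_SPLIT[1:]:
        text = text.replace(ch, _SIG_SPLIT[0])
    labels = set()
    for token in text.split(","):
        token = token.strip().lower().replace(" ", "_")
        if token and token != ".":
            labels.add(token)
    return frozenset(labels)


def read_variants(path: str | Path, format: str = "vcf") -> list[VariantRecord]:
    """Read SNPs from VCF 4.x or a ClinVar-style TSV.

    VCF: CHROM/POS/ID columns plus INFO:CLNSIG; the 1-based POS becomes a
    0-based internal position and ID "." means no dbSNP id.  TSV: columns
    rs_id, chromosome, position (0-based), clinical_significance.
    Records with malformed positions are dropped with a warning.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                logger.warning("rejecting malformed VCF line %d", lineno)
                continue
            chrom, pos_text, vcf_id = fields[0], fields[1], fields[2]
            try:
                position = int(pos_text) - 1  # 1-based -> 0-based
                if position < 0:
                    raise ValueError
            except ValueError:
                logger.warning("rejecting VCF line %d: bad position %r", lineno, pos_text)
                continue
            rs_id = None if vcf_id == "." or not vcf_id else vcf_id
            sig: frozenset[str] = frozenset()
            if len(fields) >= 8:
                for entry in fields[7].split(";"):
                    if entry.startswith("CLNSIG="):
                        sig = _parse_significance(entry[len("CLNSIG="):])
            records.append(VariantRecord(chrom, position, rs_id, sig))
    return records


def _read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"rs_id", "chromosome", "position", "clinical_significance"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    records: list[VariantRecord] = []
    for row in frame.itertuples(index=False):
        try:
            position = int(row.position)
            if position < 0:
                raise ValueError
        except ValueError:
            logger.warning("rejecting variant row: bad position %r", row.position)
            continue
        rs_id = row.rs_id.strip() or None
        if rs_id in {".", "-"}:
            rs_id = None
        records.append(
            VariantRecord(row.chromosome, position, rs_id,
                          _parse_significance(row.clinical_significance))
        )
    return records


def write_variants_vcf(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            vcf_id = v.rs_id if v.rs_id else "."
            info = (
                "CLNSIG=" + ",".join(sorted(v.clinical_significance))
                if v.clinical_significance
                else "."
            )
            handle.write(f"{v.chromosome}\t{v.position + 1}\t{vcf_id}\tN\tN\t.\t.\t{info}\n")


def variants_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Tabular view (chromosome, position, has_rs_id, labels) for vector ops."""
    return pd.DataFrame(
        [
            {
                "chromosome": v.chromosome,
                "position": v.position,
                "rs_id": v.rs_id,
                "clinical_significance": v.clinical_significance,
            }
            for v in variants
        ]
    )


# ---------------------------------------------------------------------------
# interactions (BioGRID tab-like TSV)
# ---------------------------------------------------------------------------

_INTERACTOR_A = ("gene_a", "interactor_a", "official_symbol_interactor_a")
_INTERACTOR_B = ("gene_b", "interactor_b", "official_symbol_interactor_b")
_SYSTEM_TYPE = ("system_class", "experimental_system_type", "system_type")
_MODIFICATION = ("modification", "post_translational_modification")


def _find_column(columns: list[str], candidates: tuple[str, ...], what: str,
                 required: bool = True) -> str | None:
    normalised = {c.strip().lower().replace(" ", "_"): c for c in columns}
    for cand in candidates:
        if cand in normalised:
            return normalised[cand]
    if required:
        raise ValueError(f"interaction table missing {what} column "
                         f"(looked for {candidates})")
    return None


def read_interactions(path: str | Path) -> list[InteractionEdge]:
    """Read a BioGRID-like edge list; edges are normalised to undirected
    canonical order and de-duplicated.  Genetic edges are retained here and
    flagged -- filtering is a downstream concern."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    col_a = _find_column(cols, _INTERACTOR_A, "interactor A")
    col_b = _find_column(cols, _INTERACTOR_B, "interactor B")
    col_sys = _find_column(cols, _SYSTEM_TYPE, "system type", required=False)
    col_mod = _find_column(cols, _MODIFICATION, "modification", required=False)

    a_col = frame[col_a].astype(str).str.strip()
    b_col = frame[col_b].astype(str).str.strip()
    sys_col = (frame[col_sys].astype(str).str.strip().str.lower()
               if col_sys else pd.Series("physical", index=frame.index))
    mod_col = (frame[col_mod].astype(str).str.strip()
               if col_mod else pd.Series("", index=frame.index))

    seen: dict[tuple[str, str, str, str | None], InteractionEdge] = {}
    for a, b, system, mod in zip(a_col, b_col, sys_col, mod_col):
        if not a or not b:
            raise ValueError("empty interactor id in interaction table")
        if system not in {"physical", "genetic"}:
            system = "physical"
        modification = mod if mod and mod != "-" else None
        edge = InteractionEdge(a, b, system, modification).canonical()
        key = (edge.gene_a, edge.gene_b, edge.system_class, edge.modification)
        seen.setdefault(key, edge)
    return list(seen.values())


def write_interactions(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    rows = [
        {
            "Official Symbol Interactor A": e.gene_a,
            "Official Symbol Interactor B": e.gene_b,
            "Experimental System Type": e.system_class,
            "Modification": e.modification or "-",
        }
        for e in edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tissue expression matrix / annotation tables / GAF
# ---------------------------------------------------------------------------

def read_tissue_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x tissue expression matrix (TSV, first column gene ids).

    Multiple rows per gene are averaged per tissue; negative values (seen
    in processed microarray data) are clipped to 0 on construction."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame = frame.groupby(level=0, sort=False).mean()
    return frame.clip(lower=0.0)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Long-format per-gene annotation table: gene_id, feature_name, value."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "feature_name", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if frame.duplicated(subset=["gene_id", "feature_name"]).any():
        raise ValueError("duplicate (gene_id, feature_name) in annotation table")
    return frame


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x association file into (gene_id, qualifier, go_id).

    gene_id is taken from the DB Object Symbol column (column 3); comment
    lines start with '!'.
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed GAF line: {line!r}")
            rows.append(
                {"gene_id": fields[2], "qualifier": fields[3], "go_id": fields[4]}
            )
    return pd.DataFrame(rows, columns=["gene_id", "qualifier", "go_id"])


def write_gaf(annotations: pd.DataFrame, path: str | Path) -> None:
    """Write (gene_id, qualifier, go_id) rows as a minimal GAF 2.2 file."""
    with open(path, "w") as handle:
        handle.write("!gaf-version: 2.2\n")
        for row in annotations.itertuples(index=False):
            qualifier = row.qualifier or "located_in"
            handle.write(
                "\t".join(
                    [
                        "SYN", row.gene_id, row.gene_id, qualifier, row.go_id,
                        "SYN:ref", "IDA", "", "C", "", "", "protein", "taxon:9606",
                        "20170101", "SYN", "", "",
                    ]
                )
                + "\n"
            )


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a derived table as TSV with round-trip float precision."""
    frame.to_csv(path, sep="\t", index=index, float_format="%.17g")
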