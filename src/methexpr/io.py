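"""Readers, writers and in-memory containers for the pipeline's file formats.

Formats handled: beta-value matrices and sample sheets (TSV), Illumina-style
probe manifests (CSV), gene models (BED12), expression status tables (TSV).

Coordinate convention: everything in memory is 0-based half-open, the BED
standard. Illumina manifests carry 1-based positions and are converted on
read; writers convert back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CGI_LEVELS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "None")

CONDITIONS = ("cancer", "normal")


class FormatError(ValueError):
    """A file violated the format contract (bad value, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# Beta matrices and sample sheets
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values in [0, 1].

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns; missing measurements are NaN.
    """

    values: pd.DataFrame
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate probe ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise FormatError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleSheet:
    """Maps sample id -> condition (cancer/normal) and cohort."""

    table: pd.DataFrame  # columns: sample_id, condition, cohort

    def __post_init__(self) -> None:
        req = {"sample_id", "condition", "cohort"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sheet")
        bad = ~self.table["condition"].isin(CONDITIONS)
        if bad.any():
            raise FormatError(
                f"conditions outside {CONDITIONS}: "
                f"{sorted(self.table.loc[bad, 'condition'].unique())}"
            )

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["condition"].iloc[0])

    def samples(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_beta_matrix(
    path: str | Path, sheet: SampleSheet | None = None, cohort: str = ""
) -> BetaMatrix:
    """Read a probe x sample TSV (first column = probe id, header = samples).

    Empty cells and "NA" parse as missing. If a sheet is given, every matrix
    column must have a sheet row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=True, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    if sheet is not None:
        known = set(sheet.table["sample_id"])
        orphans = [c for c in df.columns if c not in known]
        if orphans:
            raise FormatError(f"matrix columns missing from sample sheet: {orphans[:5]}")
    return BetaMatrix(df, cohort=cohort)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Probe manifests
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Illumina-style probe annotation.

    ``probes``: one row per probe — probe_id, chrom, pos (0-based),
    cgi_relation, on_sparse, on_dense.
    ``associations``: one row per (probe, gene) pair — probe_id, gene,
    region_tag. A probe may map to several genes; a probe with no gene has
    no association rows but stays in ``probes``.
    """

    probes: pd.DataFrame
    associations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.probes["probe_id"].duplicated().any():
            raise FormatError("duplicate probe ids in manifest")
        bad = ~self.probes["cgi_relation"].isin(CGI_LEVELS)
        if bad.any():
            raise FormatError(
                f"cgi_relation outside vocabulary: "
                f"{sorted(self.probes.loc[bad, 'cgi_relation'].unique())}"
            )
        if (self.probes["pos"] < 0).any():
            raise FormatError("negative probe position")

    def subset_platform(self, platform: str) -> "AnnotationTable":
        col = {"sparse": "on_sparse", "dense": "on_dense"}[platform]
        probes = self.probes.loc[self.probes[col]].reset_index(drop=True)
        keep = set(probes["probe_id"])
        assoc = self.associations.loc[
            self.associations["probe_id"].isin(keep)
        ].reset_index(drop=True)
        return AnnotationTable(probes, assoc)

    def genes_of(self, probe_id: str) -> list[str]:
        sel = self.associations.loc[self.associations["probe_id"] == probe_id, "gene"]
        return list(sel)

    def probes_of(self, gene: str) -> list[str]:
        sel = self.associations.loc[self.associations["gene"] == gene, "probe_id"]
        return list(sel)


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes"}


def read_manifest(path: str | Path) -> AnnotationTable:
    """Read a manifest CSV into an AnnotationTable.

    Expected columns: probe_id, chrom, position (1-based), genes
    (semicolon-separated symbols), region_tags (semicolon-separated, parallel
    to genes), cgi_relation; optional on_sparse/on_dense flags (dense assumed
    when absent). Multi-gene probes expand to one association per distinct
    symbol; a mismatch between gene and tag list lengths is logged and paired
    best-effort.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    req = {"probe_id", "chrom", "position", "genes", "region_tags", "cgi_relation"}
    missing = req - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")

    probes_rows = []
    assoc_rows = []
    for row in df.itertuples(index=False):
        try:
            pos1 = int(row.position)
        except ValueError as exc:
            raise FormatError(
                f"malformed position {row.position!r} for probe {row.probe_id}"
            ) from exc
        if pos1 < 1:
            raise FormatError(f"position {pos1} < 1 for probe {row.probe_id}")
        cgi = row.cgi_relation.strip() or "None"
        probes_rows.append(
            {
                "probe_id": row.probe_id,
                "chrom": row.chrom,
                "pos": pos1 - 1,
                "cgi_relation": cgi,
                "on_sparse": _parse_bool(getattr(row, "on_sparse", "0")),
                "on_dense": _parse_bool(getattr(row, "on_dense", "1")),
            }
        )
        genes = [g for g in row.genes.split(";") if g.strip()]
        tags = [t for t in row.region_tags.split(";") if t.strip()]
        if genes and tags and len(genes) != len(tags):
            logger.warning(
                "probe %s: %d genes vs %d region tags; pairing best-effort",
                row.probe_id, len(genes), len(tags),
            )
        seen: set[str] = set()
        for i, g in enumerate(genes):
            g = g.strip()
            if g in seen:
                continue
            seen.add(g)
            tag = tags[i].strip() if i < len(tags) else ""
            assoc_rows.append({"probe_id": row.probe_id, "gene": g, "region_tag": tag})

    probes = pd.DataFrame(
        probes_rows,
        columns=["probe_id", "chrom", "pos", "cgi_relation", "on_sparse", "on_dense"],
    )
    assoc = pd.DataFrame(assoc_rows, columns=["probe_id", "gene", "region_tag"])
    return AnnotationTable(probes, assoc)


def write_manifest(annotation: AnnotationTable, path: str | Path) -> None:
    assoc = annotation.associations
    by_probe = {
        pid: grp for pid, grp in assoc.groupby("probe_id", sort=False)
    }
    rows = []
    for row in annotation.probes.itertuples(index=False):
        grp = by_probe.get(row.probe_id)
        genes = ";".join(grp["gene"]) if grp is not None else ""
        tags = ";".join(grp["region_tag"]) if grp is not None else ""
        rows.append(
            {
                "probe_id": row.probe_id,
                "chrom": row.chrom,
                "position": row.pos + 1,
                "genes": genes,
                "region_tags": tags,
                "cgi_relation": row.cgi_relation,
                "on_sparse": int(row.on_sparse),
                "on_dense": int(row.on_dense),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """One transcript with exon/CDS geometry, 0-based half-open intervals."""

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    thick_start: int
    thick_end: int

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: start for +, end - 1 for -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, _e1) in zip(self.exons, self.exons[1:]):
            out.append((e0, s1))
        return tuple(out)

    @property
    def coding(self) -> bool:
        return self.thick_end > self.thick_start

    @property
    def coding_exons(self) -> tuple[tuple[int, int], ...]:
        if not self.coding:
            return ()
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.thick_start), min(e, self.thick_end)
            if ce > cs:
                out.append((cs, ce))
        return tuple(out)

    def _utr(self, side: str) -> tuple[tuple[int, int], ...]:
        if not self.coding:
            return ()
        # genomic-left UTR is 5' on + strand, 3' on -
        left = []
        right = []
        for s, e in self.exons:
            if s < self.thick_start:
                left.append((s, min(e, self.thick_start)))
            if e > self.thick_end:
                right.append((max(s, self.thick_end), e))
        if (side == "5") == (self.strand == "+"):
            return tuple(left)
        return tuple(right)

    @property
    def utr5(self) -> tuple[tuple[int, int], ...]:
        return self._utr("5")

    @property
    def utr3(self) -> tuple[tuple[int, int], ...]:
        return self._utr("3")

    def _first(self, intervals: tuple[tuple[int, int], ...]):
        if not intervals:
            return None
        return intervals[0] if self.strand == "+" else intervals[-1]

    @property
    def first_exon(self):
        return self._first(self.exons)

    @property
    def first_intron(self):
        return self._first(self.introns)

    @property
    def first_coding_exon(self):
        return self._first(self.coding_exons)


REGION_KINDS = ("utr3", "utr5", "coding_exons", "exons", "introns")
FIRST_KINDS = ("first_coding_exon", "first_exon", "first_intron")


@dataclass
class GeneModel:
    """All transcripts sharing a gene symbol; possibly multiple TSSs."""

    symbol: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def tss_list(self) -> list[int]:
        return sorted({t.tss for t in self.transcripts})

    def region_intervals(self, kind: str) -> list[tuple[int, int]]:
        """Union (as a list, unmerged) of a region type over transcripts."""
        attr = {"utr3": "utr3", "utr5": "utr5", "coding_exons": "coding_exons",
                "exons": "exons", "introns": "introns"}[kind]
        out: list[tuple[int, int]] = []
        for t in self.transcripts:
            out.extend(getattr(t, attr))
        return out

    def first_intervals(self, kind: str) -> list[tuple[int, int]]:
        attr = {"first_coding_exon": "first_coding_exon",
                "first_exon": "first_exon",
                "first_intron": "first_intron"}[kind]
        out = []
        for t in self.transcripts:
            iv = getattr(t, attr)
            if iv is not None:
                out.append(iv)
        return out


def read_gene_models_bed12(path: str | Path) -> dict[str, GeneModel]:
    """Parse BED12 into GeneModels keyed by the name field's gene symbol.

    The BED name field is either ``SYMBOL`` or ``SYMBOL|transcript_id``;
    multiple records with the same symbol become multiple transcripts.
    Records whose block arithmetic disagrees with chromEnd are rejected and
    logged.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                logger.warning("line %d: block count mismatch; record skipped", lineno)
                continue
            exons = tuple((start + o, start + o + s) for o, s in zip(starts, sizes))
            if starts[0] != 0 or exons[-1][1] != end:
                logger.warning(
                    "line %d (%s): block arithmetic inconsistent with chromEnd; "
                    "record skipped", lineno, name,
                )
                continue
            symbol = name.split("|")[0]
            tx = Transcript(
                name=name, chrom=chrom, strand=strand, start=start, end=end,
                exons=exons, thick_start=thick_start, thick_end=thick_end,
            )
            models.setdefault(symbol, GeneModel(symbol)).transcripts.append(tx)
    return models


def write_gene_models_bed12(models: dict[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(models):
            for tx in models[symbol].transcripts:
                sizes = ",".join(str(e - s) for s, e in tx.exons) + ","
                offsets = ",".join(str(s - tx.start) for s, _ in tx.exons) + ","
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            tx.chrom, tx.start, tx.end, tx.name, 0, tx.strand,
                            tx.thick_start, tx.thick_end, "0,0,0",
                            len(tx.exons), sizes, offsets,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Expression status tables
# ---------------------------------------------------------------------------

EXPR_STATUSES = ("UP", "DOWN", "NS")


@dataclass
class ExpressionStatusTable:
    """Gene-level differential expression summary: logFC, p, UP/DOWN/NS."""

    table: pd.DataFrame  # columns: gene, logFC, p_value, status

    def __post_init__(self) -> None:
        req = {"gene", "logFC", "p_value", "status"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"expression table missing columns: {sorted(missing)}")
        bad = ~self.table["status"].isin(EXPR_STATUSES)
        if bad.any():
            raise FormatError("expression status outside {UP, DOWN, NS}")
        up = self.table["status"] == "UP"
        down = self.table["status"] == "DOWN"
        if (self.table.loc[up, "logFC"] <= 0).any():
            raise FormatError("UP gene with non-positive logFC")
        if (self.table.loc[down, "logFC"] >= 0).any():
            raise FormatError("DOWN gene with non-negative logFC")

    def status_of(self, gene: str) -> str:
        sel = self.table.loc[self.table["gene"] == gene, "status"]
        return str(sel.iloc[0]) if len(sel) else "NS"

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["status"]))


def read_expression_status(path: str | Path) -> ExpressionStatusTable:
    df = pd.read_csv(path, sep="\t")
    df["gene"] = df["gene"].astype(str)
    return ExpressionStatusTable(df)


def write_expression_status(table: ExpressionStatusTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample continuous expression TSV (log2-like scale)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")
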