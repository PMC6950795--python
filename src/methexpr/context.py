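"""Genomic context of methylation probes: TSS distance, CGI relation,
gene-region overlap.

Distances are strand-aware and signed: negative = upstream of the TSS on
the gene's strand, 0 = exactly at the TSS (counted downstream). A gene may
have several TSSs; the nearest one (minimum |offset|, ties to the upstream
offset) defines the probe's distance. Window counts use |d| <= w for the
windows 50..2000 bp; the signed histogram uses fixed half-open [lo, hi)
bins from -1500 to 2000+, each split into high (|delta-beta| >= 0.2) and
low fold-change probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationTable, FIRST_KINDS, GeneModel, REGION_KINDS

logger = logging.getLogger(__name__)

TSS_WINDOWS = (50, 100, 200, 300, 400, 500, 1000, 1500, 2000)

_EDGES = (-1500, -1000, -500, -400, -300, -200, -100, -50, 0,
          50, 100, 200, 300, 400, 500, 1000, 1500, 2000)


def _bin_labels() -> list[str]:
    labels = [f"(-inf,{_EDGES[0]})"]
    for lo, hi in zip(_EDGES[:-1], _EDGES[1:]):
        labels.append(f"[{lo},{hi})")
    labels.append(f"[{_EDGES[-1]},inf)")
    return labels


@dataclass(frozen=True)
class DistanceBinSpec:
    """Signed-distance histogram bins plus the fold-change split."""

    edges: tuple[int, ...] = _EDGES
    high_threshold: float = 0.2   # |delta-beta| >= threshold -> "high"
    high_cap: float = 0.5         # documented upper end of the high range

    def __post_init__(self) -> None:
        if not (0 < self.high_threshold <= 0.5):
            raise ValueError("fold-change split must be in (0, 0.5]")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("bin edges must be sorted")

    @property
    def labels(self) -> list[str]:
        labels = [f"(-inf,{self.edges[0]})"]
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            labels.append(f"[{lo},{hi})")
        labels.append(f"[{self.edges[-1]},inf)")
        return labels

    def assign(self, d: float) -> str:
        idx = int(np.searchsorted(self.edges, d, side="right"))
        return self.labels[idx]


def tss_distance(probe_pos: int, gene: GeneModel, chrom: str | None = None) -> dict | None:
    """Signed strand-aware distance from a probe to its gene's nearest TSS.

    Returns dict with gene, d (nearest signed offset), n_tss, and
    window membership booleans w50..w2000; None (logged) on chromosome
    mismatch. Offset convention: + strand probe - TSS, - strand TSS - probe;
    among several TSSs the minimum |offset| wins, ties taken upstream
    (negative).
    """
    if chrom is not None and chrom != gene.chrom:
        logger.info("probe on %s but gene %s on %s; no distance",
                    chrom, gene.symbol, gene.chrom)
        return None
    sign = 1 if gene.strand == "+" else -1
    offsets = [sign * (probe_pos - tss) for tss in gene.tss_list]
    # nearest |offset|; tie -> the upstream (negative) one
    offsets.sort(key=lambda d: (abs(d), d))
    d = offsets[0]
    rec = {"gene": gene.symbol, "d": d, "n_tss": len(gene.tss_list)}
    for w in TSS_WINDOWS:
        rec[f"w{w}"] = abs(d) <= w
    return rec


def tss_distance_table(
    annotation: AnnotationTable,
    models: dict[str, GeneModel],
    genes: set[str] | list[str],
    probe_ids: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Nearest-TSS distance for every (probe, gene) association in a set."""
    genes = set(genes)
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    assoc = assoc.loc[assoc["gene"].isin(genes)]
    if probe_ids is not None:
        assoc = assoc.loc[assoc["probe_id"].isin(set(probe_ids))]
    pos = annotation.probes.set_index("probe_id")[["chrom", "pos"]]

    rows = []
    for row in assoc.sort_values(["probe_id", "gene"]).itertuples(index=False):
        model = models.get(row.gene)
        if model is None:
            logger.info("gene %s has no model; probe %s skipped", row.gene, row.probe_id)
            continue
        p = pos.loc[row.probe_id]
        rec = tss_distance(int(p["pos"]), model, chrom=str(p["chrom"]))
        if rec is None:
            continue
        rec["probe_id"] = row.probe_id
        rows.append(rec)
    cols = ["probe_id", "gene", "d", "n_tss"] + [f"w{w}" for w in TSS_WINDOWS]
    return pd.DataFrame(rows, columns=cols)


def window_counts(distances: pd.DataFrame) -> pd.DataFrame:
    """Probe and gene counts per TSS window (|d| <= w)."""
    rows = []
    for w in TSS_WINDOWS:
        inw = distances.loc[distances[f"w{w}"]]
        rows.append({"window": w, "n_probes": len(inw),
                     "n_genes": inw["gene"].nunique()})
    return pd.DataFrame(rows, columns=["window", "n_probes", "n_genes"])


def upstream_fraction(distances: pd.DataFrame) -> float:
    """Fraction of (probe, gene) pairs strictly upstream (d < 0)."""
    if distances.empty:
        return float("nan")
    return float((distances["d"] < 0).mean())


def bin_distances(
    distances: pd.DataFrame,
    diff: pd.DataFrame,
    spec: DistanceBinSpec = DistanceBinSpec(),
) -> pd.DataFrame:
    """Signed-distance histogram split by fold-change magnitude.

    Each (probe, gene) nearest distance lands in exactly one half-open bin
    and is counted under "high" when the probe's |delta-beta| >= the split
    threshold, else "low". Output: bin, high_count, low_count in bin order.
    """
    delta_map = dict(zip(diff["probe_id"], diff["delta_beta"]))
    labels = spec.labels
    high = dict.fromkeys(labels, 0)
    low = dict.fromkeys(labels, 0)
    for row in distances.itertuples(index=False):
        delta = delta_map.get(row.probe_id)
        if delta is None or np.isnan(delta):
            continue
        label = spec.assign(row.d)
        if abs(delta) >= spec.high_threshold:
            high[label] += 1
        else:
            low[label] += 1
    return pd.DataFrame(
        {"bin": labels,
         "high_count": [high[b] for b in labels],
         "low_count": [low[b] for b in labels]}
    )


# ---------------------------------------------------------------------------
# CGI context
# ---------------------------------------------------------------------------


def cgi_summary(
    annotation: AnnotationTable,
    genes: set[str] | list[str],
    probe_ids: set[str] | list[str],
) -> dict:
    """CGI-relation composition of a probe set and its genes.

    Counts probes per six-level relation, pools shores and shelves across
    N/S, and reports the fraction of genes in the set with at least one
    listed probe in an island, shore or shelf ("any" fraction).
    """
    genes = set(genes)
    probe_ids = set(probe_ids)
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    assoc = assoc.loc[assoc["gene"].isin(genes) & assoc["probe_id"].isin(probe_ids)]
    rel = annotation.probes.set_index("probe_id")["cgi_relation"]

    per_relation: dict[str, int] = {
        k: 0 for k in ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "None")
    }
    gene_sets: dict[str, set] = {"Island": set(), "Shore": set(), "Shelf": set(),
                                 "None": set()}
    seen_probes = set()
    for row in assoc.itertuples(index=False):
        r = str(rel.get(row.probe_id, "None"))
        if row.probe_id not in seen_probes:
            per_relation[r] += 1
            seen_probes.add(row.probe_id)
        pooled = ("Shore" if r.endswith("Shore")
                  else "Shelf" if r.endswith("Shelf") else r)
        gene_sets[pooled].add(row.gene)

    genes_any = gene_sets["Island"] | gene_sets["Shore"] | gene_sets["Shelf"]
    n_genes = len(genes)
    return {
        "probe_counts": per_relation,
        "pooled_probe_counts": {
            "Island": per_relation["Island"],
            "Shore": per_relation["N_Shore"] + per_relation["S_Shore"],
            "Shelf": per_relation["N_Shelf"] + per_relation["S_Shelf"],
            "None": per_relation["None"],
        },
        "gene_counts": {k: len(v) for k, v in gene_sets.items()},
        "n_genes_any": len(genes_any),
        "frac_genes_any": (len(genes_any) / n_genes) if n_genes else float("nan"),
    }


# ---------------------------------------------------------------------------
# Gene-region fractions
# ---------------------------------------------------------------------------

_REGION_PRINT = {"utr3": "3'UTR", "utr5": "5'UTR", "coding_exons": "Coding exons",
                 "exons": "Exons", "introns": "Introns"}
_FIRST_BASE = {"first_coding_exon": "coding_exons", "first_exon": "exons",
               "first_intron": "introns"}


def _point_in(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def region_fractions(
    annotation: AnnotationTable,
    diff: pd.DataFrame,
    models: dict[str, GeneModel],
    genes: set[str] | list[str],
) -> pd.DataFrame:
    """Fractions of hyper and non-diff probes per gene region type.

    A probe is checked against the region geometry of its ASSOCIATED gene
    only and may count in several region types (an exon position is also a
    coding-exon or UTR position). Denominators: for the five region types,
    all probes of the given status in the set; for the three "first"
    ordinals, the probes hitting any interval of the matching region type.
    First-ordinal membership is strand-aware and satisfied by any
    transcript.

    Output rows: region x status(hyper|nondiff) with count, denominator,
    fraction.
    """
    genes = set(genes)
    call_map = dict(zip(diff["probe_id"], diff["call"]))
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    assoc = assoc.loc[assoc["gene"].isin(genes)]
    pos_map = annotation.probes.set_index("probe_id")["pos"]

    counts = {(k, st): 0 for k in REGION_KINDS + FIRST_KINDS
              for st in ("hyper", "nondiff")}
    totals = {"hyper": 0, "nondiff": 0}

    n_no_model = 0
    for row in assoc.sort_values(["probe_id", "gene"]).itertuples(index=False):
        call = call_map.get(row.probe_id)
        if call == "HYPER":
            st = "hyper"
        elif call == "NS":
            st = "nondiff"
        else:
            continue
        model = models.get(row.gene)
        if model is None:
            n_no_model += 1
            continue
        pos = int(pos_map[row.probe_id])
        totals[st] += 1
        for kind in REGION_KINDS:
            if _point_in(pos, model.region_intervals(kind)):
                counts[(kind, st)] += 1
        for kind in FIRST_KINDS:
            if _point_in(pos, model.first_intervals(kind)):
                counts[(kind, st)] += 1
    if n_no_model:
        logger.info("%d (probe, gene) pairs skipped: gene without model", n_no_model)

    rows = []
    for kind in REGION_KINDS:
        for st in ("hyper", "nondiff"):
            denom = totals[st]
            c = counts[(kind, st)]
            rows.append(
                {"region": _REGION_PRINT[kind], "status": st, "count": c,
                 "denominator": denom,
                 "fraction": (c / denom) if denom else float("nan")}
            )
    for kind in FIRST_KINDS:
        base = _FIRST_BASE[kind]
        for st in ("hyper", "nondiff"):
            denom = counts[(base, st)]
            c = counts[(kind, st)]
            rows.append(
                {"region": kind.replace("_", " ").title(), "status": st,
                 "count": c, "denominator": denom,
                 "fraction": (c / denom) if denom else float("nan")}
            )
    return pd.DataFrame(rows, columns=["region", "status", "count",
                                       "denominator", "fraction"])
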