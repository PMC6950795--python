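"""Regulation-pattern groups from multi-cohort methylation and expression.

A probe reaches HYPER (resp. HYPO) consensus when it is testable in every
required cohort and called HYPER (HYPO) in all of them; otherwise its
consensus is NONE. Gene methylation status follows its probes' consensus
(UP / DOWN / BOTH / NONE) and crossing with expression status yields the
four regulation groups:

  UPUP, UPDOWN, DOWNUP, DOWNDOWN

Genes with both hyper- and hypomethylated probes are kept in every
direction-compatible group and flagged inconsistent. The "-only" refinement
re-tallies each UPUP / UPDOWN gene on a dense (450k-like) cohort and keeps
genes with at least one hypermethylated probe and no hypomethylated probe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionStatusTable

logger = logging.getLogger(__name__)

GROUP_NAMES = ("UPUP", "UPDOWN", "DOWNUP", "DOWNDOWN")

ONLY_STATUSES = ("only", "excluded_hypo", "excluded_no_hyper", "excluded_no_probes")


def probe_consensus(
    results_by_cohort: dict[str, pd.DataFrame],
    required_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-cohort consensus calls.

    Output columns: probe_id, consensus (HYPER/HYPO/NONE), mean_delta_beta
    (over every cohort where the probe is testable), n_testable, calls
    (comma-joined per-cohort calls in required-cohort order, '-' where
    untestable). A probe untestable in any required cohort is NONE.
    """
    if not results_by_cohort:
        raise ValueError("at least one cohort result table is required")
    required = list(required_cohorts or results_by_cohort.keys())
    for name in required:
        if name not in results_by_cohort:
            raise ValueError(f"required cohort {name!r} has no result table")

    call_maps = {
        name: dict(zip(df["probe_id"], df["call"]))
        for name, df in results_by_cohort.items()
    }
    all_probes = sorted(set().union(*(m.keys() for m in call_maps.values())))

    delta_frames = [
        df[["probe_id", "delta_beta"]] for df in results_by_cohort.values()
    ]
    deltas = pd.concat(delta_frames).groupby("probe_id")["delta_beta"]
    mean_delta = deltas.mean()
    n_testable = deltas.count()

    rows = []
    n_untestable = 0
    for pid in all_probes:
        calls = [call_maps[name].get(pid) for name in required]
        if any(c is None for c in calls):
            consensus = "NONE"
            n_untestable += 1
        elif all(c == "HYPER" for c in calls):
            consensus = "HYPER"
        elif all(c == "HYPO" for c in calls):
            consensus = "HYPO"
        else:
            consensus = "NONE"
        rows.append(
            {
                "probe_id": pid,
                "consensus": consensus,
                "mean_delta_beta": float(mean_delta.get(pid, np.nan)),
                "n_testable": int(n_testable.get(pid, 0)),
                "calls": ",".join(c if c is not None else "-" for c in calls),
            }
        )
    if n_untestable:
        logger.info(
            "%d probes untestable in >=1 required cohort -> consensus NONE",
            n_untestable,
        )
    out = pd.DataFrame(
        rows, columns=["probe_id", "consensus", "mean_delta_beta", "n_testable", "calls"]
    )
    if out.empty:
        logger.warning("empty probe intersection across cohorts")
    return out


def average_gene_fold_change(
    results_by_cohort: dict[str, pd.DataFrame], annotation: AnnotationTable
) -> pd.Series:
    """Gene-level average delta-beta over all (probe, cohort) pairs.

    Every mapped, testable probe contributes one term per cohort in which it
    is testable — significant or not. Genes with no testable mapped probe
    are absent.
    """
    assoc = annotation.associations[["probe_id", "gene"]]
    frames = []
    for df in results_by_cohort.values():
        merged = df[["probe_id", "delta_beta"]].merge(assoc, on="probe_id")
        frames.append(merged)
    if not frames:
        return pd.Series(dtype=float, name="avg_delta_beta")
    allpairs = pd.concat(frames)
    out = allpairs.groupby("gene")["delta_beta"].mean()
    out.name = "avg_delta_beta"
    return out


def assign_groups(
    consensus: pd.DataFrame,
    annotation: AnnotationTable,
    expression: ExpressionStatusTable,
    results_by_cohort: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Cross per-gene methylation consensus with expression status.

    Output columns: gene, meth_status (UP/DOWN/BOTH/NONE), expr_status,
    memberships (comma-joined subset of the four groups), inconsistent,
    avg_delta_beta, n_hyper, n_hypo, n_nondiff. Genes with expression status
    NS (or no expression record) get empty memberships; the latter are
    tallied in the log.
    """
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    merged = consensus.merge(assoc, on="probe_id", how="inner")

    expr_map = expression.as_mapping()
    avg = (
        average_gene_fold_change(results_by_cohort, annotation)
        if results_by_cohort is not None
        else consensus.merge(assoc, on="probe_id").groupby("gene")["mean_delta_beta"].mean()
    )

    rows = []
    n_no_expr = 0
    for gene, grp in merged.groupby("gene", sort=True):
        counts = grp["consensus"].value_counts()
        n_hyper = int(counts.get("HYPER", 0))
        n_hypo = int(counts.get("HYPO", 0))
        n_nondiff = int(counts.get("NONE", 0))
        if n_hyper and n_hypo:
            meth = "BOTH"
        elif n_hyper:
            meth = "UP"
        elif n_hypo:
            meth = "DOWN"
        else:
            meth = "NONE"

        if gene in expr_map:
            expr = expr_map[gene]
        else:
            expr = "NS"
            n_no_expr += 1

        memberships = []
        if meth in ("UP", "BOTH") and expr == "UP":
            memberships.append("UPUP")
        if meth in ("UP", "BOTH") and expr == "DOWN":
            memberships.append("UPDOWN")
        if meth in ("DOWN", "BOTH") and expr == "UP":
            memberships.append("DOWNUP")
        if meth in ("DOWN", "BOTH") and expr == "DOWN":
            memberships.append("DOWNDOWN")

        rows.append(
            {
                "gene": gene,
                "meth_status": meth,
                "expr_status": expr,
                "memberships": ",".join(memberships),
                "inconsistent": meth == "BOTH",
                "avg_delta_beta": float(avg.get(gene, np.nan)),
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "n_nondiff": n_nondiff,
            }
        )
    if n_no_expr:
        logger.info("%d genes with probes but no expression record", n_no_expr)
    return pd.DataFrame(
        rows,
        columns=["gene", "meth_status", "expr_status", "memberships",
                 "inconsistent", "avg_delta_beta", "n_hyper", "n_hypo", "n_nondiff"],
    )


def members(groups: pd.DataFrame, name: str) -> list[str]:
    """Genes belonging to one regulation group."""
    sel = groups["memberships"].str.split(",").apply(lambda ms: name in ms)
    return sorted(groups.loc[sel, "gene"])


def filter_only_groups(
    groups: pd.DataFrame,
    dense_results: pd.DataFrame,
    annotation: AnnotationTable,
    base_groups: tuple[str, ...] = ("UPUP", "UPDOWN"),
) -> pd.DataFrame:
    """Refine groups on a dense cohort into "-only" membership.

    For each gene of each base group, tally its dense-manifest probes by
    call. The gene is kept ("only") when it has >= 1 HYPER probe and no
    HYPO probe; otherwise it is excluded with the reason recorded:
    excluded_hypo (>=1 HYPO probe), excluded_no_hyper (probes but none
    HYPER), excluded_no_probes (no dense probe with data).

    Output columns: gene, base_group, status, n_dense_hyper, n_dense_hypo,
    n_dense_ns, frac_hyper.
    """
    call_map = dict(zip(dense_results["probe_id"], dense_results["call"]))
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    probes_by_gene = assoc.groupby("gene")["probe_id"].apply(list)

    rows = []
    for base in base_groups:
        for gene in members(groups, base):
            pids = probes_by_gene.get(gene, [])
            calls = [call_map[p] for p in pids if p in call_map]
            n_hyper = sum(c == "HYPER" for c in calls)
            n_hypo = sum(c == "HYPO" for c in calls)
            n_ns = sum(c == "NS" for c in calls)
            if not calls:
                status = "excluded_no_probes"
            elif n_hypo > 0:
                status = "excluded_hypo"
            elif n_hyper == 0:
                status = "excluded_no_hyper"
            else:
                status = "only"
            rows.append(
                {
                    "gene": gene,
                    "base_group": base,
                    "status": status,
                    "n_dense_hyper": n_hyper,
                    "n_dense_hypo": n_hypo,
                    "n_dense_ns": n_ns,
                    "frac_hyper": (n_hyper / len(calls)) if calls else np.nan,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene", "base_group", "status", "n_dense_hyper",
                 "n_dense_hypo", "n_dense_ns", "frac_hyper"],
    )
    for base in base_groups:
        sub = out.loc[out["base_group"] == base]
        logger.info(
            "%s: %d -> %d after -only filter (%d hypo-excluded, %d no-hyper, "
            "%d no-probes)",
            base, len(sub), int((sub["status"] == "only").sum()),
            int((sub["status"] == "excluded_hypo").sum()),
            int((sub["status"] == "excluded_no_hyper").sum()),
            int((sub["status"] == "excluded_no_probes").sum()),
        )
    return out


def only_members(only_table: pd.DataFrame, base_group: str) -> list[str]:
    sel = (only_table["base_group"] == base_group) & (only_table["status"] == "only")
    return sorted(only_table.loc[sel, "gene"])


def rank_genes(
    dense_results: pd.DataFrame,
    annotation: AnnotationTable,
    genes: list[str],
    k: int = 10,
) -> pd.DataFrame:
    """Rank genes by the mean raw p of their dense HYPER probes (ascending).

    Ties break lexicographically on the gene symbol. Asking for more genes
    than available returns all of them with a warning.
    """
    if not genes:
        raise ValueError("gene set is empty")
    hyper = dense_results.loc[dense_results["call"] == "HYPER",
                              ["probe_id", "p_value"]]
    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    merged = hyper.merge(assoc, on="probe_id")
    merged = merged.loc[merged["gene"].isin(set(genes))]
    scores = merged.groupby("gene")["p_value"].agg(["mean", "count"])
    scores = scores.rename(columns={"mean": "avg_p", "count": "n_hyper_probes"})
    scores = scores.reset_index().sort_values(
        ["avg_p", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    if k > len(scores):
        logger.warning("asked for top %d but only %d genes scored", k, len(scores))
        k = len(scores)
    return scores.head(k)
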