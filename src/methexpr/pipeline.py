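"""End-to-end orchestration: simulate -> differential methylation per cohort
-> cross-cohort consensus and regulation groups -> "-only" refinement on the
dense cohort -> matched-sample correlation -> genomic context -> summary.

One RunConfig (a YAML mapping) drives the whole run; every stage writes its
table under the output directory and the run summary JSON records per-stage
probe/gene counts so funnels like "713 -> 105" are visible in one place.
Reruns with the same config and seed reproduce every output byte for byte
(the summary's timing block aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .context import (
    DistanceBinSpec,
    bin_distances,
    cgi_summary,
    region_fractions,
    tss_distance_table,
    upstream_fraction,
    window_counts,
)
from .correlation import correlate_group, modal_bin
from .diffmeth import TestConfig, run_cohort, write_results
from .groups import (
    assign_groups,
    filter_only_groups,
    members,
    only_members,
    probe_consensus,
    rank_genes,
)
from .io import (
    read_beta_matrix,
    read_expression_matrix,
    read_expression_status,
    read_gene_models_bed12,
    read_manifest,
    read_sample_sheet,
)
from .simulate import SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """RunConfig invalid (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Input data violated a contract (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    outdir: str = "methexpr_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    inputs: dict = field(default_factory=dict)     # paths for non-simulate mode
    mode: str = "simulate"                         # "simulate" or "files"
    alpha: float = 0.05
    test: str = "welch"
    adjust: str = "none"
    required_cohorts: list[str] = field(default_factory=list)
    dense_cohort: str = ""
    matched_cohort: str = ""
    fold_change_split: float = 0.2
    rank_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            needed = {"manifest", "gene_models", "expression_status", "cohorts"}
            missing = needed - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs missing keys: {sorted(missing)}")
        if len(set(self.required_cohorts)) != len(self.required_cohorts):
            raise ConfigError("required cohort names must be unique")


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run summary dict.

    Stage order: (I) differential methylation on every cohort and the
    four-group classification from the consensus of the required cohorts;
    (II) "-only" refinement on the dense cohort; (III) probe-expression
    correlation on the matched cohort; (IV) TSS / CGI / gene-region context
    for both "-only" groups.
    """
    t0 = time.time()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_out: dict[str, str] = {}
    counts: dict = {}
    stage = "setup"

    try:
        # ------------------------------------------------------ inputs
        stage = "simulate" if config.mode == "simulate" else "load"
        if config.mode == "simulate":
            sim_args = dict(config.simulate)
            sim_args.setdefault("seed", config.seed)
            sim = SimConfig.from_dict(sim_args)
            ds = simulate_dataset(sim, matched_cohort=config.matched_cohort or None)
            manifest_out.update(write_dataset(ds, outdir / "data"))
            annotation = ds.annotation
            models = ds.gene_models
            expr_status = ds.expression_status
            expr_matrix = ds.expression
            cohorts = ds.cohorts
            matched_name = ds.matched_cohort
            counts["simulated"] = {
                "n_genes": int(len(ds.truth.genes)),
                "n_probes": int(len(ds.truth.probes)),
                "planted_groups": ds.truth.genes["group"].value_counts().to_dict(),
            }
        else:
            annotation = read_manifest(config.inputs["manifest"])
            models = read_gene_models_bed12(config.inputs["gene_models"])
            expr_status = read_expression_status(config.inputs["expression_status"])
            expr_matrix = (
                read_expression_matrix(config.inputs["expression_matrix"])
                if "expression_matrix" in config.inputs
                else None
            )
            cohorts = {}
            for name, paths in config.inputs["cohorts"].items():
                sheet = read_sample_sheet(paths["samples"])
                beta = read_beta_matrix(paths["matrix"], sheet, cohort=name)
                cohorts[name] = (beta, sheet)
            matched_name = config.matched_cohort

        required = config.required_cohorts or list(cohorts)
        dense_name = config.dense_cohort or list(cohorts)[-1]
        if dense_name not in cohorts:
            raise ConfigError(f"dense cohort {dense_name!r} not among cohorts")

        # ------------------------------------------------- stage I: diffmeth
        stage = "diffmeth"
        tcfg = TestConfig(alpha=config.alpha, test=config.test, adjust=config.adjust)
        results = {}
        for name, (beta, sheet) in cohorts.items():
            res = run_cohort(beta, sheet, tcfg)
            results[name] = res
            manifest_out[f"diffmeth_{name}"] = _write(
                res, outdir / f"diffmeth_{name}.tsv")
            counts.setdefault("diffmeth", {})[name] = {
                "n_testable": int(len(res)),
                "n_hyper": int((res["call"] == "HYPER").sum()),
                "n_hypo": int((res["call"] == "HYPO").sum()),
            }

        # -------------------------------------------- stage I: classification
        stage = "classify"
        sparse_results = {name: results[name] for name in required}
        consensus = probe_consensus(sparse_results, required)
        manifest_out["consensus"] = _write(consensus, outdir / "consensus.tsv")
        counts["consensus"] = {
            "n_probes": int(len(consensus)),
            "n_hyper": int((consensus["consensus"] == "HYPER").sum()),
            "n_hypo": int((consensus["consensus"] == "HYPO").sum()),
        }

        group_table = assign_groups(consensus, annotation, expr_status,
                                    results_by_cohort=sparse_results)
        manifest_out["groups"] = _write(group_table, outdir / "groups.tsv")
        counts["groups"] = {g: len(members(group_table, g))
                            for g in ("UPUP", "UPDOWN", "DOWNUP", "DOWNDOWN")}
        counts["groups"]["inconsistent"] = int(group_table["inconsistent"].sum())

        # ------------------------------------------- stage II: "-only" filter
        stage = "only_filter"
        dense_res = results[dense_name]
        only_table = filter_only_groups(group_table, dense_res, annotation)
        manifest_out["only_groups"] = _write(only_table, outdir / "only_groups.tsv")
        counts["only_filter"] = {}
        for base in ("UPUP", "UPDOWN"):
            sub = only_table.loc[only_table["base_group"] == base]
            kept = sub.loc[sub["status"] == "only"]
            counts["only_filter"][base] = {
                "before": int(len(sub)),
                "after": int(len(kept)),
                "excluded_hypo": int((sub["status"] == "excluded_hypo").sum()),
                "excluded_no_hyper": int((sub["status"] == "excluded_no_hyper").sum()),
                "excluded_no_probes": int((sub["status"] == "excluded_no_probes").sum()),
                "mean_hyper_probes_per_gene": (
                    float(kept["n_dense_hyper"].mean()) if len(kept) else float("nan")),
                "frac_genes_gt50pct_hyper": (
                    float((kept["frac_hyper"] > 0.5).mean()) if len(kept) else float("nan")),
                "frac_genes_all_hyper": (
                    float((kept["frac_hyper"] == 1.0).mean()) if len(kept) else float("nan")),
            }
            logger.info("%s: %d -> %d after -only filter", base,
                        len(sub), len(kept))

        ranked = {}
        for base in ("UPUP", "UPDOWN"):
            genes_only = only_members(only_table, base)
            if genes_only:
                rk = rank_genes(dense_res, annotation, genes_only, k=config.rank_k)
                ranked[base] = rk
                manifest_out[f"ranked_{base}"] = _write(
                    rk, outdir / f"ranked_{base}_only.tsv")

        # -------------------------------------- stage III: matched correlation
        stage = "correlate"
        counts["correlation"] = {}
        if expr_matrix is not None and matched_name in cohorts:
            meth_matched = cohorts[matched_name][0]
            hyper_probes = set(
                dense_res.loc[dense_res["call"] == "HYPER", "probe_id"])
            for base in ("UPUP", "UPDOWN"):
                genes_only = only_members(only_table, base)
                if not genes_only:
                    continue
                records, summary = correlate_group(
                    meth_matched, expr_matrix, annotation, genes_only,
                    probe_ids=hyper_probes)
                manifest_out[f"correlation_{base}"] = _write(
                    records, outdir / f"correlation_{base}_only.tsv")
                manifest_out[f"correlation_summary_{base}"] = _write(
                    summary, outdir / f"correlation_summary_{base}_only.tsv")
                counts["correlation"][base] = {
                    "n_records": int(len(records)),
                    "modal_bin": modal_bin(summary) if len(records) else "",
                }

        # ------------------------------------------- stage IV: genomic context
        stage = "context"
        spec = DistanceBinSpec(high_threshold=config.fold_change_split)
        counts["context"] = {}
        for base in ("UPUP", "UPDOWN"):
            genes_only = only_members(only_table, base)
            if not genes_only:
                continue
            hyper_probes = set(
                dense_res.loc[dense_res["call"] == "HYPER", "probe_id"])
            dist = tss_distance_table(annotation, models, genes_only,
                                      probe_ids=hyper_probes)
            manifest_out[f"tss_distances_{base}"] = _write(
                dist, outdir / f"tss_distances_{base}_only.tsv")
            manifest_out[f"window_counts_{base}"] = _write(
                window_counts(dist), outdir / f"window_counts_{base}_only.tsv")
            all_dist = tss_distance_table(annotation, models, genes_only)
            manifest_out[f"distance_bins_{base}"] = _write(
                bin_distances(all_dist, dense_res, spec),
                outdir / f"distance_bins_{base}_only.tsv")
            cgi = cgi_summary(annotation, genes_only, hyper_probes)
            with open(outdir / f"cgi_summary_{base}_only.json", "w") as fh:
                json.dump(cgi, fh, indent=1, sort_keys=True)
                fh.write("\n")
            manifest_out[f"cgi_summary_{base}"] = str(
                outdir / f"cgi_summary_{base}_only.json")
            frac = region_fractions(annotation, dense_res, models, genes_only)
            manifest_out[f"region_fractions_{base}"] = _write(
                frac, outdir / f"region_fractions_{base}_only.tsv")
            counts["context"][base] = {
                "n_hyper_probe_gene_pairs": int(len(dist)),
                "upstream_fraction": upstream_fraction(dist),
                "frac_genes_cgi_any": cgi["frac_genes_any"],
            }

    except (ConfigError, DataError):
        raise
    except ValueError as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    summary = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "required_cohorts": required,
        "dense_cohort": dense_name,
        "counts": counts,
        "outputs": manifest_out,
        "timing": {"wall_clock_s": round(time.time() - t0, 3)},
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
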