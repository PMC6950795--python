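"""Synthetic multi-cohort methylation + expression data with planted structure.

The generator emulates the study design this pipeline targets: several
cancer-vs-normal cohorts measured on Illumina-style beta-value arrays, one
sparse (27k-like, promoter-focused) and the rest dense (450k-like), plus a
gene-level expression status table and a matched methylation/expression
cohort. Genes are planted into regulation-pattern groups:

  UPUP      methylation gain,  expression up
  UPDOWN    methylation gain,  expression down
  DOWNUP    methylation loss,  expression up
  DOWNDOWN  methylation loss,  expression down
  NULL      no methylation effect, no expression change

Methylation effects are applied on the logit scale (so beta values stay in
(0,1)) with the logit shift calibrated per probe so the beta-scale mean
difference matches the requested delta-beta. Probes of one gene share a
per-sample gene factor carrying half the noise variance, so probes of the
same gene are correlated within condition as on real arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import expit, logit, stream_seed
from .io import (
    AnnotationTable,
    BetaMatrix,
    ExpressionStatusTable,
    GeneModel,
    SampleSheet,
    Transcript,
    write_beta_matrix,
    write_expression_matrix,
    write_expression_status,
    write_gene_models_bed12,
    write_manifest,
    write_sample_sheet,
)

GROUPS = ("UPUP", "UPDOWN", "DOWNUP", "DOWNDOWN", "NULL")

_EXPR_STATUS = {"UPUP": "UP", "DOWNUP": "UP", "UPDOWN": "DOWN",
                "DOWNDOWN": "DOWN", "NULL": "NS"}
_METH_DIR = {"UPUP": "HYPER", "UPDOWN": "HYPER", "DOWNUP": "HYPO",
             "DOWNDOWN": "HYPO", "NULL": "NONE"}
_EXPR_SIGN = {"UPUP": 1.0, "DOWNDOWN": 1.0, "UPDOWN": -1.0,
              "DOWNUP": -1.0, "NULL": 0.0}

_BETA_EPS = 0.001  # beta values clipped to [eps, 1-eps]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_cancer: int
    n_normal: int
    platform: str = "dense"  # "sparse" (27k-like) or "dense" (450k-like)


def _default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec("Absher", 95, 86, "sparse"),
        CohortSpec("Kirby", 73, 63, "dense"),
        CohortSpec("TCGA", 503, 50, "dense"),
    ]


def _default_fractions() -> dict[str, float]:
    return {"UPUP": 0.15, "UPDOWN": 0.30, "DOWNUP": 0.08,
            "DOWNDOWN": 0.12, "NULL": 0.35}


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the targeted study design."""

    seed: int = 0
    n_genes: int = 500
    probes_per_gene_sparse: int = 2
    probes_per_gene_dense: int = 16
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    group_fractions: dict[str, float] = field(default_factory=_default_fractions)
    delta_beta_effect: float = 0.2   # planted |mean(cancer) - mean(normal)|
    beta_noise_sd: float = 0.5       # total logit-scale noise sd
    gene_factor_share: float = 0.5   # fraction of noise variance shared per gene
    expr_coupling: float = 0.5       # target |Pearson r| meth vs expression
    frac_inconsistent: float = 0.02  # non-null genes given one opposite probe
    tss_span: int = 2000             # probes scattered in +/- span bp of TSS
    baseline_low: tuple[float, float] = (2.0, 10.0)   # Beta(a,b), low mode
    baseline_high: tuple[float, float] = (10.0, 2.0)  # Beta(a,b), high mode

    def validate(self) -> None:
        total = sum(self.group_fractions.get(g, 0.0) for g in GROUPS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"group_fractions sum to {total}, not 1")
        extra = set(self.group_fractions) - set(GROUPS)
        if extra:
            raise ConfigurationError(f"unknown groups: {sorted(extra)}")
        if any(f < 0 for f in self.group_fractions.values()):
            raise ConfigurationError("negative group fraction")
        if not (0 < self.delta_beta_effect <= 0.5):
            raise ConfigurationError("delta_beta_effect must be in (0, 0.5]")
        if min(self.n_genes, self.probes_per_gene_sparse,
               self.probes_per_gene_dense) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.probes_per_gene_dense < self.probes_per_gene_sparse:
            raise ConfigurationError("dense probe count must be >= sparse")
        if not (0 <= self.expr_coupling < 1):
            raise ConfigurationError("expr_coupling must be in [0, 1)")
        if not (0 <= self.frac_inconsistent <= 1):
            raise ConfigurationError("frac_inconsistent must be in [0, 1]")
        if self.beta_noise_sd <= 0:
            raise ConfigurationError("beta_noise_sd must be > 0")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigurationError("cohort names must be unique")
        for c in self.cohorts:
            if min(c.n_cancer, c.n_normal) < 1:
                raise ConfigurationError(f"cohort {c.name}: counts must be >= 1")
            if c.platform not in ("sparse", "dense"):
                raise ConfigurationError(f"cohort {c.name}: unknown platform")

    def cohort(self, name: str) -> CohortSpec:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown cohort {name!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "cohorts" in d:
            d["cohorts"] = [
                c if isinstance(c, CohortSpec) else CohortSpec(**c)
                for c in d["cohorts"]
            ]
        if "baseline_low" in d:
            d["baseline_low"] = tuple(d["baseline_low"])
        if "baseline_high" in d:
            d["baseline_high"] = tuple(d["baseline_high"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TruthTable:
    """Planted ground truth: per-gene group labels, per-probe effects.

    ``genes``: gene, group, expr_status.
    ``probes``: probe_id, gene, probe_index (within gene), direction
    (HYPER/HYPO/NONE), delta_beta (signed), baseline (normal-tissue mean
    beta), on_sparse.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "probes": self.probes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["genes"]), pd.DataFrame(payload["probes"]))


def generate_truth(config: SimConfig) -> TruthTable:
    """Plant gene group labels and per-probe methylation effects."""
    config.validate()
    rng = np.random.default_rng(stream_seed(config.seed, "truth"))

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    probs = [config.group_fractions.get(g, 0.0) for g in GROUPS]
    labels = rng.choice(GROUPS, size=config.n_genes, p=probs)

    gene_df = pd.DataFrame(
        {"gene": genes, "group": labels,
         "expr_status": [_EXPR_STATUS[g] for g in labels]}
    )

    k = config.probes_per_gene_dense
    a_lo, b_lo = config.baseline_low
    a_hi, b_hi = config.baseline_high

    rows = []
    pid = 0
    for gene, group in zip(genes, labels):
        direction = _METH_DIR[group]
        for j in range(k):
            if direction == "HYPER":
                base = rng.beta(a_lo, b_lo)
                delta = config.delta_beta_effect
            elif direction == "HYPO":
                base = rng.beta(a_hi, b_hi)
                delta = -config.delta_beta_effect
            else:
                base = rng.beta(a_lo, b_lo) if rng.random() < 0.5 else rng.beta(a_hi, b_hi)
                delta = 0.0
            base = float(np.clip(base, 0.05, 0.95))
            rows.append(
                {"probe_id": f"cg{pid:07d}", "gene": gene, "probe_index": j,
                 "direction": direction if delta != 0 else "NONE",
                 "delta_beta": delta, "baseline": base,
                 "on_sparse": j < config.probes_per_gene_sparse}
            )
            pid += 1
    probe_df = pd.DataFrame(rows)

    # one opposite-direction probe for a share of non-null genes; the flipped
    # probe is the gene's last (dense-only when dense > sparse) probe
    non_null = gene_df.loc[gene_df["group"] != "NULL", "gene"].to_numpy()
    n_flip = int(round(config.frac_inconsistent * len(non_null)))
    if n_flip > 0:
        flip_genes = rng.choice(non_null, size=n_flip, replace=False)
        for gene in flip_genes:
            mask = (probe_df["gene"] == gene) & (probe_df["probe_index"] == k - 1)
            idx = probe_df.index[mask][0]
            old_dir = probe_df.at[idx, "direction"]
            new_dir = "HYPO" if old_dir == "HYPER" else "HYPER"
            new_delta = (config.delta_beta_effect
                         if new_dir == "HYPER" else -config.delta_beta_effect)
            new_base = float(np.clip(
                rng.beta(a_lo, b_lo) if new_dir == "HYPER" else rng.beta(a_hi, b_hi),
                0.05, 0.95))
            probe_df.loc[idx, ["direction", "delta_beta", "baseline"]] = (
                new_dir, new_delta, new_base)

    return TruthTable(gene_df, probe_df)


# ---------------------------------------------------------------------------
# Annotation and gene models
# ---------------------------------------------------------------------------

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_GENE_SPACING = 100_000
_BODY_LEN = 2400


def _gene_geometry(i: int, gene: str) -> Transcript:
    """Deterministic toy transcript: 3 exons over a 2400 bp body."""
    chrom = _CHROMS[i % len(_CHROMS)]
    slot = i // len(_CHROMS)
    anchor = _GENE_SPACING * (slot + 1)
    strand = "+" if i % 2 == 0 else "-"
    if strand == "+":
        start = anchor
        exon_offsets = [(0, 300), (800, 1100), (1900, _BODY_LEN)]
        exons = tuple((start + a, start + b) for a, b in exon_offsets)
        thick = (start + 150, start + 2100)
        end = start + _BODY_LEN
    else:
        end = anchor + 1               # TSS = end - 1 = anchor
        start = end - _BODY_LEN
        exon_offsets = [(0, 500), (1300, 1600), (2100, _BODY_LEN)]
        exons = tuple((start + a, start + b) for a, b in exon_offsets)
        thick = (start + 300, start + 2250)
    return Transcript(
        name=f"{gene}|tx1", chrom=chrom, strand=strand, start=start, end=end,
        exons=exons, thick_start=thick[0], thick_end=thick[1],
    )


def _cgi_relation(offset_genomic: int) -> str:
    """Island/shore/shelf by genomic distance from the TSS-centred island."""
    d = abs(offset_genomic)
    if d <= 200:
        return "Island"
    side = "N" if offset_genomic < 0 else "S"
    if d <= 2000:
        return f"{side}_Shore"
    if d <= 4000:
        return f"{side}_Shelf"
    return "None"


def _region_tag(signed_offset: int) -> str:
    if abs(signed_offset) <= 200:
        return "TSS200"
    if abs(signed_offset) <= 1500:
        return "TSS1500"
    if 0 <= signed_offset <= _BODY_LEN:
        return "Body"
    return ""


def generate_annotation(
    config: SimConfig, truth: TruthTable
) -> tuple[AnnotationTable, dict[str, GeneModel]]:
    """Place genes on chromosomes and scatter probes around each TSS."""
    rng = np.random.default_rng(stream_seed(config.seed, "annotation"))
    gene_list = list(truth.genes["gene"])
    models: dict[str, GeneModel] = {}
    for i, gene in enumerate(gene_list):
        tx = _gene_geometry(i, gene)
        models[gene] = GeneModel(gene, [tx])

    probe_rows = []
    assoc_rows = []
    for row in truth.probes.itertuples(index=False):
        model = models[row.gene]
        tx = model.transcripts[0]
        # signed offset in gene orientation: negative = upstream
        offset = int(rng.integers(-config.tss_span, config.tss_span + 1))
        if tx.strand == "+":
            pos = tx.tss + offset
        else:
            pos = tx.tss - offset
        genomic_delta = pos - tx.tss
        probe_rows.append(
            {"probe_id": row.probe_id, "chrom": tx.chrom, "pos": pos,
             "cgi_relation": _cgi_relation(genomic_delta),
             "on_sparse": bool(row.on_sparse), "on_dense": True}
        )
        assoc_rows.append(
            {"probe_id": row.probe_id, "gene": row.gene,
             "region_tag": _region_tag(offset)}
        )
    annotation = AnnotationTable(pd.DataFrame(probe_rows), pd.DataFrame(assoc_rows))
    return annotation, models


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------


def _logit_shift(base: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Per-probe logit shift whose beta-scale effect is the planted delta."""
    target = np.clip(base + delta, 0.01, 0.99)
    return logit(target) - logit(np.clip(base, 0.01, 0.99))


def generate_cohort(
    config: SimConfig, truth: TruthTable, cohort_name: str
) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate one cohort's beta matrix and its sample sheet.

    A sparse-platform cohort exposes only the sparse probe subset. Each
    cohort has its own RNG stream derived from the master seed and the
    cohort name, so adding or reordering cohorts does not change another
    cohort's data.
    """
    config.validate()
    spec = config.cohort(cohort_name)
    rng = np.random.default_rng(stream_seed(config.seed, "cohort", spec.name))

    probes = truth.probes
    if spec.platform == "sparse":
        probes = probes.loc[probes["on_sparse"]].reset_index(drop=True)

    n_c, n_n = spec.n_cancer, spec.n_normal
    n = n_c + n_n
    sample_ids = [f"{spec.name}_C{i:03d}" for i in range(n_c)] + [
        f"{spec.name}_N{i:03d}" for i in range(n_n)
    ]

    base = probes["baseline"].to_numpy()
    delta = probes["delta_beta"].to_numpy()
    shift = _logit_shift(base, delta)

    sd = config.beta_noise_sd
    share = config.gene_factor_share
    sd_gene = sd * np.sqrt(share)
    sd_probe = sd * np.sqrt(1.0 - share)

    gene_codes, gene_uniques = pd.factorize(probes["gene"])
    gene_factor = rng.normal(0.0, sd_gene, size=(len(gene_uniques), n))
    probe_noise = rng.normal(0.0, sd_probe, size=(len(probes), n))

    x = logit(base)[:, None] + gene_factor[gene_codes, :] + probe_noise
    x[:, :n_c] += shift[:, None]
    beta = np.clip(expit(x), _BETA_EPS, 1.0 - _BETA_EPS)

    values = pd.DataFrame(beta, index=list(probes["probe_id"]), columns=sample_ids)
    sheet = SampleSheet(
        pd.DataFrame(
            {"sample_id": sample_ids,
             "condition": ["cancer"] * n_c + ["normal"] * n_n,
             "cohort": spec.name}
        )
    )
    return BetaMatrix(values, cohort=spec.name), sheet


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: SimConfig,
    truth: TruthTable,
    beta: BetaMatrix,
    sheet: SampleSheet,
) -> tuple[pd.DataFrame, ExpressionStatusTable]:
    """Matched expression coupled to per-gene mean methylation.

    Per gene g and sample s:
        expr[g, s] = baseline_g + sign_g * slope_g * (m[g, s] - mean m) + e
    where m is the mean beta over the gene's probes present in ``beta``,
    sign is +1 for UPUP/DOWNDOWN, -1 for UPDOWN/DOWNUP, 0 for NULL, and
    slope is calibrated against the empirical spread of m so the population
    |Pearson r| between m and expression is ``expr_coupling``.
    """
    config.validate()
    rng = np.random.default_rng(stream_seed(config.seed, "expression", beta.cohort))

    probes = truth.probes.loc[truth.probes["probe_id"].isin(beta.probe_ids)]
    vals = beta.values
    genes = list(truth.genes["gene"])
    groups = dict(zip(truth.genes["gene"], truth.genes["group"]))

    n = len(vals.columns)
    sd_e = 1.0
    r = config.expr_coupling
    slope_scale = (r / np.sqrt(1.0 - r * r)) if r > 0 else 0.0

    rows = np.empty((len(genes), n))
    for gi, gene in enumerate(genes):
        pids = probes.loc[probes["gene"] == gene, "probe_id"]
        baseline = rng.normal(8.0, 2.0)
        noise = rng.normal(0.0, sd_e, size=n)
        sign = _EXPR_SIGN[groups[gene]]
        if len(pids) == 0 or sign == 0.0 or slope_scale == 0.0:
            rows[gi] = baseline + noise
            continue
        m = vals.loc[pids].to_numpy().mean(axis=0)
        sd_m = m.std()
        if sd_m == 0:
            rows[gi] = baseline + noise
            continue
        slope = slope_scale * sd_e / sd_m
        rows[gi] = baseline + sign * slope * (m - m.mean()) + noise

    expr = pd.DataFrame(rows, index=genes, columns=list(vals.columns))

    # gene-level status table mirrors the planted labels
    status_rows = []
    for gene in genes:
        st = _EXPR_STATUS[groups[gene]]
        if st == "UP":
            lfc = float(rng.uniform(0.5, 3.0))
            p = float(10 ** rng.uniform(-8, -3))
        elif st == "DOWN":
            lfc = float(-rng.uniform(0.5, 3.0))
            p = float(10 ** rng.uniform(-8, -3))
        else:
            lfc = float(rng.normal(0.0, 0.05))
            p = float(rng.uniform(0.1, 1.0))
        status_rows.append({"gene": gene, "logFC": lfc, "p_value": p, "status": st})
    status = ExpressionStatusTable(pd.DataFrame(status_rows))
    return expr, status


# ---------------------------------------------------------------------------
# One-call dataset writer
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    truth: TruthTable
    annotation: AnnotationTable
    gene_models: dict[str, GeneModel]
    cohorts: dict[str, tuple[BetaMatrix, SampleSheet]]
    expression: pd.DataFrame
    expression_status: ExpressionStatusTable
    matched_cohort: str


def simulate_dataset(config: SimConfig, matched_cohort: str | None = None) -> SimulatedDataset:
    """Generate truth, annotation, every cohort, and matched expression."""
    config.validate()
    truth = generate_truth(config)
    annotation, models = generate_annotation(config, truth)
    cohorts = {c.name: generate_cohort(config, truth, c.name) for c in config.cohorts}
    if matched_cohort is None:
        dense = [c.name for c in config.cohorts if c.platform == "dense"]
        matched_cohort = dense[-1] if dense else config.cohorts[-1].name
    beta, sheet = cohorts[matched_cohort]
    expr, status = generate_expression(config, truth, beta, sheet)
    return SimulatedDataset(config, truth, annotation, models, cohorts,
                            expr, status, matched_cohort)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write every artifact as text files; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ds.truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    write_manifest(ds.annotation, outdir / "manifest.csv")
    paths["manifest"] = str(outdir / "manifest.csv")
    write_gene_models_bed12(ds.gene_models, outdir / "gene_models.bed12")
    paths["gene_models"] = str(outdir / "gene_models.bed12")
    for name, (beta, sheet) in ds.cohorts.items():
        write_beta_matrix(beta, outdir / f"beta_{name}.tsv")
        write_sample_sheet(sheet, outdir / f"samples_{name}.tsv")
        paths[f"beta_{name}"] = str(outdir / f"beta_{name}.tsv")
        paths[f"samples_{name}"] = str(outdir / f"samples_{name}.tsv")
    write_expression_matrix(ds.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    write_expression_status(ds.expression_status, outdir / "expression_status.tsv")
    paths["expression_status"] = str(outdir / "expression_status.tsv")

    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(ds.config), fh, indent=1, default=list)
        fh.write("\n")
    paths["sim_config"] = str(outdir / "sim_config.json")
    return paths
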