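"""Probe methylation vs gene expression correlation on matched samples.

Each (probe, gene) association is scored with the Pearson correlation of the
probe's beta profile against the gene's expression profile across the shared
samples (cancer and normal pooled). Correlations fall into 11 named bins on
|r| boundaries 0.1 / 0.2 / 0.4 / 0.5:

  very strong negative  (-1.0, -0.5]      very weak positive  (0, 0.1]
  strong negative       (-0.5, -0.4]      weak positive       (0.1, 0.2]
  intermediate negative (-0.4, -0.2]      intermediate positive (0.2, 0.4]
  weak negative         (-0.2, -0.1]      strong positive     (0.4, 0.5]
  very weak negative    (-0.1, 0)         very strong positive (0.5, 1.0]
  no correlation        r = 0

A boundary belongs to the stronger (outer) bin; |r| = 0.4 is intermediate,
|r| exactly 0.5 is strong — the half-open (lo, hi] convention on |r|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnnotationTable, BetaMatrix

_STRENGTHS = ("very weak", "weak", "intermediate", "strong", "very strong")
_BOUNDS = (0.0, 0.1, 0.2, 0.4, 0.5, 1.0)

BIN_LABELS = tuple(
    [f"{s} negative" for s in reversed(_STRENGTHS)]
    + ["no correlation"]
    + [f"{s} positive" for s in _STRENGTHS]
)

_TOL = 1e-12


def pearson(x, y) -> float:
    """Pairwise-complete Pearson r; NaN when undefined (<3 pairs or a
    constant vector)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return float("nan")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def bin_correlation(r: float) -> str:
    """Map a defined correlation to one of the 11 labels."""
    if np.isnan(r):
        raise ValueError("correlation undefined; cannot bin NaN")
    if abs(r) > 1 + _TOL:
        raise ValueError(f"|r| = {abs(r)} exceeds 1")
    r = float(np.clip(r, -1.0, 1.0))
    if r == 0.0:
        return "no correlation"
    family = "positive" if r > 0 else "negative"
    a = abs(r)
    for lo, hi, strength in zip(_BOUNDS[:-1], _BOUNDS[1:], _STRENGTHS):
        if lo < a <= hi:
            return f"{strength} {family}"
    raise AssertionError("unreachable: bins cover (0, 1]")


def bin_correlations(r: np.ndarray) -> np.ndarray:
    """Vectorised bin_correlation over an array of defined r values."""
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise ValueError("correlation undefined; cannot bin NaN")
    if (np.abs(r) > 1 + _TOL).any():
        raise ValueError("|r| exceeds 1")
    r = np.clip(r, -1.0, 1.0)
    a = np.abs(r)
    # searchsorted with side='left' puts boundary values in the inner bin,
    # matching the (lo, hi] convention
    idx = np.searchsorted(_BOUNDS[1:-1], a, side="left")
    strengths = np.array(_STRENGTHS, dtype=object)[idx]
    out = np.where(
        r == 0.0,
        "no correlation",
        np.where(r > 0, strengths + " positive", strengths + " negative"),
    )
    return out.astype(object)


def correlate_group(
    meth: BetaMatrix,
    expr: pd.DataFrame,
    annotation: AnnotationTable,
    genes: set[str] | list[str],
    probe_ids: set[str] | list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every (probe, gene) association for a gene set.

    ``probe_ids`` optionally restricts the associations to a probe subset
    (e.g. the group's hypermethylated probes). Returns (records, summary):
    records has one row per association — probe_id, gene, r, n, defined,
    bin; summary counts probes and distinct genes per bin with percentages
    over defined records.
    """
    genes = set(genes)
    shared = [s for s in meth.sample_ids if s in set(expr.columns)]
    if not shared:
        raise ValueError("no shared samples between methylation and expression")

    assoc = annotation.associations[["probe_id", "gene"]].drop_duplicates()
    assoc = assoc.loc[assoc["gene"].isin(genes)]
    if probe_ids is not None:
        assoc = assoc.loc[assoc["probe_id"].isin(set(probe_ids))]
    assoc = assoc.loc[assoc["probe_id"].isin(set(meth.probe_ids))]
    assoc = assoc.loc[assoc["gene"].isin(set(expr.index))]
    assoc = assoc.sort_values(["probe_id", "gene"]).reset_index(drop=True)

    m = meth.values[shared]
    e = expr[shared]
    rows = []
    for row in assoc.itertuples(index=False):
        r = pearson(m.loc[row.probe_id].to_numpy(), e.loc[row.gene].to_numpy())
        defined = not np.isnan(r)
        rows.append(
            {
                "probe_id": row.probe_id,
                "gene": row.gene,
                "r": r,
                "n": len(shared),
                "defined": defined,
                "bin": bin_correlation(r) if defined else "",
            }
        )
    records = pd.DataFrame(
        rows, columns=["probe_id", "gene", "r", "n", "defined", "bin"]
    )

    defined = records.loc[records["defined"]]
    total = len(defined)
    summary_rows = []
    for label in BIN_LABELS:
        sub = defined.loc[defined["bin"] == label]
        summary_rows.append(
            {
                "bin": label,
                "n_probes": len(sub),
                "pct_probes": (100.0 * len(sub) / total) if total else 0.0,
                "n_genes": sub["gene"].nunique(),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["bin", "n_probes", "pct_probes", "n_genes"])
    return records, summary


def modal_bin(summary: pd.DataFrame) -> str:
    """Most populated bin; ties break toward the earlier label order."""
    best = summary.loc[summary["n_probes"].idxmax()]
    return str(best["bin"])
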