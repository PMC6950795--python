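"""Per-probe differential methylation between cancer and normal samples.

The effect size is the delta-beta, mean(cancer) - mean(normal) on the beta
scale (the array literature's "methylation fold change"). Significance comes
from a two-sample t test on beta values — Welch by default, pooled-variance
optionally — with the HYPER/HYPO/NS call made at a raw-p threshold, or at a
Benjamini-Hochberg-adjusted threshold when requested.

Tests run on beta values rather than M-values because the downstream fold
change thresholds (0.2 / 0.5) are defined in beta units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

CALLS = ("HYPER", "HYPO", "NS")

MIN_GROUP_N = 3  # probes need >=3 non-missing values per condition


@dataclass(frozen=True)
class TestConfig:
    alpha: float = 0.05
    test: str = "welch"     # "welch" or "pooled"
    adjust: str = "none"    # "none" or "BH"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("welch", "pooled"):
            raise ValueError("test must be 'welch' or 'pooled'")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")


def _two_sample_t(
    x: np.ndarray, y: np.ndarray, test: str
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t on 2-D arrays with NaN missing values.

    Returns (t, p). Rows with zero variance in both groups get t=0, p=1.
    """
    nx = np.sum(~np.isnan(x), axis=1).astype(float)
    ny = np.sum(~np.isnan(y), axis=1).astype(float)
    mx = np.nanmean(x, axis=1)
    my = np.nanmean(y, axis=1)
    vx = np.nanvar(x, axis=1, ddof=1)
    vy = np.nanvar(y, axis=1, ddof=1)
    vx = np.where(np.isnan(vx), 0.0, vx)
    vy = np.where(np.isnan(vy), 0.0, vy)

    degenerate = (vx == 0) & (vy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "welch":
            se2 = vx / nx + vy / ny
            t = (mx - my) / np.sqrt(se2)
            df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        else:
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            t = (mx - my) / np.sqrt(sp2 * (1 / nx + 1 / ny))
            df = nx + ny - 2
        p = 2.0 * stats.t.sf(np.abs(t), df)

    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return t, p


def _call(delta: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    out = np.full(delta.shape, "NS", dtype=object)
    out[(p < alpha) & (delta > 0)] = "HYPER"
    out[(p < alpha) & (delta < 0)] = "HYPO"
    return out


def test_probe(
    values_cancer, values_normal, config: TestConfig = TestConfig(), probe_id: str = ""
) -> dict:
    """Differential methylation for a single probe.

    Returns a dict with delta_beta, p_value, call, n_cancer, n_normal.
    Raises ValueError if either group has fewer than 3 non-missing values
    (the probe is untestable, not NS).
    """
    x = np.asarray(values_cancer, dtype=float)
    y = np.asarray(values_normal, dtype=float)
    nx = int(np.sum(~np.isnan(x)))
    ny = int(np.sum(~np.isnan(y)))
    if nx < MIN_GROUP_N or ny < MIN_GROUP_N:
        raise ValueError(
            f"probe {probe_id or '<unnamed>'}: needs >= {MIN_GROUP_N} "
            f"non-missing values per group (got {nx}/{ny})"
        )
    t, p = _two_sample_t(x[None, :], y[None, :], config.test)
    delta = float(np.nanmean(x) - np.nanmean(y))
    return {
        "probe_id": probe_id,
        "delta_beta": delta,
        "p_value": float(p[0]),
        "call": str(_call(np.array([delta]), p, config.alpha)[0]),
        "n_cancer": nx,
        "n_normal": ny,
    }


def run_cohort(
    matrix: BetaMatrix, sheet: SampleSheet, config: TestConfig = TestConfig()
) -> pd.DataFrame:
    """Differential methylation for every testable probe of one cohort.

    Output columns: probe_id, cohort, delta_beta, p_value, adj_p, call,
    n_cancer, n_normal — one row per testable probe; untestable probes
    (fewer than 3 non-missing values in either condition) are logged and
    dropped. The call uses adj_p when the config asks for BH.
    """
    cancer = [s for s in matrix.sample_ids if sheet.condition_of(s) == "cancer"]
    normal = [s for s in matrix.sample_ids if sheet.condition_of(s) == "normal"]
    if len(cancer) < MIN_GROUP_N or len(normal) < MIN_GROUP_N:
        raise ValueError(
            f"cohort {matrix.cohort!r}: needs >= {MIN_GROUP_N} samples per "
            f"condition (got {len(cancer)} cancer / {len(normal)} normal)"
        )

    x = matrix.values[cancer].to_numpy(dtype=float)
    y = matrix.values[normal].to_numpy(dtype=float)
    nx = np.sum(~np.isnan(x), axis=1)
    ny = np.sum(~np.isnan(y), axis=1)
    testable = (nx >= MIN_GROUP_N) & (ny >= MIN_GROUP_N)
    n_drop = int(np.sum(~testable))
    if n_drop:
        dropped = [pid for pid, ok in zip(matrix.probe_ids, testable) if not ok]
        logger.info(
            "cohort %s: %d untestable probes excluded (e.g. %s)",
            matrix.cohort, n_drop, dropped[:3],
        )

    x, y = x[testable], y[testable]
    probe_ids = [pid for pid, ok in zip(matrix.probe_ids, testable) if ok]
    t, p = _two_sample_t(x, y, config.test)
    delta = np.nanmean(x, axis=1) - np.nanmean(y, axis=1)

    if config.adjust == "BH":
        adj = multipletests(p, method="fdr_bh")[1]
    else:
        adj = np.full_like(p, np.nan)
    p_for_call = adj if config.adjust == "BH" else p

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cohort": matrix.cohort,
            "delta_beta": delta,
            "p_value": p,
            "adj_p": adj,
            "call": _call(delta, p_for_call, config.alpha),
            "n_cancer": nx[testable],
            "n_normal": ny[testable],
        }
    )


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["probe_id"] = df["probe_id"].astype(str)
    return df
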