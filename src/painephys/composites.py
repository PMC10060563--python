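"""Signed z-score composites and the resilience-excitability correlation.

Behavioral and electrophysiological readouts live on incommensurate scales, so
each measure is z-scored across the pooled cohort (all experimental groups
together, sample SD with n-1) and combined with signs chosen so that "more"
always means the same thing:

* resilience  = mean( z(splash grooming), -z(TST immobility), -z(FST immobility) )
  per animal -- higher = less depressed;
* neuronal excitability = mean( z(R_in), -z(rheobase) ) per cell, averaged over
  each animal's cells -- higher = more excitable.

The two per-animal composites are then related by an ordinary least-squares
line (resilience on excitability) and the Pearson correlation coefficient.
Composites are invariant to affine rescaling of any raw measure, and the mean
(vs sum) of signed z-scores leaves the correlation coefficient unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ZeroVarianceError",
    "zscore",
    "resilience_scores",
    "excitability_scores",
    "CorrelationResult",
    "correlate_resilience_excitability",
]


class ZeroVarianceError(ValueError):
    """Raised when a measure has no spread and cannot be z-scored."""


def zscore(values: Sequence[float]) -> np.ndarray:
    """(x - mean)/SD with sample SD (n-1); requires >= 2 values and spread."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values to z-score, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise ValueError("z-score input contains non-finite values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ZeroVarianceError("cannot z-score a constant series")
    return (x - np.mean(x)) / sd


def resilience_scores(behavior: pd.DataFrame) -> pd.Series:
    """Per-animal resilience composite from a behavior table.

    Expects columns ``animal_id``, ``splash_s``, ``tst_s``, ``fst_s`` with one
    row per animal.  Each assay is z-scored across ALL animals pooled, then
    resilience = mean(z_splash, -z_TST, -z_FST).  Animals missing any assay
    are dropped with a warning.
    """
    cols = ["splash_s", "tst_s", "fst_s"]
    df = behavior[["animal_id"] + cols].copy()
    complete = df.dropna(subset=cols)
    dropped = set(df["animal_id"]) - set(complete["animal_id"])
    if dropped:
        warnings.warn(
            f"animals missing behavioral scores excluded from resilience: {sorted(dropped)}"
        )
    if complete["animal_id"].duplicated().any():
        raise ValueError("behavior table has multiple scored rows per animal")
    if len(complete) < 2:
        raise ValueError("need at least 2 fully scored animals")
    z_splash = zscore(complete["splash_s"])
    z_tst = zscore(complete["tst_s"])
    z_fst = zscore(complete["fst_s"])
    res = (z_splash - z_tst - z_fst) / 3.0
    return pd.Series(res, index=pd.Index(complete["animal_id"], name="animal_id"),
                     name="resilience")


def excitability_scores(features: pd.DataFrame, pooling: str = "cells") -> pd.Series:
    """Per-animal neuronal-excitability composite from a cell-features table.

    Expects columns ``animal_id``, ``rin_MOhm``, ``rheobase_pA`` and optionally
    ``excluded`` (QC verdict).  With ``pooling='cells'`` (default) R_in and
    rheobase are z-scored across all QC-passing cells pooled, combined per cell
    as mean(z_Rin, -z_rheobase), and averaged within animal.  With
    ``pooling='animal-means'`` the per-animal means of the raw measures are
    z-scored across animals instead.
    """
    df = features.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=["rin_MOhm", "rheobase_pA"])
    if len(df) < 2:
        raise ValueError("need at least 2 QC-passing cells")
    all_animals = set(features["animal_id"])
    kept = set(df["animal_id"])
    if all_animals - kept:
        warnings.warn(
            f"animals with no QC-passing cells excluded: {sorted(all_animals - kept)}"
        )
    if pooling == "cells":
        z_rin = zscore(df["rin_MOhm"])
        z_rheo = zscore(df["rheobase_pA"])
        cell_score = (z_rin - z_rheo) / 2.0
        out = (
            pd.DataFrame({"animal_id": df["animal_id"].values, "exc": cell_score})
            .groupby("animal_id")["exc"]
            .mean()
        )
    elif pooling == "animal-means":
        means = df.groupby("animal_id")[["rin_MOhm", "rheobase_pA"]].mean()
        out = pd.Series(
            (zscore(means["rin_MOhm"]) - zscore(means["rheobase_pA"])) / 2.0,
            index=means.index,
        )
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    out.name = "excitability"
    out.index.name = "animal_id"
    return out


@dataclass
class CorrelationResult:
    """Per-animal composites plus the fitted line and correlation statistics."""

    per_animal: pd.DataFrame  # animal_id, resilience, excitability[, n_cells]
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n_animals: int
    method: str = "pearson"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r2": self.r_squared,
            "p": self.p_value,
            "n": self.n_animals,
            "method": self.method,
        }


def correlate_resilience_excitability(
    resilience: pd.Series,
    excitability: pd.Series,
    method: str = "pearson",
) -> CorrelationResult:
    """Relate per-animal resilience (y) to neuronal excitability (x).

    Animals are matched by id (order-independent); at least 3 matched animals
    with spread on both axes are required.  The line is ordinary least squares
    of resilience on excitability; ``r`` and its two-sided p-value are Pearson
    by default, Spearman optionally.
    """
    merged = pd.concat(
        [resilience.rename("resilience"), excitability.rename("excitability")],
        axis=1, join="inner",
    ).sort_index()
    if len(merged) < 3:
        raise ValueError(f"need >= 3 matched animals, got {len(merged)}")
    x = merged["excitability"].to_numpy(dtype=float)
    y = merged["resilience"].to_numpy(dtype=float)
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise ZeroVarianceError("no spread on one of the composite axes")
    fit = sps.linregress(x, y)
    if method == "pearson":
        r, p = float(fit.rvalue), float(fit.pvalue)
    elif method == "spearman":
        rho = sps.spearmanr(x, y)
        r, p = float(rho.statistic), float(rho.pvalue)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        per_animal=merged.reset_index(),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        r_squared=r * r,
        p_value=p,
        n_animals=len(merged),
        method=method,
    )
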