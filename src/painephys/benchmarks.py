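"""Cohort-level recovery benchmarks: run the full pipeline on simulated cohorts
with known ground truth and measure how well the composites and statistics
recover it.

These are the package's own validation studies: correlation recovery under a
known latent depression-excitability coupling, false-positive calibration
under the null, and reproduction of the qualitative group pattern (injured
standard-housed animals score lowest on resilience and highest on neuronal
excitability; extended enrichment restores both).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .composites import (
    correlate_resilience_excitability,
    excitability_scores,
    resilience_scores,
)
from .features import extract_cell_features, features_table
from .stats import two_way_anova

__all__ = [
    "derive_seed",
    "cohort_composites",
    "pipeline_correlation",
    "correlation_recovery",
    "pattern_fractions",
    "anova_interaction_type1_rate",
]


def derive_seed(base_seed: int, *branch: int) -> int:
    """Deterministic child seed (< 2^31) for an independent simulation stream."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, branch)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def cohort_composites(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort and return per-animal composites with group labels."""
    coh = simulate_cohort(config)
    feats = [
        extract_cell_features(rec)
        for recs in coh.recordings.values()
        for rec in recs
    ]
    fdf = features_table(feats)
    final = coh.behavior[coh.behavior.timepoint_day == coh.behavior.timepoint_day.max()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = resilience_scores(final)
        exc = excitability_scores(fdf)
    out = pd.concat([res, exc], axis=1, join="inner").reset_index()
    groups = final.set_index("animal_id")
    out["group"] = out["animal_id"].map(groups["surgery"] + "-" + groups["housing"])
    return out


def pipeline_correlation(config: CohortConfig):
    """Full-pipeline resilience-excitability correlation for one cohort."""
    comps = cohort_composites(config)
    return correlate_resilience_excitability(
        comps.set_index("animal_id")["resilience"],
        comps.set_index("animal_id")["excitability"],
    )


def correlation_recovery(
    n_seeds: int, coupling: float, base_seed: int = 0
) -> dict:
    """Estimated r over ``n_seeds`` coupling-benchmark cohorts (16 animals x 6 cells).

    Returns mean/SD of r, the fraction of negative estimates, and the rejection
    rate of the r != 0 test at alpha = 0.05 (the type-I rate when coupling=0).
    """
    rs, ps = [], []
    for i in range(n_seeds):
        cfg = CohortConfig.coupling_benchmark(
            seed=derive_seed(base_seed, 1, i), coupling=coupling
        )
        result = pipeline_correlation(cfg)
        rs.append(result.r)
        ps.append(result.p_value)
    rs = np.asarray(rs)
    ps = np.asarray(ps)
    return {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "frac_negative": float(np.mean(rs < 0)),
        "reject_rate_alpha05": float(np.mean(ps < 0.05)),
        "n_seeds": n_seeds,
    }


def pattern_fractions(n_seeds: int, base_seed: int = 0) -> dict:
    """Fraction of default-cohort seeds reproducing the qualitative group pattern.

    Pattern (i): mean resilience of SNI-SH below both sham-SH and SNI-ExEE.
    Pattern (ii): mean excitability of SNI-SH above all three other groups.
    """
    hit_res = hit_exc = 0
    for i in range(n_seeds):
        cfg = CohortConfig(seed=derive_seed(base_seed, 2, i))
        comps = cohort_composites(cfg)
        means = comps.groupby("group")[["resilience", "excitability"]].mean()
        if (
            means.loc["SNI-SH", "resilience"] < means.loc["sham-SH", "resilience"]
            and means.loc["SNI-SH", "resilience"] < means.loc["SNI-ExEE", "resilience"]
        ):
            hit_res += 1
        others = means.drop(index="SNI-SH")["excitability"]
        if (means.loc["SNI-SH", "excitability"] > others).all():
            hit_exc += 1
    return {
        "frac_resilience_pattern": hit_res / n_seeds,
        "frac_excitability_pattern": hit_exc / n_seeds,
        "n_seeds": n_seeds,
    }


def anova_interaction_type1_rate(
    n_datasets: int, n_per_cell: int = 4, base_seed: int = 0, alpha: float = 0.05
) -> float:
    """Empirical interaction false-positive rate under the global null."""
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 3]))
    hits = 0
    labels_a = np.repeat(["SNI", "sham"], 2 * n_per_cell)
    labels_b = np.tile(np.repeat(["SH", "ExEE"], n_per_cell), 2)
    for _ in range(n_datasets):
        df = pd.DataFrame(
            {"surgery": labels_a, "housing": labels_b,
             "y": rng.standard_normal(4 * n_per_cell)}
        )
        res = two_way_anova(df, "y")
        if res.effects["interaction"].p < alpha:
            hits += 1
    return hits / n_datasets
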