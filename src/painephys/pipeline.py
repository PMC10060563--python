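"""End-to-end orchestration: simulate -> screen -> features -> correlate -> stats.

A :class:`RunConfig` (serializable to YAML) plus a seed reproduces every output
byte-for-byte.  The run writes, under the output directory:

* ``cohort/``            behavior.csv, ground_truth.json, traces/ (optional)
* ``screened.csv``       behavior with von Frey inclusion verdicts
* ``features.csv``       per-cell excitability features
* ``composites.csv``     per-animal resilience & excitability composites
* ``correlation.json``   the fitted resilience-excitability line
* ``stats.json``         ANOVA / post-hoc battery on behavior and features
* ``summary.txt``        human-readable digest
* ``run_config.yaml``    the exact configuration used
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .behavior import screen_behavior
from .cohort import CohortConfig, CohortResult, simulate_cohort
from .composites import (
    correlate_resilience_excitability,
    excitability_scores,
    resilience_scores,
)
from .features import extract_cell_features, features_table
from .neuron import NeuronParams, StepProtocol
from .stats import rm_two_way_anova, two_way_anova

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Full pipeline configuration; ``seed`` overrides the cohort seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    # spike-detection settings forwarded to the extractors
    spike_vcross_mV: float = -20.0
    spike_dvdt_V_per_s: float = 20.0
    # composite settings
    pooling: str = "cells"
    correlation_method: str = "pearson"
    # stats settings
    posthoc_method: str = "tukey"
    alpha: float = 0.05
    # outputs
    write_traces: bool = False

    def detect_kwargs(self) -> dict:
        return {
            "v_cross_mV": self.spike_vcross_mV,
            "dvdt_threshold_V_per_s": self.spike_dvdt_V_per_s,
        }

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cd = dict(d.pop("cohort", {}))
        if "base_neuron" in cd:
            cd["base_neuron"] = NeuronParams(**cd["base_neuron"])
        if "protocol" in cd:
            p = dict(cd["protocol"])
            p["current_amplitudes_pA"] = tuple(p.get("current_amplitudes_pA", ()))
            cd["protocol"] = StepProtocol(**p)
        for key in ("groups", "cells_per_animal", "timepoints_day"):
            if key in cd:
                cd[key] = tuple(cd[key])
        if "pwt_ipsi_timecourse_g" in cd:
            cd["pwt_ipsi_timecourse_g"] = {
                k: tuple(v) for k, v in cd["pwt_ipsi_timecourse_g"].items()
            }
        d["cohort"] = CohortConfig(**cd)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plainify(obj):
    """Make a config dict YAML-safe (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage {name!r} failed: {err}") from err
        return wrapped
    return deco


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute the whole pipeline; returns a summary dict (also written to disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)

    cohort = _stage("simulate")(simulate_cohort)(cohort_cfg)
    _stage("write-cohort")(pio.write_cohort)(
        cohort, out_dir / "cohort", traces=config.write_traces
    )

    # -- behavioral screening (per-animal verdict at the final timepoint)
    screened = _stage("screen")(screen_behavior)(cohort.behavior, alpha=config.alpha)
    screened.to_csv(out_dir / "screened.csv", index=False)
    final_day = screened["timepoint_day"].max()
    final = screened[screened["timepoint_day"] == final_day]
    included_animals = set(final.loc[final["included"], "animal_id"])
    excluded_animals = sorted(set(final["animal_id"]) - included_animals)

    # -- electrophysiology features
    def _features():
        feats = []
        for aid, recs in sorted(cohort.recordings.items()):
            for rec in recs:
                feats.append(extract_cell_features(rec, **config.detect_kwargs()))
        return features_table(feats)

    feat_df = _stage("features")(_features)()
    feat_df.to_csv(out_dir / "features.csv", index=False)

    # -- composites + correlation
    def _correlate():
        beh = final[final["animal_id"].isin(included_animals)]
        fdf = feat_df[feat_df["animal_id"].isin(included_animals)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = resilience_scores(beh)
            exc = excitability_scores(fdf, pooling=config.pooling)
        return correlate_resilience_excitability(
            res, exc, method=config.correlation_method
        )

    corr = _stage("correlate")(_correlate)()
    corr.per_animal.assign(
        n_cells=corr.per_animal["animal_id"].map(
            feat_df.groupby("animal_id").size()
        )
    ).to_csv(out_dir / "composites.csv", index=False)
    (out_dir / "correlation.json").write_text(
        json.dumps(corr.to_dict(), indent=1, sort_keys=True)
    )

    # -- statistics battery
    def _stats():
        out = {}
        for outcome in ("splash_s", "tst_s", "fst_s"):
            res = two_way_anova(
                final, outcome, "surgery", "housing",
                posthoc_method=config.posthoc_method, alpha=config.alpha,
            )
            out[outcome] = res.to_dict()
        # per-cell excitability measures
        feats = feat_df.merge(
            final[["animal_id", "surgery", "housing"]], on="animal_id", how="left"
        )
        feats = feats[~feats["excluded"].astype(bool)]
        for outcome in ("rheobase_pA", "rin_MOhm"):
            res = two_way_anova(
                feats, outcome, "surgery", "housing",
                posthoc_method="holm_sidak", alpha=config.alpha,
            )
            out[outcome] = res.to_dict()
        # PWT time course (ipsilateral mean per animal x timepoint)
        pwt = screened.copy()
        pwt["pwt_ipsi_mean_g"] = pwt[[f"pwt_ipsi_{i}_g" for i in range(1, 7)]].mean(axis=1)
        pwt["group"] = pwt["surgery"] + "-" + pwt["housing"]
        res = rm_two_way_anova(
            pwt, "pwt_ipsi_mean_g", subject="animal_id",
            within="timepoint_day", between="group",
        )
        out["pwt_ipsi_timecourse"] = res.to_dict()
        return out

    stats_out = _stage("stats")(_stats)()
    (out_dir / "stats.json").write_text(
        json.dumps(_plainify(stats_out), indent=1, sort_keys=True, allow_nan=True)
    )

    # -- summary
    summary = {
        "seed": config.seed,
        "n_animals": len(cohort.animal_ids),
        "n_cells": int(sum(len(v) for v in cohort.recordings.values())),
        "excluded_animals": excluded_animals,
        "correlation": corr.to_dict(),
    }
    config.to_yaml(out_dir / "run_config.yaml")
    _write_summary_txt(out_dir / "summary.txt", config, final, feat_df, corr,
                       excluded_animals, stats_out)
    return summary


def _write_summary_txt(path, config, final, feat_df, corr, excluded, stats_out) -> None:
    lines = []
    lines.append("painephys pipeline summary")
    lines.append(f"seed: {config.seed}")
    lines.append("")
    lines.append("group means +/- SEM (final timepoint):")
    final = final.copy()
    final["group"] = final["surgery"] + "-" + final["housing"]
    for outcome, unit in (("splash_s", "s"), ("tst_s", "s"), ("fst_s", "s")):
        g = final.groupby("group")[outcome]
        parts = [
            f"{grp}: {m:.1f}+/-{s:.1f} {unit}"
            for grp, m, s in zip(g.mean().index, g.mean(), g.sem())
        ]
        lines.append(f"  {outcome}: " + "; ".join(parts))
    lines.append("")
    if excluded:
        lines.append(f"excluded animals (von Frey screen): {excluded}")
    else:
        lines.append("excluded animals (von Frey screen): none")
    lines.append("")
    lines.append(
        "resilience vs excitability: "
        f"r={corr.r:.3f}, r2={corr.r_squared:.3f}, slope={corr.slope:.3f}, "
        f"p={corr.p_value:.3g}, n={corr.n_animals}"
    )
    lines.append("")
    lines.append("ANOVA battery (F, p):")
    for outcome, res in stats_out.items():
        eff = res["effects"]
        parts = [f"{k}: F={v['F']:.3g}, p={v['p']:.3g}" for k, v in eff.items()]
        lines.append(f"  {outcome}: " + "; ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")
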