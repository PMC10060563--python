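"""Synthetic cohort generator with known ground truth.

Emulates a 2x2 neuropathic-pain study: surgery (SNI vs sham) crossed with
housing (standard SH vs extended enrichment ExEE), four animals per group by
default.  Each animal carries a latent depression score ``d`` (group mean plus
within-group noise) and a latent excitability score ``x`` coupled to it:

    d_a = d_group + sigma_d * eps
    x_a = shift_group + beta * (d_a - d_group) + sigma_x * eta

Behavioral scalars move against/with ``d`` (less grooming, more immobility in
depressed animals); the cell-level LIF parameters move with ``x`` (higher
membrane resistance and lower spike-threshold voltage in excitable animals, so
lower rheobase).  Von Frey paw-withdrawal thresholds follow a per-group time
course: the injured (ipsilateral) paw collapses after SNI and is partially
rescued under extended enrichment.  Splash/TST/FST are scored at the final
timepoint only.

Ground truth records every latent and every true cell parameter, so any
downstream estimate can be checked exactly.  A config plus its seed determines
the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

from .neuron import NeuronParams, Recording, StepProtocol, lif_rheobase_pA, simulate_neuron

__all__ = ["DEFAULT_GROUPS", "CohortConfig", "CohortResult", "simulate_cohort"]

DEFAULT_GROUPS: tuple[str, ...] = ("sham-SH", "SNI-SH", "sham-ExEE", "SNI-ExEE")

SPLASH_MAX_S = 300.0
IMMOBILITY_MAX_S = 360.0


def _default_depression_means() -> dict[str, float]:
    # SNI under standard housing develops the depression-like phenotype;
    # extended enrichment largely rescues it, sham groups stay at baseline.
    return {"sham-SH": 0.0, "SNI-SH": 1.0, "sham-ExEE": 0.0, "SNI-ExEE": 0.2}


def _default_excitability_shifts() -> dict[str, float]:
    # one latent unit in SNI-SH maps to +30% R_m and -3 mV V_th via the gains
    return {"sham-SH": 0.0, "SNI-SH": 1.0, "sham-ExEE": 0.0, "SNI-ExEE": 0.0}


def _default_pwt_ipsi_timecourse() -> dict[str, tuple[float, ...]]:
    # grams at days (-1, +7, +21, +42, +56); injured paw collapses after SNI,
    # extended enrichment partially restores it over time
    return {
        "sham-SH": (4.5, 4.5, 4.5, 4.5, 4.5),
        "SNI-SH": (4.5, 1.6, 1.7, 1.8, 1.8),
        "sham-ExEE": (4.5, 4.5, 4.5, 4.5, 4.5),
        "SNI-ExEE": (4.5, 2.8, 3.0, 3.4, 3.8),
    }


@dataclass
class CohortConfig:
    """All simulator parameters; ``seed`` fully determines the cohort."""

    n_animals_per_group: int = 4
    groups: tuple[str, ...] = DEFAULT_GROUPS
    cells_per_animal: tuple[int, int] = (3, 8)
    seed: int = 0

    # latent structure
    depression_group_mean: dict[str, float] = field(default_factory=_default_depression_means)
    depression_sd: float = 0.3
    latent_coupling: float = 0.6
    excitability_group_shift: dict[str, float] = field(default_factory=_default_excitability_shifts)
    excitability_noise_sd: float = 0.25

    # latent -> neuron mapping
    base_neuron: NeuronParams = field(
        default_factory=lambda: NeuronParams(
            membrane_resistance_MOhm=150.0,
            membrane_capacitance_pF=150.0,
            resting_potential_mV=-70.0,
            spike_threshold_mV=-50.0,
            reset_potential_mV=-65.0,
            refractory_ms=2.0,
            voltage_noise_sd_mV=0.5,
        )
    )
    rm_gain_per_unit: float = 0.30       # fractional R_m change per latent unit
    vth_gain_mV_per_unit: float = 3.0    # V_th depolarization removed per latent unit
    rm_cell_cv: float = 0.08             # cell-to-cell R_m variability (fractional)
    vth_cell_sd_mV: float = 0.5
    protocol: StepProtocol = field(default_factory=StepProtocol)

    # behavior: value = mean - slope * d (splash) or mean + slope * d (TST/FST)
    splash_mean_s: float = 90.0
    splash_slope_s_per_unit: float = 35.0
    splash_sd_s: float = 15.0
    tst_mean_s: float = 120.0
    tst_slope_s_per_unit: float = 60.0
    tst_sd_s: float = 20.0
    fst_mean_s: float = 150.0
    fst_slope_s_per_unit: float = 50.0
    fst_sd_s: float = 20.0

    # von Frey
    timepoints_day: tuple[float, ...] = (-1.0, 7.0, 21.0, 42.0, 56.0)
    pwt_ipsi_timecourse_g: dict[str, tuple[float, ...]] = field(
        default_factory=_default_pwt_ipsi_timecourse
    )
    pwt_contra_g: float = 4.5
    pwt_sd_g: float = 0.3

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 2:
            raise ValueError("n_animals_per_group must be >= 2")
        if len(self.groups) * self.n_animals_per_group < 2:
            raise ValueError("cohort needs at least 2 animals")
        lo, hi = self.cells_per_animal
        if not (1 <= lo <= hi):
            raise ValueError("cells_per_animal must be a (min, max) range with min >= 1")
        for name in ("depression_sd", "excitability_noise_sd", "rm_cell_cv",
                     "vth_cell_sd_mV", "splash_sd_s", "tst_sd_s", "fst_sd_s", "pwt_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for g in self.groups:
            for d in (self.depression_group_mean, self.excitability_group_shift,
                      self.pwt_ipsi_timecourse_g):
                if g not in d:
                    raise ValueError(f"group {g!r} missing from a per-group parameter map")
            if len(self.pwt_ipsi_timecourse_g[g]) != len(self.timepoints_day):
                raise ValueError("PWT time course length must match timepoints_day")

    # -- preset configurations -----------------------------------------
    @classmethod
    def coupling_benchmark(cls, seed: int = 0, coupling: float = 0.8) -> "CohortConfig":
        """Benchmark cohort with a pure latent depression-excitability coupling.

        Group means are equalized and the latent pair (d, x) is standardized
        with corr(d, x) = ``coupling`` (default 0.8, i.e. a true animal-level
        resilience-excitability correlation near -0.8).  16 animals, 6 cells
        each.  Latent-to-parameter gains are reduced so rheobase stays inside
        the tested current range across the wider latent spread.
        """
        if not (0.0 <= coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        return cls(
            seed=seed,
            cells_per_animal=(6, 6),
            depression_group_mean={g: 0.0 for g in DEFAULT_GROUPS},
            depression_sd=1.0,
            latent_coupling=coupling,
            excitability_group_shift={g: 0.0 for g in DEFAULT_GROUPS},
            excitability_noise_sd=float(np.sqrt(1.0 - coupling**2)),
            rm_gain_per_unit=0.20,
            vth_gain_mV_per_unit=2.0,
        )

    @classmethod
    def null_benchmark(cls, seed: int = 0) -> "CohortConfig":
        """Coupling benchmark with beta = 0: depression and excitability independent."""
        return cls.coupling_benchmark(seed=seed, coupling=0.0)


@dataclass
class CohortResult:
    """Simulated cohort: behavior table, recordings per animal, ground truth."""

    behavior: pd.DataFrame
    recordings: dict[str, list[Recording]]
    ground_truth: dict
    config: CohortConfig

    @property
    def animal_ids(self) -> list[str]:
        return sorted(self.recordings.keys())


def simulate_cohort(config: CohortConfig, simulate_recordings: bool = True) -> CohortResult:
    """Generate the full cohort determined by ``config`` (and its seed).

    With ``simulate_recordings=False`` only latents, behavior and true cell
    parameters are produced (fast path for generator-level checks).
    """
    ss = np.random.SeedSequence(config.seed)
    ss_latent, ss_behavior, ss_cells = ss.spawn(3)
    rng_latent = np.random.default_rng(ss_latent)
    rng_behavior = np.random.default_rng(ss_behavior)

    animals: list[dict] = []
    idx = 0
    for group in config.groups:
        surgery, housing = group.split("-")
        d_mean = config.depression_group_mean[group]
        shift = config.excitability_group_shift[group]
        for _ in range(config.n_animals_per_group):
            idx += 1
            aid = f"A{idx:02d}"
            d = d_mean + config.depression_sd * rng_latent.standard_normal()
            x = (
                shift
                + config.latent_coupling * (d - d_mean)
                + config.excitability_noise_sd * rng_latent.standard_normal()
            )
            animals.append(
                {"animal_id": aid, "group": group, "surgery": surgery,
                 "housing": housing, "d": d, "x": x}
            )

    # -- behavior table -------------------------------------------------
    rows = []
    final_day = config.timepoints_day[-1]
    for a in animals:
        course = config.pwt_ipsi_timecourse_g[a["group"]]
        for t_i, day in enumerate(config.timepoints_day):
            ipsi = np.clip(
                course[t_i] + config.pwt_sd_g * rng_behavior.standard_normal(6),
                0.2, None,
            )
            contra = np.clip(
                config.pwt_contra_g + config.pwt_sd_g * rng_behavior.standard_normal(6),
                0.2, None,
            )
            row = {"animal_id": a["animal_id"], "surgery": a["surgery"],
                   "housing": a["housing"], "timepoint_day": day}
            if day == final_day:
                row["splash_s"] = float(np.clip(
                    config.splash_mean_s
                    - config.splash_slope_s_per_unit * a["d"]
                    + config.splash_sd_s * rng_behavior.standard_normal(),
                    0.0, SPLASH_MAX_S,
                ))
                row["tst_s"] = float(np.clip(
                    config.tst_mean_s
                    + config.tst_slope_s_per_unit * a["d"]
                    + config.tst_sd_s * rng_behavior.standard_normal(),
                    0.0, IMMOBILITY_MAX_S,
                ))
                row["fst_s"] = float(np.clip(
                    config.fst_mean_s
                    + config.fst_slope_s_per_unit * a["d"]
                    + config.fst_sd_s * rng_behavior.standard_normal(),
                    0.0, IMMOBILITY_MAX_S,
                ))
            else:
                row["splash_s"] = row["tst_s"] = row["fst_s"] = np.nan
            for i in range(6):
                row[f"pwt_ipsi_{i+1}_g"] = float(ipsi[i])
                row[f"pwt_contra_{i+1}_g"] = float(contra[i])
            rows.append(row)
    col_order = (
        ["animal_id", "surgery", "housing", "splash_s", "tst_s", "fst_s"]
        + [f"pwt_ipsi_{i}_g" for i in range(1, 7)]
        + [f"pwt_contra_{i}_g" for i in range(1, 7)]
        + ["timepoint_day"]
    )
    behavior = pd.DataFrame(rows)[col_order]

    # -- cells ----------------------------------------------------------
    base = config.base_neuron
    lo, hi = config.cells_per_animal
    recordings: dict[str, list[Recording]] = {}
    true_cells: dict[str, dict] = {}
    animal_streams = ss_cells.spawn(len(animals))
    for a, a_ss in zip(animals, animal_streams):
        a_rng = np.random.default_rng(a_ss)
        n_cells = int(a_rng.integers(lo, hi + 1)) if hi > lo else lo
        cell_seeds = a_ss.spawn(n_cells)
        recs: list[Recording] = []
        for c in range(n_cells):
            cid = f"{a['animal_id']}_c{c+1}"
            rm = base.membrane_resistance_MOhm * (
                1.0 + config.rm_gain_per_unit * a["x"]
            ) * (1.0 + config.rm_cell_cv * a_rng.standard_normal())
            rm = float(max(rm, 0.2 * base.membrane_resistance_MOhm))
            vth = (
                base.spike_threshold_mV
                - config.vth_gain_mV_per_unit * a["x"]
                + config.vth_cell_sd_mV * a_rng.standard_normal()
            )
            vth = float(max(vth, base.reset_potential_mV + 2.0))
            params = replace(
                base, membrane_resistance_MOhm=rm, spike_threshold_mV=vth
            )
            true_cells[cid] = {
                "animal_id": a["animal_id"],
                "membrane_resistance_MOhm": rm,
                "spike_threshold_mV": vth,
                "tau_ms": params.tau_ms,
                "rheobase_pA": lif_rheobase_pA(params),
            }
            if simulate_recordings:
                seed = int(cell_seeds[c].generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
                recs.append(
                    simulate_neuron(params, config.protocol, seed=seed,
                                    cell_id=cid, animal_id=a["animal_id"])
                )
        recordings[a["animal_id"]] = recs

    d_vec = np.array([a["d"] for a in animals])
    x_vec = np.array([a["x"] for a in animals])
    corr_d_x = float(np.corrcoef(d_vec, x_vec)[0, 1]) if np.std(d_vec) > 0 and np.std(x_vec) > 0 else float("nan")
    ground_truth = {
        "depression": {a["animal_id"]: a["d"] for a in animals},
        "excitability": {a["animal_id"]: a["x"] for a in animals},
        "group": {a["animal_id"]: a["group"] for a in animals},
        "cells": true_cells,
        "corr_depression_excitability": corr_d_x,
        "true_resilience_excitability_r": -corr_d_x,
    }
    return CohortResult(behavior=behavior, recordings=recordings,
                        ground_truth=ground_truth, config=config)
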