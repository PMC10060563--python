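"""Excitability feature extraction from current-clamp step recordings.

Per cell the extractor measures the quantities used to phenotype intrinsic
excitability of cortical pyramidal neurons:

* spike times per sweep (voltage-crossing + dV/dt criterion),
* the input-output (f-I) curve: spike count / firing rate per current step,
* rheobase, i.e. the minimum current eliciting one action potential, read off
  a monotone shape-preserving cubic spline through the f-I counts,
* input resistance R_in = dV/I from the hyperpolarizing -300 pA step,
* resting membrane potential, membrane time constant (single-exponential fit
  to the step onset), and action-potential amplitude / half-width / voltage
  threshold.

Quality-control flags accumulate per cell; cells with undefined rheobase or
input resistance are marked ``excluded`` and left out of downstream composite
scores.  Input traces are assumed already low-pass filtered by the acquisition
chain; optional Savitzky-Golay smoothing is applied to the dV/dt estimate only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.signal import savgol_filter

from .neuron import Recording, StepProtocol

__all__ = [
    "FICurve",
    "CellFeatures",
    "detect_spikes",
    "compute_fi_curve",
    "estimate_rheobase",
    "compute_input_resistance",
    "compute_passive_and_ap_features",
    "extract_cell_features",
    "features_table",
]

#: default spike criterion
SPIKE_VCROSS_MV = -20.0
SPIKE_DVDT_V_PER_S = 20.0
SPIKE_LOCKOUT_MS = 2.0

RIN_WINDOW_MS = 100.0     #: averaging window for dV (end of step vs end of baseline)
RIN_CURRENT_PA = -300.0   #: hyperpolarizing step used for R_in
TAU_FIT_MS = 200.0        #: fit window from step onset for the membrane time constant


def detect_spikes(
    sweep: Sequence[float],
    protocol: StepProtocol,
    v_cross_mV: float = SPIKE_VCROSS_MV,
    dvdt_threshold_V_per_s: float = SPIKE_DVDT_V_PER_S,
    lockout_ms: float = SPIKE_LOCKOUT_MS,
    savgol_window: Optional[int] = None,
) -> np.ndarray:
    """Detect action potentials in one voltage sweep; return times in seconds.

    A spike is an upward crossing of ``v_cross_mV`` whose preceding slope
    exceeds ``dvdt_threshold_V_per_s`` (note mV/ms == V/s).  The reported time
    is the first sample of the contiguous fast-slope run leading into the
    crossing — i.e. spike onset, not the peak.  Crossings within ``lockout_ms``
    of the previously accepted spike are suppressed.

    ``savgol_window`` (odd sample count) smooths the trace for the slope
    estimate only; the crossing test uses the raw trace.
    """
    v = np.asarray(sweep, dtype=float)
    if v.size == 0:
        raise ValueError("cannot detect spikes in an empty sweep")
    dt = protocol.dt_ms
    if savgol_window is not None:
        vs = savgol_filter(v, savgol_window, polyorder=3)
    else:
        vs = v
    dvdt = np.empty_like(vs)
    dvdt[0] = 0.0
    dvdt[1:] = np.diff(vs) / dt  # mV/ms == V/s

    crossings = np.flatnonzero((v[1:] >= v_cross_mV) & (v[:-1] < v_cross_mV)) + 1
    fast = dvdt > dvdt_threshold_V_per_s

    times: list[float] = []
    last_ms = -np.inf
    for i in crossings:
        if not fast[i]:
            continue
        j = i
        while j > 1 and fast[j - 1]:
            j -= 1
        t_ms = j * dt
        if t_ms - last_ms < lockout_ms:
            continue
        times.append(t_ms)
        last_ms = t_ms
    return np.asarray(times) / 1000.0


@dataclass
class FICurve:
    """Input-output relationship: spike counts / firing rates per current step."""

    currents_pA: np.ndarray
    spike_counts: np.ndarray
    firing_rates_Hz: np.ndarray

    def __post_init__(self) -> None:
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        self.spike_counts = np.asarray(self.spike_counts, dtype=float)
        self.firing_rates_Hz = np.asarray(self.firing_rates_Hz, dtype=float)
        n = self.currents_pA.size
        if self.spike_counts.size != n or self.firing_rates_Hz.size != n:
            raise ValueError("FICurve fields must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(self.spike_counts < 0):
                raise ValueError("spike counts must be non-negative")

    def __len__(self) -> int:
        return self.currents_pA.size


def compute_fi_curve(rec: Recording, **detect_kwargs) -> FICurve:
    """Count spikes inside the step window of every sweep and form the f-I curve."""
    counts = np.zeros(rec.n_sweeps)
    t0 = rec.protocol.baseline_ms / 1000.0
    t1 = (rec.protocol.baseline_ms + rec.protocol.step_ms) / 1000.0
    for s in range(rec.n_sweeps):
        t = detect_spikes(rec.sweeps[s], rec.protocol, **detect_kwargs)
        counts[s] = np.count_nonzero((t >= t0) & (t < t1))
    rates = counts / (rec.protocol.step_ms / 1000.0)
    return FICurve(
        currents_pA=np.asarray(rec.protocol.current_amplitudes_pA),
        spike_counts=counts,
        firing_rates_Hz=rates,
    )


def estimate_rheobase(
    fi: FICurve, grid_step_pA: float = 1.0
) -> tuple[Optional[float], list[str]]:
    """Spline-based rheobase: smallest current where the f-I spline reaches 1 spike.

    A monotone shape-preserving cubic (PCHIP) is fit to (current, spike count)
    over the non-negative currents and evaluated on a ``grid_step_pA`` grid
    between the largest zero-count current and the smallest spiking current
    above it, guaranteeing the estimate lies in that half-open bracket.

    Returns ``(rheobase_pA, flags)``; ``rheobase_pA`` is ``None`` (flag
    ``rheobase_undefined``) when no sweep spikes, and the smallest tested
    non-negative current (flag ``rheobase_all_spiking``) when every
    non-negative step already spikes.
    """
    flags: list[str] = []
    mask = fi.currents_pA >= 0
    currents = fi.currents_pA[mask]
    counts = fi.spike_counts[mask]
    if currents.size < 2:
        return None, ["rheobase_undefined"]
    if not np.any(fi.spike_counts >= 1):
        return None, ["rheobase_undefined"]

    zero = np.flatnonzero(counts < 1)
    if zero.size == 0:
        return float(currents[0]), ["rheobase_all_spiking"]
    i0 = zero[-1]
    above = np.flatnonzero((counts >= 1) & (np.arange(counts.size) > i0))
    if above.size == 0:
        # spikes only below the largest zero-count current (noise artifact)
        return None, ["rheobase_undefined", "rheobase_nonmonotonic_counts"]
    i1 = above[0]
    if i1 > i0 + 1:
        flags.append("rheobase_nonmonotonic_counts")

    spline = PchipInterpolator(currents, counts)
    lo, hi = currents[i0], currents[i1]
    grid = lo + grid_step_pA * np.arange(1, int(np.floor((hi - lo) / grid_step_pA)) + 1)
    grid = grid[grid <= hi]
    if grid.size == 0 or not np.isclose(grid[-1], hi):
        grid = np.append(grid, hi)
    vals = spline(grid)
    hit = np.flatnonzero(vals >= 1.0)
    est = float(grid[hit[0]]) if hit.size else float(hi)
    return est, flags


def compute_input_resistance(
    rec: Recording,
    current_pA: float = RIN_CURRENT_PA,
    window_ms: float = RIN_WINDOW_MS,
    **detect_kwargs,
) -> tuple[float, float, list[str]]:
    """Input resistance from the hyperpolarizing step: returns (R_in MOhm, dV mV, flags).

    dV = mean voltage over the last ``window_ms`` of the step minus the mean
    over the ``window_ms`` immediately before step onset; R_in = 1000 * dV / I
    so that 1 mV per 1 pA equals 1000 MOhm.  Both dV and I are negative for the
    hyperpolarizing step, giving a positive resistance.
    """
    flags: list[str] = []
    sweep = rec.sweep_at(current_pA)  # raises if the protocol lacks the step
    p = rec.protocol
    n_win = int(round(window_ms / p.dt_ms))
    n_win = min(n_win, p.n_baseline, p.n_step)
    if n_win < 1:
        raise ValueError("averaging window shorter than one sample")
    base = sweep[p.n_baseline - n_win : p.n_baseline]
    steady = sweep[p.n_baseline + p.n_step - n_win : p.n_baseline + p.n_step]
    delta_v = float(np.mean(steady) - np.mean(base))
    rin = 1000.0 * delta_v / current_pA

    spikes = detect_spikes(sweep, p, **detect_kwargs)
    if spikes.size:
        flags.append("rin_spikes_in_sweep")
    if abs(delta_v) < 0.5:
        flags.append("rin_implausible")
    if rin < 0:
        flags.append("rin_negative")
    return rin, delta_v, flags


def _exp_decay(t, a, b, tau):
    return a + b * np.exp(-t / tau)


def _exp_decay_jac(t, a, b, tau):
    e = np.exp(-t / tau)
    return np.stack([np.ones_like(t), e, b * t * e / tau**2], axis=1)


@dataclass
class PassiveAPFeatures:
    rmp_mV: float
    tau_ms: float
    ap_amplitude_mV: float
    ap_halfwidth_ms: float
    ap_threshold_mV: float
    flags: list[str] = field(default_factory=list)


def compute_passive_and_ap_features(
    rec: Recording,
    tau_current_pA: float = RIN_CURRENT_PA,
    n_spikes_for_ap: int = 3,
    **detect_kwargs,
) -> PassiveAPFeatures:
    """Resting potential, membrane time constant, and action-potential shape.

    * RMP: mean pre-step baseline voltage pooled over all sweeps.
    * tau: single-exponential fit to the first 200 ms of the hyperpolarizing
      step onset.
    * AP features: averaged over the first up to three spikes of the lowest
      suprathreshold sweep.  The voltage threshold is the membrane potential at
      the last sample before dV/dt exceeds 20 V/s; amplitude is peak minus
      threshold; half-width is the (sub-sample interpolated) duration at half
      amplitude.
    """
    flags: list[str] = []
    p = rec.protocol
    n_base_win = min(int(round(RIN_WINDOW_MS / p.dt_ms)), p.n_baseline)
    rmp = float(np.mean(rec.sweeps[:, p.n_baseline - n_base_win : p.n_baseline]))

    # -- membrane time constant ----------------------------------------
    tau_ms = float("nan")
    try:
        sweep = rec.sweep_at(tau_current_pA)
        n_fit = min(int(round(TAU_FIT_MS / p.dt_ms)), p.n_step)
        seg = sweep[p.n_baseline : p.n_baseline + n_fit]
        t = np.arange(seg.size) * p.dt_ms
        v0, v1 = float(seg[0]), float(np.mean(seg[-max(seg.size // 10, 1):]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)  # flat-trace fits
            popt, _ = curve_fit(
                _exp_decay, t, seg, p0=(v1, v0 - v1, 20.0),
                jac=_exp_decay_jac, maxfev=2000,
            )
        tau_ms = float(popt[2])
        if not (0.01 < tau_ms < 1000.0):
            tau_ms = float("nan")
            flags.append("tau_fit_failed")
    except (ValueError, RuntimeError):
        flags.append("tau_fit_failed")

    # -- AP shape -------------------------------------------------------
    amp = hw = thr = float("nan")
    spike_sweep = None
    amps = np.asarray(p.current_amplitudes_pA)
    t0 = p.baseline_ms / 1000.0
    t1 = (p.baseline_ms + p.step_ms) / 1000.0
    for s in np.argsort(amps):
        if amps[s] <= 0:
            continue
        st = detect_spikes(rec.sweeps[s], p, **detect_kwargs)
        st = st[(st >= t0) & (st < t1)]
        if st.size:
            spike_sweep, spike_times = s, st
            break
    if spike_sweep is None:
        flags.append("ap_no_spikes")
    else:
        v = rec.sweeps[spike_sweep]
        amps_i, hws_i, thrs_i = [], [], []
        for t_s in spike_times[:n_spikes_for_ap]:
            j0 = int(round(t_s * 1000.0 / p.dt_ms))
            j_end = min(j0 + int(round(3.0 / p.dt_ms)), v.size)
            seg = v[j0:j_end]
            if seg.size < 3:
                continue
            pk = int(np.argmax(seg))
            v_peak = float(seg[pk])
            v_thr = float(v[max(j0 - 1, 0)])
            a = v_peak - v_thr
            half = v_thr + a / 2.0
            hw_ms = _width_at_level(seg, pk, half, p.dt_ms)
            amps_i.append(a)
            hws_i.append(hw_ms)
            thrs_i.append(v_thr)
        if amps_i:
            amp = float(np.mean(amps_i))
            hw = float(np.nanmean(hws_i))
            thr = float(np.mean(thrs_i))
        else:
            flags.append("ap_no_spikes")
    return PassiveAPFeatures(rmp, tau_ms, amp, hw, thr, flags)


def _width_at_level(seg: np.ndarray, pk: int, level: float, dt_ms: float) -> float:
    """Sub-sample width of the waveform segment above ``level`` around ``pk``."""
    if seg[pk] <= level:
        return float("nan")
    i = pk
    while i > 0 and seg[i - 1] > level:
        i -= 1
    if i == 0:
        t_up = 0.0
    else:
        frac = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
        t_up = (i - 1 + frac) * dt_ms
    j = pk
    while j < seg.size - 1 and seg[j + 1] > level:
        j += 1
    if j == seg.size - 1:
        t_dn = j * dt_ms
    else:
        frac = (seg[j] - level) / (seg[j] - seg[j + 1])
        t_dn = (j + frac) * dt_ms
    return t_dn - t_up


@dataclass
class CellFeatures:
    """Extracted excitability measures for one cell."""

    cell_id: str
    animal_id: str
    rheobase_pA: Optional[float]
    input_resistance_MOhm: float
    delta_v_mV: float
    rmp_mV: float
    tau_ms: float
    ap_amplitude_mV: float
    ap_halfwidth_ms: float
    ap_threshold_mV: float
    fi: FICurve
    qc_flags: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        """Cells without a defined rheobase or a plausible R_in leave composites."""
        return (
            self.rheobase_pA is None
            or not np.isfinite(self.input_resistance_MOhm)
            or "rin_implausible" in self.qc_flags
            or "rin_negative" in self.qc_flags
        )

    def n_spikes_at(self, current_pA: float) -> float:
        idx = np.flatnonzero(np.isclose(self.fi.currents_pA, current_pA))
        return float(self.fi.spike_counts[idx[0]]) if idx.size else float("nan")


def extract_cell_features(rec: Recording, **detect_kwargs) -> CellFeatures:
    """Run all extractors on one recording and assemble a :class:`CellFeatures`."""
    fi = compute_fi_curve(rec, **detect_kwargs)
    rheo, rheo_flags = estimate_rheobase(fi)
    try:
        rin, dv, rin_flags = compute_input_resistance(rec, **detect_kwargs)
    except ValueError:
        rin, dv, rin_flags = float("nan"), float("nan"), ["rin_missing_sweep"]
    passive = compute_passive_and_ap_features(rec, **detect_kwargs)
    return CellFeatures(
        cell_id=rec.cell_id,
        animal_id=rec.animal_id,
        rheobase_pA=rheo,
        input_resistance_MOhm=rin,
        delta_v_mV=dv,
        rmp_mV=passive.rmp_mV,
        tau_ms=passive.tau_ms,
        ap_amplitude_mV=passive.ap_amplitude_mV,
        ap_halfwidth_ms=passive.ap_halfwidth_ms,
        ap_threshold_mV=passive.ap_threshold_mV,
        fi=fi,
        qc_flags=rheo_flags + rin_flags + passive.flags,
    )


def features_table(features: Sequence[CellFeatures]) -> pd.DataFrame:
    """Tabulate per-cell features (one row per cell) for CSV export."""
    rows = []
    for f in features:
        rows.append(
            {
                "cell_id": f.cell_id,
                "animal_id": f.animal_id,
                "rheobase_pA": np.nan if f.rheobase_pA is None else f.rheobase_pA,
                "rin_MOhm": f.input_resistance_MOhm,
                "delta_v_mV": f.delta_v_mV,
                "rmp_mV": f.rmp_mV,
                "tau_ms": f.tau_ms,
                "ap_amp_mV": f.ap_amplitude_mV,
                "ap_halfwidth_ms": f.ap_halfwidth_ms,
                "ap_threshold_mV": f.ap_threshold_mV,
                "n_spikes_at_200pA": f.n_spikes_at(200.0),
                "excluded": f.excluded,
                "qc_flags": ";".join(f.qc_flags),
            }
        )
    return pd.DataFrame(rows)
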