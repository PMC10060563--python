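"""Leaky integrate-and-fire (LIF) model neuron under a square current-step protocol.

The simulator stands in for whole-cell current-clamp recordings of cortical
pyramidal neurons: a family of square current injections is applied on top of a
silent baseline, the membrane is integrated with forward Euler at the protocol
sampling rate, and each threshold crossing is rendered as a stereotyped 2 ms
action-potential waveform so that downstream spike-shape code has something to
measure.  The LIF membrane equation is

    C_m dV/dt = -(V - E_L)/R_m + I(t)

with spike-and-reset at ``V_th`` and an absolute refractory period.  Because the
dynamics are closed-form between spikes, every downstream feature extractor can
be tested against analytic oracles:

* rheobase  = (V_th - E_L)/R_m
* steady-state deflection  dV = I * R_m
* interspike interval  ISI = t_ref + tau * ln((V_inf - V_reset)/(V_inf - V_th))

Units throughout: mV, pA, ms, MOhm, pF.  With those units the membrane time
constant is ``tau_ms = R_m * C_m / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_AMPLITUDES_PA",
    "StepProtocol",
    "NeuronParams",
    "Recording",
    "simulate_neuron",
    "lif_rheobase_pA",
    "lif_spike_count",
    "spike_waveform",
]

#: the ten-step family from -300 pA to +600 pA in 100 pA increments
DEFAULT_AMPLITUDES_PA: tuple[float, ...] = tuple(float(i) for i in range(-300, 601, 100))

AP_PEAK_MV = 30.0  #: rendered action-potential peak
AP_RISE_MS = 0.4   #: rise time of the pasted waveform
AP_TOTAL_MS = 2.0  #: total pasted waveform duration


@dataclass(frozen=True)
class StepProtocol:
    """Square current-step stimulation protocol.

    Defaults follow a ten-step family of progressively increasing currents from
    -300 pA to +600 pA digitized at 10 kHz.  Step timing (200 ms baseline,
    500 ms step, 200 ms post) is configurable; 500 ms exceeds five membrane
    time constants for any plausible cortical tau, so the steady state used for
    input-resistance measurement is reached within the step.
    """

    current_amplitudes_pA: tuple[float, ...] = DEFAULT_AMPLITUDES_PA
    baseline_ms: float = 200.0
    step_ms: float = 500.0
    post_ms: float = 200.0
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.current_amplitudes_pA)
        object.__setattr__(self, "current_amplitudes_pA", amps)
        if len(amps) < 1:
            raise ValueError("protocol needs at least one current amplitude")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("current amplitudes must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.baseline_ms < 0 or self.post_ms < 0:
            raise ValueError("baseline_ms and post_ms must be non-negative")

    # -- derived timing -------------------------------------------------
    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_baseline(self) -> int:
        return int(round(self.baseline_ms / self.dt_ms))

    @property
    def n_step(self) -> int:
        return int(round(self.step_ms / self.dt_ms))

    @property
    def n_post(self) -> int:
        return int(round(self.post_ms / self.dt_ms))

    @property
    def n_samples(self) -> int:
        return self.n_baseline + self.n_step + self.n_post

    @property
    def step_window(self) -> slice:
        """Sample slice covering the current step."""
        return slice(self.n_baseline, self.n_baseline + self.n_step)

    @property
    def sweep_duration_ms(self) -> float:
        return self.baseline_ms + self.step_ms + self.post_ms

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class NeuronParams:
    """Passive and spiking parameters of the LIF model neuron."""

    membrane_resistance_MOhm: float
    membrane_capacitance_pF: float
    resting_potential_mV: float = -70.0
    spike_threshold_mV: float = -50.0
    reset_potential_mV: float = -65.0
    refractory_ms: float = 2.0
    voltage_noise_sd_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.membrane_resistance_MOhm <= 0:
            raise ValueError("membrane_resistance_MOhm must be positive")
        if self.membrane_capacitance_pF <= 0:
            raise ValueError("membrane_capacitance_pF must be positive")
        if self.reset_potential_mV >= self.spike_threshold_mV:
            raise ValueError("reset_potential_mV must lie below spike_threshold_mV")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be non-negative")
        if self.voltage_noise_sd_mV < 0:
            raise ValueError("voltage_noise_sd_mV must be non-negative")

    @property
    def tau_ms(self) -> float:
        return self.membrane_resistance_MOhm * self.membrane_capacitance_pF / 1000.0

    @property
    def rheobase_pA(self) -> float:
        """Analytic rheobase (V_th - E_L)/R_m in pA."""
        return lif_rheobase_pA(self)


@dataclass
class Recording:
    """One cell's sweep set: a voltage matrix plus its stimulation protocol.

    ``sweeps`` has shape (n_sweeps, n_samples) in mV, one row per current
    amplitude, in protocol order.  ``ground_truth`` is attached by the
    simulator (true parameters, analytic rheobase, exact spike times) and is
    absent for imported data.
    """

    sweeps: np.ndarray
    protocol: StepProtocol
    cell_id: str = ""
    animal_id: str = ""
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError(f"sweeps must be 2-D, got shape {self.sweeps.shape}")
        n_amps = len(self.protocol.current_amplitudes_pA)
        if self.sweeps.shape[0] != n_amps:
            raise ValueError(
                f"recording {self.cell_id!r}: {self.sweeps.shape[0]} sweeps but "
                f"{n_amps} protocol amplitudes"
            )
        if self.sweeps.shape[1] != self.protocol.n_samples:
            raise ValueError(
                f"recording {self.cell_id!r}: sweep length {self.sweeps.shape[1]} "
                f"does not match protocol ({self.protocol.n_samples} samples)"
            )

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def sweep_at(self, current_pA: float) -> np.ndarray:
        """Return the sweep recorded at ``current_pA`` (exact-ish match)."""
        amps = np.asarray(self.protocol.current_amplitudes_pA)
        idx = np.flatnonzero(np.isclose(amps, current_pA, atol=1e-6))
        if idx.size == 0:
            raise ValueError(f"no sweep at {current_pA} pA (have {list(amps)})")
        return self.sweeps[idx[0]]


# ----------------------------------------------------------------------
# closed-form oracles
# ----------------------------------------------------------------------

def lif_rheobase_pA(params: NeuronParams) -> float:
    """Minimum sustained current (pA) that drives the LIF membrane to threshold."""
    return (
        (params.spike_threshold_mV - params.resting_potential_mV)
        / params.membrane_resistance_MOhm
        * 1000.0
    )


def lif_spike_count(params: NeuronParams, current_pA: float, step_ms: float) -> int:
    """Closed-form spike count of a noiseless LIF during a step of ``step_ms``.

    First-spike latency from rest and the steady interspike interval follow
    from the exponential charging solution; the count is the number of spike
    times strictly inside the step window.
    """
    v_inf = params.resting_potential_mV + current_pA * params.membrane_resistance_MOhm / 1000.0
    if v_inf <= params.spike_threshold_mV:
        return 0
    tau = params.tau_ms
    t_first = tau * np.log(
        (v_inf - params.resting_potential_mV) / (v_inf - params.spike_threshold_mV)
    )
    if t_first >= step_ms:
        return 0
    isi = params.refractory_ms + tau * np.log(
        (v_inf - params.reset_potential_mV) / (v_inf - params.spike_threshold_mV)
    )
    return 1 + int(np.floor((step_ms - t_first) / isi - 1e-12))


# ----------------------------------------------------------------------
# forward-Euler integration kernel
# ----------------------------------------------------------------------

def _lif_euler(I_pA, n_base, n_step, n_total, dt, R, C, EL, Vth, Vres, ref_samples,
               V, spike_idx, spike_counts):  # pragma: no cover - thin kernel
    # Forward Euler per sample, with sub-sample interpolation of the threshold
    # crossing: the refractory clock starts at the interpolated crossing time,
    # so the per-spike discretization bias does not accumulate across a sweep.
    n_sweeps = I_pA.shape[0]
    for s in range(n_sweeps):
        v = EL
        V[s, 0] = EL
        resume = -1.0e30  # end of refractory, in fractional sample units
        k = 0
        for i in range(1, n_total):
            if i <= resume:
                v = Vres
                V[s, i] = v
                continue
            if n_base <= i - 1 < n_base + n_step:
                i_ext = I_pA[s]
            else:
                i_ext = 0.0
            if i - 1.0 < resume:
                # partial step out of refractory within this sample interval
                width = i - resume
                v_start = Vres
            else:
                width = 1.0
                v_start = v
            v = v_start + width * dt * (i_ext - (v_start - EL) * 1000.0 / R) / C
            if v >= Vth:
                if v > v_start:
                    t_cross = i - (v - Vth) / (v - v_start) * width
                else:
                    t_cross = float(i)
                V[s, i] = Vth
                spike_idx[s, k] = i
                k += 1
                v = Vres
                resume = t_cross + ref_samples
            else:
                V[s, i] = v
        spike_counts[s] = k


try:  # numba accelerates the sample loop ~100x; plain Python remains correct
    from numba import njit as _njit

    _lif_euler_jit = _njit(cache=True)(_lif_euler)
except ImportError:  # pragma: no cover
    _lif_euler_jit = _lif_euler


def spike_waveform(params: NeuronParams, dt_ms: float) -> np.ndarray:
    """Stereotyped action-potential waveform pasted after each threshold crossing.

    Linear rise from threshold to +30 mV over 0.4 ms, then linear decay to the
    reset potential over the remaining 1.6 ms.  The rise slope (200 mV/ms)
    comfortably exceeds the 20 V/s spike-detection criterion.
    """
    n_rise = max(int(round(AP_RISE_MS / dt_ms)), 1)
    n_fall = max(int(round((AP_TOTAL_MS - AP_RISE_MS) / dt_ms)), 1)
    rise = np.linspace(params.spike_threshold_mV, AP_PEAK_MV, n_rise + 1)[1:]
    fall = np.linspace(AP_PEAK_MV, params.reset_potential_mV, n_fall + 1)[1:]
    return np.concatenate([rise, fall])


def simulate_neuron(
    params: NeuronParams,
    protocol: StepProtocol,
    seed: Optional[int] = None,
    cell_id: str = "cell",
    animal_id: str = "",
) -> Recording:
    """Simulate one cell's full sweep family under ``protocol``.

    The membrane is integrated noiselessly with forward Euler at the protocol
    sampling rate; threshold crossings are recorded exactly and then rendered
    with :func:`spike_waveform`.  ``voltage_noise_sd_mV`` is applied afterwards
    as per-sample measurement noise on the recorded traces, so the attached
    ground truth (spike times, counts, analytic rheobase) is exact.
    """
    amps = np.asarray(protocol.current_amplitudes_pA, dtype=float)
    n_total = protocol.n_samples
    n_sweeps = amps.size
    n_ref_cap = int(round(params.refractory_ms / protocol.dt_ms))
    # one spike consumes at least (refractory + 1) samples; +2 slack
    cap = n_total // max(n_ref_cap + 1, 1) + 2
    V = np.empty((n_sweeps, n_total), dtype=float)
    spike_idx = np.full((n_sweeps, cap), -1, dtype=np.int64)
    spike_counts = np.zeros(n_sweeps, dtype=np.int64)
    ref_samples = params.refractory_ms / protocol.dt_ms
    _lif_euler_jit(
        amps, protocol.n_baseline, protocol.n_step, n_total, protocol.dt_ms,
        params.membrane_resistance_MOhm, params.membrane_capacitance_pF,
        params.resting_potential_mV, params.spike_threshold_mV,
        params.reset_potential_mV, ref_samples, V, spike_idx, spike_counts,
    )

    wave = spike_waveform(params, protocol.dt_ms)
    true_spike_samples: list[np.ndarray] = []
    step_counts = np.zeros(n_sweeps, dtype=int)
    lo, hi = protocol.n_baseline, protocol.n_baseline + protocol.n_step
    for s in range(n_sweeps):
        idx = spike_idx[s, : spike_counts[s]]
        true_spike_samples.append(idx.copy())
        step_counts[s] = int(np.count_nonzero((idx >= lo) & (idx < hi)))
        for i in idx:
            seg = V[s, i + 1 : i + 1 + wave.size]
            seg[:] = wave[: seg.size]

    if params.voltage_noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, params.voltage_noise_sd_mV, size=V.shape)

    ground_truth = {
        "params": {
            "membrane_resistance_MOhm": params.membrane_resistance_MOhm,
            "membrane_capacitance_pF": params.membrane_capacitance_pF,
            "resting_potential_mV": params.resting_potential_mV,
            "spike_threshold_mV": params.spike_threshold_mV,
            "reset_potential_mV": params.reset_potential_mV,
            "refractory_ms": params.refractory_ms,
            "voltage_noise_sd_mV": params.voltage_noise_sd_mV,
        },
        "tau_ms": params.tau_ms,
        "rheobase_pA": params.rheobase_pA,
        "spike_times_s": [
            (idx / protocol.sampling_rate_hz).tolist() for idx in true_spike_samples
        ],
        "spike_counts_step": step_counts.tolist(),
    }
    return Recording(
        sweeps=V,
        protocol=protocol,
        cell_id=cell_id,
        animal_id=animal_id,
        ground_truth=ground_truth,
    )
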