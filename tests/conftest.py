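"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from painephys.neuron import NeuronParams, StepProtocol


@pytest.fixture(scope="session")
def protocol() -> StepProtocol:
    """The default ten-step protocol (-300..+600 pA, 10 kHz)."""
    return StepProtocol()


@pytest.fixture(scope="session")
def quiet_cell() -> NeuronParams:
    """Noiseless reference neuron: R_m=100 MOhm, C_m=100 pF, rheobase 200 pA."""
    return NeuronParams(
        membrane_resistance_MOhm=100.0,
        membrane_capacitance_pF=100.0,
        resting_potential_mV=-70.0,
        spike_threshold_mV=-50.0,
        reset_potential_mV=-65.0,
        refractory_ms=2.0,
        voltage_noise_sd_mV=0.0,
    )


# ----------------------------------------------------------------------
# independent oracles (deliberately written as explicit per-sample loops /
# textbook formulas, separate from the package implementation)
# ----------------------------------------------------------------------

def brute_force_spike_times_s(
    v, dt_ms, v_cross=-20.0, dvdt_thr=20.0, lockout_ms=2.0
) -> list[float]:
    """Exhaustive per-sample scan of the spike criterion.

    A spike is an upward crossing of ``v_cross`` whose entering slope exceeds
    ``dvdt_thr`` (V/s); the reported time is the first sample of the
    contiguous fast-slope run; crossings within ``lockout_ms`` of the previous
    accepted spike are suppressed.
    """
    times_ms: list[float] = []
    last = -1e18
    for i in range(1, len(v)):
        if v[i] >= v_cross and v[i - 1] < v_cross:
            if (v[i] - v[i - 1]) / dt_ms > dvdt_thr:
                j = i
                while j > 1 and (v[j - 1] - v[j - 2]) / dt_ms > dvdt_thr:
                    j -= 1
                t = j * dt_ms
                if t - last >= lockout_ms:
                    times_ms.append(t)
                    last = t
    return [t / 1000.0 for t in times_ms]


def isi_oracle_count(
    R_m, C_m, E_L, V_th, V_reset, t_ref, current_pA, step_ms
) -> int:
    """Closed-form LIF spike count during a step: latency + steady ISI."""
    v_inf = E_L + current_pA * R_m / 1000.0
    if v_inf <= V_th:
        return 0
    tau = R_m * C_m / 1000.0
    t_first = tau * np.log((v_inf - E_L) / (v_inf - V_th))
    if t_first >= step_ms:
        return 0
    isi = t_ref + tau * np.log((v_inf - V_reset) / (v_inf - V_th))
    return 1 + int(np.floor((step_ms - t_first) / isi - 1e-12))


def pearson_oracle(x, y) -> float:
    """Textbook Pearson formula: sum((x-xb)(y-yb)) / sqrt(sum sq * sum sq)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xb, yb = x.mean(), y.mean()
    num = float(np.sum((x - xb) * (y - yb)))
    den = float(np.sqrt(np.sum((x - xb) ** 2) * np.sum((y - yb) ** 2)))
    return num / den
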