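"""Transient simulation of memristor-based spiking neuron circuits.

Two circuits are modeled:

* **LIF relaxation oscillator** — the threshold-switching memristor (in series
  with a small readout resistor ``r_read``) sits in parallel with a membrane
  capacitor ``c_mem``; the pair is driven through a series load resistor
  ``r_load``.  The capacitor integrates the input; once its voltage is high
  enough that the device terminal voltage reaches ``v_th``, the device
  collapses to LRS, the capacitor dumps its charge through the ON device
  (the output spike), and when the device voltage falls below ``v_hold``
  the filament breaks and integration restarts.

* **Adaptive LIF (ALIF)** — the same oscillator plus a spike-driven leakage
  feedback: each output spike charges an adaptation capacitor ``c2`` (raising
  a gate voltage ``v_g``), and a threshold-linear transconductance ``g_leak``
  drains membrane charging current once ``v_g`` exceeds the transistor turn-on
  voltage ``vt_m3``.  ``v_g`` relaxes through ``r3`` with time constant
  ``tau_a = r3 * c2``, which must be much longer than the membrane time
  constant for the adaptation to act as a slow variable.

Both are integrated with a fixed-step exponential-Euler scheme sharing one
numba kernel; the LIF is the ALIF with the feedback path disabled, which makes
the "feedback off implies plain LIF" reduction exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .memristor import MemristorParams, njit, _drive, _update_latch

__all__ = [
    "LIFCircuitParams",
    "ALIFCircuitParams",
    "CircuitTrace",
    "NoOscillationError",
    "simulate_lif",
    "simulate_alif",
    "lif_period_closed_form",
    "vg_frequency_curve",
    "isi_series",
    "spike_frequency",
    "write_trace_csv",
]


class NoOscillationError(ValueError):
    """Raised when circuit parameters do not admit self-oscillation."""


@dataclass(frozen=True)
class LIFCircuitParams:
    """LIF oscillator: series load ``r_load``, parallel ``c_mem``, readout ``r_read``."""

    r_load: float = 18.0e3
    c_mem: float = 1.0e-9
    r_read: float = 50.0
    memristor: MemristorParams = field(default_factory=MemristorParams)

    def __post_init__(self) -> None:
        if min(self.r_load, self.c_mem, self.r_read) <= 0.0:
            raise ValueError("resistances and capacitances must be > 0")


@dataclass(frozen=True)
class ALIFCircuitParams:
    """ALIF = LIF core plus adaptation store (c2, r3), charge pump i_adapt and
    threshold-linear leakage transistor (vt_m3, g_leak)."""

    lif: LIFCircuitParams = field(default_factory=LIFCircuitParams)
    r1: float = 500.0
    c2: float = 2.0e-8
    r3: float = 1.0e5
    i_adapt: float = 5.0e-4
    vt_m3: float = 0.7
    g_leak: float = 2.8e-4

    def __post_init__(self) -> None:
        if min(self.c2, self.r3) <= 0.0:
            raise ValueError("c2 and r3 must be > 0")
        if min(self.r1, self.i_adapt, self.g_leak) < 0.0:
            raise ValueError("r1, i_adapt and g_leak must be >= 0")
        tau_m = (self.lif.memristor.r_off + self.r1) * self.lif.c_mem
        if self.r3 * self.c2 < 10.0 * tau_m:
            raise ValueError("adaptation time constant r3*c2 must be >> "
                             "membrane time constant (r_off + r1)*c_mem")

    @property
    def tau_a(self) -> float:
        return self.r3 * self.c2


@dataclass
class CircuitTrace:
    """Uniformly sampled transient waveforms plus detected spike times."""

    time: np.ndarray
    v_m: np.ndarray
    v_spike: np.ndarray
    spike_times: np.ndarray
    v_g: np.ndarray | None = None
    dt: float = 0.0


@njit(cache=True)
def _transient_kernel(i_src, dt, c1, g_src, r1, r_read,
                      v_th, v_hold, r_on, r_off, steepness, k_dev,
                      c2, r3, i_adapt, vt_m3, g_leak,
                      vg0, vg_clamped, adapt_on):
    """Shared exponential-Euler core.

    i_src : input current waveform [A] (Norton form; g_src is the source
    conductance, 0 for an ideal current source).
    Returns (v_m, v_g, v_spike, lrs) traces.
    """
    n = i_src.shape[0]
    vm_tr = np.empty(n)
    vg_tr = np.empty(n)
    vsp_tr = np.empty(n)
    lrs_tr = np.zeros(n, dtype=np.uint8)
    v_m = 0.0
    v_g = vg0
    v_c = 0.0
    lrs = False
    k_a = math.exp(-dt / (r3 * c2))
    for i in range(n):
        g_dev = (1.0 - v_c) / r_off + v_c / r_on
        r_fire = 1.0 / g_dev + r1 + r_read
        i_leak = 0.0
        # The leak transistor drains charging current only while the membrane
        # is above ground (it cannot source current into the capacitor).
        if adapt_on and v_g > vt_m3 and v_m > 0.0:
            i_leak = g_leak * (v_g - vt_m3)
        g_tot = g_src + 1.0 / r_fire
        v_inf = (i_src[i] - i_leak) / g_tot
        v_m = v_inf + (v_m - v_inf) * math.exp(-dt * g_tot / c1)
        v_dev = v_m * (1.0 / g_dev) / r_fire
        mag = v_dev if v_dev >= 0.0 else -v_dev
        if not lrs:
            # subthreshold the device is a nominal HRS resistor: the residual
            # conductance from the comparator's soft tail must not blur the
            # firing condition (it would pin v_dev just below threshold at
            # slow charge rates)
            mag0 = v_m * r_off / (r_off + r1 + r_read)
            if mag0 < 0.0:
                mag0 = -mag0
            lrs = mag0 >= v_th
        else:
            lrs = mag > v_hold
        d = _drive(v_dev, 0.0, v_th, v_hold, steepness, lrs)
        v_c = d + (v_c - d) * k_dev
        if v_c > 1.0:
            v_c = 1.0
        elif v_c < 0.0:
            v_c = 0.0
        spiking = v_c >= 0.5
        if adapt_on and not vg_clamped:
            target = r3 * i_adapt if spiking else 0.0
            v_g = target + (v_g - target) * k_a
        vm_tr[i] = v_m
        vg_tr[i] = v_g
        vsp_tr[i] = v_m * r_read / r_fire
        lrs_tr[i] = 1 if spiking else 0
    return vm_tr, vg_tr, vsp_tr, lrs_tr


def _detect_spikes(v_spike: np.ndarray, dt: float, params) -> np.ndarray:
    """Spike times from the readout waveform: rising-edge crossings of half the
    peak, floored at half the minimum plausible spike amplitude so a spikeless
    smooth trace yields no events."""
    mem = params.lif.memristor if isinstance(params, ALIFCircuitParams) else params.memristor
    r_read = params.lif.r_read if isinstance(params, ALIFCircuitParams) else params.r_read
    # During LRS, v_spike = v_m * r_read / r_fire and the device voltage stays
    # >= v_hold until the filament breaks, so any true spike reaches at least
    # v_hold * r_read / r_on.
    floor = 0.5 * mem.v_hold * r_read / mem.r_on
    level = max(0.5 * float(np.max(v_spike, initial=0.0)), floor)
    above = v_spike >= level
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return edges * dt


def _default_dt(tau_c: float, mem: MemristorParams) -> float:
    return min(mem.tau_switch, tau_c) / 50.0


def simulate_lif(params: LIFCircuitParams, v_in, dt: float | None = None,
                 duration: float | None = None) -> CircuitTrace:
    """Transient simulation of the LIF relaxation oscillator.

    ``v_in`` is the applied voltage waveform (scalar for a DC drive).  When
    the Thevenin steady-state capacitor voltage exceeds the effective
    threshold, the circuit self-oscillates, emitting one spike per
    charge/discharge cycle.
    """
    mem = params.memristor
    tau_c = params.c_mem * _parallel(params.r_load, mem.r_off + params.r_read)
    if dt is None:
        dt = _default_dt(tau_c, mem)
    _check_dt(dt, tau_c, mem)
    if duration is None:
        try:
            period = lif_period_closed_form(params, float(np.max(np.atleast_1d(v_in))))
            duration = 12.0 * period
        except NoOscillationError:
            duration = 20.0 * tau_c
    n = max(2, int(round(duration / dt)))
    v = np.broadcast_to(np.asarray(v_in, dtype=np.float64), (n,)) \
        if np.ndim(v_in) == 0 else np.asarray(v_in, dtype=np.float64)[:n]
    if v.shape[0] < n:
        raise ValueError("v_in waveform shorter than duration/dt samples")
    i_src = np.ascontiguousarray(v / params.r_load)
    k_dev = math.exp(-dt / mem.tau_switch)
    vm, vg, vsp, _ = _transient_kernel(
        i_src, dt, params.c_mem, 1.0 / params.r_load, 0.0, params.r_read,
        mem.v_th, mem.v_hold, mem.r_on, mem.r_off, mem.steepness, k_dev,
        1.0, 1.0, 0.0, 0.0, 0.0, 0.0, True, False)
    t = np.arange(n) * dt
    return CircuitTrace(time=t, v_m=vm, v_spike=vsp,
                        spike_times=_detect_spikes(vsp, dt, params), dt=dt)


def simulate_alif(params: ALIFCircuitParams, i_in, dt: float | None = None,
                  duration: float | None = None, clamp_vg: float | None = None,
                  source_resistance: float | None = None) -> CircuitTrace:
    """Transient simulation of the adaptive LIF neuron driven by a current.

    ``i_in`` is the input current waveform [A] (scalar for a step drive from
    an ideal current source; pass ``source_resistance`` for a Norton source).
    ``clamp_vg`` pins the adaptation gate voltage to a fixed value, disabling
    its dynamics (used for the v_g-frequency characteristic).
    """
    lif = params.lif
    mem = lif.memristor
    tau_c = lif.c_mem * (mem.r_off + params.r1 + lif.r_read)
    if dt is None:
        dt = _default_dt(tau_c, mem)
    _check_dt(dt, tau_c, mem)
    if duration is None:
        duration = 5.0 * params.tau_a
    n = max(2, int(round(duration / dt)))
    i = np.broadcast_to(np.asarray(i_in, dtype=np.float64), (n,)) \
        if np.ndim(i_in) == 0 else np.asarray(i_in, dtype=np.float64)[:n]
    if i.shape[0] < n:
        raise ValueError("i_in waveform shorter than duration/dt samples")
    g_src = 0.0 if source_resistance is None else 1.0 / source_resistance
    k_dev = math.exp(-dt / mem.tau_switch)
    vg0 = 0.0 if clamp_vg is None else float(clamp_vg)
    vm, vg, vsp, _ = _transient_kernel(
        np.ascontiguousarray(i), dt, lif.c_mem, g_src, params.r1, lif.r_read,
        mem.v_th, mem.v_hold, mem.r_on, mem.r_off, mem.steepness, k_dev,
        params.c2, params.r3, params.i_adapt, params.vt_m3, params.g_leak,
        vg0, clamp_vg is not None, True)
    t = np.arange(n) * dt
    return CircuitTrace(time=t, v_m=vm, v_spike=vsp, v_g=vg,
                        spike_times=_detect_spikes(vsp, dt, params), dt=dt)


def _parallel(a: float, b: float) -> float:
    return a * b / (a + b)


def _check_dt(dt: float, tau_c: float, mem: MemristorParams) -> None:
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    if dt > mem.tau_switch or dt > tau_c / 10.0:
        raise ValueError(
            f"dt={dt:g}s does not resolve the circuit time constants "
            f"(device r0*c0={mem.tau_switch:g}s, charging tau={tau_c:g}s)")


def lif_period_closed_form(params: LIFCircuitParams, v_in: float) -> float:
    """Oscillation period from piecewise RC analysis (test oracle for
    :func:`simulate_lif`).

    Charging phase (device OFF): the capacitor relaxes towards the Thevenin
    steady state ``V_inf`` with ``tau_c = c_mem * (r_load || (r_off+r_read))``
    from the effective holding voltage up to the effective threshold; the
    discharge phase is the analogous LRS expression.  Raises
    :class:`NoOscillationError` if the steady state cannot reach threshold or
    the ON-state steady state does not fall below holding.
    """
    mem = params.memristor
    r_off_s = mem.r_off + params.r_read
    r_on_s = mem.r_on + params.r_read
    v_th_eff = mem.v_th * r_off_s / mem.r_off
    v_hold_eff = mem.v_hold * r_on_s / mem.r_on
    v_inf_off = v_in * r_off_s / (params.r_load + r_off_s)
    v_inf_on = v_in * r_on_s / (params.r_load + r_on_s)
    if v_inf_off <= v_th_eff:
        raise NoOscillationError(
            f"steady-state capacitor voltage {v_inf_off:.3g} V does not exceed "
            f"effective threshold {v_th_eff:.3g} V: no oscillation")
    if v_inf_on >= v_hold_eff:
        raise NoOscillationError(
            "ON-state steady state does not fall below the holding condition: "
            "device latches instead of oscillating")
    tau_c = params.c_mem * _parallel(params.r_load, r_off_s)
    tau_d = params.c_mem * _parallel(params.r_load, r_on_s)
    t_charge = tau_c * math.log((v_inf_off - v_hold_eff) / (v_inf_off - v_th_eff))
    t_disch = tau_d * math.log((v_th_eff - v_inf_on) / (v_hold_eff - v_inf_on))
    return t_charge + t_disch


def vg_frequency_curve(params: ALIFCircuitParams, v_g_grid, i_in: float,
                       dt: float | None = None, duration: float | None = None):
    """Spiking frequency versus externally clamped gate voltage.

    Below the transistor turn-on voltage the leakage path is off and the
    frequency is independent of ``v_g``; above it the frequency decreases
    monotonically until a finite cutoff beyond which the membrane can no
    longer reach threshold and the neuron is silent (frequency 0).
    """
    grid = np.asarray(v_g_grid, dtype=np.float64)
    if duration is None:
        # Long enough for >= ~8 spikes in the unadapted regime.
        lif_eq = params.lif
        mem = lif_eq.memristor
        tau_m = lif_eq.c_mem * (mem.r_off + params.r1 + lif_eq.r_read)
        duration = 30.0 * tau_m
    freqs = np.empty_like(grid)
    for k, vg in enumerate(grid):
        tr = simulate_alif(params, i_in, dt=dt, duration=duration, clamp_vg=vg)
        st = tr.spike_times
        if st.size < 2:
            freqs[k] = 0.0
        else:
            freqs[k] = spike_frequency(st)
    return list(zip(grid.tolist(), freqs.tolist()))


def isi_series(spike_times) -> np.ndarray:
    """Consecutive inter-spike intervals [s]; needs at least two spikes."""
    st = np.asarray(spike_times, dtype=np.float64)
    if st.size < 2:
        raise ValueError("need at least 2 spikes for an ISI series")
    return np.diff(st)


def spike_frequency(spike_times, window=None) -> float:
    """Reciprocal of the mean inter-spike interval [Hz], optionally restricted
    to spikes within a (t_start, t_stop) window."""
    st = np.asarray(spike_times, dtype=np.float64)
    if window is not None:
        t0, t1 = window
        st = st[(st >= t0) & (st <= t1)]
    return 1.0 / float(np.mean(isi_series(st)))


def write_trace_csv(trace: CircuitTrace, path) -> None:
    """Write the trace as CSV (time, v_m[, v_g], v_spike)."""
    cols = ["time_s", "v_m_V"]
    arrs = [trace.time, trace.v_m]
    if trace.v_g is not None:
        cols.append("v_g_V")
        arrs.append(trace.v_g)
    cols.append("v_spike_V")
    arrs.append(trace.v_spike)
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in zip(*arrs):
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")
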