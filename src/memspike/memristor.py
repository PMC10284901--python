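"""Behavioral model of a volatile, polarity-symmetric threshold-switching memristor.

The device (a VO2-class metal-insulator-transition threshold switch) sits in a
high-resistance state (HRS) until the magnitude of the voltage across it
exceeds a switching threshold ``v_th``; it then collapses to a low-resistance
state (LRS) and stays there until the voltage magnitude falls below a holding
voltage ``v_hold``, at which point it relaxes back to HRS.  There is no
retention: the switching is volatile, and positive and negative polarities
behave identically.

The model is the classic behavioral-SPICE construction: a smooth ``tanh``
comparator decides, based on the present binary state, whether the device
"wants" to be ON (compare |V| against ``v_th`` in HRS, against ``v_hold`` in
LRS); the comparator output is low-pass filtered through an internal RC
(``r0 * c0``) that gives the device its finite switching time; and the
filtered state variable ``v_c`` in [0, 1] mixes the ON/OFF conductances:

    1 / R  =  (1 - v_c) / r_off  +  v_c / r_on

``v_c = 0`` is a fully OFF device (HRS, resistance ``r_off``); ``v_c = 1`` is
fully ON (LRS, ``r_on``).  The binary state used to select the comparator
branch is read from ``v_c`` with a fixed cut at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

__all__ = [
    "MemristorParams",
    "MemristorState",
    "IVTrace",
    "comparator_drive",
    "step",
    "resistance",
    "quasi_static_sweep",
    "sweep_switching_points",
    "write_iv_csv",
]


@dataclass(frozen=True)
class MemristorParams:
    """Device parameters of the volatile threshold switch.

    Parameters
    ----------
    v_th : float
        Switching threshold [V]; |V| >= v_th flips HRS -> LRS.
    v_hold : float
        Holding voltage [V]; |V| <= v_hold lets LRS relax back to HRS.
    r_on, r_off : float
        ON (LRS) and OFF (HRS) resistances [Ohm].
    steepness : float
        Comparator steepness [1/V].  Large values make the tanh comparator
        effectively a step at circuit scale.
    r0, c0 : float
        Internal RC limiting the switching speed; ``r0 * c0`` is the
        switching time constant [s].
    """

    v_th: float = 3.4
    v_hold: float = 1.45
    r_on: float = 1.0e3
    r_off: float = 1.0e5
    steepness: float = 1.0e4
    r0: float = 1.0e3
    c0: float = 5.0e-11

    def __post_init__(self) -> None:
        if not (0.0 < self.v_hold < self.v_th):
            raise ValueError("require 0 < v_hold < v_th")
        if not (0.0 < self.r_on < self.r_off):
            raise ValueError("require 0 < r_on < r_off")
        if self.steepness <= 0.0:
            raise ValueError("steepness must be > 0")
        if self.r0 * self.c0 <= 0.0:
            raise ValueError("r0 * c0 must be > 0")

    @property
    def tau_switch(self) -> float:
        """Switching time constant r0 * c0 [s]."""
        return self.r0 * self.c0


@dataclass(frozen=True)
class MemristorState:
    """Dynamic state of the device.

    ``v_c`` in [0, 1] is the RC-filtered comparator output that interpolates
    the resistance.  ``lrs`` is the comparator latch selecting the comparison
    branch: it flips ON the instant the terminal voltage magnitude reaches
    ``v_th`` and OFF the instant it falls to ``v_hold``.  Latching on the
    *unfiltered* comparator output is what lets the device switch fully even
    when a series load pulls its terminal voltage down as it turns on (the
    negative-differential-resistance operating point of relaxation
    oscillators); the RC on ``v_c`` then only sets the finite switching time
    of the resistance.
    """

    v_c: float = 0.0
    lrs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.v_c <= 1.0):
            raise ValueError("v_c must lie in [0, 1]")

    @property
    def binary_state(self) -> str:
        return "LRS" if self.lrs else "HRS"


@njit(cache=True)
def _drive(v_top: float, v_bot: float, v_th: float, v_hold: float,
           steepness: float, lrs: bool) -> float:
    # Polarity fold: compare the magnitude of the terminal voltage against the
    # threshold selected by the present binary state.
    mag = v_top - v_bot
    if mag < 0.0:
        mag = -mag
    ref = v_hold if lrs else v_th
    return 0.5 * (1.0 + math.tanh(2.0 * steepness * (mag - ref)))


def comparator_drive(params: MemristorParams, v_top: float, v_bot: float,
                     state: MemristorState) -> float:
    """Smooth comparator output in [0, 1] driving the state variable.

    > 0.5 pushes the device towards LRS, < 0.5 towards HRS.  In HRS the
    magnitude |v_top - v_bot| is compared against ``v_th``; in LRS against
    ``v_hold``; both polarities are treated symmetrically.
    """
    return float(_drive(float(v_top), float(v_bot), params.v_th,
                        params.v_hold, params.steepness, state.lrs))


@njit(cache=True)
def _update_latch(mag: float, v_th: float, v_hold: float, lrs: bool) -> bool:
    if lrs:
        return mag > v_hold
    return mag >= v_th


def step(params: MemristorParams, state: MemristorState, v_top: float,
         v_bot: float, dt: float) -> MemristorState:
    """Advance the device state by ``dt`` under a fixed terminal voltage.

    The comparator latch responds instantaneously to the terminal voltage
    (flip ON at |V| >= v_th, OFF at |V| <= v_hold); the filtered state
    ``v_c`` then relaxes towards the comparator output with time constant
    ``r0 * c0`` (exponential-Euler update: exact for piecewise-constant
    drive, unconditionally stable).  ``dt`` should be small compared to
    ``r0 * c0`` for the transient to be resolved.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    mag = abs(float(v_top) - float(v_bot))
    lrs = bool(_update_latch(mag, params.v_th, params.v_hold, state.lrs))
    d = comparator_drive(params, v_top, v_bot, MemristorState(v_c=state.v_c, lrs=lrs))
    k = math.exp(-dt / params.tau_switch)
    v_c = d + (state.v_c - d) * k
    # Guard against rounding drift out of [0, 1].
    v_c = min(1.0, max(0.0, v_c))
    return MemristorState(v_c=v_c, lrs=lrs)


def resistance(params: MemristorParams, state: MemristorState) -> float:
    """Device resistance [Ohm]: conductances of the ON/OFF branches mix linearly in v_c."""
    g = (1.0 - state.v_c) / params.r_off + state.v_c / params.r_on
    return 1.0 / g


@njit(cache=True)
def _sweep_kernel(vs, dt, v_th, v_hold, r_on, r_off, steepness, tau):
    n = vs.shape[0]
    cur = np.empty(n)
    vc_tr = np.empty(n)
    lrs_tr = np.zeros(n, dtype=np.uint8)
    v_c = 0.0
    lrs = False
    k = math.exp(-dt / tau)
    for i in range(n):
        mag = vs[i] if vs[i] >= 0.0 else -vs[i]
        lrs = _update_latch(mag, v_th, v_hold, lrs)
        d = _drive(vs[i], 0.0, v_th, v_hold, steepness, lrs)
        v_c = d + (v_c - d) * k
        if v_c > 1.0:
            v_c = 1.0
        elif v_c < 0.0:
            v_c = 0.0
        g = (1.0 - v_c) / r_off + v_c / r_on
        cur[i] = vs[i] * g
        vc_tr[i] = v_c
        lrs_tr[i] = 1 if lrs else 0
    return cur, vc_tr, lrs_tr


@dataclass
class IVTrace:
    """Current-voltage trace from a quasi-static sweep."""

    voltage: np.ndarray
    current: np.ndarray
    v_c: np.ndarray = field(repr=False, default=None)
    lrs: np.ndarray = field(repr=False, default=None)

    def __iter__(self):
        return iter(zip(self.voltage, self.current))


def quasi_static_sweep(params: MemristorParams, v_sequence, dt: float) -> IVTrace:
    """Simulate the device I-V response to a (slow) applied-voltage sequence.

    For a triangular sweep peaking above ``v_th`` the trace is the familiar
    hysteretic loop: the current jumps when |V| first exceeds ~``v_th`` on the
    up-sweep and collapses when |V| falls below ~``v_hold`` on the way down.
    The sweep should be slow relative to ``r0 * c0`` for the switching points
    to be sharp.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    vs = np.ascontiguousarray(np.asarray(v_sequence, dtype=np.float64))
    if vs.ndim != 1 or vs.size == 0:
        raise ValueError("v_sequence must be a non-empty 1-D array")
    cur, vc, lrs = _sweep_kernel(vs, float(dt), params.v_th, params.v_hold,
                                 params.r_on, params.r_off, params.steepness,
                                 params.tau_switch)
    return IVTrace(voltage=vs, current=cur, v_c=vc, lrs=lrs)


def sweep_switching_points(trace: IVTrace, from_resistance: bool = True):
    """Extract (switch-up |V|, switch-down |V|) from a sweep trace.

    Switch-up is the applied |V| at the first HRS->LRS transition of the
    (filtered) resistance state; switch-down the |V| at the first subsequent
    LRS->HRS transition.  Returns ``(None, None)`` if the device never
    switched.  With ``from_resistance=False`` the instantaneous comparator
    latch is used instead of the filtered state.
    """
    on = (trace.v_c >= 0.5) if from_resistance else (trace.lrs > 0)
    edges_up = np.flatnonzero(~on[:-1] & on[1:]) + 1
    if edges_up.size == 0:
        return None, None
    i_up = edges_up[0]
    edges_dn = np.flatnonzero(on[:-1] & ~on[1:]) + 1
    edges_dn = edges_dn[edges_dn > i_up]
    v_up = abs(float(trace.voltage[i_up]))
    v_dn = abs(float(trace.voltage[edges_dn[0]])) if edges_dn.size else None
    return v_up, v_dn


def write_iv_csv(trace: IVTrace, path) -> None:
    """Write a two-column CSV (volts, amps)."""
    with open(path, "w") as fh:
        fh.write("voltage_V,current_A\n")
        for v, i in zip(trace.voltage, trace.current):
            fh.write(f"{v:.17g},{i:.17g}\n")
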