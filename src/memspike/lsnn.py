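"""Recurrent spiking network (LSNN) with mixed LIF/ALIF units and
surrogate-gradient backpropagation-through-time.

The hidden layer mixes plain leaky integrate-and-fire units with adaptive
units whose firing history raises a slow gate voltage ``v_g`` that drains
membrane charging current (spike-frequency adaptation); the slow adaptation
variable is what gives the network its long short-term memory.  Discretized
dynamics per timestep ``dt``::

    LIF:   v_m <- a*v_m + (1-a) * r_eff * x,            a = exp(-dt/(r_eff*c1))
    ALIF:  v_m <- a*v_m + (1-a) * r_eff * (x - i_leak), i_leak = g_leak*max(0, v_g - vt_m3)
           v_g <- b*v_g + (1-b) * r3 * i_a * z,         b = exp(-dt/(r3*c2))

with a hard threshold (spike ``z=1`` and reset to ``v_hold_eff`` when
``v_m >= v_th_eff``).  Input and recurrent connections carry per-connection
integer synaptic delays; hidden spikes pass a first-order low-pass trace
before the linear readout, and the class decision is the argmax of the
last-timestep logits.  Training minimizes last-timestep cross-entropy plus a
firing-rate regularizer pulling each unit's average rate towards a target,
using the triangular surrogate derivative ``max(0, gamma*(1-|x|))`` of the
spike step (``x`` = membrane distance to threshold, normalized by the
threshold).

All forward/backward arithmetic is plain NumPy; gradients are validated in
the test-suite against central finite differences on a continuous-activation
twin of the network (``mode="soft"``), whose activation integrates exactly to
the surrogate derivative.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "NeuronConstants",
    "LSNNConfig",
    "LSNN",
    "TrainHistory",
    "lif_step",
    "alif_step",
    "surrogate",
    "soft_spike",
    "total_loss",
    "train",
    "classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NeuronConstants:
    """Neuron constants derived from the circuit values.

    ``r_eff`` is the device HRS resistance in series with the readout
    resistor; ``v_th_eff``/``v_hold_eff`` the effective switching/holding
    voltages seen by the membrane.  The membrane decay ``decay_alpha`` and
    adaptation decay ``adapt_beta`` follow from the two RC products; the
    adaptation time constant must exceed the membrane time constant.
    """

    dt: float = 1.0e-3
    r_eff: float = 100_050.0
    c1: float = 2.0e-7
    v_th_eff: float = 3.4017
    v_hold_eff: float = 1.5225
    r3: float = 6.0e6
    c2: float = 1.0e-7
    i_a: float = 6.0e-5
    vt_m3: float = 0.7
    g_leak: float = 1.0e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.decay_alpha < 1.0):
            raise ValueError("decay_alpha must lie in (0, 1)")
        if not (0.0 < self.adapt_beta < 1.0):
            raise ValueError("adapt_beta must lie in (0, 1)")
        if self.adapt_beta <= self.decay_alpha:
            raise ValueError("adaptation must be slower than the membrane "
                             "(adapt_beta > decay_alpha)")
        if not (0.0 < self.v_hold_eff < self.v_th_eff):
            raise ValueError("require 0 < v_hold_eff < v_th_eff")

    @property
    def tau_m(self) -> float:
        return self.r_eff * self.c1

    @property
    def tau_a(self) -> float:
        return self.r3 * self.c2

    @property
    def decay_alpha(self) -> float:
        """Membrane decay per step, exp(-dt / (r_eff * c1))."""
        return math.exp(-self.dt / self.tau_m)

    @property
    def adapt_beta(self) -> float:
        """Adaptation decay per step, exp(-dt / (r3 * c2))."""
        return math.exp(-self.dt / self.tau_a)


@dataclass(frozen=True)
class LSNNConfig:
    """Network architecture and training constants.

    The first ``n_alif`` hidden units are adaptive; the rest are plain LIF.
    ``current_unit`` converts the dimensionless learned weights into membrane
    input current; by default one unit is the current whose fixed point sits
    exactly at threshold, so O(1) weights produce O(threshold) drive.
    """

    n_in: int = 3
    n_hidden: int = 100
    n_alif: int = 40
    n_out: int = 4
    constants: NeuronConstants = field(default_factory=NeuronConstants)
    max_delay: int = 5
    lowpass_tau: float = 20.0
    surrogate_gamma: float = 0.3
    reg_lambda: float = 1.0e-4
    target_rate: float = 10.0
    cue_steps: int = 200
    seed: int = 0
    current_unit: float | None = None
    # input spikes are sparse binary events, so input weights start larger
    # than the 1/sqrt(fan-in) recurrent scale to land units inside the
    # surrogate's support at initialization
    input_gain: float = 8.0
    # the CUE channel prompts the readout: its input weights start excitatory
    # so the hidden layer is tonically active during the output period (set
    # to None to disable; the CUE row is the last input channel by layout)
    cue_channel: int | None = -1

    def __post_init__(self) -> None:
        if not (0 <= self.n_alif <= self.n_hidden):
            raise ValueError("require 0 <= n_alif <= n_hidden")
        if self.max_delay < 0:
            raise ValueError("max_delay must be >= 0")
        if self.surrogate_gamma <= 0.0:
            raise ValueError("surrogate_gamma must be > 0")
        if self.lowpass_tau <= 0.0:
            raise ValueError("lowpass_tau must be > 0")

    @property
    def i_unit(self) -> float:
        c = self.constants
        return self.current_unit if self.current_unit is not None \
            else c.v_th_eff / c.r_eff

    @property
    def lowpass_kappa(self) -> float:
        return math.exp(-1.0 / self.lowpass_tau)


def surrogate(x_normalized, gamma: float = 0.3):
    """Triangular surrogate derivative ``max(0, gamma * (1 - |x|))``."""
    x = np.asarray(x_normalized, dtype=np.float64)
    return np.maximum(0.0, gamma * (1.0 - np.abs(x)))


def soft_spike(x_normalized, gamma: float = 0.3):
    """Continuous activation whose derivative is exactly :func:`surrogate`;
    used only to validate the BPTT gradients by finite differences."""
    x = np.asarray(x_normalized, dtype=np.float64)
    xc = np.clip(x, -1.0, 1.0)
    return np.where(xc <= 0.0,
                    gamma * (xc + 1.0) ** 2 / 2.0,
                    gamma * (0.5 + xc - xc ** 2 / 2.0))


def lif_step(v_m, constants: NeuronConstants, x):
    """One discretized LIF update: returns (new v_m, spike indicator)."""
    a = constants.decay_alpha
    v = a * np.asarray(v_m, dtype=np.float64) + (1.0 - a) * constants.r_eff * np.asarray(x, dtype=np.float64)
    z = (v >= constants.v_th_eff).astype(np.float64)
    v = np.where(z > 0, constants.v_hold_eff, v)
    return v, z


def alif_step(v_m, v_g, constants: NeuronConstants, x):
    """One discretized ALIF update: returns (new v_m, new v_g, spike)."""
    a = constants.decay_alpha
    b = constants.adapt_beta
    vg = np.asarray(v_g, dtype=np.float64)
    i_leak = constants.g_leak * np.maximum(0.0, vg - constants.vt_m3)
    v = a * np.asarray(v_m, dtype=np.float64) \
        + (1.0 - a) * constants.r_eff * (np.asarray(x, dtype=np.float64) - i_leak)
    z = (v >= constants.v_th_eff).astype(np.float64)
    v = np.where(z > 0, constants.v_hold_eff, v)
    vg = b * vg + (1.0 - b) * constants.r3 * constants.i_a * z
    return v, vg, z


@dataclass
class ForwardResult:
    """Outputs (and backward cache) of one forward pass."""

    logits: np.ndarray      # [B, T, n_out]
    z: np.ndarray           # [B, T, N] hidden spike raster
    v_g: np.ndarray         # [B, T, N] adaptation gate voltage entering each step
    v_pre: np.ndarray = field(repr=False, default=None)   # pre-reset membrane
    psi: np.ndarray = field(repr=False, default=None)     # dz/dv_pre
    f_last: np.ndarray = field(repr=False, default=None)  # low-pass trace at T-1
    x: np.ndarray = field(repr=False, default=None)


@dataclass
class TrainHistory:
    """Per-epoch loss and test accuracy, final weight digest and seed record."""

    losses: list
    test_accuracy: list
    weights_digest: str
    seed: int
    epochs: int


def _softmax(y: np.ndarray) -> np.ndarray:
    e = np.exp(y - np.max(y, axis=-1, keepdims=True))
    return e / np.sum(e, axis=-1, keepdims=True)


class LSNN:
    """Recurrent spiking network with per-connection synaptic delays.

    Weights are Gaussian-initialized with 1/sqrt(fan-in) scale; recurrent
    self-connections are zeroed; delays are drawn uniformly from
    {0..max_delay} on the input and recurrent connections (the readout is
    undelayed so the decision timestep is not shifted).
    """

    def __init__(self, config: LSNNConfig):
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        self.w_in = rng.normal(0.0, c.input_gain / math.sqrt(c.n_in), (c.n_in, c.n_hidden))
        if c.cue_channel is not None:
            self.w_in[c.cue_channel] = np.abs(self.w_in[c.cue_channel])
        self.w_rec = rng.normal(0.0, 1.0 / math.sqrt(c.n_hidden), (c.n_hidden, c.n_hidden))
        np.fill_diagonal(self.w_rec, 0.0)
        self.w_out = rng.normal(0.0, 1.0 / math.sqrt(c.n_hidden), (c.n_hidden, c.n_out))
        self.d_in = rng.integers(0, c.max_delay + 1, (c.n_in, c.n_hidden))
        self.d_rec = rng.integers(0, c.max_delay + 1, (c.n_hidden, c.n_hidden))
        # per-unit constants: first n_alif units adaptive
        alif = np.zeros(c.n_hidden)
        alif[:c.n_alif] = 1.0
        self.alif_mask = alif
        k = c.constants
        self.i_a_vec = alif * k.i_a
        self.g_leak_vec = alif * k.g_leak

    # -- plumbing -----------------------------------------------------------

    def _delay_masks(self, delays: np.ndarray):
        return [(delays == d) for d in range(self.config.max_delay + 1)]

    def _masked(self, w: np.ndarray, delays: np.ndarray):
        return [w * m for m in self._delay_masks(delays)]

    @property
    def weights(self):
        return {"w_in": self.w_in, "w_rec": self.w_rec, "w_out": self.w_out}

    def weights_digest(self) -> str:
        h = hashlib.sha256()
        for w in (self.w_in, self.w_rec, self.w_out):
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()

    # -- forward ------------------------------------------------------------

    def forward(self, input_spikes: np.ndarray, mode: str = "hard",
                cache: bool = False) -> ForwardResult:
        """Run the network over a batch of spike arrays [B, T, n_in] (a single
        [T, n_in] array is promoted to a batch of one).

        Per timestep: delayed weighted input plus delayed weighted
        previous-step hidden spikes drive the LIF/ALIF updates; hidden spikes
        feed a first-order low-pass trace; logits are the linear readout of
        that trace.  ``mode="soft"`` replaces the hard spike with the
        continuous :func:`soft_spike` activation (gradient validation only).
        """
        X = np.asarray(input_spikes, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.config.n_in:
            raise ValueError(f"input spikes must be [B, T, {self.config.n_in}]")
        c = self.config
        k = c.constants
        B, T, _ = X.shape
        N = c.n_hidden
        a = k.decay_alpha
        b = k.adapt_beta
        kap = c.lowpass_kappa
        gamma = c.surrogate_gamma
        vth = k.v_th_eff

        win_d = self._masked(self.w_in, self.d_in)
        wrec_d = self._masked(self.w_rec, self.d_rec)

        # input drive precomputed over all timesteps
        drive = np.zeros((B, T, N))
        for d, wd in enumerate(win_d):
            if d < T:
                drive[:, d:, :] += X[:, :T - d, :] @ wd

        Z = np.zeros((B, T, N))
        VG = np.zeros((B, T, N))
        VPRE = np.zeros((B, T, N))
        PSI = np.zeros((B, T, N))
        F = np.zeros((B, T, N))

        v_post = np.zeros((B, N))
        v_g = np.zeros((B, N))
        f = np.zeros((B, N))
        for t in range(T):
            at = drive[:, t, :].copy()
            for d, wd in enumerate(wrec_d):
                s = t - 1 - d
                if s >= 0:
                    at += Z[:, s, :] @ wd
            i_leak = self.g_leak_vec * np.maximum(0.0, v_g - k.vt_m3)
            v_pre = a * v_post + (1.0 - a) * k.r_eff * (c.i_unit * at - i_leak)
            xn = (v_pre - vth) / vth
            psi = surrogate(xn, gamma) / vth
            if mode == "hard":
                z = (v_pre >= vth).astype(np.float64)
            elif mode == "soft":
                z = soft_spike(xn, gamma)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            v_post = v_pre + z * (k.v_hold_eff - v_pre)
            VG[:, t, :] = v_g
            v_g = b * v_g + (1.0 - b) * k.r3 * self.i_a_vec * z
            f = kap * f + z
            Z[:, t, :] = z
            VPRE[:, t, :] = v_pre
            PSI[:, t, :] = psi
            F[:, t, :] = f

        logits = F @ self.w_out
        res = ForwardResult(logits=logits, z=Z, v_g=VG)
        if cache:
            res.v_pre = VPRE
            res.psi = PSI
            res.f_last = F[:, -1, :]
            res.x = X
        else:
            res.f_last = F[:, -1, :]
        return res

    # -- loss and backward --------------------------------------------------

    def loss(self, fwd: ForwardResult, targets: np.ndarray):
        return total_loss(fwd.logits[:, -1, :], targets, fwd.z, self.config)

    def backward(self, fwd: ForwardResult, targets: np.ndarray):
        """Gradients of the total loss w.r.t. w_in, w_rec, w_out by
        backpropagation-through-time with the surrogate spike derivative."""
        if fwd.v_pre is None:
            raise ValueError("forward must be run with cache=True")
        c = self.config
        k = c.constants
        B, T, N = fwd.z.shape
        a = k.decay_alpha
        b = k.adapt_beta
        kap = c.lowpass_kappa
        onehot = _one_hot(targets, c.n_out)

        p = _softmax(fwd.logits[:, -1, :])
        dy = (p - onehot) / B
        g_w_out = fwd.f_last.T @ dy
        g_f = dy @ self.w_out.T

        # firing-rate regularizer: fbar_n = sum z / (dt * B * T)
        fbar = fwd.z.sum(axis=(0, 1)) / (k.dt * B * T)
        reg_dz = (2.0 * c.reg_lambda / N) * (fbar - c.target_rate) / (k.dt * B * T)

        wrec_d = self._masked(self.w_rec, self.d_rec)
        nd = c.max_delay + 1
        gin_d = [np.zeros_like(self.w_in) for _ in range(nd)]
        grec_d = [np.zeros_like(self.w_rec) for _ in range(nd)]

        lam_vpost = np.zeros((B, N))
        lam_vg = np.zeros((B, N))      # adjoint of v_g[t+1]
        dz_buf = np.zeros((B, T, N))
        vg_gain = (1.0 - b) * k.r3 * self.i_a_vec
        X = fwd.x
        Z = fwd.z
        for t in range(T - 1, -1, -1):
            dz = g_f + reg_dz + dz_buf[:, t, :] \
                + lam_vpost * (k.v_hold_eff - fwd.v_pre[:, t, :]) \
                + lam_vg * vg_gain
            dv = lam_vpost * (1.0 - Z[:, t, :]) + dz * fwd.psi[:, t, :]
            d_ileak = -(1.0 - a) * k.r_eff * dv
            lam_vg = b * lam_vg + d_ileak * self.g_leak_vec * (fwd.v_g[:, t, :] > k.vt_m3)
            lam_vpost = a * dv
            da = (1.0 - a) * k.r_eff * c.i_unit * dv
            for d in range(nd):
                if t - d >= 0:
                    gin_d[d] += X[:, t - d, :].T @ da
                s = t - 1 - d
                if s >= 0:
                    grec_d[d] += Z[:, s, :].T @ da
                    dz_buf[:, s, :] += da @ wrec_d[d].T
            g_f = kap * g_f

        masks_in = self._delay_masks(self.d_in)
        masks_rec = self._delay_masks(self.d_rec)
        g_w_in = sum(m * g for m, g in zip(masks_in, gin_d))
        g_w_rec = sum(m * g for m, g in zip(masks_rec, grec_d))
        np.fill_diagonal(g_w_rec, 0.0)
        return {"w_in": g_w_in, "w_rec": g_w_rec, "w_out": g_w_out}

    # -- inference ----------------------------------------------------------

    def classify(self, input_spikes: np.ndarray):
        """Class of a single spike array: argmax of last-timestep softmax,
        ties broken towards the lowest class index."""
        fwd = self.forward(input_spikes)
        probs = _softmax(fwd.logits[:, -1, :])[0]
        return int(np.argmax(probs)), probs

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities [n, n_out] for a stack of spike arrays."""
        out = []
        for i in range(0, X.shape[0], batch_size):
            fwd = self.forward(X[i:i + batch_size])
            out.append(_softmax(fwd.logits[:, -1, :]))
        return np.concatenate(out) if out else np.empty((0, self.config.n_out))

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Labels for a stack of spike arrays [n, T, n_in]."""
        out = []
        for i in range(0, X.shape[0], batch_size):
            fwd = self.forward(X[i:i + batch_size])
            out.append(np.argmax(fwd.logits[:, -1, :], axis=-1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def _one_hot(targets, n_out: int) -> np.ndarray:
    t = np.asarray(targets)
    if t.ndim == 2:
        return t.astype(np.float64)
    oh = np.zeros((t.shape[0], n_out))
    oh[np.arange(t.shape[0]), t.astype(int)] = 1.0
    return oh


def total_loss(logits_last, targets, hidden_raster, config: LSNNConfig):
    """Cross-entropy of the last-timestep softmax plus the firing-rate
    regularizer ``(lambda_f / N) * sum_n (fbar_n - f_0)^2`` with per-unit
    average rate ``fbar_n`` = spikes averaged over batch and time, divided by
    dt.  Returns (total, cross_entropy, regularizer)."""
    y = np.atleast_2d(np.asarray(logits_last, dtype=np.float64))
    onehot = _one_hot(targets, config.n_out)
    z = np.asarray(hidden_raster, dtype=np.float64)
    if z.ndim == 2:
        z = z[None]
    B, T, N = z.shape
    logp = y - np.max(y, axis=-1, keepdims=True)
    logp = logp - np.log(np.sum(np.exp(logp), axis=-1, keepdims=True))
    ce = float(-np.sum(onehot * logp) / B)
    fbar = z.sum(axis=(0, 1)) / (config.constants.dt * B * T)
    reg = float(config.reg_lambda / N * np.sum((fbar - config.target_rate) ** 2))
    return ce + reg, ce, reg


class _Adam:
    def __init__(self, shapes, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model_or_config, train_data, test_data=None, epochs: int = 150,
          lr: float = 1.0e-3, batch_size: int = 32, seed: int | None = None,
          verbose: bool = False):
    """Train by surrogate-gradient BPTT with an Adam optimizer.

    ``train_data``/``test_data`` are ``(X, y)`` with ``X`` of shape
    [n, T, n_in] and integer labels ``y``.  Deterministic given the seed and
    settings.  Returns ``(model, TrainHistory)``; a non-finite loss aborts
    with a report.
    """
    model = LSNN(model_or_config) if isinstance(model_or_config, LSNNConfig) else model_or_config
    cfg = model.config
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed + 1)
    X, y = train_data
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    losses = []
    test_acc = []
    opt = _Adam({k: w.shape for k, w in model.weights.items()}, lr=lr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i in range(0, n, batch_size):
            sel = order[i:i + batch_size]
            fwd = model.forward(X[sel], cache=True)
            loss, ce, reg = model.loss(fwd, y[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, batch {nb}: "
                    f"loss={loss} (ce={ce}, reg={reg})")
            grads = model.backward(fwd, y[sel])
            opt.update(model.weights, grads)
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / max(nb, 1))
        if test_data is not None:
            Xt, yt = test_data
            acc = float(np.mean(model.predict(np.asarray(Xt)) == np.asarray(yt)))
            test_acc.append(acc)
        if verbose:
            msg = f"epoch {epoch + 1}/{epochs} loss {losses[-1]:.4f}"
            if test_acc:
                msg += f" test_acc {test_acc[-1]:.4f}"
            print(msg)
    history = TrainHistory(losses=losses, test_accuracy=test_acc,
                           weights_digest=model.weights_digest(),
                           seed=seed, epochs=epochs)
    return model, history


def classify(model: LSNN, input_spikes: np.ndarray):
    """Functional wrapper around :meth:`LSNN.classify`."""
    return model.classify(input_spikes)


_FORMAT_VERSION = 1


def save_model(model: LSNN, path) -> None:
    """Single-file checkpoint: config, weights, delays, format version."""
    cfg = asdict(model.config)
    np.savez(path,
             config_json=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             w_in=model.w_in, w_rec=model.w_rec, w_out=model.w_out,
             d_in=model.d_in, d_rec=model.d_rec,
             version=np.array([_FORMAT_VERSION]))


def load_model(path) -> LSNN:
    with np.load(path) as data:
        if int(data["version"][0]) != _FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["constants"] = NeuronConstants(**cfg["constants"])
        model = LSNN(LSNNConfig(**cfg))
        model.w_in = data["w_in"]
        model.w_rec = data["w_rec"]
        model.w_out = data["w_out"]
        model.d_in = data["d_in"]
        model.d_rec = data["d_rec"]
    return model
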