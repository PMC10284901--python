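"""Synthetic physiological signals, preprocessing and spike-dataset assembly.

The generators provide desk-scale stand-ins for the two task domains:

* Single-lead ECG heartbeats as sums of Gaussian bumps (P, Q, R, S, T waves)
  with class-specific morphology for the four AAMI beat classes — Normal (N),
  ventricular ectopic (VEB: wide, large QRS, no P wave, discordant T),
  supraventricular ectopic (SVEB: early beat with an abnormal P wave close to
  a narrow QRS) and fusion (F: a blend of N and VEB).  Beats are 1000
  timesteps at 1800 Hz and normalized to 0–0.6 V.

* Multi-channel EEG clips of background activity (1/f-shaped noise) with
  seizure clips carrying correlated rhythmic 3–12 Hz high-amplitude bursts;
  18 channels x 1000 timesteps at 800 Hz, in 0–0.6 V.  Normal clips may
  optionally contain brief non-rhythmic movement-artifact transients, which
  emulates the artifact-laden character of real scalp recordings.

`build_spike_dataset` runs every channel through the delta encoder, stacks
UP/DOWN rows plus a CUE row (active only during the appended cue window), and
performs a stratified train/test split.  No claim of clinical realism is
made; the generators exist so the full pipeline is testable without
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .encoder import EncoderParams, encode, reconstruct

__all__ = [
    "HeartbeatSpec",
    "EEGClipSpec",
    "SpikeDataset",
    "synth_heartbeat",
    "beat_features",
    "synth_eeg_sequence",
    "preprocess",
    "build_spike_dataset",
    "make_burst_task",
    "make_cue_memory_task",
    "read_record",
    "write_record",
]

BEAT_CLASSES = ("N", "VEB", "SVEB", "F")

# Gaussian-bump morphology: wave -> (center as fraction of window, width, amp).
# R peak of a normal beat sits at 40% of the window.
_MORPH = {
    "N": {"P": (0.22, 0.025, 0.15), "Q": (0.37, 0.012, -0.10),
          "R": (0.40, 0.016, 1.00), "S": (0.43, 0.012, -0.18),
          "T": (0.62, 0.050, 0.30)},
    "VEB": {"Q": (0.33, 0.030, -0.25), "R": (0.40, 0.055, 1.05),
            "S": (0.49, 0.035, -0.45), "T": (0.67, 0.070, -0.35)},
    "SVEB": {"P": (0.30, 0.018, 0.06), "Q": (0.33, 0.012, -0.10),
             "R": (0.36, 0.016, 1.00), "S": (0.39, 0.012, -0.18),
             "T": (0.56, 0.045, 0.28)},
    "F": {"P": (0.22, 0.025, 0.05), "Q": (0.35, 0.022, -0.18),
          "R": (0.40, 0.034, 1.00), "S": (0.46, 0.024, -0.30),
          "T": (0.64, 0.060, 0.05)},
}


@dataclass(frozen=True)
class HeartbeatSpec:
    """Specification of a synthetic single-lead heartbeat."""

    class_label: str = "N"
    n_timesteps: int = 1000
    fs: float = 1800.0
    amplitude_range: tuple = (0.0, 0.6)
    center_jitter: float = 0.01
    width_jitter: float = 0.08
    amp_jitter: float = 0.08
    noise_std: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class {self.class_label!r}; "
                             f"expected one of {BEAT_CLASSES}")


def _normalize(x: np.ndarray, amplitude_range) -> np.ndarray:
    lo, hi = amplitude_range
    span = x.max() - x.min()
    if span == 0.0:
        # degenerate constant input maps to the range minimum
        return np.full_like(x, lo)
    return lo + (x - x.min()) / span * (hi - lo)


def synth_heartbeat(spec: HeartbeatSpec, rng=None) -> np.ndarray:
    """Generate one heartbeat waveform (pure function of spec + seed)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_timesteps)
    x = np.zeros(spec.n_timesteps)
    for c, w, a in _MORPH[spec.class_label].values():
        c = c + spec.center_jitter * rng.standard_normal()
        w = w * (1.0 + spec.width_jitter * rng.standard_normal())
        a = a * (1.0 + spec.amp_jitter * rng.standard_normal())
        x += a * np.exp(-0.5 * ((t - c) / max(w, 1e-4)) ** 2)
    x += spec.noise_std * rng.standard_normal(spec.n_timesteps)
    return _normalize(x, spec.amplitude_range)


def beat_features(waveform: np.ndarray, fs: float) -> tuple[float, float]:
    """(QRS width [s] at half the R amplitude, R amplitude above baseline [V])."""
    w = np.asarray(waveform, dtype=np.float64)
    i_r = int(np.argmax(w))
    base = np.median(w)
    half = base + 0.5 * (w[i_r] - base)
    lo = i_r
    while lo > 0 and w[lo - 1] > half:
        lo -= 1
    hi = i_r
    while hi < w.size - 1 and w[hi + 1] > half:
        hi += 1
    return (hi - lo + 1) / fs, float(w[i_r] - base)


@dataclass(frozen=True)
class EEGClipSpec:
    """Specification of synthetic multi-channel EEG clips."""

    state: str = "Normal"
    n_channels: int = 18
    n_timesteps: int = 1000
    fs: float = 800.0
    amplitude_range: tuple = (0.0, 0.6)
    background_std: float = 0.03
    seizure_band: tuple = (3.0, 12.0)
    seizure_gain: float = 0.22
    channel_corr: float = 0.7
    artifact_prob: float = 0.0
    artifact_gain: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in ("Normal", "Epileptic"):
            raise ValueError("state must be 'Normal' or 'Epileptic'")


def _pink_noise(rng, n_channels: int, n: int) -> np.ndarray:
    """1/f-shaped background noise, unit std per channel."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x

def _eeg_clip(spec: EEGClipSpec, rng, seizure: bool, artifact: bool) -> np.ndarray:
    n_ch, n = spec.n_channels, spec.n_timesteps
    mid = 0.5 * (spec.amplitude_range[0] + spec.amplitude_range[1])
    x = mid + spec.background_std * _pink_noise(rng, n_ch, n)
    t = np.arange(n) / spec.fs
    if seizure:
        # correlated rhythmic burst: shared oscillation + per-channel component
        f0 = rng.uniform(*spec.seizure_band)
        phase = rng.uniform(0, 2 * np.pi)
        env = 0.5 * (1.0 - np.cos(2 * np.pi * np.minimum(t / t[-1], 1.0)))
        shared = np.sin(2 * np.pi * f0 * t + phase) * env
        rho = spec.channel_corr
        for ch in range(n_ch):
            f_i = f0 * (1.0 + 0.08 * rng.standard_normal())
            own = np.sin(2 * np.pi * f_i * t + rng.uniform(0, 2 * np.pi)) * env
            x[ch] += spec.seizure_gain * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
    elif artifact:
        # brief high-amplitude non-rhythmic transient on a few channels
        n_aff = max(2, n_ch // 4)
        chans = rng.choice(n_ch, size=n_aff, replace=False)
        i0 = rng.integers(0, max(1, n - n // 5))
        width = n // 5
        burst_env = np.zeros(n)
        burst_env[i0:i0 + width] = np.hanning(min(width, n - i0))
        for ch in chans:
            x[ch] += spec.artifact_gain * burst_env * rng.standard_normal(n)
    return np.clip(x, *spec.amplitude_range)


def synth_eeg_sequence(spec: EEGClipSpec, n_clips: int, seizure_runs,
                       rng=None):
    """Contiguous clip sequence with sparse seizure runs.

    ``seizure_runs`` is a list of ``(start, length)`` clip indices; runs must
    lie within bounds and not overlap.  Returns ``(clips, labels)`` where
    clips is [n_clips, n_channels, n_timesteps] and labels is 0 (Normal) / 1
    (Epileptic).  Normal clips carry movement artifacts with probability
    ``spec.artifact_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = np.zeros(n_clips, dtype=int)
    occupied = np.zeros(n_clips, dtype=bool)
    for start, length in seizure_runs:
        if start < 0 or length <= 0 or start + length > n_clips:
            raise ValueError(f"seizure run ({start}, {length}) out of bounds")
        if occupied[start:start + length].any():
            raise ValueError("seizure runs must not overlap")
        occupied[start:start + length] = True
        labels[start:start + length] = 1
    clips = np.empty((n_clips, spec.n_channels, spec.n_timesteps))
    for i in range(n_clips):
        seiz = bool(labels[i])
        art = (not seiz) and (rng.random() < spec.artifact_prob)
        clips[i] = _eeg_clip(spec, rng, seiz, art)
    return clips, labels


def preprocess(raw, fs_in: float, fs_out: float, n_timesteps: int,
               amplitude_range=(0.0, 0.6)) -> np.ndarray:
    """Resample to ``fs_out``, crop/pad to ``n_timesteps`` samples and
    min-max normalize into ``amplitude_range`` (a constant input maps to the
    range minimum)."""
    x = np.asarray(raw, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be > 0")
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if fs_in != fs_out:
        from fractions import Fraction
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    if x.shape[1] >= n_timesteps:
        x = x[:, :n_timesteps]
    else:
        x = np.pad(x, ((0, 0), (0, n_timesteps - x.shape[1])), mode="edge")
    out = np.vstack([_normalize(row, amplitude_range) for row in x])
    return out[0] if single else out


@dataclass
class SpikeDataset:
    """Spike-encoded dataset: X [n, T, n_in] binary, labels y, layout of the
    input channels (UP/DOWN per signal channel + trailing CUE), stratified
    split indices and the seed that produced them."""

    X: np.ndarray
    y: np.ndarray
    layout: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    cue_steps: int
    seed: int

    @property
    def n_in(self) -> int:
        return self.X.shape[2]

    def train_arrays(self):
        return self.X[self.train_idx], self.y[self.train_idx]

    def test_arrays(self):
        return self.X[self.test_idx], self.y[self.test_idx]


def _encode_channels(wave: np.ndarray, fs: float, params: EncoderParams,
                     cue_steps: int) -> np.ndarray:
    """One waveform [n_ch, T] (or [T]) -> binary spike array
    [T + cue_steps, 2*n_ch + 1] with the CUE row active in the cue window."""
    w = np.atleast_2d(np.asarray(wave, dtype=np.float64))
    n_ch, T = w.shape
    out = np.zeros((T + cue_steps, 2 * n_ch + 1), dtype=np.uint8)
    for ch in range(n_ch):
        ev = encode(w[ch], fs, params)
        i = np.round(ev.times * fs).astype(int)
        up = i[ev.polarity == 1]
        dn = i[ev.polarity == -1]
        out[up, 2 * ch] = 1
        out[dn, 2 * ch + 1] = 1
    out[T:, -1] = 1
    return out


def _stratified_split(y: np.ndarray, train_frac: float, rng):
    n = y.shape[0]
    n_train = int(round(train_frac * n))
    classes = np.unique(y)
    base = []
    rema = []
    per_class = {}
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        k_exact = train_frac * idx.size
        per_class[c] = (idx, int(np.floor(k_exact)))
        base.append(int(np.floor(k_exact)))
        rema.append((k_exact - np.floor(k_exact), c))
    short = n_train - sum(base)
    rema.sort(reverse=True)
    bump = {c for _, c in rema[:short]}
    train, test = [], []
    for c, (idx, k) in per_class.items():
        k = k + (1 if c in bump else 0)
        train.append(idx[:k])
        test.append(idx[k:])
    train = np.sort(np.concatenate(train))
    test = np.sort(np.concatenate(test))
    return train, test


def build_spike_dataset(waveforms, labels, encoder_params: EncoderParams,
                        fs: float, cue_steps: int = 200,
                        train_frac: float = 0.832, seed: int = 0,
                        channel_names=None) -> SpikeDataset:
    """Encode waveforms into UP/DOWN spike rows, append the CUE window, and
    split stratified by class.  With 2000 beats and the default fraction the
    split is exactly 1664 train / 336 test."""
    y = np.asarray(labels)
    if len(waveforms) != y.shape[0]:
        raise ValueError("waveforms and labels must have equal length")
    X = np.stack([_encode_channels(w, fs, encoder_params, cue_steps)
                  for w in waveforms])
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y, train_frac, rng)
    n_ch = (X.shape[2] - 1) // 2
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    layout = []
    for name in channel_names:
        layout += [f"{name}_UP", f"{name}_DOWN"]
    layout.append("CUE")
    return SpikeDataset(X=X, y=y, layout=layout, train_idx=train_idx,
                        test_idx=test_idx, cue_steps=cue_steps, seed=seed)


def decode_dataset_channel(sample: np.ndarray, channel: int, fs: float,
                           delta: float, initial_value: float) -> np.ndarray:
    """Invert the UP/DOWN rows of one signal channel back to a staircase
    waveform (round-trip check against the original)."""
    up = sample[:, 2 * channel].astype(np.int64)
    dn = sample[:, 2 * channel + 1].astype(np.int64)
    return initial_value + delta * np.cumsum(up - dn)


# -- synthetic spike benchmarks for the network ------------------------------

def make_burst_task(n_samples: int = 240, t_signal: int = 100,
                    cue_steps: int = 25, burst_len: int = 20,
                    p_background: float = 0.05, p_burst: float = 0.8,
                    seed: int = 0):
    """Two-class temporal task: a dense UP-channel burst sits in the first
    (class 0) or second (class 1) half of the signal window; inputs are
    (UP, DOWN, CUE).  Returns (X [n, T, 3] uint8, y)."""
    rng = np.random.default_rng(seed)
    T = t_signal + cue_steps
    X = np.zeros((n_samples, T, 3), dtype=np.uint8)
    y = rng.integers(0, 2, n_samples)
    half = t_signal // 2
    for i in range(n_samples):
        X[i, :t_signal, 0] = rng.random(t_signal) < p_background
        X[i, :t_signal, 1] = rng.random(t_signal) < p_background
        lo = 0 if y[i] == 0 else half
        start = lo + rng.integers(0, half - burst_len)
        X[i, start:start + burst_len, 0] = rng.random(burst_len) < p_burst
        X[i, t_signal:, 2] = 1
    return X, y


def make_cue_memory_task(n_samples: int = 240, t_signal: int = 200,
                         cue_steps: int = 40, burst_len: int = 20,
                         burst_start: int = 10, p_burst: float = 0.8,
                         p_background: float = 0.02, seed: int = 0):
    """Memory task across the cue gap: an early burst arrives on channel 0
    (class 0) or channel 1 (class 1), followed by a long silent gap before
    the cue window; the decision at the last timestep requires retaining the
    burst identity far beyond the membrane time constant."""
    rng = np.random.default_rng(seed)
    T = t_signal + cue_steps
    X = np.zeros((n_samples, T, 3), dtype=np.uint8)
    y = rng.integers(0, 2, n_samples)
    for i in range(n_samples):
        X[i, :t_signal, 0] = rng.random(t_signal) < p_background
        X[i, :t_signal, 1] = rng.random(t_signal) < p_background
        ch = int(y[i])
        X[i, burst_start:burst_start + burst_len, ch] = rng.random(burst_len) < p_burst
        X[i, t_signal:, 2] = 1
    return X, y


# -- record I/O --------------------------------------------------------------

def write_record(path, waveform: np.ndarray, fs: float, channel_names=None) -> None:
    """Write a multichannel waveform as CSV (one row per sample, a ``#fs=``
    metadata line, header = channel names)."""
    w = np.atleast_2d(np.asarray(waveform, dtype=np.float64))
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(w.shape[0])]
    with open(path, "w") as fh:
        fh.write(f"#fs={float(fs)!r}\n")
        fh.write(",".join(channel_names) + "\n")
        for row in w.T:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_record(path, format: str = "csv"):
    """Read a multichannel record; returns (waveform [n_ch, n], fs).

    Only the plain-CSV format written by :func:`write_record` is supported;
    no network access, ever.
    """
    import os

    if format != "csv":
        raise ValueError(f"unknown record format {format!r}; supported: 'csv'")
    if not os.path.exists(path):
        raise FileNotFoundError(f"record file not found: {path}")
    fs = None
    rows = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#fs="):
                fs = float(line[4:])
            elif not header_seen:
                header_seen = True  # channel-name header
            else:
                rows.append([float(v) for v in line.split(",")])
    if fs is None or not rows:
        raise ValueError(f"malformed record file: {path}")
    return np.asarray(rows).T, fs
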