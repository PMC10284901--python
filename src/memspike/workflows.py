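"""End-to-end study assemblies tying the generators, encoder, network and
evaluation together.

`run_seizure_study` mirrors the reference seizure-detection layout: a
balanced training set of independent clips, a long contiguous and highly
imbalanced test sequence (one short seizure run inside an hour-scale
recording), per-channel delta encoding into UP/DOWN spike trains plus a CUE
window, a small mixed-unit recurrent spiking network trained by
surrogate-gradient BPTT, and moving-average post-processing of the contiguous
decisions.  Test-sequence normals carry occasional movement artifacts that
the (clean) training set lacks, emulating the domain shift that makes real
classifiers emit scattered false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoder import EncoderParams
from .evaluation import ClassifiedSequence, PostprocessParams, evaluate_pipeline
from .lsnn import LSNN, LSNNConfig, TrainHistory, train
from .signals import EEGClipSpec, SpikeDataset, _encode_channels, synth_eeg_sequence

__all__ = ["SeizureStudyResult", "run_seizure_study", "encode_clips"]


def encode_clips(clips: np.ndarray, fs: float, params: EncoderParams,
                 cue_steps: int) -> np.ndarray:
    """Delta-encode a stack of clips [n, n_ch, T] into spike arrays
    [n, T + cue_steps, 2*n_ch + 1]."""
    return np.stack([_encode_channels(c, fs, params, cue_steps) for c in clips])


@dataclass
class SeizureStudyResult:
    report: ClassifiedSequence
    history: TrainHistory
    model: LSNN
    train_labels: np.ndarray
    test_labels: np.ndarray


def run_seizure_study(seed: int = 0, n_train_per_class: int = 150,
                      n_test: int = 2878, seizure_run=(2300, 31),
                      n_channels: int = 18, n_timesteps: int = 1000,
                      cue_steps: int = 25, delta: float = 0.05,
                      epochs: int = 25, lr: float = 1e-3,
                      artifact_prob: float = 0.12,
                      n_hidden: int = 40, n_alif: int = 16,
                      lowpass_tau: float = 300.0, i_a: float = 6.0e-6,
                      positive_threshold: float = 0.2,
                      postprocess_params: PostprocessParams | None = None,
                      verbose: bool = False) -> SeizureStudyResult:
    """Train on balanced clean clips, evaluate on a contiguous imbalanced
    sequence, post-process with the moving-average + threshold rule."""
    rng = np.random.default_rng(seed)
    spec = EEGClipSpec(n_channels=n_channels, n_timesteps=n_timesteps,
                       seed=seed)

    # balanced, independent, artifact-free training clips
    n_tr = 2 * n_train_per_class
    train_labels = rng.permutation(
        np.repeat([0, 1], n_train_per_class)).astype(int)
    train_clips = np.empty((n_tr, n_channels, n_timesteps))
    from .signals import _eeg_clip
    for i, lab in enumerate(train_labels):
        train_clips[i] = _eeg_clip(spec, rng, seizure=bool(lab), artifact=False)

    # contiguous test sequence with sparse seizure run and artifact-bearing
    # normals (absent from training: the domain shift producing scattered
    # false positives)
    test_spec = replace(spec, artifact_prob=artifact_prob,
                        seed=seed + 1)
    test_clips, test_labels = synth_eeg_sequence(
        test_spec, n_test, [tuple(seizure_run)])

    enc = EncoderParams(delta=delta, seed=seed)
    X_train = encode_clips(train_clips, spec.fs, enc, cue_steps)
    X_test = encode_clips(test_clips, spec.fs, enc, cue_steps)

    from .lsnn import NeuronConstants
    cfg = LSNNConfig(n_in=2 * n_channels + 1, n_hidden=n_hidden,
                     n_alif=n_alif, n_out=2, cue_steps=cue_steps, seed=seed,
                     lowpass_tau=lowpass_tau,
                     constants=NeuronConstants(i_a=i_a))
    model, history = train(cfg, (X_train, train_labels), epochs=epochs,
                           lr=lr, seed=seed, verbose=verbose)
    # sensitivity-first per-clip decision, the operating point a detection
    # screen runs at (missed seizures cost far more than false alarms, which
    # the post-processing removes)
    report = evaluate_pipeline(model, X_test, test_labels,
                               postprocess_params or PostprocessParams(),
                               positive_threshold=positive_threshold)
    return SeizureStudyResult(report=report, history=history, model=model,
                              train_labels=train_labels,
                              test_labels=test_labels)
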