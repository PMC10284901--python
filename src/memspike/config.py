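"""Global YAML configuration: build parameter objects from one config file.

The file holds one top-level section per component, e.g.::

    memristor: {v_th: 3.4, v_hold: 1.45, r_on: 1.0e3, r_off: 1.0e5}
    lif: {r_load: 18.0e3, c_mem: 1.0e-9}
    alif: {r3: 1.0e5, c2: 1.0e-8}
    encoder: {delta: 0.05}
    lsnn: {n_hidden: 100, n_alif: 40, constants: {dt: 1.0e-3}}
    postprocess: {window: 9, threshold: 0.8}

Missing sections/keys fall back to the documented defaults.
"""

from __future__ import annotations

import yaml

from .circuits import ALIFCircuitParams, LIFCircuitParams
from .encoder import EncoderParams
from .evaluation import PostprocessParams
from .lsnn import LSNNConfig, NeuronConstants
from .memristor import MemristorParams

__all__ = ["load_config", "params_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def params_from_config(cfg: dict) -> dict:
    """Instantiate every parameter object the config describes."""
    mem = MemristorParams(**cfg.get("memristor", {}))
    lif = LIFCircuitParams(memristor=mem, **cfg.get("lif", {}))
    alif = ALIFCircuitParams(lif=lif, **cfg.get("alif", {}))
    enc = EncoderParams(memristor=mem, **cfg.get("encoder", {}))
    lsnn_cfg = dict(cfg.get("lsnn", {}))
    const = NeuronConstants(**lsnn_cfg.pop("constants", {}))
    lsnn = LSNNConfig(constants=const, **lsnn_cfg)
    post = PostprocessParams(**cfg.get("postprocess", {}))
    return {"memristor": mem, "lif": lif, "alif": alif, "encoder": enc,
            "lsnn": lsnn, "postprocess": post}
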