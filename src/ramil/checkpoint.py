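"""Model checkpoints: parameter NPZ plus a JSON sidecar of architecture metadata.

The sidecar records the pooling variant, C, D, L, the encoder spec, and a
config hash so a checkpoint can be rebuilt exactly and an evaluation run can
refuse a checkpoint whose architecture disagrees with its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .encoders import EncoderSpec, build_encoder
from .pooling import MILModel


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def save_checkpoint(
    model: MILModel,
    path: str | Path,
    encoder_spec: EncoderSpec | None = None,
    extra: dict | None = None,
) -> Path:
    """Write ``<path>.npz`` (parameters) and ``<path>.json`` (metadata)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    spec = encoder_spec or getattr(model.encoder, "spec", None)
    meta = {
        "variant": model.variant,
        "C": model.C,
        "D": model.D,
        "L": model.encoder.out_dim,
        "encoder_spec": asdict(spec) if spec is not None else None,
        "extra": extra or {},
    }
    meta["config_hash"] = config_hash(meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path, encoder=None) -> tuple[MILModel, dict]:
    """Rebuild a model from checkpoint files; returns (model, metadata).

    The encoder is rebuilt from the sidecar's encoder spec unless one is
    passed explicitly (e.g. an IdentityEncoder for precomputed features).
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if encoder is None:
        if meta["encoder_spec"] is None:
            raise ValueError("checkpoint has no encoder spec; pass encoder explicitly")
        spec = EncoderSpec(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["encoder_spec"].items()
        })
        encoder = build_encoder(spec)
    model = MILModel(encoder, variant=meta["variant"], C=meta["C"], D=meta["D"])
    with np.load(path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, meta
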