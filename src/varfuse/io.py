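"""Serialization: JSONL caption records, embedding tensor files with a sidecar
manifest, single-file model checkpoints, and YAML config round-trips."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml


def write_jsonl(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def save_embeddings(embeddings: dict[str, np.ndarray], path) -> None:
    """Binary tensor file (npz) plus a JSON sidecar manifest listing modality,
    shape, and dtype for each stored array."""
    path = Path(path)
    np.savez(path, **embeddings)
    manifest = {
        mod: {"shape": list(arr.shape), "dtype": str(arr.dtype)}
        for mod, arr in embeddings.items()
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2))


def load_embeddings(path) -> dict[str, np.ndarray]:
    path = Path(path)
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    with np.load(path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")) as z:
        data = {k: z[k] for k in z.files}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for mod, meta in manifest.items():
            if list(data[mod].shape) != meta["shape"]:
                raise ValueError(f"{mod}: manifest shape {meta['shape']} != {data[mod].shape}")
    return data


def save_checkpoint(model, path, config=None) -> None:
    """Single-file archive: weight blobs plus the config as a JSON string."""
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    if config is not None:
        cfg = asdict(config) if is_dataclass(config) else dict(config)
        state["__config__"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict | None]:
    with np.load(path) as z:
        config = None
        state = {}
        for k in z.files:
            if k == "__config__":
                config = json.loads(z[k].tobytes().decode())
            elif k.startswith("param::"):
                state[k[len("param::"):]] = z[k]
    return state, config


def config_to_yaml(config) -> str:
    cfg = asdict(config) if is_dataclass(config) else dict(config)
    return yaml.safe_dump(cfg, sort_keys=True)


def config_from_yaml(text: str, cls):
    return cls(**yaml.safe_load(text))
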