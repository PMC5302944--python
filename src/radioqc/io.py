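"""File I/O: TIFF stacks with YAML sidecars, CSV tables, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml


def write_image(path, array: np.ndarray, **metadata) -> Path:
    """Write a (multi-page) TIFF plus a YAML sidecar with physical metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(_plain(metadata), fh, sort_keys=True)
    return path


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF and its YAML sidecar (empty dict when absent)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return data, meta


def write_manifest(path, stage: str, parameters: dict, inputs: list, outputs: list, seed=None):
    """Write a JSON manifest next to a stage's artifacts (no timestamps, so
    re-runs with the same seed are byte-identical)."""
    from radioqc import __version__

    manifest = {
        "stage": stage,
        "software": {"name": "radioqc", "version": __version__},
        "seed": seed,
        "parameters": _plain(parameters),
        # file names only: manifests stay byte-identical across output roots
        "inputs": [Path(p).name for p in inputs],
        "outputs": [Path(p).name for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return Path(path)


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples to plain types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
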