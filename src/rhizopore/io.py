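"""TIFF / JSON input-output for volumes, labels and run metadata."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile


def write_gray_tiff(path, volume: np.ndarray) -> None:
    """16-bit multi-page TIFF; float volumes are clipped to [0, 65535]."""
    arr = np.clip(np.round(volume), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, labels.astype(np.uint8))


def write_float_tiff(path, volume: np.ndarray) -> None:
    tifffile.imwrite(path, volume.astype(np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def read_volume(path, sidecar=None) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack, or a raw binary volume described by a JSON header.

    The raw header must give ``shape`` (z, y, x), ``dtype`` and
    ``voxel_size_um``; a TIFF may carry the same keys in a sidecar JSON.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = read_json(sidecar) if sidecar else {}
        return tifffile.imread(path), meta
    meta = read_json(sidecar if sidecar else path.with_suffix(".json"))
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    return arr.reshape(meta["shape"]), meta


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
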