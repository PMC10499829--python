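"""Shared I/O helpers: image stacks (TIFF/HDF5), seeded substreams, logging.

HDF5 is the canonical interchange format for simulated data (multi-dimensional
stacks with rich attributes); multi-page TIFF is the human-inspection format.
All metadata needed to reproduce a file (seeds, physical parameters) travels
with it, either as HDF5 attributes or as JSON in the TIFF description tag.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "get_logger",
    "substream",
    "spawn_rng",
    "write_stack",
    "read_stack",
    "write_h5_stack",
    "read_h5_stack",
]

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str = "deeptfm", logfile: str | Path | None = None) -> logging.Logger:
    """Structured logger to stderr, optionally duplicated to a logfile."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        path = Path(logfile)
        if not any(
            isinstance(h, logging.FileHandler) and Path(h.baseFilename) == path
            for h in logger.handlers
        ):
            fh = logging.FileHandler(path)
            fh.setFormatter(logging.Formatter(_LOG_FORMAT))
            logger.addHandler(fh)
    return logger


def substream(global_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Derive a per-stage seed stream from the global seed.

    The derivation is a stable function of (global_seed, stage name, item
    index): the stage name is folded through CRC-32 so the mapping does not
    depend on Python's randomized string hashing.  Equal inputs always yield
    the same stream; distinct stages or indices yield independent streams.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, tag, int(index)])


def spawn_rng(global_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator on the :func:`substream` of (seed, stage, index)."""
    return np.random.default_rng(substream(global_seed, stage, index))


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, data: np.ndarray, metadata: dict | None = None) -> Path:
    """Write a 2-D/3-D array as a multi-page float32 (or uint16/uint8) TIFF.

    Metadata is stored as JSON in the ImageDescription tag and recovered by
    :func:`read_stack`.
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = arr.astype(np.float32)
    desc = json.dumps(metadata or {})
    tifffile.imwrite(path, arr, description=desc, photometric="minisblack")
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Integer stacks are promoted to float32 with the promotion scale recorded
    in the returned metadata (``promoted_from``/``scale``).  Missing metadata
    is tolerated: defaults are returned and a warning logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
            if not isinstance(meta, dict):
                meta = {}
        except json.JSONDecodeError:
            meta = {}
    if not meta:
        get_logger().warning("no metadata in %s; applying defaults", path)
    if arr.dtype in (np.uint8, np.uint16):
        info = np.iinfo(arr.dtype)
        meta.setdefault("promoted_from", str(arr.dtype))
        meta.setdefault("scale", float(info.max))
        arr = arr.astype(np.float32)
    else:
        arr = np.asarray(arr, dtype=np.float32)
    return arr, meta


# ---------------------------------------------------------------------------
# HDF5 stacks
# ---------------------------------------------------------------------------

def write_h5_stack(
    path: str | Path,
    datasets: dict[str, np.ndarray],
    attrs: dict | None = None,
) -> Path:
    """Write named arrays plus scalar/JSON-able attributes to one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in datasets.items():
            f.create_dataset(name, data=np.asarray(arr))
        for key, value in (attrs or {}).items():
            if isinstance(value, (dict, list, tuple)):
                f.attrs[key] = json.dumps(value)
            else:
                f.attrs[key] = value
    return path


def read_h5_stack(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read back every dataset and attribute written by :func:`write_h5_stack`."""
    path = Path(path)
    datasets: dict[str, np.ndarray] = {}
    attrs: dict = {}
    with h5py.File(path, "r") as f:
        def _collect(name, obj):
            if isinstance(obj, h5py.Dataset):
                datasets[name] = obj[()]
        f.visititems(_collect)
        for key, value in f.attrs.items():
            if isinstance(value, (bytes, str)):
                s = value.decode() if isinstance(value, bytes) else value
                try:
                    attrs[key] = json.loads(s)
                except (json.JSONDecodeError, ValueError):
                    attrs[key] = s
            else:
                attrs[key] = value
    return datasets, attrs
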