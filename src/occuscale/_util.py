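"""Small shared helpers: RNG handling, numerics, file hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def check_seed(seed: int) -> int:
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return int(seed)


def spawn_seed(seed: int, stream: str) -> int:
    """Derive an independent child seed (< 2**31) for a named stream."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def rng_for(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(spawn_seed(check_seed(seed), stream))


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def log_expit(x):
    """log(sigmoid(x)), numerically stable."""
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, -x)


def softmax(u):
    u = np.asarray(u, dtype=float)
    m = u.max()
    e = np.exp(u - m)
    return e / e.sum()


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
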