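"""Shared helpers: seeded RNG streams and config hashing."""

from __future__ import annotations

import hashlib
import json

import numpy as np

# Fixed per-stage offsets so every analysis stage draws from its own child
# stream of one master seed, and reruns are bit-reproducible.
_STAGE_OFFSETS = {
    "stimuli": 11,
    "neurons": 23,
    "layers": 37,
    "sorting": 41,
    "bootstrap": 53,
    "splits": 67,
    "subsample": 79,
    "projection": 97,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a master seed."""
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown RNG stage: {stage!r}")
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))


def stable_hash(obj) -> str:
    """SHA-256 of a canonical JSON encoding; used to stamp outputs."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
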