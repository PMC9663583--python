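"""On-disk TrialSet format: one directory per set.

Arrays are stored as ``.npy`` (self-describing binary array format) and the
scalar metadata lives in a diffable JSON sidecar.  Unknown extra keys in the
sidecar are preserved on round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import TrialSet

FORMAT_VERSION = 1

_ARRAY_FILES = ("data", "condition", "subject", "event_sample")


def write_trialset(t: TrialSet, path) -> None:
    """Write ``t`` to directory ``path`` (created if absent).

    Layout: ``data.npy``, ``condition.npy``, ``subject.npy``,
    ``event_sample.npy`` plus ``meta.json`` with fs, channels, format
    version and any extra metadata.
    """
    if t.n_trials == 0:
        raise ValueError("no trials")
    if not np.isfinite(t.data).all():
        raise ValueError("refusing to write non-finite data")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", t.data)
    np.save(path / "condition.npy", t.condition.astype(str))
    np.save(path / "subject.npy", t.subject.astype(str))
    np.save(path / "event_sample.npy", t.event_sample)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "fs": float(t.fs),
        "channels": list(t.channels),
        "n_trials": int(t.n_trials),
        "n_samples": int(t.n_samples),
        "extra": dict(t.meta),
    }
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_trialset(path) -> TrialSet:
    """Read a TrialSet directory written by :func:`write_trialset`."""
    path = Path(path)
    sidecar_path = path / "meta.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    version = sidecar.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"format version mismatch: file has {version}, reader supports {FORMAT_VERSION}")
    arrays = {}
    for name in _ARRAY_FILES:
        f = path / f"{name}.npy"
        if not f.exists():
            raise FileNotFoundError(f"missing array file {f}")
        arrays[name] = np.load(f, allow_pickle=False)
    fs = float(sidecar["fs"])
    if fs <= 0:
        raise ValueError(f"fs must be positive; got {fs}")
    channels = sidecar["channels"]
    if arrays["data"].ndim != 3 or arrays["data"].shape[2] != len(channels):
        raise ValueError(
            f"shape mismatch: sidecar claims {len(channels)} channels, "
            f"array has shape {arrays['data'].shape}"
        )
    return TrialSet(
        data=arrays["data"],
        fs=fs,
        channels=tuple(channels),
        condition=arrays["condition"],
        subject=arrays["subject"],
        event_sample=arrays["event_sample"],
        meta=dict(sidecar.get("extra", {})),
    )
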