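"""File formats and reproducibility plumbing.

Images travel as multipage TIFF with channel names embedded in the JSON
image description (tifffile's shaped-metadata convention, which — unlike
OME-XML with its per-file UUID — keeps identical runs byte-identical);
tables as CSV (pandas); models, reports and run manifests as JSON.
Every run manifest embeds the SHA-256 hash of the canonicalized
configuration and the seed that produced the outputs, so results can be
traced to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .profiles import RadialProfile
from .synth import MultichannelImage

__all__ = [
    "config_hash",
    "write_manifest",
    "write_image",
    "read_image",
    "write_profile",
    "read_profile",
    "write_events",
]


def _canonical(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration dict."""
    payload = json.dumps(_canonical(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int | None,
                   outputs: list[str] | None = None) -> dict:
    """Write a machine-readable run manifest (JSON) next to the outputs."""
    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "config": _canonical(config),
        "outputs": outputs or [],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest


def write_image(path: str | Path, image: MultichannelImage) -> None:
    """Write a multichannel image as TIFF with channel-name metadata."""
    data = np.asarray(image.data, dtype=np.float32)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(image.channels)},
    )


def read_image(path: str | Path) -> MultichannelImage:
    """Read a TIFF written by :func:`write_image` (or any plain stack)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        names = None
        if tif.shaped_metadata:
            names = tif.shaped_metadata[0].get("channels")
    if data.ndim == 2:
        data = data[None]
    if not names or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return MultichannelImage(data=np.asarray(data, dtype=float),
                             channels=list(names), meta={"path": str(path)})


def write_profile(path: str | Path, profile: RadialProfile) -> None:
    """Write a radial profile as CSV (ell plus one column per channel)."""
    profile.to_frame().to_csv(path, index=False)


def read_profile(path: str | Path) -> RadialProfile:
    return RadialProfile.from_frame(pd.read_csv(path))


def write_events(path: str | Path, events, fmt: str | None = None) -> None:
    """Write decoded events as CSV or JSON (by extension or ``fmt``)."""
    rows = [
        {
            "kind": e.kind,
            "time_h": e.time,
            "raw_time_h": e.raw_time,
            "channel": e.channel,
            "radius": e.radius,
            "amplitude": e.amplitude,
            "flags": ";".join(e.flags),
        }
        for e in events
    ]
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows, columns=["kind", "time_h", "raw_time_h", "channel",
                                    "radius", "amplitude", "flags"]).to_csv(
            path, index=False
        )
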