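"""TIFF and CSV plumbing.

Fields are written as multi-page TIFF (one page per channel) with a sidecar
JSON recording channel order and metadata; tables are CSV with a fixed
float format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import FieldImage

FLOAT_FORMAT = "%.9g"


def write_field(image: FieldImage, path: str | Path) -> Path:
    path = Path(path)
    stack = np.stack([image.channels[name] for name in image.channel_order]).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {
        "channel_order": image.channel_order,
        "metadata": image.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_field(path: str | Path) -> FieldImage:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        names = sidecar["channel_order"]
        metadata = sidecar.get("metadata", {})
    else:
        names = [f"channel_{i}" for i in range(stack.shape[0])]
        metadata = {}
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    return FieldImage(channels=channels, metadata=metadata)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)
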