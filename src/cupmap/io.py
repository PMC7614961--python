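"""File I/O helpers: TIFF volumes, CSV tables with provenance headers,
YAML configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__


def save_volume(path, volume) -> None:
    """Write a (z, y, x) volume as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(volume, dtype=np.float32))


def load_volume(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def save_mask(path, mask) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    return (np.asarray(tifffile.imread(str(path))) > 0).astype(np.uint8)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance_line(seed, config: dict | None = None, stage: str = "") -> str:
    h = config_hash(config) if config else "-"
    return (f"# cupmap {__version__} stage={stage} seed={seed} "
            f"config={h}")


def save_table(path, df: pd.DataFrame, seed=None, config=None,
               stage: str = "") -> None:
    """CSV with a one-line provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config, stage) + "\n")
        df.to_csv(fh, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
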