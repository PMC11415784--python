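"""Output conventions: CSV at 6 significant digits for human inspection,
a full-precision parquet sidecar for numerically exact reuse, and a run
manifest recording config hash, seed and library versions."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, _to_plain

__all__ = ["write_table", "write_manifest", "config_hash"]


def write_table(df: pd.DataFrame, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    if sidecar:
        try:
            df.to_parquet(path.with_suffix(".parquet"))
        except (ImportError, ValueError):
            # full precision fallback when parquet is unavailable
            df.to_csv(path.with_suffix(".full.csv"), index=False, float_format="%.17g")


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_to_plain(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    config: PipelineConfig, out_dir: str | Path, stage_log: list[dict]
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.synthetic.seed,
        "config_hash": config_hash(config),
        "stages": stage_log,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
    return path
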