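"""Round-trip readers/writers and run configuration.

All interchange files are plain UTF-8 comma-separated text with a header row
and ISO-8601 timestamps, so runs are bit-exact to re-read and diff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .cat import CATConfig, SelectionCriterion, StoppingRule
from .grm import QuadratureGrid

__all__ = [
    "read_response_log",
    "write_response_log",
    "read_summaries",
    "write_summaries",
    "write_smoothed",
    "read_smoothed",
    "load_cat_config",
    "cat_config_from_dict",
    "RunManifest",
]

_TIME_COLS = {"scheduled_time", "response_time", "timestamp"}


def _write_csv(df: pd.DataFrame, path) -> None:
    df = df.copy()
    for col in df.columns:
        if col in _TIME_COLS:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False, encoding="utf-8")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    for col in df.columns:
        if col in _TIME_COLS:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def write_response_log(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def read_response_log(path) -> pd.DataFrame:
    return _read_csv(path)


def write_summaries(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def read_summaries(path) -> pd.DataFrame:
    return _read_csv(path)


def write_smoothed(smoothed, path) -> None:
    """Write a SmoothedSeries as ``time,fit,se_band_low,se_band_high``."""
    pd.DataFrame(
        {
            "time": smoothed.eval_times,
            "fit": smoothed.fitted,
            "se_band_low": smoothed.band_low,
            "se_band_high": smoothed.band_high,
        }
    ).to_csv(path, index=False, encoding="utf-8")


def read_smoothed(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


_CONFIG_DEFAULTS = {
    "estimator": "eap",
    "criterion": "mepv",
    "randomesque_n": 1,
    "se_threshold": 0.3,
    "max_items": None,  # None -> bank size at run time
    "min_items": 1,
    "prior_policy": "dynamic",
    "inflation": 0.0,
    "grid_lo": -6.0,
    "grid_hi": 6.0,
    "grid_points": 161,
    "seed": 0,
}


def cat_config_from_dict(raw: dict, bank_size: Optional[int] = None) -> tuple[CATConfig, dict]:
    """Build a CATConfig from a flat key-value mapping.

    Unknown keys raise; missing keys take the study defaults (EAP, MEPV,
    SE < 0.3, dynamic priors).  Returns the config plus the fully resolved
    mapping (for manifests).
    """
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**_CONFIG_DEFAULTS, **raw}
    if cfg["estimator"] != "eap":
        raise ValueError(f"unsupported estimator {cfg['estimator']!r} (only 'eap')")
    max_items = cfg["max_items"]
    if max_items is None:
        max_items = bank_size if bank_size is not None else 10**9
    import numpy as np

    config = CATConfig(
        criterion=SelectionCriterion(kind=cfg["criterion"], randomesque_n=int(cfg["randomesque_n"])),
        rule=StoppingRule(
            se_threshold=float(cfg["se_threshold"]),
            max_items=int(max_items),
            min_items=int(cfg["min_items"]),
        ),
        grid=QuadratureGrid.default(
            lo=float(cfg["grid_lo"]), hi=float(cfg["grid_hi"]), n=int(cfg["grid_points"])
        ),
        rng=np.random.default_rng(int(cfg["seed"])),
    )
    cfg["max_items"] = int(max_items)
    return config, cfg


def load_cat_config(path, bank_size: Optional[int] = None) -> tuple[CATConfig, dict]:
    """Load a YAML/JSON key-value assessment configuration file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return cat_config_from_dict(raw, bank_size=bank_size)


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    config: dict
    master_seed: int
    outputs: list = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self, out_dir) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists outputs that do not exist: {missing}")
        path = Path(out_dir) / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "master_seed": self.master_seed,
                    "config": self.config,
                    "outputs": [str(p) for p in self.outputs],
                    "started": self.started,
                    "finished": self.finished,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        return path
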