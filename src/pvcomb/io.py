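"""Readers and writers: p-value lists, simulation configs, result records."""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combine import CombinedResult, PValueVector
from .simulate import SimulationConfig

__all__ = [
    "read_pvalues",
    "read_sim_config",
    "write_sim_config",
    "results_to_json",
    "results_to_frame",
]


def read_pvalues(path) -> PValueVector:
    """Read a one- or two-column p-value file (plain text, CSV, or TSV).

    A header is optional; when present the p-value column must be named
    ``p`` and an optional second column ``weight``.  Headerless files are
    one value per line or comma/tab separated.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty p-value file")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].replace(sep, " ").split()
    has_header = any(tok.strip().lower() in ("p", "weight") for tok in first)
    try:
        if has_header:
            df = pd.read_csv(path, sep=sep)
            df.columns = [c.strip().lower() for c in df.columns]
            if "p" not in df.columns:
                raise ValueError("header present but no column named 'p'")
            values = df["p"].to_numpy(dtype=float)
            weights = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
        else:
            rows = [re.split(r"[,\t\s]+", line.strip())
                    for line in text.splitlines() if line.strip()]
            values = np.array([float(r[0]) for r in rows])
            weights = (np.array([float(r[1]) for r in rows])
                       if all(len(r) > 1 for r in rows) else None)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: could not parse p-value file ({exc})") from exc
    try:
        return PValueVector(values, weights)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_sim_config(path) -> SimulationConfig:
    """Read a simulation configuration from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        return SimulationConfig.from_dict(raw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_sim_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def results_to_json(results: list[CombinedResult], header: dict | None = None) -> str:
    payload = {"results": [r.to_dict() for r in results]}
    if header:
        payload = {**header, **payload}
    return json.dumps(payload, indent=2)


def results_to_frame(results: list[CombinedResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
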