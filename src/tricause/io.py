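"""Dataset, configuration and result readers/writers.

Datasets travel as plain CSV with the column contract
``patient_id,cluster_id,z,x,y0,y1,w0,w1[,u,y1_po_1,y1_po_0]``; the oracle
columns are only written on request and are firewalled from estimators on
read.  Scenario configurations round-trip through a flat YAML file (scalar
fields plus ``coef`` and ``flags`` sections); unknown keys are errors.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .scenarios import ScenarioConfig
from .simulate import AnalyticDataset, CORE_COLUMNS, ORACLE_COLUMNS


def read_dataset(path) -> AnalyticDataset:
    """Read and validate an analytic dataset CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return AnalyticDataset(frame)


def write_dataset(data: AnalyticDataset, path, oracle: bool = False) -> None:
    """Write a dataset CSV; oracle columns only with ``oracle=True``."""
    cols = list(CORE_COLUMNS)
    if oracle:
        if not data.has_oracle:
            raise ValueError("dataset carries no oracle columns to write")
        cols += ORACLE_COLUMNS
    data.frame[cols].to_csv(path, index=False)


def read_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config file must be a mapping")
    return ScenarioConfig.from_dict(raw)


def write_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_estimates(results, path) -> None:
    """Write a list of :class:`EffectResults` as a JSON array."""
    payload = [r.to_dict() for r in results]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_manifest(path, command: str, seed: int | None,
                   inputs: dict | None = None, outputs: list | None = None) -> None:
    """Run manifest: command, input hashes, seed, version, outputs."""
    hashes = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists():
            hashes[name] = {
                "path": str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": hashes,
        "outputs": [str(o) for o in (outputs or [])],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
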