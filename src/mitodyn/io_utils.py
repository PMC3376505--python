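"""Result serialization (CSV + JSON) and run records."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunRecord", "write_results", "read_scan_csv"]


@dataclass
class RunRecord:
    """Provenance attached to every emitted result file."""

    config_hash: str
    command: str = ""
    solver_stats: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "command": self.command,
            "solver_stats": self.solver_stats,
            "warnings": self.warnings,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
            "platform": platform.python_version(),
        }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(result, out_prefix: str | Path, record: RunRecord,
                  formats: tuple[str, ...] = ("csv", "json")) -> list[Path]:
    """Write a scan result (or any table-like result) to CSV and/or JSON.

    CSV columns are emitted in deterministic (sorted, swept-column-first)
    order with 12 significant digits; JSON round-trips bit-exactly.
    Collapse cells are serialized with an explicit ``converged`` flag, never
    omitted.  Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    if "csv" in formats:
        p = out_prefix.with_suffix(".csv")
        frame.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    if "json" in formats:
        p = out_prefix.with_suffix(".json")
        payload = {
            "run_record": record.to_dict(),
            "data": _jsonable(frame.to_dict(orient="list")),
        }
        if hasattr(result, "extra_json"):
            payload.update(_jsonable(result.extra_json()))
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(p)
    return written


def read_scan_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
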