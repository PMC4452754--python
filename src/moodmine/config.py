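"""Run configuration and reproducibility manifest.

A single YAML file with per-stage sections configures a full run; every
parameter plus the master seed and derived per-stage child seeds are echoed
into a JSON run manifest alongside digests of the artifacts written, so any
output can be regenerated from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import version, PackageNotFoundError

import yaml

from .cohort import _STAGES, child_seed

__all__ = ["default_config", "load_config", "save_config", "RunManifest"]


def default_config() -> dict:
    return {
        "seed": 0,
        "cohort": {
            "n": 27_704,
            "mode": "model",
            "target_prevalence": 0.121,
        },
        "notes": {
            "misspelling_rate": 0.1,
            "documentation_sensitivity": 1.0,
            "notes_per_patient": [2, 4],
            "window_days": 30,
        },
        "gazetteer": {"top_k": 10, "window": 2},
        "classifier": {
            "target_precision": 0.90,
            "active_learning_k": 100,
            "C": 1.0,
            "initial_frac": 0.5,
        },
        "aggregation": {"window_days": 30, "lookback_days": 0},
        "analysis": {"windows": [12, 24, 36, 48, 60], "include_zinb": False},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    child_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, config: dict, master_seed: int) -> "RunManifest":
        return cls(
            config=config,
            master_seed=master_seed,
            child_seeds={stage: child_seed(master_seed, stage) for stage in _STAGES},
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def record(self, name: str, path) -> None:
        self.artifacts[name] = {"path": str(path), "sha256": _digest(path)}

    def write(self, path) -> None:
        try:
            pkg_version = version("moodmine")
        except PackageNotFoundError:  # pragma: no cover
            pkg_version = "unknown"
        payload = {
            "package_version": pkg_version,
            "master_seed": self.master_seed,
            "child_seeds": self.child_seeds,
            "config": self.config,
            "artifacts": self.artifacts,
            "timestamp": self.timestamp,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
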