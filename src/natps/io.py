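"""Run configuration, archives and manifests.

A run is described by a small YAML file with two sections, ``model`` and
``run``; every key has a default, unknown keys are rejected.  Archives are
self-describing directories holding a JSON manifest next to a single
``.npz`` container with all numeric fields at full precision, so a finished
run can be reloaded (or re-created bit-for-bit from its manifest and seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from natps import __version__
from natps.integrator import HopEvent, Trajectory
from natps.model import ModelParams
from natps.tps import PathEnsemble, ShotRecord, TPSConfig

ARCHIVE_VERSION = 1

_MODEL_KEYS = {"epsilon", "x0", "Vc", "mass"}
_RUN_KEYS = {
    "temperature",
    "n_paths",
    "alpha",
    "dt",
    "max_steps_per_side",
    "burn_in_fraction",
    "seed",
    "n_sub",
    "reverse_accept",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated model + run configuration."""

    model: ModelParams
    tps: TPSConfig


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")


def config_from_dict(data: dict) -> RunConfig:
    """Build a configuration from nested mappings, applying all defaults."""
    data = dict(data or {})
    _check_keys("top level", data, {"model", "run"})
    model_map = dict(data.get("model") or {})
    run_map = dict(data.get("run") or {})
    _check_keys("model", model_map, _MODEL_KEYS)
    _check_keys("run", run_map, _RUN_KEYS)
    model = ModelParams(**model_map)
    run_map.setdefault("temperature", 12_000.0)
    tps = TPSConfig(**run_map)
    return RunConfig(model=model, tps=tps)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; errors name the bad key."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    data = {"model": asdict(config.model), "run": asdict(config.tps)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def make_manifest(config: RunConfig, command: str = "", extra: dict | None = None) -> dict:
    manifest = {
        "archive_version": ARCHIVE_VERSION,
        "code_version": __version__,
        "command": command,
        "model": asdict(config.model),
        "run": asdict(config.tps),
    }
    if extra:
        manifest.update(extra)
    return manifest


def _hops_to_arrays(hops) -> dict:
    return {
        "hop_t": np.array([h.t for h in hops]),
        "hop_q": np.array([h.q for h in hops]),
        "hop_phi": np.array([h.phi for h in hops]),
        "hop_up": np.array([h.direction == "up" for h in hops], dtype=bool),
        "hop_frustrated": np.array([h.frustrated for h in hops], dtype=bool),
    }


def _hops_from_arrays(d: dict, prefix: str = "hop_") -> list[HopEvent]:
    return [
        HopEvent(
            t=float(t),
            q=float(q),
            phi=float(phi),
            direction="up" if up else "down",
            frustrated=bool(fr),
        )
        for t, q, phi, up, fr in zip(
            d[prefix + "t"], d[prefix + "q"], d[prefix + "phi"], d[prefix + "up"], d[prefix + "frustrated"]
        )
    ]


def write_archive(obj, path, manifest: dict | None = None) -> None:
    """Write a :class:`Trajectory` or :class:`PathEnsemble` archive directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest or {})
    manifest.setdefault("archive_version", ARCHIVE_VERSION)
    manifest.setdefault("code_version", __version__)

    if isinstance(obj, Trajectory):
        manifest["kind"] = "trajectory"
        arrays = {
            "t": obj.t,
            "q": obj.q,
            "p": obj.p,
            "c": obj.c,
            "active": obj.active,
            "dt": np.array(obj.dt),
            **_hops_to_arrays(obj.hops),
        }
    elif isinstance(obj, PathEnsemble):
        manifest["kind"] = "ensemble"
        manifest["run"] = manifest.get("run", asdict(obj.config))
        manifest["burn_in"] = int(obj.burn_in)
        manifest["total_steps_generated"] = int(obj.total_steps_generated)
        offsets = np.cumsum([0] + [len(p) for p in obj.paths])
        hops = [h for p in obj.paths for h in p.hops]
        hop_path = np.array([i for i, p in enumerate(obj.paths) for _ in p.hops], dtype=np.int64)
        arrays = {
            "t": np.concatenate([p.t for p in obj.paths]),
            "q": np.concatenate([p.q for p in obj.paths]),
            "p": np.concatenate([p.p for p in obj.paths]),
            "c": np.concatenate([p.c for p in obj.paths]),
            "active": np.concatenate([p.active for p in obj.paths]),
            "offsets": offsets,
            "dt": np.array(obj.config.dt),
            "chain": obj.chain,
            "rec_index": np.array([r.shoot_index for r in obj.records], dtype=np.int64),
            "rec_accepted": np.array([r.accepted for r in obj.records], dtype=bool),
            "rec_steps": np.array([r.steps_generated for r in obj.records], dtype=np.int64),
            "hop_path": hop_path,
            **_hops_to_arrays(hops),
        }
    else:
        raise TypeError(f"cannot archive object of type {type(obj).__name__}")

    np.savez(path / "data.npz", **arrays)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_archive(path):
    """Read an archive directory back into its in-memory object.

    Returns (object, manifest).  Raises on a missing or corrupt archive or
    an unknown archive version.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    data_path = path / "data.npz"
    if not manifest_path.exists() or not data_path.exists():
        raise FileNotFoundError(f"not an archive directory (missing manifest or data): {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    version = manifest.get("archive_version")
    if version != ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {version!r} (expected {ARCHIVE_VERSION})")
    try:
        d = dict(np.load(data_path, allow_pickle=False))
    except Exception as exc:
        raise ValueError(f"corrupt archive data in {data_path}: {exc}") from exc

    if manifest.get("kind") == "trajectory":
        return (
            Trajectory(
                t=d["t"], q=d["q"], p=d["p"], c=d["c"], active=d["active"],
                dt=float(d["dt"]), hops=_hops_from_arrays(d),
            ),
            manifest,
        )
    if manifest.get("kind") == "ensemble":
        offsets = d["offsets"]
        all_hops = _hops_from_arrays(d)
        hop_path = d["hop_path"]
        paths = []
        for i in range(len(offsets) - 1):
            lo, hi = offsets[i], offsets[i + 1]
            hops = [h for h, owner in zip(all_hops, hop_path) if owner == i]
            paths.append(
                Trajectory(
                    t=d["t"][lo:hi], q=d["q"][lo:hi], p=d["p"][lo:hi], c=d["c"][lo:hi],
                    active=d["active"][lo:hi], dt=float(d["dt"]), hops=hops,
                )
            )
        records = [
            ShotRecord(int(i), bool(a), int(s))
            for i, a, s in zip(d["rec_index"], d["rec_accepted"], d["rec_steps"])
        ]
        run = dict(manifest.get("run", {}))
        config = TPSConfig(**{k: v for k, v in run.items() if k in _RUN_KEYS})
        ensemble = PathEnsemble(
            paths=paths,
            chain=d["chain"],
            records=records,
            total_steps_generated=int(manifest["total_steps_generated"]),
            burn_in=int(manifest["burn_in"]),
            config=config,
        )
        return ensemble, manifest
    raise ValueError(f"unknown archive kind {manifest.get('kind')!r}")
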