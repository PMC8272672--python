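"""Run configuration: loading, validation, seeding, logging.

A run is described by a nested YAML/JSON document with sections
``phantom``, ``backbone``, ``head``, ``fusion`` (RBM training) and
``experiment``, plus a single global ``seed`` and an ``outdir``.  Unknown
keys are rejected with the full dotted key path; every section validates
through its module's dataclass.  The single global seed deterministically
derives per-module substreams, so one integer reproduces an entire run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import zlib

import yaml

from . import backbone as bb
from . import energy_fusion as ef
from .errors import ConfigurationError
from .phantom import PhantomConfig
from .pipeline import ExperimentConfig, TaskSpec

__all__ = ["RunConfig", "load_config", "dump_config", "derive_seed",
           "setup_logging"]


def derive_seed(global_seed: int, name: str) -> int:
    """Deterministic per-module substream seed (< 2^31)."""
    return (int(global_seed) * 2654435761 + zlib.crc32(name.encode())) % (2 ** 31)


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomConfig
    backbone: bb.BackboneConfig
    experiment: ExperimentConfig
    task: TaskSpec
    seed: int = 0
    outdir: str = "runs"


_SECTION_FIELDS = {
    "phantom": {f.name for f in dataclasses.fields(PhantomConfig)},
    "backbone": {f.name for f in dataclasses.fields(bb.BackboneConfig)},
    "fusion": {f.name for f in dataclasses.fields(ef.TrainConfig)},
    "head": {"pool_size", "deep_dim"},
    "task": {"task", "plane"},
}
_TOP_KEYS = set(_SECTION_FIELDS) | {"seed", "outdir"}


def _check_keys(section: str, given: dict) -> None:
    allowed = _SECTION_FIELDS[section]
    for key in given:
        if key not in allowed:
            raise ConfigurationError(f"unknown config key {section}.{key}")


def _coerce(raw: dict) -> RunConfig:
    for key in raw:
        if key not in _TOP_KEYS:
            raise ConfigurationError(f"unknown config key {key}")
    seed = int(raw.get("seed", 0))
    sections = {name: dict(raw.get(name, {}) or {}) for name in _SECTION_FIELDS}
    for name, given in sections.items():
        _check_keys(name, given)

    phantom_kw = sections["phantom"]
    phantom_kw.setdefault("seed", derive_seed(seed, "phantom"))
    phantom = PhantomConfig(**phantom_kw)

    backbone_kw = sections["backbone"]
    backbone_kw.setdefault("seed", derive_seed(seed, "backbone"))
    if "block_range" in backbone_kw:
        backbone_kw["block_range"] = tuple(backbone_kw["block_range"])
    if "channels" in backbone_kw:
        backbone_kw["channels"] = tuple(backbone_kw["channels"])
    backbone = bb.BackboneConfig(**backbone_kw)

    fusion_kw = sections["fusion"]
    fusion_kw.setdefault("seed", derive_seed(seed, "fusion"))
    fusion_kw.setdefault("log_exact_likelihood", False)
    fusion_kw.setdefault("n_hidden", 24)
    fusion_kw.setdefault("epochs", 30)
    train = ef.TrainConfig(**fusion_kw)

    head_kw = sections["head"]
    experiment = ExperimentConfig(
        backbone=backbone,
        pool_size=int(head_kw.get("pool_size", 8)),
        deep_dim=int(head_kw.get("deep_dim", 64)),
        train=train,
        seed=seed,
    )
    task = TaskSpec(**sections["task"]) if sections["task"] else TaskSpec()
    return RunConfig(phantom=phantom, backbone=backbone, experiment=experiment,
                     task=task, seed=seed, outdir=str(raw.get("outdir", "runs")))


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; ``None`` gives all defaults."""
    raw: dict = {}
    if path is not None:
        if not os.path.exists(path):
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            text = fh.read()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config root must be a mapping")
        raw = loaded
    for key, val in (overrides or {}).items():
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return _coerce(raw)


def _clean(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig) -> dict:
    """Effective config in the input schema; reloadable via load_config."""
    return {
        "seed": cfg.seed,
        "outdir": cfg.outdir,
        "phantom": _clean(cfg.phantom),
        "backbone": _clean(cfg.backbone),
        "fusion": _clean(cfg.experiment.train),
        "head": {"pool_size": cfg.experiment.pool_size,
                 "deep_dim": cfg.experiment.deep_dim},
        "task": _clean(cfg.task),
    }


def echo_config(cfg: RunConfig, outdir: str) -> str:
    """Write the effective config (with package version) next to outputs."""
    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, "effective_config.json")
    with open(path, "w") as fh:
        json.dump({"version": __version__, "config": dump_config(cfg)}, fh, indent=2)
    return path


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
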