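"""Structured run configuration with strict validation.

A :class:`RunConfig` mirrors each stage's defaults; unknown keys are
rejected and every threshold is checked against its documented domain
before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .model import InputError
from .qc import QcThresholds
from .simulate import Interval, Knockout, TissueModel

__all__ = ["RunConfig", "ValidationError", "load_config", "config_hash"]

STAGES = ("simulate", "qc", "signatures", "assign", "graph")


class ValidationError(InputError):
    """Configuration fails its domain checks."""


@dataclass
class SimulateConfig:
    n_singles: int = 700
    n_clusters: int = 700
    condition: str = "control"
    model: TissueModel = field(default_factory=TissueModel)


@dataclass
class SignatureConfig:
    logfc_min: float = 0.25
    padj_max: float = 0.05
    top_n: int = 20


@dataclass
class AssignConfig:
    r_min: float = 0.6
    p_max: float = 0.01
    n_perm: int = 1000
    n_groups: int | None = None
    height: float | None = None
    # consensus over grouping resolutions (None: single grouping pass)
    resolutions: tuple[int, ...] | None = (6, 8, 10, 12, 14, 16, 18)


@dataclass
class GraphConfig:
    min_support: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    signatures: SignatureConfig = field(default_factory=SignatureConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValidationError("stages must respect pipeline order")
        sig = self.signatures
        if not 0 < sig.padj_max <= 1:
            raise ValidationError(f"padj_max={sig.padj_max} outside (0, 1]")
        if sig.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        a = self.assign
        if not -1 <= a.r_min <= 1:
            raise ValidationError(f"r_min={a.r_min} outside [-1, 1]")
        if not 0 < a.p_max <= 1:
            raise ValidationError(f"p_max={a.p_max} outside (0, 1]")
        if a.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if a.resolutions is not None:
            if len(a.resolutions) == 0 or any(r < 2 for r in a.resolutions):
                raise ValidationError("assign.resolutions must be integers >= 2")
        elif (a.n_groups is None) == (a.height is None):
            raise ValidationError(
                "set exactly one of assign.n_groups / assign.height "
                "(or use assign.resolutions)"
            )
        if self.graph.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if self.simulate.n_singles < 0 or self.simulate.n_clusters < 0:
            raise ValidationError("library counts must be >= 0")


def _build(cls, data: dict, path: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    kwargs = {}
    for name, value in data.items():
        if name == "model" and isinstance(value, dict):
            value = _build_model(value, f"{path}.model")
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except InputError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"invalid value under {path!r}: {exc}") from exc


def _build_model(data: dict, path: str) -> TissueModel:
    data = dict(data)
    if "domain_layout" in data:
        data["domain_layout"] = tuple(
            Interval(int(iv[0]), float(iv[1]), float(iv[2]))
            for iv in data["domain_layout"]
        )
    if "knockout" in data and data["knockout"] is not None:
        ko = data["knockout"]
        data["knockout"] = Knockout(
            int(ko["removed_state"]),
            (int(ko["hybrid_pair"][0]), int(ko["hybrid_pair"][1])),
        )
    allowed = {f.name for f in fields(TissueModel)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    try:
        return TissueModel(**data)
    except InputError as exc:
        raise ValidationError(str(exc)) from exc


def load_config(source) -> RunConfig:
    """Load and validate a RunConfig from a YAML path, mapping, or None."""
    if source is None:
        cfg = RunConfig()
    elif isinstance(source, dict):
        cfg = _from_mapping(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config root must be a mapping")
        cfg = _from_mapping(data)
    cfg.validate()
    return cfg


def _from_mapping(data: dict) -> RunConfig:
    data = dict(data)
    sections = {
        "simulate": SimulateConfig,
        "qc": QcThresholds,
        "signatures": SignatureConfig,
        "assign": AssignConfig,
        "graph": GraphConfig,
    }
    allowed = {"seed", "out_dir", "stages", *sections}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    if "stages" in data:
        kwargs["stages"] = tuple(data["stages"])
    for key, cls in sections.items():
        if key in data:
            try:
                kwargs[key] = _build(cls, dict(data[key] or {}), key)
            except InputError:
                raise
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the run parameters (output location excluded)."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        return obj

    payload = encode(cfg)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
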