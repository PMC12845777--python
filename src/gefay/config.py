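"""YAML run configuration: one source of truth for model, attention and
training settings.

``load_config`` fills defaults, validates every field, and reports
violations with the precise key path (e.g. ``attention.variant``).
``dump_config`` emits the fully-resolved document; load -> dump -> load
is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .attention import VARIANTS, AttentionSpec, EcaKernelPolicy
from .loss import LossWeights
from .model import ALL_SLOTS, DEFAULT_ANCHORS, ModelSpec
from .train import TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "loads_config",
           "dump_config"]


class ConfigError(ValueError):
    """A schema violation; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    model: ModelSpec
    train: TrainConfig
    data_root: str = "data/synth"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        import hashlib
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:12]


def _get(section: dict, key: str, default, caster, path: str):
    if key not in section:
        return default
    raw = section.pop(key)
    try:
        return caster(raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}.{key}: {e}") from None


def _expect_mapping(doc, key: str) -> dict:
    sec = doc.pop(key, {}) or {}
    if not isinstance(sec, dict):
        raise ConfigError(f"{key}: expected a mapping, got {type(sec).__name__}")
    return dict(sec)


def _no_leftovers(section: dict, path: str):
    if section:
        raise ConfigError(f"{path}.{next(iter(section))}: unknown key")


def loads_config(text: str) -> RunConfig:
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("top level: expected a mapping")

    att = _expect_mapping(doc, "attention")
    variant = _get(att, "variant", "none", str, "attention")
    if variant not in VARIANTS:
        raise ConfigError(f"attention.variant: unknown variant {variant!r}; "
                          f"expected one of {VARIANTS}")
    policy = EcaKernelPolicy(
        gamma=_get(att, "gamma", 2.0, float, "attention"),
        b=_get(att, "b", 2.0, float, "attention"),
        min_k=_get(att, "min_k", 3, int, "attention"),
    )
    try:
        attention = AttentionSpec(
            variant=variant,
            groups=_get(att, "groups", 8, int, "attention"),
            local_grid=_get(att, "local_grid", 5, int, "attention"),
            reduction=_get(att, "reduction", None,
                           lambda v: None if v is None else int(v), "attention"),
            kernel_policy=policy,
            group_kernel=_get(att, "group_kernel", 1, int, "attention"),
            group_width_factor=_get(att, "group_width_factor", 1.625, float,
                                    "attention"),
            share_mixer=_get(att, "share_mixer", True, bool, "attention"),
        )
    except ValueError as e:
        raise ConfigError(f"attention: {e}") from None
    _no_leftovers(att, "attention")

    mod = _expect_mapping(doc, "model")
    placement = _get(mod, "attention_placement", list(ALL_SLOTS),
                     lambda v: [str(s) for s in v], "model")
    anchors = _get(mod, "anchors", DEFAULT_ANCHORS,
                   lambda v: tuple(tuple(tuple(map(float, a)) for a in scale)
                                   for scale in v), "model")
    try:
        model = ModelSpec(
            nc=_get(mod, "nc", 12, int, "model"),
            depth_multiple=_get(mod, "depth_multiple", 0.33, float, "model"),
            width_multiple=_get(mod, "width_multiple", 0.50, float, "model"),
            input_size=_get(mod, "input_size", 640, int, "model"),
            anchors=anchors,
            attention=attention,
            attention_placement=tuple(placement),
        )
    except ValueError as e:
        raise ConfigError(f"model: {e}") from None
    _no_leftovers(mod, "model")

    tr = _expect_mapping(doc, "train")
    lw = _expect_mapping(tr, "loss_weights") if "loss_weights" in tr else {}
    weights = LossWeights(
        box=_get(lw, "box", 0.05, float, "train.loss_weights"),
        obj=_get(lw, "obj", 1.0, float, "train.loss_weights"),
        cls=_get(lw, "cls", 0.5, float, "train.loss_weights"),
        anchor_t=_get(lw, "anchor_t", 4.0, float, "train.loss_weights"),
    )
    _no_leftovers(lw, "train.loss_weights")
    epochs = _get(tr, "epochs", 300, int, "train")
    try:
        train = TrainConfig(
            epochs=epochs,
            batch_size=_get(tr, "batch_size", 40, int, "train"),
            lr=_get(tr, "lr", 0.01, float, "train"),
            momentum=_get(tr, "momentum", 0.937, float, "train"),
            optimizer=_get(tr, "optimizer", "sgd", str, "train"),
            early_stop_patience=_get(tr, "early_stop_patience",
                                     min(100, epochs), int, "train"),
            image_size=_get(tr, "image_size", 640, int, "train"),
            seed=_get(tr, "seed", 0, int, "train"),
            weight_decay=_get(tr, "weight_decay", 0.0005, float, "train"),
            warmup_steps=_get(tr, "warmup_steps", 50, int, "train"),
            augment=_get(tr, "augment", True, bool, "train"),
            conf_thresh=_get(tr, "conf_thresh", 0.001, float, "train"),
            iou_thresh=_get(tr, "iou_thresh", 0.45, float, "train"),
            eval_every=_get(tr, "eval_every", 1, int, "train"),
            loss_weights=weights,
        )
    except ValueError as e:
        raise ConfigError(f"train: {e}") from None
    _no_leftovers(tr, "train")

    cfg = RunConfig(
        model=model,
        train=train,
        data_root=_get(doc, "data_root", "data/synth", str, ""),
        seed=_get(doc, "seed", 0, int, ""),
        log_level=_get(doc, "log_level", "INFO", str, ""),
    )
    _no_leftovers(doc, "")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return loads_config(p.read_text())


def dump_config(cfg: RunConfig) -> str:
    a = cfg.model.attention
    doc = {
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "data_root": cfg.data_root,
        "model": {
            "nc": cfg.model.nc,
            "depth_multiple": cfg.model.depth_multiple,
            "width_multiple": cfg.model.width_multiple,
            "input_size": cfg.model.input_size,
            "anchors": [[[float(v) for v in x] for x in s]
                        for s in cfg.model.anchors],
            "attention_placement": list(cfg.model.attention_placement),
        },
        "attention": {
            "variant": a.variant,
            "groups": a.groups,
            "local_grid": a.local_grid,
            "reduction": a.reduction,
            "gamma": a.kernel_policy.gamma,
            "b": a.kernel_policy.b,
            "min_k": a.kernel_policy.min_k,
            "group_kernel": a.group_kernel,
            "group_width_factor": a.group_width_factor,
            "share_mixer": a.share_mixer,
        },
        "train": {
            "epochs": cfg.train.epochs,
            "batch_size": cfg.train.batch_size,
            "lr": cfg.train.lr,
            "momentum": cfg.train.momentum,
            "optimizer": cfg.train.optimizer,
            "early_stop_patience": cfg.train.early_stop_patience,
            "image_size": cfg.train.image_size,
            "seed": cfg.train.seed,
            "weight_decay": cfg.train.weight_decay,
            "warmup_steps": cfg.train.warmup_steps,
            "augment": cfg.train.augment,
            "conf_thresh": cfg.train.conf_thresh,
            "iou_thresh": cfg.train.iou_thresh,
            "eval_every": cfg.train.eval_every,
            "loss_weights": {
                "box": cfg.train.loss_weights.box,
                "obj": cfg.train.loss_weights.obj,
                "cls": cfg.train.loss_weights.cls,
                "anchor_t": cfg.train.loss_weights.anchor_t,
            },
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
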