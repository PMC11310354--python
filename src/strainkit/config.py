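"""YAML run configuration with strict key checking and overrides."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import yaml

from .synthetic import DeformationRanges, NoiseParams, SpeckleParams
from .types import LoadProtocol

__all__ = ["load_config", "RunConfig"]

_SCHEMA: dict[str, set[str]] = {
    "image": {"height", "width", "grain_sigma", "base_level", "contrast",
              "band_center_frac", "band_halfwidth_frac", "band_gain"},
    "geometry": {"superficial_ratio", "band_center_frac",
                 "band_halfwidth_frac"},
    "deformation": {"tension", "compression", "rigid_shift"},
    "noise": {"speckle_var", "additive_sigma", "gain", "offset", "scale"},
    "protocol": {"ramp_s", "hold_s", "relax_s"},
    "counts": {"n_pairs", "class_mix", "levels", "fps"},
    "training": {"profile", "epochs", "learning_rate", "batch_classifier",
                 "batch_regressor", "val_fraction"},
}
_TOP_LEVEL = set(_SCHEMA) | {"seed", "verbosity", "out_dir"}


def _check_keys(block: str, given: dict) -> None:
    allowed = _SCHEMA[block]
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in config block {block!r}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


def _set_nested(cfg: dict, dotted: str, value: str) -> None:
    keys = dotted.split(".")
    node = cfg
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    node[keys[-1]] = yaml.safe_load(value)


class RunConfig:
    """Parsed run configuration; block accessors build the domain records."""

    def __init__(self, raw: dict[str, Any]):
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        for block in _SCHEMA:
            if block in raw:
                if not isinstance(raw[block], dict):
                    raise ValueError(f"config block {block!r} must be a mapping")
                _check_keys(block, raw[block])
        self.raw = raw
        self.seed = int(raw.get("seed", 0))

    def _block(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    @property
    def image_shape(self) -> tuple[int, int]:
        blk = self._block("image")
        return int(blk.get("height", 64)), int(blk.get("width", 64))

    def speckle_params(self) -> SpeckleParams:
        blk = self._block("image")
        blk.pop("height", None)
        blk.pop("width", None)
        return SpeckleParams(**blk)

    def noise_params(self) -> NoiseParams:
        blk = self._block("noise")
        scale = blk.pop("scale", 1.0)
        blk = {k: tuple(v) for k, v in blk.items()}
        return NoiseParams(**blk).scaled(scale)

    def deformation_ranges(self) -> DeformationRanges:
        blk = self._block("deformation")
        for k in ("tension", "compression"):
            if k in blk:
                blk[k] = tuple(blk[k])
        return DeformationRanges(**blk)

    def protocol(self) -> LoadProtocol:
        return LoadProtocol(**self._block("protocol"))

    def geometry_kwargs(self) -> dict:
        return self._block("geometry")

    def counts(self) -> dict:
        blk = self._block("counts")
        return {
            "n_pairs": int(blk.get("n_pairs", 300)),
            "class_mix": tuple(blk.get("class_mix", (1 / 3, 1 / 3, 1 / 3))),
            "levels": tuple(blk.get("levels", (0.04, 0.07, 0.10, 0.13, 0.16))),
            "fps": float(blk.get("fps", 2.0)),
        }

    def training_kwargs(self) -> dict:
        return self._block("training")


def load_config(
    path: str | Path | None = None,
    overrides: Sequence[str] = (),
) -> RunConfig:
    """Load a YAML config; apply ``key.path=value`` overrides."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a YAML mapping")
            raw = loaded
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, value = item.split("=", 1)
        _set_nested(raw, key, value)
    return RunConfig(raw)
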