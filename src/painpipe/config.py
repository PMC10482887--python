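"""YAML run configuration with strict key validation.

A run config has nested sections mirroring the pipeline stages; unknown
keys are rejected so typos never silently fall back to defaults. Every
run directory stores a serialized snapshot of the config plus the seed,
which together reproduce the run bit-identically for deterministic
backends.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .synthetic import SyntheticConfig


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "synthetic": {f.name for f in dataclasses.fields(SyntheticConfig)},
    "sampling": {"sample_interval_s", "max_duration_s"},
    "detector": {"kind", "threshold"},
    "crop": {"pad_frac", "out_size"},
    "grayst": {"enabled", "stride"},
    "backend": {"kind", "grid", "histogram_bins"},
    "selection": {"n"},
    "evaluation": {"n_val", "seed", "grayst_grid"},
}


@dataclasses.dataclass
class RunConfig:
    synthetic: SyntheticConfig
    pipeline: PipelineConfig
    n_val: int = 4
    seed: int = 0
    grayst_grid: bool = True  # evaluate both GrayST on and off
    source_path: str | None = None

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self.synthetic)
        d["frame_size"] = list(d["frame_size"])
        p = dataclasses.asdict(self.pipeline)
        p["out_size"] = list(p["out_size"])
        return {
            "synthetic": d,
            "pipeline": p,
            "n_val": self.n_val,
            "seed": self.seed,
            "grayst_grid": self.grayst_grid,
        }


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SECTIONS[section]
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or flat overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown_sections = set(raw) - set(_SECTIONS)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, mapping in raw.items():
        if not isinstance(mapping, dict):
            raise ConfigError(f"section [{section}] must be a mapping")
        _check_keys(section, mapping)
    if overrides:
        for dotted, value in overrides.items():
            section, _, key = dotted.partition(".")
            if section not in _SECTIONS or key not in _SECTIONS[section]:
                raise ConfigError(f"unknown override {dotted!r}")
            raw.setdefault(section, {})[key] = value

    syn_kwargs = dict(raw.get("synthetic", {}))
    if "frame_size" in syn_kwargs:
        syn_kwargs["frame_size"] = tuple(syn_kwargs["frame_size"])
    synthetic = SyntheticConfig(**syn_kwargs)

    pipe_kwargs: dict = {}
    pipe_kwargs.update(raw.get("sampling", {}))
    det = raw.get("detector", {})
    if "kind" in det:
        pipe_kwargs["detector_kind"] = det["kind"]
    if "threshold" in det:
        pipe_kwargs["detector_threshold"] = det["threshold"]
    crop = raw.get("crop", {})
    if "pad_frac" in crop:
        pipe_kwargs["pad_frac"] = crop["pad_frac"]
    if "out_size" in crop:
        pipe_kwargs["out_size"] = tuple(crop["out_size"])
    gs = raw.get("grayst", {})
    if "enabled" in gs:
        pipe_kwargs["grayst_enabled"] = bool(gs["enabled"])
    if "stride" in gs:
        pipe_kwargs["grayst_stride"] = gs["stride"]
    be = raw.get("backend", {})
    if "kind" in be:
        pipe_kwargs["backend_kind"] = be["kind"]
    if "grid" in be:
        pipe_kwargs["backend_grid"] = be["grid"]
    if "histogram_bins" in be:
        pipe_kwargs["backend_histogram_bins"] = be["histogram_bins"]
    if "n" in raw.get("selection", {}):
        pipe_kwargs["selection_n"] = raw["selection"]["n"]
    pipeline = PipelineConfig(**pipe_kwargs)

    ev = raw.get("evaluation", {})
    return RunConfig(
        synthetic=synthetic,
        pipeline=pipeline,
        n_val=int(ev.get("n_val", 4)),
        seed=int(ev.get("seed", synthetic.seed)),
        grayst_grid=bool(ev.get("grayst_grid", True)),
        source_path=str(path) if path is not None else None,
    )
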