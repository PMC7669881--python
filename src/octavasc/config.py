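"""Structured pipeline configuration (YAML).

A config file has up to five blocks -- ``geometry``, ``preprocessing``,
``morphometry``, ``phantom`` and ``output`` -- with a fixed vocabulary
of keys; unknown keys are rejected so that typos cannot silently
disable a step.  Every CLI run writes the fully resolved configuration
next to its outputs, which together with the seed makes the run
reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .volume import AcquisitionGeometry

__all__ = ["PipelineConfig", "load_config", "dump_config"]

_ALLOWED = {
    "geometry": {"fov_mm", "dims"},
    "preprocessing": {
        "wiener",
        "wiener_kernel",
        "wiener_axis",
        "cap",
        "cap_k",
        "rescale",
        "nlm",
        "nlm_patch",
        "nlm_search",
        "nlm_h",
    },
    "morphometry": {"probe_file", "line_width", "n_spline", "page_axis"},
    "phantom": {
        "background_level",
        "layer_stack",
        "speckle_contrast",
        "detector_noise_sd",
        "edge_smooth_voxels",
        "lumen_level",
        "vessels",
        "seed",
    },
    "output": {"directory"},
}


@dataclass
class PipelineConfig:
    geometry: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def acquisition_geometry(self) -> AcquisitionGeometry:
        if "fov_mm" not in self.geometry or "dims" not in self.geometry:
            raise ValueError(
                "config geometry block must provide fov_mm and dims "
                "(per-axis field of view in mm and sample counts)"
            )
        return AcquisitionGeometry(
            fov_mm=tuple(self.geometry["fov_mm"]), dims=tuple(self.geometry["dims"])
        )


def _validate(raw: dict) -> None:
    unknown_blocks = set(raw) - set(_ALLOWED)
    if unknown_blocks:
        raise ValueError(f"unknown config blocks: {sorted(unknown_blocks)}")
    for block, keys in raw.items():
        if keys is None:
            continue
        extra = set(keys) - _ALLOWED[block]
        if extra:
            raise ValueError(f"unknown keys in config block {block!r}: {sorted(extra)}")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    _validate(raw)
    return PipelineConfig(**{k: (v or {}) for k, v in raw.items()})


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the resolved configuration next to the run outputs."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
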