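"""Run configuration: defaults, YAML loading, validation, scaling, hashing.

A :class:`RunConfig` bundles everything one simulated QA experiment needs:
phantom layout, acquisition protocol, reconstruction parameters, the
repeatability design (days x scans/day), the noise level, and seeds.  The
defaults are the reference protocol (FOV 38.4 cm, 15,460 spokes, TR 5 ms,
TE 0.5 ms, FA 30 deg, 12 averages, 1.5 mm reconstruction).

``scaled(s)`` produces a desk-scale configuration: grid shapes and spoke
count shrink by s while the FOV is preserved; voxel sizes (and hence 1/kmax)
grow by 1/s so the sampling geometry stays self-consistent.  s = 0.25 gives
a ~64^3 reconstruction with ~3,800 spokes, the size used for fast end-to-end
experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .acquisition import AcqParams
from .phantom import PhantomConfig
from .recon import ReconParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acq: AcqParams = field(default_factory=AcqParams)
    recon: ReconParams = field(default_factory=ReconParams)
    n_days: int = 3
    scans_per_day: int = 3
    target_snr: float = 79.0
    noise_sigma: float = 0.0          # per-repeat k-space noise SD
    drift_percent: float = 2.0        # per-day global intensity drift bound
    calibration_concentrations: tuple[float, ...] = (77.0, 38.5, 19.25, 9.625)
    seed: int = 0
    scale_factor: float = 1.0
    output_dir: str = "results"

    def scaled(self, scale: float) -> "RunConfig":
        """Desk-scale variant: grid shapes and n_spokes scaled by ``scale``,
        FOV preserved, resolutions scaled by 1/scale."""
        if not 0 < scale <= 1:
            raise ValueError("scale must lie in (0, 1]")
        if scale == 1.0:
            return replace(self, scale_factor=1.0)
        phantom = dataclasses.replace(
            self.phantom,
            grid_shape=tuple(max(8, int(round(n * scale)))
                             for n in self.phantom.grid_shape))
        acq = dataclasses.replace(
            self.acq,
            n_spokes=max(1, int(round(self.acq.n_spokes * scale))),
            nominal_resolution=self.acq.nominal_resolution / scale)
        rec = dataclasses.replace(
            self.recon, recon_resolution=self.recon.recon_resolution / scale)
        return replace(self, phantom=phantom, acq=acq, recon=rec,
                       scale_factor=scale)


_SECTION_TYPES = {"phantom": PhantomConfig, "acquisition": AcqParams,
                  "recon": ReconParams}
_TOP_KEYS = {"phantom", "acquisition", "recon", "n_days", "scans_per_day",
             "target_snr", "noise_sigma", "drift_percent",
             "calibration_concentrations", "seed", "scale_factor",
             "output_dir"}

# YAML aliases for dataclass field names (protocol vocabulary)
_ACQ_ALIASES = {"TR": "tr", "TE": "te", "FA": "flip_angle", "B0": "b0"}


def _build_section(cls, data: dict, section: str):
    from .phantom import RelaxationParams, VialSpec

    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        name = _ACQ_ALIASES.get(key, key) if cls is AcqParams else key
        if name not in fields:
            raise ValueError(f"unknown key {key!r} in section {section!r}")
        if name == "relaxation" and isinstance(value, dict):
            value = RelaxationParams(**value)
        elif name == "vials" and value is not None:
            value = [VialSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in spec.items()}) for spec in value]
        elif name == "vial_dimensions" and isinstance(value, dict):
            value = {k: tuple(v) for k, v in value.items()}
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration; missing keys take the protocol
    defaults, unknown keys are rejected by name."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs["acq" if section == "acquisition" else section] = \
                _build_section(cls, data[section] or {}, section)
    for key in _TOP_KEYS - set(_SECTION_TYPES):
        if key in data:
            value = data[key]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    # scale_factor in a file records the scale of the stored sections; it is
    # not re-applied here (use RunConfig.scaled or the CLI --scale flag).
    return RunConfig(**kwargs)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def save_config(config: RunConfig, path) -> None:
    data = _to_jsonable(config)
    data["acquisition"] = data.pop("acq")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable hash identifying a configuration (embedded in outputs)."""
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
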