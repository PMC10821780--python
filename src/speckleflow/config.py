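"""Run configuration: schema validation, preset resolution, provenance.

Configs are YAML or JSON mappings with a strict schema — unknown keys
are rejected and a seed is mandatory (no wall-clock seeding anywhere).
Instrument presets reproduce the three simulated systems (850 nm
Si-SPAD DCS, 1064 nm SNSPD DCS, 850 nm CMOS SCOS) and can be overridden
field by field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import instruments as instr
from .pipeline import MeasurementConfig

__all__ = ["RunConfig", "ConfigError", "load_and_validate_config", "provenance_block"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the key."""


_TOP_KEYS = {
    "schema_version", "seed", "technique", "wavelength_nm", "sds_mm",
    "detector", "laser", "fiber", "strategy", "fit_fraction", "t_exp",
    "s_over_p", "sample_rate", "n_realizations", "dark_count_rate",
    "per_mode_throughput_factor", "geometry", "sweep_preset", "out_dir",
}
_GEOMETRY_KEYS = {"extracerebral_mm", "sds_mm", "detector_radius_mm",
                  "detector_na", "n_photons"}


@dataclass(frozen=True)
class RunConfig:
    """A validated, fully resolved run description."""

    seed: int
    measurement: MeasurementConfig | None
    geometry: dict
    sweep_preset: str | None
    out_dir: str
    schema_version: int = SCHEMA_VERSION

    def resolved_dict(self) -> dict:
        """Fully explicit mapping (all defaults materialized) suitable for
        the provenance log; reloading it reproduces this object."""
        d: dict[str, Any] = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "geometry": dict(self.geometry),
            "sweep_preset": self.sweep_preset,
            "out_dir": self.out_dir,
        }
        if self.measurement is not None:
            m = self.measurement
            d.update({
                "technique": m.technique,
                "wavelength_nm": m.wavelength_nm,
                "sds_mm": m.sds_mm,
                "detector": dataclasses.asdict(m.detector),
                "laser": dataclasses.asdict(m.laser),
                "fiber": dataclasses.asdict(m.fiber),
                "strategy": m.strategy,
                "fit_fraction": m.fit_fraction,
                "t_exp": m.t_exp,
                "s_over_p": m.s_over_p,
                "sample_rate": m.sample_rate,
                "n_realizations": m.n_realizations,
                "dark_count_rate": m.dark_count_rate,
                "per_mode_throughput_factor": m.per_mode_throughput_factor,
            })
        return d


def _resolve_component(value, presets: Mapping[str, Any], cls, key: str):
    """A component is a preset name, or a mapping (optionally extending a
    preset via its 'preset' key), or absent (None)."""
    if value is None:
        return None
    if isinstance(value, str):
        if value not in presets:
            raise ConfigError(f"{key}: unknown preset {value!r}; "
                              f"choose from {sorted(presets)}")
        return presets[value]
    if isinstance(value, Mapping):
        value = dict(value)
        base = value.pop("preset", None)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(value) - fields
        if unknown:
            raise ConfigError(f"{key}.{unknown.pop()}: unknown field for {cls.__name__}")
        if base is not None:
            if base not in presets:
                raise ConfigError(f"{key}.preset: unknown preset {base!r}")
            return dataclasses.replace(presets[base], **value)
        try:
            return cls(**value)
        except TypeError as err:
            raise ConfigError(f"{key}: {err}") from err
    raise ConfigError(f"{key}: expected preset name or mapping, got {type(value).__name__}")


def load_and_validate_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config.

    Raises :class:`ConfigError` with the offending key path on unknown
    keys, type mismatches or constraint violations; a seed is required.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    if "seed" not in raw:
        raise ConfigError("seed: required (explicit seeding is mandatory)")
    if not isinstance(raw["seed"], int):
        raise ConfigError("seed: must be an integer")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: expected {SCHEMA_VERSION}")

    geometry = dict(raw.get("geometry") or {})
    g_unknown = set(geometry) - _GEOMETRY_KEYS
    if g_unknown:
        raise ConfigError(f"geometry.{sorted(g_unknown)[0]}: unknown key")

    measurement = None
    if "technique" in raw:
        detector = _resolve_component(raw.get("detector"), instr.DETECTOR_PRESETS,
                                      instr.DetectorModel, "detector")
        laser = _resolve_component(raw.get("laser"), instr.LASER_PRESETS,
                                   instr.LaserModel, "laser")
        fiber = _resolve_component(raw.get("fiber"), instr.FIBER_PRESETS,
                                   instr.FiberModel, "fiber")
        technique = raw["technique"]
        if technique == "dcs":
            wl = raw.get("wavelength_nm", 850.0)
            detector = detector or instr.DETECTOR_PRESETS[
                "dcs_850_sispad" if int(wl) == 850 else "dcs_1064_snspd"]
            laser = laser or instr.LASER_PRESETS[
                "laser_850" if int(wl) == 850 else "laser_1064"]
            fiber = fiber or instr.FIBER_PRESETS["single_mode_780hp"]
        else:
            wl = raw.get("wavelength_nm", 850.0)
            detector = detector or instr.DETECTOR_PRESETS["scos_850_cmos"]
            laser = laser or instr.LASER_PRESETS["laser_850"]
            fiber = fiber or instr.FIBER_PRESETS["bundle_2000x50um"]
        kwargs = {k: raw[k] for k in (
            "strategy", "fit_fraction", "t_exp", "s_over_p", "sample_rate",
            "n_realizations", "dark_count_rate", "per_mode_throughput_factor",
        ) if k in raw}
        if technique == "dcs":
            kwargs.setdefault("fit_fraction", 1.0)
        try:
            measurement = MeasurementConfig(
                technique=technique, wavelength_nm=float(wl),
                sds_mm=float(raw.get("sds_mm", 25.0)), detector=detector,
                laser=laser, fiber=fiber, seed=raw["seed"], **kwargs,
            )
        except (ValueError, TypeError) as err:
            raise ConfigError(str(err)) from err

    return RunConfig(
        seed=raw["seed"],
        measurement=measurement,
        geometry=geometry,
        sweep_preset=raw.get("sweep_preset"),
        out_dir=raw.get("out_dir", "."),
    )


def provenance_block(config: RunConfig, input_files: Mapping[str, str] | None = None) -> dict:
    """Provenance for a run: resolved config, seed, package version and
    SHA-256 of every input file."""
    from . import __version__

    hashes = {}
    for name, p in (input_files or {}).items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        hashes[name] = h.hexdigest()
    return {
        "resolved_config": config.resolved_dict(),
        "seed": config.seed,
        "code_version": __version__,
        "input_hashes": hashes,
    }
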