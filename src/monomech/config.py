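"""Declarative run configuration for the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .fields import MonolayerSpec, SubstrateSpec
from .piv import PIVConfig


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML.

    Defaults mirror the standard acquisition: 64 px / 0.5 overlap PIV on
    phase contrast, 32 px / 0.5 on beads, 10 min frame interval, 4 h
    early/late split.
    """

    beads: str = "beads.tif"
    reference: str = "beads_reference.tif"
    phase: str | None = None
    masks: str = "masks.tif"
    output_dir: str = "output"

    pixel_size: float = 0.65          # µm/px
    frame_interval: float = 10.0      # minutes
    split_time: float = 4.0           # hours

    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    monolayer: MonolayerSpec = field(default_factory=MonolayerSpec)
    piv_phase: PIVConfig = field(default_factory=lambda: PIVConfig(window=64))
    piv_beads: PIVConfig = field(default_factory=lambda: PIVConfig(window=32))

    regularization: float = 0.0
    mss_mode: str = "half-difference"
    ecc_mode: str = "eccentricity"
    kymo_side: str = "averaged"
    erosion_direction: str = "x"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "substrate" in kw:
            kw["substrate"] = SubstrateSpec(**kw["substrate"])
        if "monolayer" in kw:
            kw["monolayer"] = MonolayerSpec(**kw["monolayer"])
        for key in ("piv_phase", "piv_beads"):
            if key in kw:
                kw[key] = PIVConfig(**kw[key])
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def validate_config(config: RunConfig | dict, base_dir: str | Path = ".",
                    check_paths: bool = True) -> list[str]:
    """Schema and physical-sanity checks; returns a list of issues.

    Accepts either a built :class:`RunConfig` or a raw mapping (e.g. a
    parsed YAML file), so invalid physical values are reported rather
    than raised.
    """
    issues: list[str] = []
    if isinstance(config, dict):
        raw = config
        sub = raw.get("substrate", {})
        if sub.get("youngs_modulus", 1) <= 0:
            issues.append("substrate.youngs_modulus must be > 0")
        if not 0 <= sub.get("poisson", 0.457) <= 0.5:
            issues.append("substrate.poisson must lie in [0, 0.5]")
        if sub.get("thickness", 1) <= 0:
            issues.append("substrate.thickness must be > 0")
        mono = raw.get("monolayer", {})
        if mono.get("height", 1) <= 0:
            issues.append("monolayer.height must be > 0")
        for key in ("piv_phase", "piv_beads"):
            piv = raw.get(key, {})
            w = piv.get("window", 64)
            if w < 16 or (w & (w - 1)) != 0:
                issues.append(f"{key}.window must be a power of two >= 16")
            if not 0 <= piv.get("overlap", 0.5) < 1:
                issues.append(f"{key}.overlap must lie in [0, 1)")
        if issues:
            return issues
        try:
            config = RunConfig.from_dict(raw)
        except (TypeError, ValueError) as exc:
            return [str(exc)]
    base = Path(base_dir)
    if check_paths:
        for name in ("beads", "reference", "masks", "phase"):
            p = getattr(config, name)
            if p is None:
                continue
            if not (base / p).exists():
                issues.append(f"{name} path not found: {p}")
    if config.pixel_size <= 0:
        issues.append("pixel_size must be > 0")
    if config.frame_interval <= 0:
        issues.append("frame_interval must be > 0")
    if config.regularization < 0:
        issues.append("regularization must be >= 0")
    for name, piv in (("piv_phase", config.piv_phase),
                      ("piv_beads", config.piv_beads)):
        if piv.window < 16:
            issues.append(f"{name}.window must be >= 16")
        if not 0 <= piv.overlap < 1:
            issues.append(f"{name}.overlap must lie in [0, 1)")
    if config.mss_mode not in ("half-difference", "difference"):
        issues.append(f"unknown mss_mode {config.mss_mode!r}")
    if config.ecc_mode not in ("eccentricity", "ratio"):
        issues.append(f"unknown ecc_mode {config.ecc_mode!r}")
    if config.kymo_side not in ("left", "right", "averaged"):
        issues.append(f"unknown kymo_side {config.kymo_side!r}")
    if config.erosion_direction not in ("x", "iso"):
        issues.append(f"unknown erosion_direction {config.erosion_direction!r}")
    return issues
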