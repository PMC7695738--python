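"""Run configuration: flat key=value text with strict validation.

The config file holds paths, ROIs, scales, thresholds and the fixed assay
geometry (tissue volume, electrode count/depth/spacing, intracellular [K+],
glycerol sample volume). Unknown keys are rejected so parameter names cannot
silently drift. Sections use dotted keys, e.g. ``phmap.scale_mm_per_px=0.05``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # geometry / assay constants
    tissue_volume_uL: float = 3000.0
    n_electrodes: int = 3
    depth_mm: float = 12.0
    spacing_mm: float = 3.0
    intracellular_mM: float = 130.0
    sample_volume_uL: float = 1000.0
    dilution_factor: float = 10.0
    # imaging
    scale_mm_per_px: float = 0.05
    scale_um_per_px: float = 1.0
    sd_multiplier: float = 1.0
    min_component_px: int = 25
    denoise_radius: int = 1
    min_seed_separation_px: int = 5
    anode_roi: tuple[int, int, int, int] | None = None
    cathode_roi: tuple[int, int, int, int] | None = None
    thresholds: dict[str, float] = field(default_factory=lambda: {
        "bodipy": 0.3, "hoechst": 0.3, "calcein": 0.3, "ethd1": 0.3,
    })
    # run control
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("tissue_volume_uL", "n_electrodes", "depth_mm", "spacing_mm",
                     "intracellular_mM", "sample_volume_uL", "dilution_factor",
                     "scale_mm_per_px", "scale_um_per_px"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")


_FLOAT_KEYS = {
    "tissue_volume_uL", "depth_mm", "spacing_mm", "intracellular_mM",
    "sample_volume_uL", "dilution_factor", "scale_mm_per_px", "scale_um_per_px",
    "sd_multiplier",
}
_INT_KEYS = {"n_electrodes", "min_component_px", "denoise_radius",
             "min_seed_separation_px", "seed"}
_ROI_KEYS = {"anode_roi", "cathode_roi"}
_STR_KEYS = {"out_dir"}


def parse_roi(text: str) -> tuple[int, int, int, int]:
    parts = [int(p) for p in text.replace(" ", "").split(",")]
    if len(parts) != 4:
        raise ConfigError(f"ROI needs 4 integers r0,r1,c0,c1, got {text!r}")
    return tuple(parts)


def load_config(path: str | Path) -> RunConfig:
    """Parse a key=value config file; fail on unknown keys or bad values."""
    known = {f.name for f in fields(RunConfig)}
    kwargs: dict = {}
    thresholds: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("threshold."):
            channel = key.split(".", 1)[1]
            if channel not in ("bodipy", "hoechst", "calcein", "ethd1"):
                raise ConfigError(f"line {lineno}: unknown channel {channel!r}")
            thresholds[channel] = float(value)
            continue
        if key not in known or key == "thresholds":
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        if key in _FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key in _INT_KEYS:
            kwargs[key] = int(value)
        elif key in _ROI_KEYS:
            kwargs[key] = parse_roi(value)
        elif key in _STR_KEYS:
            kwargs[key] = value
        else:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
    cfg = RunConfig(**kwargs)
    if thresholds:
        cfg.thresholds.update(thresholds)
    return cfg
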