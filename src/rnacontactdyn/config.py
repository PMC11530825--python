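"""Run configuration: validated, serializable, and embedded verbatim in
every output header so results are reproducible from their own files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .topology import RegionScheme


class ConfigError(ValueError):
    """Raised for unusable run configurations."""


@dataclass
class RunConfig:
    """All knobs of the analysis pipeline.

    Windows are in nanoseconds (mapped to frames through the ensemble's
    time stamps, never assumed uniform); distances in Angstrom.
    """

    input_pdb: str | None = None          # None -> built-in synthetic scene
    params_table: str | None = None       # None -> synthetic parameters
    seed: int = 1
    out_dir: str = "results"
    simulate_frames: int = 120
    renumber: str = "contiguous"          # or "preserve"

    # region mapping (residue index ranges, inclusive)
    aso: tuple[int, int] = (1, 10)
    hairpin_strand1: tuple[int, int] = (11, 26)
    hairpin_strand2: tuple[int, int] = (27, 42)

    # contact criteria
    hbond_dist: float = 3.0
    hbond_angle: float = 135.0
    salt_dist: float = 4.0
    apolar_dist: float = 4.0
    occupancy_threshold: float = 0.10
    n_blocks: int = 4

    # windows / smoothing
    window_ns: tuple[float, float] | None = None
    smooth_ns: float = 1.0

    # energies
    cutoff_A: float = 10.0

    # PCA
    pca_modes: int = 3

    def region_scheme(self) -> RegionScheme:
        return RegionScheme(
            aso=tuple(self.aso),
            hairpin_strand1=tuple(self.hairpin_strand1),
            hairpin_strand2=tuple(self.hairpin_strand2),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # where results land does not affect what they contain
        d.pop("out_dir")
        d["aso"] = list(d["aso"])
        d["hairpin_strand1"] = list(d["hairpin_strand1"])
        d["hairpin_strand2"] = list(d["hairpin_strand2"])
        if d["window_ns"] is not None:
            d["window_ns"] = list(d["window_ns"])
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected, not ignored."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("aso", "hairpin_strand1", "hairpin_strand2", "window_ns"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def validate_config(config: RunConfig) -> list[str]:
    """All cross-field constraint violations (complete list, not the
    first failure); an empty list means the config is usable."""
    errors: list[str] = []
    if not 0.0 < config.occupancy_threshold < 1.0:
        errors.append(
            f"occupancy_threshold {config.occupancy_threshold} not in (0, 1)"
        )
    for name in ("hbond_dist", "salt_dist", "apolar_dist", "cutoff_A",
                 "smooth_ns"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if not 0.0 < config.hbond_angle <= 180.0:
        errors.append("hbond_angle must be in (0, 180]")
    if config.n_blocks < 1:
        errors.append("n_blocks must be >= 1")
    if config.simulate_frames < 2:
        errors.append("simulate_frames must be >= 2")
    if config.pca_modes < 1:
        errors.append("pca_modes must be >= 1")
    if config.renumber not in ("contiguous", "preserve"):
        errors.append(f"unknown renumber mode {config.renumber!r}")
    if config.window_ns is not None:
        lo, hi = config.window_ns
        if lo >= hi:
            errors.append(f"window_ns ordering error: {lo} >= {hi}")
    errors.extend(config.region_scheme().validate())
    if config.input_pdb is not None and not Path(config.input_pdb).exists():
        errors.append(f"input_pdb not found: {config.input_pdb}")
    if config.params_table is not None and not Path(config.params_table).exists():
        errors.append(f"params_table not found: {config.params_table}")
    return errors
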