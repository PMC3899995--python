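"""Engine configuration: lattice geometry, developmental clock, and code space.

The simulated body lives on a bounded 2-D or 3-D integer lattice with at most
one cell per site.  Development runs for ``n_stages`` discrete stages counted
by a global clock.  Driver-cell states (MOCs) and the genome-side match
sequences (MOSs) are length-``moc_length`` strings over the integer alphabet
``[0, alphabet_size)``; the code space ``alphabet_size ** moc_length`` must be
able to name every driver cell that could ever be created on this grid, which
is checked at construction time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError, FormatError


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of the development engine.

    Parameters
    ----------
    dims
        Lattice dimensionality, 2 or 3.
    grid_extent
        Per-axis lattice size (sites are ``0 .. extent-1``); hard walls,
        change volumes clip and never wrap.
    n_stages
        Number of developmental stages (global-clock range ``1..n_stages``).
    moc_length, alphabet_size
        Length L and alphabet size A of the integer code sequences used for
        both driver states (MOC) and genome match sequences (MOS).
    radius_max
        Largest allowed change-volume half-side.
    driver_spacing
        Spacing d of the regular sublattice on which proliferation deposits
        new driver cells (>= 2).
    n_colors
        Palette size for differentiated cells.
    genome_max_units
        Hard cap on genome length (units beyond it are truncated).
    tm_max
        Upper bound for the timer field of a genetic unit.  May exceed
        ``n_stages``: a unit whose timer lies beyond the last stage can never
        fire in this life, one of the dormancy routes.
    """

    dims: int
    grid_extent: tuple[int, ...]
    n_stages: int = 15
    moc_length: int = 8
    alphabet_size: int = 10
    radius_max: int = 4
    driver_spacing: int = 3
    n_colors: int = 4
    genome_max_units: int = 64
    tm_max: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_extent", tuple(int(e) for e in self.grid_extent))
        if self.dims not in (2, 3):
            raise ConfigError(f"dims must be 2 or 3, got {self.dims}")
        if len(self.grid_extent) != self.dims:
            raise ConfigError(
                f"grid_extent has {len(self.grid_extent)} axes but dims={self.dims}"
            )
        if any(e < 1 for e in self.grid_extent):
            raise ConfigError(f"grid_extent axes must be >= 1, got {self.grid_extent}")
        if self.n_stages < 1:
            raise ConfigError(f"n_stages must be >= 1, got {self.n_stages}")
        if self.moc_length < 1 or self.alphabet_size < 2:
            raise ConfigError(
                f"need moc_length >= 1 and alphabet_size >= 2, "
                f"got L={self.moc_length}, A={self.alphabet_size}"
            )
        if self.radius_max < 1:
            raise ConfigError(f"radius_max must be >= 1, got {self.radius_max}")
        if self.driver_spacing < 2:
            raise ConfigError(f"driver_spacing must be >= 2, got {self.driver_spacing}")
        if self.n_colors < 1:
            raise ConfigError(f"n_colors must be >= 1, got {self.n_colors}")
        if self.genome_max_units < 1:
            raise ConfigError(f"genome_max_units must be >= 1, got {self.genome_max_units}")
        if self.tm_max < 1:
            raise ConfigError(f"tm_max must be >= 1, got {self.tm_max}")
        # Every stage can at most re-driver every lattice site, so the founder
        # plus n_sites per stage bounds the number of codes ever needed.
        capacity = self.alphabet_size**self.moc_length
        worst_case_drivers = 1 + self.n_sites * self.n_stages
        if capacity < worst_case_drivers:
            raise ConfigError(
                f"code space A**L = {capacity} cannot name the up to "
                f"{worst_case_drivers} driver cells creatable on this grid"
            )

    @property
    def n_sites(self) -> int:
        n = 1
        for e in self.grid_extent:
            n *= e
        return n

    @property
    def center(self) -> tuple[int, ...]:
        return tuple(e // 2 for e in self.grid_extent)

    def in_bounds(self, pos: tuple[int, ...]) -> bool:
        return all(0 <= p < e for p, e in zip(pos, self.grid_extent))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_extent"] = list(self.grid_extent)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown engine config keys: {sorted(unknown)}")
        missing = {"dims", "grid_extent"} - set(data)
        if missing:
            raise FormatError(f"engine config missing required keys: {sorted(missing)}")
        return cls(**data)


def load_engine_config(path: str | Path) -> EngineConfig:
    """Read an engine config from YAML (flat mapping, or under an ``engine:`` key)."""
    data = _load_yaml_mapping(path)
    if "engine" in data and isinstance(data["engine"], dict):
        data = data["engine"]
    try:
        return EngineConfig.from_dict(data)
    except TypeError as exc:
        raise FormatError(f"{path}: bad engine config: {exc}") from exc


def save_engine_config(config: EngineConfig, path: str | Path) -> None:
    from ._io import atomic_write_text

    atomic_write_text(path, yaml.safe_dump(config.to_dict(), sort_keys=True))


def _load_yaml_mapping(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise FormatError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise FormatError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} must contain a key/value mapping")
    return data
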