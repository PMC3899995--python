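"""Target voxel shapes and the fitness of a developed body against them.

Fitness is the proximity of the developed body to a colored target shape:

    fitness = (n_match + w_color * n_shape_only - w_spurious * n_spurious) / |target|

where ``n_match`` counts cells sitting on a target voxel with the target
color, ``n_shape_only`` cells on a target voxel with the wrong color (partial
credit ``w_color``, default 0.5 — this smooths the landscape for evolution),
and ``n_spurious`` cells outside the target (penalty ``w_spurious``, default
1.0, normalized by target size so small targets are not trivially "solved" by
growing nothing).  A perfect reproduction scores exactly 1; fitness can go
negative when spurious growth dominates.  Driver cells occupy positions like
any cell but carry no color, so they earn shape-only credit unless color-blind
scoring is enabled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

from ._io import write_csv
from .config import EngineConfig
from .engine import CellKind, Embryo, Pos
from .errors import ConfigError, FormatError

#: Palette index -> RGB; shared by bitmap import and PNG rendering.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
)


@dataclass(frozen=True)
class TargetShape:
    """Colored voxel target: pos -> palette color, on a bounded lattice."""

    dims: int
    extent: tuple[int, ...]
    voxels: dict[Pos, int]

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ConfigError("target shape is empty")
        for pos in self.voxels:
            if len(pos) != self.dims or any(
                not 0 <= p < e for p, e in zip(pos, self.extent)
            ):
                raise ConfigError(f"target voxel {pos} out of bounds {self.extent}")

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class FitnessWeights:
    w_color: float = 0.5
    w_spurious: float = 1.0
    #: score any covering cell as a full match, ignoring color entirely
    color_blind: bool = False


@dataclass(frozen=True)
class FitnessReport:
    n_match: int
    n_shape_only: int
    n_spurious: int
    n_missing: int
    fitness: float


def fitness(
    embryo: Embryo, target: TargetShape, weights: FitnessWeights = FitnessWeights()
) -> FitnessReport:
    """Score a developed body against a target shape (see module docstring)."""
    cfg = embryo.config
    if cfg.dims != target.dims or cfg.grid_extent != target.extent:
        raise ConfigError(
            f"embryo grid {cfg.grid_extent} does not match target extent {target.extent}"
        )
    n_match = n_shape_only = n_spurious = 0
    for pos, cell in embryo.cells.items():
        want = target.voxels.get(pos)
        if want is None:
            n_spurious += 1
        elif weights.color_blind:
            n_match += 1
        elif cell.kind is not CellKind.DRIVER and cell.color == want:
            n_match += 1
        else:
            n_shape_only += 1
    n_missing = len(target) - n_match - n_shape_only
    score = (
        n_match + weights.w_color * n_shape_only - weights.w_spurious * n_spurious
    ) / len(target)
    return FitnessReport(n_match, n_shape_only, n_spurious, n_missing, score)


# ---------------------------------------------------------------------------
# Shape construction
# ---------------------------------------------------------------------------

def make_disc(
    extent: tuple[int, int], center: tuple[int, int], radius: float, color: int
) -> TargetShape:
    """2-D Euclidean disc: lattice points with ||p - center||_2 <= radius."""
    return _ball(2, extent, center, radius, color)


def make_sphere(
    extent: tuple[int, int, int], center: tuple[int, int, int], radius: float, color: int
) -> TargetShape:
    """3-D Euclidean ball: lattice points with ||p - center||_2 <= radius."""
    return _ball(3, extent, center, radius, color)


def _ball(dims, extent, center, radius, color) -> TargetShape:
    if radius < 0:
        raise ConfigError(f"radius must be >= 0, got {radius}")
    r = int(math.floor(radius))
    voxels: dict[Pos, int] = {}
    for off in itertools.product(range(-r, r + 1), repeat=dims):
        if sum(o * o for o in off) <= radius * radius:
            pos = tuple(c + o for c, o in zip(center, off))
            if any(not 0 <= p < e for p, e in zip(pos, extent)):
                raise ConfigError(f"shape voxel {pos} falls outside extent {extent}")
            voxels[pos] = color
    return TargetShape(dims, tuple(extent), voxels)


def make_box(
    extent: tuple[int, ...], origin: tuple[int, ...], size: tuple[int, ...], color: int
) -> TargetShape:
    """Axis-aligned filled box of the given size anchored at ``origin``."""
    if any(s < 1 for s in size):
        raise ConfigError(f"box size axes must be >= 1, got {size}")
    voxels: dict[Pos, int] = {}
    for off in itertools.product(*(range(s) for s in size)):
        pos = tuple(o + d for o, d in zip(origin, off))
        if any(not 0 <= p < e for p, e in zip(pos, extent)):
            raise ConfigError(f"box voxel {pos} falls outside extent {extent}")
        voxels[pos] = color
    return TargetShape(len(extent), tuple(extent), voxels)


def target_from_bitmap(path: str | Path, extent: tuple[int, int] | None = None) -> TargetShape:
    """Read a 2-D image; every non-white pixel becomes a voxel of the nearest
    palette color.  Pixel (col, row) maps to lattice position (x=col, y=row)."""
    from PIL import Image

    try:
        img = Image.open(path).convert("RGB")
    except OSError as exc:
        raise FormatError(f"cannot read bitmap {path}: {exc}") from exc
    if extent is None:
        extent = (img.width, img.height)
    voxels: dict[Pos, int] = {}
    px = img.load()
    for y in range(img.height):
        for x in range(img.width):
            rgb = px[x, y]
            if rgb == (255, 255, 255):
                continue
            voxels[(x, y)] = min(
                range(len(PALETTE)),
                key=lambda i: sum((a - b) ** 2 for a, b in zip(PALETTE[i], rgb)),
            )
    if not voxels:
        raise FormatError(f"bitmap {path} contains no non-background pixels")
    return TargetShape(2, tuple(extent), voxels)


def make_target(kind: str, params: dict) -> TargetShape:
    """Dispatcher over shape kinds ('disc', 'sphere', 'box', 'bitmap')."""
    builders = {
        "disc": lambda p: make_disc(
            tuple(p["extent"]), tuple(p["center"]), p["radius"], p.get("color", 0)
        ),
        "sphere": lambda p: make_sphere(
            tuple(p["extent"]), tuple(p["center"]), p["radius"], p.get("color", 0)
        ),
        "box": lambda p: make_box(
            tuple(p["extent"]), tuple(p["origin"]), tuple(p["size"]), p.get("color", 0)
        ),
        "bitmap": lambda p: target_from_bitmap(p["path"], p.get("extent")),
    }
    if kind not in builders:
        raise FormatError(f"unknown target kind {kind!r}; expected {sorted(builders)}")
    try:
        return builders[kind](params)
    except KeyError as exc:
        raise FormatError(f"target kind {kind!r} missing parameter {exc}") from exc


# ---------------------------------------------------------------------------
# Target file I/O (CSV voxel list: x,y[,z],color)
# ---------------------------------------------------------------------------

def save_target_csv(target: TargetShape, path: str | Path) -> Path:
    axes = ["x", "y", "z"][: target.dims]
    rows = [(*pos, target.voxels[pos]) for pos in sorted(target.voxels)]
    return write_csv(path, [*axes, "color"], rows)


def load_target_csv(path: str | Path, extent: tuple[int, ...] | None = None) -> TargetShape:
    """Read a voxel-list target.  If ``extent`` is not given the minimal
    bounding extent is used."""
    try:
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    except OSError as exc:
        raise FormatError(f"cannot read target file {path}: {exc}") from exc
    if not lines:
        raise FormatError(f"target file {path} is empty")
    header = lines[0].split(",")
    if header[-1] != "color" or header[0] != "x":
        raise FormatError(f"target file {path}: bad header {lines[0]!r}")
    dims = len(header) - 1
    if dims not in (2, 3):
        raise FormatError(f"target file {path}: expected 2 or 3 axes, got {dims}")
    voxels: dict[Pos, int] = {}
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != dims + 1:
            raise FormatError(f"target file {path}: bad row {ln!r}")
        pos = tuple(int(v) for v in parts[:dims])
        voxels[pos] = int(parts[-1])
    if extent is None:
        extent = tuple(max(p[i] for p in voxels) + 1 for i in range(dims))
    return TargetShape(dims, tuple(extent), voxels)


def target_for_config(target: TargetShape, config: EngineConfig) -> TargetShape:
    """Re-embed a target in the config's grid (extents must contain it)."""
    if target.dims != config.dims:
        raise ConfigError(f"target dims {target.dims} != engine dims {config.dims}")
    if target.extent == config.grid_extent:
        return target
    return TargetShape(target.dims, config.grid_extent, dict(target.voxels))
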