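"""Static PNG rendering of phenotypes and targets, for visual inspection.

2-D grids render one pixel block per lattice site; 3-D grids render as a
horizontal strip of z-slices.  Drivers are black, stem/normal cells take
their palette color, empty sites are white.
"""

from __future__ import annotations

from pathlib import Path

from PIL import Image

from .engine import CellKind, Embryo
from .targets import PALETTE, TargetShape

_BG = (255, 255, 255)
_DRIVER = (0, 0, 0)


def _color_of(kind: CellKind | None, color: int | None) -> tuple[int, int, int]:
    if kind is CellKind.DRIVER:
        return _DRIVER
    if color is None:
        return _BG
    return PALETTE[color % len(PALETTE)]


def render_phenotype(embryo: Embryo, path: str | Path, scale: int = 8) -> Path:
    cfg = embryo.config
    if cfg.dims == 2:
        w, h = cfg.grid_extent
        img = Image.new("RGB", (w, h), _BG)
        for (x, y), cell in embryo.cells.items():
            img.putpixel((x, y), _color_of(cell.kind, cell.color))
    else:
        w, h, depth = cfg.grid_extent
        img = Image.new("RGB", ((w + 1) * depth, h), _BG)
        for (x, y, z), cell in embryo.cells.items():
            img.putpixel((z * (w + 1) + x, y), _color_of(cell.kind, cell.color))
    img = img.resize((img.width * scale, img.height * scale), Image.NEAREST)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img.save(path)
    return path


def render_target(target: TargetShape, path: str | Path, scale: int = 8) -> Path:
    if target.dims == 2:
        w, h = target.extent
        img = Image.new("RGB", (w, h), _BG)
        for (x, y), color in target.voxels.items():
            img.putpixel((x, y), PALETTE[color % len(PALETTE)])
    else:
        w, h, depth = target.extent
        img = Image.new("RGB", ((w + 1) * depth, h), _BG)
        for (x, y, z), color in target.voxels.items():
            img.putpixel((z * (w + 1) + x, y), PALETTE[color % len(PALETTE)])
    img = img.resize((img.width * scale, img.height * scale), Image.NEAREST)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img.save(path)
    return path
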