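"""Target shapes and the fitness decomposition.

Builds the standard benchmark target (a color-1 disc of radius 8 in a 24x24
grid) and scores a deliberately imperfect body against it: fitness rewards
covered target voxels (full credit for the right color, half for the wrong
one) and charges each cell grown outside the target, normalized by target
size.
"""

from epitrack import Cell, CellKind, fitness, init_embryo, make_disc
from epitrack.fixtures import engine_config_2d

config = engine_config_2d()
target = make_disc(config.grid_extent, config.center, radius=8, color=1)
print(f"target: disc radius 8 -> {len(target)} voxels")

# hand-build a body: most of the disc in the right color, a miscolored strip,
# and a few stray cells outside
embryo = init_embryo(config)
embryo.cells = {}
for i, pos in enumerate(sorted(target.voxels)):
    if i % 10 == 0:
        embryo.cells[pos] = Cell(CellKind.NORMAL, 0, None, 1)  # wrong color
    elif i % 7 != 0:
        embryo.cells[pos] = Cell(CellKind.NORMAL, 1, None, 1)  # match
for x in range(4):
    embryo.cells[(x, 0)] = Cell(CellKind.NORMAL, 1, None, 1)  # spurious

report = fitness(embryo, target)
print(f"matched voxels:        {report.n_match}")
print(f"covered, wrong color:  {report.n_shape_only}")
print(f"spurious cells:        {report.n_spurious}")
print(f"uncovered target:      {report.n_missing}")
print(f"fitness = (match + 0.5*wrong_color - spurious) / |target| = {report.fitness:.4f}")
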