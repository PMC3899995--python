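"""Independent brute-force reference for the development engine.

Deliberately naive and separate from the package implementation: its own
base-A counter encoding, its own neighborhood enumeration, and plain nested
loops over cells and units.  Used as the oracle in voxel-for-voxel
equivalence tests; it shares only the input dataclasses with the package.
"""

from __future__ import annotations

import itertools

from epitrack.config import EngineConfig
from epitrack.genome import EventType, Genome, Switch

DRIVER, STEM, NORMAL = "driver", "stem", "normal"


def ref_encode(counter: int, length: int, alphabet: int) -> tuple[int, ...]:
    digits = []
    for _ in range(length):
        digits.append(counter % alphabet)
        counter //= alphabet
    assert counter == 0, "counter overflow in reference encoding"
    return tuple(reversed(digits))


def ref_volume(center, radius, extent):
    axes = []
    for c, e in zip(center, extent):
        axes.append([v for v in range(c - radius, c + radius + 1) if 0 <= v < e])
    return [tuple(p) for p in itertools.product(*axes)]


def reference_develop(genome: Genome, config: EngineConfig):
    """Returns pos -> (kind, color, moc) after the full development."""
    L, A, d = config.moc_length, config.alphabet_size, config.driver_spacing
    center = tuple(e // 2 for e in config.grid_extent)
    cells = {center: (DRIVER, None, ref_encode(0, L, A))}
    counter = 1

    for stage in range(1, config.n_stages + 1):
        # stem cells from earlier stages become normal cells
        relabeled = {}
        for pos, (kind, color, extra) in cells.items():
            if kind == STEM and extra < stage:
                relabeled[pos] = (NORMAL, color, extra)
            else:
                relabeled[pos] = (kind, color, extra)
        cells = relabeled

        # snapshot of triggered events at stage entry: for every driver, the
        # first unit (in genome order) that is active, matches, and is timed
        fired = []
        for pos in sorted(p for p, c in cells.items() if c[0] == DRIVER):
            moc = cells[pos][2]
            for i, unit in enumerate(genome.units):
                if (
                    unit.sw is Switch.ACTIVE
                    and unit.tm == stage
                    and unit.mos == moc
                ):
                    fired.append((pos, i, moc))
                    break

        for pos, i, moc in fired:
            cell = cells.get(pos)
            if cell is None or cell[0] != DRIVER or cell[2] != moc:
                continue  # this driver was removed earlier in the stage
            unit = genome.units[i]
            volume = ref_volume(pos, unit.right.radius, config.grid_extent)
            if unit.right.event_type is EventType.APOPTOSIS:
                for q in volume:
                    cells.pop(q, None)
            else:
                for q in sorted(volume):
                    old = cells.get(q)
                    if old is not None and old[0] == DRIVER:
                        continue
                    on_sublattice = all(
                        (a - b) % d == 0 for a, b in zip(q, pos)
                    )
                    if on_sublattice:
                        cells[q] = (DRIVER, None, ref_encode(counter, L, A))
                        counter += 1
                    else:
                        # store birth stage in the third slot for stem cells
                        cells[q] = (STEM, unit.right.color, stage)

    return {
        pos: (kind, color, moc if kind == DRIVER else None)
        for pos, (kind, color, moc) in cells.items()
    }
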