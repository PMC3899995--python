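"""Deterministic staged development on a bounded lattice.

Development starts from a single driver cell at the grid center and proceeds
through ``n_stages`` discrete stages.  At every stage each driver cell is
checked against the genome: the lowest-index active unit whose MOS equals the
driver's MOC and whose timer equals the clock fires one event — proliferation
(fill the change volume with cells, seeding new drivers on a regular
sublattice) or apoptosis (clear the change volume).  Events for a stage are
computed once against the stage-entry state and applied in lexicographic
driver-position order, so development is a pure function of (genome, config):
there is no randomness anywhere in the engine.

Driver cells receive their state codes (MOCs) from a strictly increasing
counter through :func:`epitrack.genome.encode_counter_as_seq`, so all driver
MOCs are pairwise distinct for the whole of development.  Most drivers never
fire anything; those whose MOC matches no MOS anywhere in the genome form the
dormant pool that germline penetration feeds on.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path

from ._io import write_csv
from .config import EngineConfig
from .errors import ConfigError
from .genome import (
    CodeSeq,
    EventType,
    GeneticUnit,
    Genome,
    Switch,
    encode_counter_as_seq,
)

Pos = tuple[int, ...]


class CellKind(enum.Enum):
    DRIVER = "driver"
    STEM = "stem"
    NORMAL = "normal"


@dataclass(slots=True)
class Cell:
    """One lattice cell.  Drivers carry a MOC and no color; stem/normal cells
    carry a color and no MOC.  Position is the key in ``Embryo.cells``."""

    kind: CellKind
    color: int | None
    moc: CodeSeq | None
    birth_stage: int


@dataclass
class Embryo:
    """Sparse lattice of cells plus the driver-state counter and the clock."""

    config: EngineConfig
    cells: dict[Pos, Cell]
    moc_counter: int
    stage: int

    def n_cells(self) -> int:
        return len(self.cells)

    def driver_positions(self) -> list[Pos]:
        return sorted(p for p, c in self.cells.items() if c.kind is CellKind.DRIVER)

    def driver_mocs(self) -> set[CodeSeq]:
        return {c.moc for c in self.cells.values() if c.kind is CellKind.DRIVER}


@dataclass(slots=True)
class EventRecord:
    """One executed developmental event.

    ``n_created`` counts every cell written by the event and ``n_removed``
    every cell deleted, with a cell overwritten in place booked as one
    removal plus one creation — so per-stage totals satisfy
    ``total = previous - removed + created`` exactly.
    """

    stage: int
    driver_pos: Pos
    driver_moc: CodeSeq
    unit_index: int
    event_type: EventType
    radius: int
    n_created: int
    n_removed: int
    created_positions: tuple[Pos, ...] | None = None
    removed_positions: tuple[Pos, ...] | None = None


@dataclass
class DevelopmentRecord:
    """Event log of one development plus the quantities derived from it:
    which driver states ever fired and which drivers survive to the end."""

    events: list[EventRecord] = field(default_factory=list)
    fired_mocs: set[CodeSeq] = field(default_factory=set)
    final_driver_mocs: set[CodeSeq] = field(default_factory=set)
    #: (stage, total cells after the stage); stage 0 is the initial state.
    stage_totals: list[tuple[int, int]] = field(default_factory=list)
    total_drivers_created: int = 0


def init_embryo(config: EngineConfig) -> Embryo:
    """Single founder driver at the grid center, MOC = the all-zero code."""
    moc0 = encode_counter_as_seq(0, config.moc_length, config.alphabet_size)
    founder = Cell(kind=CellKind.DRIVER, color=None, moc=moc0, birth_stage=0)
    return Embryo(config=config, cells={config.center: founder}, moc_counter=1, stage=0)


def change_volume(center: Pos, radius: int, config: EngineConfig) -> list[Pos]:
    """In-bounds lattice positions with max-norm distance <= radius from
    ``center``: an axis-aligned square/cube clipped at the hard grid walls.
    Returned in lexicographic order (the canonical fill order)."""
    if radius < 1:
        raise ConfigError(f"change-volume radius must be >= 1, got {radius}")
    if not config.in_bounds(center):
        raise ConfigError(f"change-volume center {center} out of bounds")
    ranges = [
        range(max(0, c - radius), min(e, c + radius + 1))
        for c, e in zip(center, config.grid_extent)
    ]
    return [tuple(p) for p in itertools.product(*ranges)]


def triggered_events(
    embryo: Embryo, genome: Genome, stage: int
) -> list[tuple[Pos, int]]:
    """Events that fire at ``stage`` given the current embryo state.

    A driver fires the LOWEST-index unit that is active, MOS-matches its MOC,
    and has timer == stage (at most one event per driver per stage).  The
    list is sorted by driver position, the canonical execution order.
    """
    lowest_by_mos: dict[CodeSeq, int] = {}
    for i, u in enumerate(genome.units):
        if u.sw is Switch.ACTIVE and u.tm == stage and u.mos not in lowest_by_mos:
            lowest_by_mos[u.mos] = i
    if not lowest_by_mos:
        return []
    out = []
    for pos in embryo.driver_positions():
        idx = lowest_by_mos.get(embryo.cells[pos].moc)
        if idx is not None:
            out.append((pos, idx))
    return out


def _proliferate(
    embryo: Embryo, driver_pos: Pos, unit: GeneticUnit
) -> tuple[int, list[Pos], list[Pos]]:
    """Fill the change volume.  Pre-existing drivers (including the trigger)
    are preserved; every other position is (over)written — sublattice
    positions (offsets from the trigger divisible by driver_spacing on every
    axis) become fresh drivers, counter codes assigned in lexicographic
    position order, all remaining positions become stem cells of the unit's
    color.  Returns (n_written, written_positions, overwritten_positions)."""
    d = embryo.config.driver_spacing
    cells = embryo.cells
    stage = embryo.stage
    L, A = embryo.config.moc_length, embryo.config.alphabet_size
    written: list[Pos] = []
    overwritten: list[Pos] = []
    for pos in change_volume(driver_pos, unit.right.radius, embryo.config):
        existing = cells.get(pos)
        if existing is not None and existing.kind is CellKind.DRIVER:
            continue
        if existing is not None:
            overwritten.append(pos)
        if all((p - q) % d == 0 for p, q in zip(pos, driver_pos)):
            moc = encode_counter_as_seq(embryo.moc_counter, L, A)
            embryo.moc_counter += 1
            cells[pos] = Cell(CellKind.DRIVER, None, moc, stage)
        else:
            cells[pos] = Cell(CellKind.STEM, unit.right.color, None, stage)
        written.append(pos)
    return len(written), written, overwritten


def _apoptose(
    embryo: Embryo, driver_pos: Pos, unit: GeneticUnit
) -> tuple[int, list[Pos]]:
    """Delete every cell in the change volume, the triggering driver
    included.  Returns (n_removed, removed_positions)."""
    removed = []
    for pos in change_volume(driver_pos, unit.right.radius, embryo.config):
        if pos in embryo.cells:
            del embryo.cells[pos]
            removed.append(pos)
    return len(removed), removed


def apply_proliferation(
    embryo: Embryo, driver_pos: Pos, unit: GeneticUnit
) -> tuple[Embryo, int]:
    """Execute one proliferation event in place; returns (embryo, n_created)
    where n_created counts every newly written cell."""
    if unit.right.event_type is not EventType.PROLIFERATION:
        raise ConfigError("apply_proliferation called with a non-proliferation unit")
    cell = embryo.cells.get(driver_pos)
    if cell is None or cell.kind is not CellKind.DRIVER:
        raise ConfigError(f"no driver cell at {driver_pos}")
    n_created, _, _overwritten = _proliferate(embryo, driver_pos, unit)
    return embryo, n_created


def apply_apoptosis(
    embryo: Embryo, driver_pos: Pos, unit: GeneticUnit
) -> tuple[Embryo, int]:
    """Execute one apoptosis event in place; returns (embryo, n_removed)."""
    if unit.right.event_type is not EventType.APOPTOSIS:
        raise ConfigError("apply_apoptosis called with a non-apoptosis unit")
    n_removed, _ = _apoptose(embryo, driver_pos, unit)
    return embryo, n_removed


def develop(
    genome: Genome,
    config: EngineConfig,
    record_positions: bool = False,
) -> tuple[Embryo, DevelopmentRecord]:
    """Run the full developmental program; deterministic.

    Within a stage the triggered events are computed once against the
    stage-entry state and then applied sequentially in canonical order;
    drivers created mid-stage cannot fire before the next stage, and a driver
    deleted by an earlier same-stage apoptosis silently loses its turn.
    Stem cells are relabeled normal one stage after their birth (an
    annotation on the plasticity continuum, with no behavioral role).

    With ``record_positions`` each event record also carries the exact
    positions it wrote/removed (used by containment checks; off by default
    to keep evolution runs lean).
    """
    embryo = init_embryo(config)
    record = DevelopmentRecord()
    record.stage_totals.append((0, embryo.n_cells()))
    for stage in range(1, config.n_stages + 1):
        embryo.stage = stage
        for cell in embryo.cells.values():
            if cell.kind is CellKind.STEM and cell.birth_stage < stage:
                cell.kind = CellKind.NORMAL
        for driver_pos, unit_index in triggered_events(embryo, genome, stage):
            cell = embryo.cells.get(driver_pos)
            if cell is None or cell.kind is not CellKind.DRIVER:
                continue  # removed by an earlier event this stage
            unit = genome.units[unit_index]
            moc = cell.moc
            if unit.right.event_type is EventType.PROLIFERATION:
                n_created, written, overwritten = _proliferate(
                    embryo, driver_pos, unit
                )
                ev = EventRecord(
                    stage, driver_pos, moc, unit_index, EventType.PROLIFERATION,
                    unit.right.radius, n_created, len(overwritten),
                )
                if record_positions:
                    ev.created_positions = tuple(written)
                    ev.removed_positions = tuple(overwritten)
            else:
                n_removed, removed = _apoptose(embryo, driver_pos, unit)
                ev = EventRecord(
                    stage, driver_pos, moc, unit_index, EventType.APOPTOSIS,
                    unit.right.radius, 0, n_removed,
                )
                if record_positions:
                    ev.created_positions = ()
                    ev.removed_positions = tuple(removed)
            record.events.append(ev)
            record.fired_mocs.add(moc)
        record.stage_totals.append((stage, embryo.n_cells()))
    record.final_driver_mocs = embryo.driver_mocs()
    record.total_drivers_created = embryo.moc_counter
    return embryo, record


def dormant_mocs(record: DevelopmentRecord, genome: Genome) -> list[CodeSeq]:
    """Driver states eligible for germline penetration, sorted.

    A final driver is *dormant* when it never fired and its MOC matches no
    MOS anywhere in the genome — active or not.  Drivers matched by a unit
    that merely failed its switch or timer condition are excluded: those are
    one ordinary germline mutation away from firing and need no new genetic
    material.
    """
    mos_anywhere = genome.mos_set()
    return sorted(
        moc
        for moc in record.final_driver_mocs - record.fired_mocs
        if moc not in mos_anywhere
    )


# ---------------------------------------------------------------------------
# Phenotype and log export
# ---------------------------------------------------------------------------

def phenotype_signature(embryo: Embryo) -> dict[Pos, tuple[str, int | None, CodeSeq | None]]:
    """Canonical voxel-for-voxel content: pos -> (kind, color, moc)."""
    return {
        pos: (cell.kind.value, cell.color, cell.moc)
        for pos, cell in embryo.cells.items()
    }


def same_phenotype(a: Embryo, b: Embryo) -> bool:
    return phenotype_signature(a) == phenotype_signature(b)


def phenotype_rows(embryo: Embryo) -> list[tuple]:
    """Rows of the phenotype table: x,y[,z],kind,color,moc — lexicographic by
    position; moc hyphen-joined and empty for non-drivers, color empty for
    drivers."""
    rows = []
    for pos in sorted(embryo.cells):
        cell = embryo.cells[pos]
        moc_str = "-".join(str(s) for s in cell.moc) if cell.moc is not None else ""
        color = "" if cell.color is None else cell.color
        rows.append((*pos, cell.kind.value, color, moc_str))
    return rows


def phenotype_header(config: EngineConfig) -> list[str]:
    axes = ["x", "y", "z"][: config.dims]
    return [*axes, "kind", "color", "moc"]


def write_phenotype_csv(embryo: Embryo, path: str | Path) -> Path:
    return write_csv(path, phenotype_header(embryo.config), phenotype_rows(embryo))


def write_event_log_csv(record: DevelopmentRecord, path: str | Path) -> Path:
    header = ["stage", "driver_moc", "unit_index", "event_type", "n_created", "n_removed"]
    rows = [
        (
            ev.stage,
            "-".join(str(s) for s in ev.driver_moc),
            ev.unit_index,
            ev.event_type.value,
            ev.n_created,
            ev.n_removed,
        )
        for ev in record.events
    ]
    return write_csv(path, header, rows)
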