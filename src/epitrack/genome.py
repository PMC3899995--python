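"""Genomes of regulatory/effector units and their variation operators.

A genome is an ordered list of *genetic units*.  Each unit has a left
(regulatory) part — a binary switch SW, a match sequence MOS, and a timer TM —
and a right (effector) part describing one developmental event: proliferation
or apoptosis, a change-volume radius, and a palette color.  A unit fires in a
driver cell when SW is active, the unit's MOS equals the driver's state code
(MOC), and TM equals the global clock.

MOCs and MOSs are fixed-length integer sequences over a configurable alphabet
(defaults L=8, A=10, i.e. a 10^8 code space).  Matching is exact symbol-wise
equality, which makes a spontaneous match between a random MOS and a
counter-assigned MOC astronomically unlikely — the regime in which germline
penetration, not mutation, is what supplies new matches.

Standard variation never resizes a genome: mutation resamples fields in place
and recombination is a one-point crossover bounded by the shorter parent.
Genome growth happens exclusively through germline penetration
(:mod:`epitrack.penetration`).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._io import atomic_write_text
from .config import EngineConfig
from .errors import ConfigError, FormatError, MocOverflowError

#: A code sequence (MOC or MOS): a tuple of ints in [0, A), length L.
#: Tuples compare lexicographically, giving the canonical total order.
CodeSeq = tuple[int, ...]

GENOME_FORMAT_VERSION = 1


class Switch(enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class EventType(enum.Enum):
    PROLIFERATION = "proliferation"
    APOPTOSIS = "apoptosis"


class Provenance(enum.Enum):
    """Bookkeeping tag: where a unit came from (no behavioral effect)."""

    ANCESTRAL = "ancestral"
    PENETRATED = "penetrated"
    MUTATED = "mutated"


def encode_counter_as_seq(counter: int, length: int, alphabet_size: int) -> CodeSeq:
    """Base-A positional encoding of ``counter``, most-significant symbol first.

    Injective over ``[0, alphabet_size**length)``; the deterministic scheme by
    which the engine assigns a fresh, unique state code to every new driver
    cell.

    Raises
    ------
    MocOverflowError
        If ``counter >= alphabet_size**length`` (grid/config mismatch).
    """
    if counter < 0:
        raise ValueError(f"counter must be non-negative, got {counter}")
    if counter >= alphabet_size**length:
        raise MocOverflowError(
            f"counter {counter} does not fit in {length} symbols over "
            f"alphabet of size {alphabet_size}"
        )
    symbols = []
    c = counter
    for _ in range(length):
        symbols.append(c % alphabet_size)
        c //= alphabet_size
    return tuple(reversed(symbols))


def match(mos: CodeSeq, moc: CodeSeq) -> bool:
    """Exact-equality match between a unit's MOS and a driver's MOC.

    Raises :class:`FormatError` on a length mismatch (corrupt genome).
    """
    if len(mos) != len(moc):
        raise FormatError(
            f"MOS/MOC length mismatch: {len(mos)} vs {len(moc)} (corrupt genome?)"
        )
    return mos == moc


@dataclass(frozen=True)
class RightPart:
    """Effector part of a unit: the developmental event it encodes.

    ``color`` must always be a valid palette index but is ignored by
    apoptosis events.
    """

    event_type: EventType
    radius: int
    color: int

    def validate(self, config: EngineConfig) -> None:
        if not 1 <= self.radius <= config.radius_max:
            raise ConfigError(
                f"radius {self.radius} outside [1, {config.radius_max}]"
            )
        if not 0 <= self.color < config.n_colors:
            raise ConfigError(f"color {self.color} outside [0, {config.n_colors})")


@dataclass(frozen=True)
class GeneticUnit:
    """One heritable regulatory/effector unit: (SW, MOS, TM) + right part."""

    sw: Switch
    mos: CodeSeq
    tm: int
    right: RightPart
    provenance: Provenance = Provenance.ANCESTRAL

    def validate(self, config: EngineConfig) -> None:
        if len(self.mos) != config.moc_length:
            raise ConfigError(
                f"MOS length {len(self.mos)} != configured moc_length {config.moc_length}"
            )
        if any(not 0 <= s < config.alphabet_size for s in self.mos):
            raise ConfigError(f"MOS symbols outside [0, {config.alphabet_size}): {self.mos}")
        if not 1 <= self.tm <= config.tm_max:
            raise ConfigError(f"tm {self.tm} outside [1, {config.tm_max}]")
        self.right.validate(config)


@dataclass(frozen=True)
class Genome:
    """Ordered list of genetic units.  Order matters: it breaks ties when
    several units could fire in the same driver at the same stage."""

    units: tuple[GeneticUnit, ...] = ()

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, i):
        return self.units[i]

    def validate(self, config: EngineConfig) -> None:
        if len(self.units) > config.genome_max_units:
            raise ConfigError(
                f"genome has {len(self.units)} units, cap is {config.genome_max_units}"
            )
        for u in self.units:
            u.validate(config)

    def mos_set(self) -> set[CodeSeq]:
        return {u.mos for u in self.units}


@dataclass(frozen=True)
class MutationRates:
    """Independent per-field mutation probabilities.

    ``p_mos_symbol`` applies per MOS symbol and defaults to 0: with an
    immutable MOS, new regulatory matches can only enter a lineage through
    germline penetration, never through point mutation.
    """

    p_sw_flip: float = 0.02
    p_tm: float = 0.02
    p_event_type: float = 0.01
    p_radius: float = 0.02
    p_color: float = 0.02
    p_mos_symbol: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"mutation rate {f.name}={v} outside [0, 1]")


def mutate(
    genome: Genome,
    rates: MutationRates,
    config: EngineConfig,
    rng: np.random.Generator,
) -> Genome:
    """Return a mutated copy of ``genome``; the input is never modified.

    Each field of each unit is independently hit with its rate: SW toggles,
    TM resamples uniformly on [1, tm_max], radius on [1, radius_max], color
    on the palette, event type on the two event kinds, and each MOS symbol
    on the alphabet.  A unit any field of which changed is retagged
    ``MUTATED``.  Mutation never changes genome length or unit order.
    """
    n = len(genome.units)
    if n == 0:
        return genome
    hit_sw = rng.random(n) < rates.p_sw_flip
    hit_tm = rng.random(n) < rates.p_tm
    hit_ev = rng.random(n) < rates.p_event_type
    hit_rad = rng.random(n) < rates.p_radius
    hit_col = rng.random(n) < rates.p_color
    if rates.p_mos_symbol > 0.0:
        hit_mos = rng.random((n, config.moc_length)) < rates.p_mos_symbol
    else:
        hit_mos = None

    new_units = []
    for i, u in enumerate(genome.units):
        sw, tm, right, mos = u.sw, u.tm, u.right, u.mos
        changed = False
        if hit_sw[i]:
            sw = Switch.INACTIVE if sw is Switch.ACTIVE else Switch.ACTIVE
            changed = True
        if hit_tm[i]:
            tm = int(rng.integers(1, config.tm_max + 1))
            changed = True
        ev, rad, col = right.event_type, right.radius, right.color
        if hit_ev[i]:
            ev = EventType.PROLIFERATION if rng.integers(2) == 0 else EventType.APOPTOSIS
            changed = True
        if hit_rad[i]:
            rad = int(rng.integers(1, config.radius_max + 1))
            changed = True
        if hit_col[i]:
            col = int(rng.integers(0, config.n_colors))
            changed = True
        if hit_mos is not None and hit_mos[i].any():
            mos = tuple(
                int(rng.integers(0, config.alphabet_size)) if hit else s
                for s, hit in zip(mos, hit_mos[i])
            )
            changed = True
        if changed:
            new_units.append(
                GeneticUnit(sw, mos, tm, RightPart(ev, rad, col), Provenance.MUTATED)
            )
        else:
            new_units.append(u)
    return Genome(tuple(new_units))


def recombine(
    g1: Genome, g2: Genome, config: EngineConfig, rng: np.random.Generator
) -> Genome:
    """One-point crossover at a unit boundary.

    The crossover point k is uniform on ``[0, min(len(g1), len(g2))]`` so the
    operator is total on variable-length genomes; the child is
    ``g1.units[:k] + g2.units[k:]``, truncated to ``genome_max_units``.
    """
    k = int(rng.integers(0, min(len(g1), len(g2)) + 1))
    child = g1.units[:k] + g2.units[k:]
    return Genome(child[: config.genome_max_units])


def random_genome(
    config: EngineConfig,
    n_units: int,
    rng: np.random.Generator,
    bootstrap_match: bool = False,
) -> Genome:
    """Genome of ``n_units`` units with all fields sampled uniformly.

    At the default code-space size a uniform MOS has probability ~A**-L of
    matching the founder driver's all-zero code, so a fresh random genome is
    effectively certain to produce no development at all.  With
    ``bootstrap_match`` the first unit is instead guaranteed to fire at stage
    1 in the founder (handy for demos; off for ablation experiments).
    """
    units = []
    for i in range(n_units):
        if i == 0 and bootstrap_match:
            mos = encode_counter_as_seq(0, config.moc_length, config.alphabet_size)
            sw, tm = Switch.ACTIVE, 1
            ev = EventType.PROLIFERATION
        else:
            mos = tuple(
                int(s) for s in rng.integers(0, config.alphabet_size, config.moc_length)
            )
            sw = Switch.ACTIVE if rng.integers(2) == 0 else Switch.INACTIVE
            tm = int(rng.integers(1, config.tm_max + 1))
            ev = EventType.PROLIFERATION if rng.integers(2) == 0 else EventType.APOPTOSIS
        right = RightPart(
            event_type=ev,
            radius=int(rng.integers(1, config.radius_max + 1)),
            color=int(rng.integers(0, config.n_colors)),
        )
        units.append(GeneticUnit(sw, mos, tm, right))
    return Genome(tuple(units))


# ---------------------------------------------------------------------------
# Serialization: JSON genome files
# ---------------------------------------------------------------------------

def genome_to_dict(genome: Genome, config: EngineConfig) -> dict:
    return {
        "meta": {
            "moc_length": config.moc_length,
            "alphabet_size": config.alphabet_size,
            "format_version": GENOME_FORMAT_VERSION,
        },
        "units": [
            {
                "sw": u.sw.value,
                "mos": list(u.mos),
                "tm": u.tm,
                "event_type": u.right.event_type.value,
                "radius": u.right.radius,
                "color": u.right.color,
                "provenance": u.provenance.value,
            }
            for u in genome.units
        ],
    }


_UNIT_KEYS = {"sw", "mos", "tm", "event_type", "radius", "color", "provenance"}


def genome_from_dict(data: dict, source: str = "<genome>") -> tuple[Genome, dict]:
    """Parse a genome document; returns (genome, meta).  Unit order in the
    document is genome order.  Raises :class:`FormatError` on any defect,
    naming the offending field."""
    if not isinstance(data, dict) or "units" not in data or "meta" not in data:
        raise FormatError(f"{source}: genome document must have 'meta' and 'units'")
    meta = data["meta"]
    for key in ("moc_length", "alphabet_size"):
        if key not in meta:
            raise FormatError(f"{source}: meta.{key} missing")
    L = int(meta["moc_length"])
    A = int(meta["alphabet_size"])
    units = []
    for idx, ud in enumerate(data["units"]):
        where = f"{source}: units[{idx}]"
        if not isinstance(ud, dict):
            raise FormatError(f"{where}: not a mapping")
        unknown = set(ud) - _UNIT_KEYS
        if unknown:
            raise FormatError(f"{where}: unknown fields {sorted(unknown)}")
        missing = _UNIT_KEYS - {"provenance"} - set(ud)
        if missing:
            raise FormatError(f"{where}: missing fields {sorted(missing)}")
        try:
            sw = Switch(ud["sw"])
            ev = EventType(ud["event_type"])
            prov = Provenance(ud.get("provenance", "ancestral"))
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from exc
        mos = tuple(int(s) for s in ud["mos"])
        if len(mos) != L:
            raise FormatError(f"{where}: mos length {len(mos)} != meta.moc_length {L}")
        if any(not 0 <= s < A for s in mos):
            raise FormatError(f"{where}: mos symbol outside [0, {A})")
        tm = int(ud["tm"])
        if tm < 1:
            raise FormatError(f"{where}: tm must be >= 1, got {tm}")
        radius = int(ud["radius"])
        if radius < 1:
            raise FormatError(f"{where}: radius must be >= 1, got {radius}")
        color = int(ud["color"])
        if color < 0:
            raise FormatError(f"{where}: color must be >= 0, got {color}")
        units.append(GeneticUnit(sw, mos, tm, RightPart(ev, radius, color), prov))
    return Genome(tuple(units)), dict(meta)


def save_genome(genome: Genome, config: EngineConfig, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(genome_to_dict(genome, config), indent=1) + "\n")


def load_genome(path: str | Path) -> tuple[Genome, dict]:
    """Read a genome file; returns (genome, meta).  Round-trips exactly."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except OSError as exc:
        raise FormatError(f"cannot read genome file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"genome file {path} is not valid JSON: {exc}") from exc
    return genome_from_dict(data, source=str(path))
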