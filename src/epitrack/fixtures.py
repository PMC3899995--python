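"""Deterministic generation of the small demonstration/test inputs.

Everything here is synthetic and hand-designed: tiny genomes that exercise
each engine behavior (no development at all, a single proliferation, growth
followed by carving, dormant-driver production) plus small geometric targets.
All files are byte-identical across runs with the same seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import EngineConfig, save_engine_config
from .genome import (
    EventType,
    GeneticUnit,
    Genome,
    RightPart,
    Switch,
    encode_counter_as_seq,
    save_genome,
)
from .targets import make_box, make_disc, save_target_csv


def engine_config_2d() -> EngineConfig:
    """The standard desk-scale 2-D benchmark grid (24 x 24)."""
    return EngineConfig(dims=2, grid_extent=(24, 24))


def engine_config_3d() -> EngineConfig:
    """A 21^3 grid large enough that a radius-1 event never clips."""
    return EngineConfig(dims=3, grid_extent=(21, 21, 21))


def founder_moc(config: EngineConfig):
    return encode_counter_as_seq(0, config.moc_length, config.alphabet_size)


def one_unit_proliferation_genome(config: EngineConfig) -> Genome:
    """Fires once, at stage 1, in the founder: a radius-1 proliferation."""
    return Genome(
        (
            GeneticUnit(
                sw=Switch.ACTIVE,
                mos=founder_moc(config),
                tm=1,
                right=RightPart(EventType.PROLIFERATION, radius=1, color=1),
            ),
        )
    )


def grow_then_carve_genome(config: EngineConfig) -> Genome:
    """Stage-1 proliferation around the founder, stage-2 apoptosis at the
    founder that carves the middle (the founder included) back out."""
    moc0 = founder_moc(config)
    return Genome(
        (
            GeneticUnit(
                Switch.ACTIVE, moc0, 1, RightPart(EventType.PROLIFERATION, 2, 1)
            ),
            GeneticUnit(
                Switch.ACTIVE, moc0, 2, RightPart(EventType.APOPTOSIS, 1, 0)
            ),
        )
    )


def dormant_driver_genome(config: EngineConfig, rng: np.random.Generator) -> Genome:
    """A stage-1 proliferation whose freshly created drivers match nothing:
    their states populate the dormant pool.  A filler unit with a random,
    never-matching MOS is included so the genome is not a single-unit toy."""
    filler_mos = tuple(
        int(s) for s in rng.integers(0, config.alphabet_size, config.moc_length)
    )
    return Genome(
        (
            GeneticUnit(
                Switch.ACTIVE, founder_moc(config), 1,
                RightPart(EventType.PROLIFERATION, 3, 2),
            ),
            GeneticUnit(
                Switch.ACTIVE, filler_mos, 3, RightPart(EventType.APOPTOSIS, 1, 0)
            ),
        )
    )


def fixture_generator(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set under ``out_dir``; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cfg2, cfg3 = engine_config_2d(), engine_config_3d()

    paths: dict[str, Path] = {}

    def put(name: str, writer) -> None:
        path = out / name
        writer(path)
        paths[name] = path

    put("engine_2d.yaml", lambda p: save_engine_config(cfg2, p))
    put("engine_3d.yaml", lambda p: save_engine_config(cfg3, p))
    put("empty_genome.json", lambda p: save_genome(Genome(), cfg3, p))
    put(
        "one_unit_proliferation.json",
        lambda p: save_genome(one_unit_proliferation_genome(cfg3), cfg3, p),
    )
    put(
        "grow_then_carve.json",
        lambda p: save_genome(grow_then_carve_genome(cfg2), cfg2, p),
    )
    put(
        "dormant_driver.json",
        lambda p: save_genome(dormant_driver_genome(cfg2, rng), cfg2, p),
    )
    put(
        "disc_r8.csv",
        lambda p: save_target_csv(
            make_disc(cfg2.grid_extent, cfg2.center, radius=8, color=1), p
        ),
    )
    put(
        "box_3x4x5.csv",
        lambda p: save_target_csv(
            make_box(cfg3.grid_extent, origin=(8, 8, 8), size=(3, 4, 5), color=2), p
        ),
    )
    return paths
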