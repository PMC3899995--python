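"""Shared fixtures: small engine configs and a random-genome factory whose
MOS fields are biased toward codes the counter actually assigns, so that
sampled genomes exercise real event cascades instead of never firing."""

from __future__ import annotations

import numpy as np
import pytest

from epitrack import (
    EngineConfig,
    EventType,
    GeneticUnit,
    Genome,
    RightPart,
    Switch,
    encode_counter_as_seq,
)


@pytest.fixture
def config_2d() -> EngineConfig:
    return EngineConfig(dims=2, grid_extent=(24, 24))


@pytest.fixture
def config_3d() -> EngineConfig:
    return EngineConfig(dims=3, grid_extent=(21, 21, 21))


@pytest.fixture
def small_config_3d() -> EngineConfig:
    """Oracle-scale grid: <= 15^3, 3 stages."""
    return EngineConfig(
        dims=3, grid_extent=(13, 13, 13), n_stages=3, driver_spacing=2, radius_max=3
    )


def make_random_genome(
    config: EngineConfig,
    rng: np.random.Generator,
    n_units: int | None = None,
    max_units: int = 4,
    p_active: float = 0.75,
    p_counter_mos: float = 0.8,
    p_proliferation: float = 0.7,
    max_tm: int | None = None,
    max_counter: int = 12,
) -> Genome:
    """Random genome biased so that units can actually fire: most MOS fields
    are counter codes (the founder's code or an early descendant's)."""
    if n_units is None:
        n_units = int(rng.integers(0, max_units + 1))
    if max_tm is None:
        max_tm = config.n_stages + 1  # occasionally out-of-range, a dormancy route
    units = []
    for _ in range(n_units):
        if rng.random() < p_counter_mos:
            # half the draws target the founder's code so stage-1 events are
            # common and cascades (codes 1, 2, ...) get exercised too
            counter = 0 if rng.random() < 0.5 else int(rng.integers(0, max_counter))
            mos = encode_counter_as_seq(
                counter, config.moc_length, config.alphabet_size
            )
        else:
            mos = tuple(
                int(s)
                for s in rng.integers(0, config.alphabet_size, config.moc_length)
            )
        units.append(
            GeneticUnit(
                sw=Switch.ACTIVE if rng.random() < p_active else Switch.INACTIVE,
                mos=mos,
                tm=int(rng.integers(1, max_tm + 1)),
                right=RightPart(
                    event_type=(
                        EventType.PROLIFERATION
                        if rng.random() < p_proliferation
                        else EventType.APOPTOSIS
                    ),
                    radius=int(rng.integers(1, min(config.radius_max, 3) + 1)),
                    color=int(rng.integers(0, config.n_colors)),
                ),
            )
        )
    return Genome(tuple(units))
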