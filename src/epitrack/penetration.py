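"""Germline penetration: importing dormant driver states into the genome.

Most driver cells created during development never orchestrate anything.
When a driver's state code (MOC) matches no MOS anywhere in the genome, no
amount of switch/timer mutation can make it act — and with exact matching
over a ~10^8 code space, mutation essentially never invents a matching MOS.
Germline penetration closes the loop: the MOCs of such dormant drivers are
copied into the offspring genome as brand-new genetic units whose MOS is the
copied code.

The inserted units are switched OFF.  Were they born active, their unoptimised
right parts would fire immediately and wreck the offspring's development;
instead they sit neutrally in the genome until an ordinary point mutation
flips the switch, at which point selection can begin tuning the timer and the
event.  Neutrality at insertion is a hard contract of this module, exposed as
:func:`phenotype_neutrality_check`.
"""

from __future__ import annotations

import numpy as np

from .config import EngineConfig
from .engine import develop, same_phenotype
from .errors import ConfigError
from .genome import (
    CodeSeq,
    EventType,
    GeneticUnit,
    Genome,
    Provenance,
    RightPart,
    Switch,
)


def penetrate(
    genome: Genome,
    dormant_pool: list[CodeSeq],
    k_max: int,
    config: EngineConfig,
    rng: np.random.Generator,
) -> Genome:
    """Append up to ``k_max`` new inactive units built from dormant MOCs.

    Codes are sampled uniformly without replacement from the pool, skipping
    any code already present as a MOS in the genome (re-penetrating an
    existing match would be redundant).  Each inserted unit gets
    ``sw=INACTIVE``, a uniform timer on ``[1, n_stages]`` (so that once
    activated it can actually fire in a lifetime), and a uniform right part;
    it is tagged ``PENETRATED``.  If the genome then exceeds
    ``genome_max_units`` the oldest PENETRATED units are dropped first.
    The input genome is never modified.
    """
    if k_max < 0:
        raise ConfigError(f"k_max must be >= 0, got {k_max}")
    pool = sorted(set(dormant_pool))
    present = genome.mos_set()
    candidates = [moc for moc in pool if moc not in present]
    if k_max == 0 or not candidates:
        return genome
    k = min(k_max, len(candidates))
    chosen_idx = rng.permutation(len(candidates))[:k]
    new_units = []
    for i in chosen_idx:
        moc = candidates[int(i)]
        right = RightPart(
            event_type=(
                EventType.PROLIFERATION if rng.integers(2) == 0 else EventType.APOPTOSIS
            ),
            radius=int(rng.integers(1, config.radius_max + 1)),
            color=int(rng.integers(0, config.n_colors)),
        )
        new_units.append(
            GeneticUnit(
                sw=Switch.INACTIVE,
                mos=moc,
                tm=int(rng.integers(1, config.n_stages + 1)),
                right=right,
                provenance=Provenance.PENETRATED,
            )
        )
    units = list(genome.units) + new_units
    excess = len(units) - config.genome_max_units
    if excess > 0:
        # drop the oldest penetrated units first, then oldest units outright
        penetrated_idx = [
            i for i, u in enumerate(units) if u.provenance is Provenance.PENETRATED
        ]
        drop = set(penetrated_idx[:excess])
        units = [u for i, u in enumerate(units) if i not in drop]
        if len(drop) < excess:
            units = units[excess - len(drop) :]
    return Genome(tuple(units))


def phenotype_neutrality_check(
    genome: Genome, penetrated_genome: Genome, config: EngineConfig
) -> bool:
    """True iff both genomes develop into voxel-for-voxel identical bodies.

    Because penetrated units are inserted switched off, this must hold for
    every (genome, pool, seed) combination; a False return means the
    insertion contract is broken.  (Once a later mutation flips a penetrated
    unit's switch the genomes differ and the check no longer applies.)
    """
    before, _ = develop(genome, config)
    after, _ = develop(penetrated_genome, config)
    return same_phenotype(before, after)
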