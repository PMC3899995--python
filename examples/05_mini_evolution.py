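"""A small evolutionary run toward the disc target.

Every initial genome is random, so no MOS matches the founder's state code
and nothing develops at first (fitness ~ 0).  Germline penetration plants the
founder's code into offspring genomes as inactive units; once a mutation
activates one, development starts and fitness climbs as selection tunes
timers, radii and colors.
"""

from epitrack import EvolutionConfig, evolve, make_disc
from epitrack.fixtures import engine_config_2d

engine = engine_config_2d()
target = make_disc(engine.grid_extent, engine.center, radius=8, color=1)
evo = EvolutionConfig(pop_size=40, n_generations=60, master_seed=42)

result = evolve(engine, evo, target)
log = result.log
for gen in (0, 10, 20, 30, 40, 50, 59):
    row = log.iloc[gen]
    print(
        f"gen {gen:3d}: best fitness {row.best_fitness:7.4f}, "
        f"mean {row.mean_fitness:7.4f}, best genome {int(row.best_genome_length)} units"
    )
print(f"\nchampion fitness: {result.champion_fitness:.4f}")
print(f"champion genome: {len(result.champion)} units "
      f"({sum(u.provenance.value == 'penetrated' for u in result.champion)} penetrated)")
print(f"penetration events logged: {len(result.penetration_events)}")
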