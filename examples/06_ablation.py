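"""Germline-penetration ablation at reduced scale.

Runs paired replicates of the same evolutionary setup with penetration
enabled and disabled (same seeds otherwise).  Without penetration no genome
can ever acquire a MOS matching a driver state — random matches in a 10^8
code space essentially never happen — so the off arm stays flat while the on
arm improves.  The full-scale version of this experiment (5 replicates, 200
generations) is what scripts/acceptance.py reports.
"""

from epitrack import EvolutionConfig, ablation_experiment, make_disc
from epitrack.fixtures import engine_config_2d

engine = engine_config_2d()
target = make_disc(engine.grid_extent, engine.center, radius=8, color=1)
evo = EvolutionConfig(pop_size=20, n_generations=80, master_seed=7)

result = ablation_experiment(engine, evo, target, n_replicates=3)
print(result.table.to_string(index=False))
print(f"\nmedian champion fitness, penetration ON : {result.median_on:.4f}")
print(f"median champion fitness, penetration OFF: {result.median_off:.4f}")
print(f"paired sign test (on > off): p = {result.sign_test_p:.4f} "
      f"({result.n_on_greater}/{result.n_informative} informative pairs)")
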