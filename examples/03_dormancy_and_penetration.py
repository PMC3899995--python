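"""Dormant drivers and germline penetration.

A stage-1 proliferation creates a wave of new driver cells whose state codes
match nothing in the genome: they are developmentally dormant.  Germline
penetration copies those codes into an offspring genome as new, switched-off
units — which leaves the offspring's phenotype untouched (neutrality) until a
later ordinary mutation flips a switch and development can go further.
"""

import numpy as np

from epitrack import (
    develop,
    dormant_mocs,
    penetrate,
    phenotype_neutrality_check,
)
from epitrack.fixtures import dormant_driver_genome, engine_config_2d

rng = np.random.default_rng(0)
config = engine_config_2d()
genome = dormant_driver_genome(config, rng)

embryo, record = develop(genome, config)
pool = dormant_mocs(record, genome)
print(f"developed {embryo.n_cells()} cells; {len(record.final_driver_mocs)} final drivers")
print(f"dormant pool (codes matching no MOS anywhere): {len(pool)} codes")
print(f"  first few: {[''.join(map(str, m)) for m in pool[:3]]}")

offspring = penetrate(genome, pool, k_max=2, config=config, rng=rng)
print(f"genome grew from {len(genome)} to {len(offspring)} units")
for u in offspring.units[len(genome):]:
    print(
        f"  penetrated unit: sw={u.sw.value}, tm={u.tm}, "
        f"event={u.right.event_type.value}, mos={''.join(map(str, u.mos))}"
    )
print(f"phenotype unchanged by penetration: {phenotype_neutrality_check(genome, offspring, config)}")
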