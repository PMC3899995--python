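"""Two-event development: proliferate at stage 1, carve by apoptosis at stage 2.

The founder fires a radius-2 proliferation at stage 1 (a 5x5 square in 2-D),
then — still matching the genome's second unit — fires a radius-1 apoptosis at
stage 2 that deletes a 3x3 patch including the founder itself.  The per-stage
cell totals show growth followed by carving.
"""

from epitrack import develop
from epitrack.fixtures import engine_config_2d, grow_then_carve_genome

config = engine_config_2d()
genome = grow_then_carve_genome(config)
embryo, record = develop(genome, config)

for stage, total in record.stage_totals:
    marker = ""
    for ev in record.events:
        if ev.stage == stage:
            marker = f"  <- {ev.event_type.value} (+{ev.n_created}/-{ev.n_removed})"
    if stage <= 3 or marker:
        print(f"stage {stage:2d}: {total:3d} cells{marker}")
print(f"final body: {embryo.n_cells()} cells (5x5 grown, 3x3 carved out)")
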