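"""Develop a one-unit genome: a single stage-1 proliferation event.

Builds the smallest genome that does anything — one active unit matching the
founder driver's state code at stage 1 — and runs the full 15-stage
development.  The radius-1 event fills a 3x3x3 cube (27 cells) around the
founder and nothing further ever fires, because the freshly created drivers
carry new state codes that match no unit.
"""

from epitrack import develop
from epitrack.fixtures import engine_config_3d, one_unit_proliferation_genome

config = engine_config_3d()
genome = one_unit_proliferation_genome(config)
embryo, record = develop(genome, config)

print(f"grid: {config.grid_extent}, stages: {config.n_stages}")
print(f"final cell count: {embryo.n_cells()}")
print(f"events fired: {len(record.events)}")
for ev in record.events:
    print(
        f"  stage {ev.stage}: {ev.event_type.value} at {ev.driver_pos} "
        f"(radius {ev.radius}) created {ev.n_created}, removed {ev.n_removed}"
    )
print(f"drivers ever created: {record.total_drivers_created}")
# 27 cells = the 3^3 change volume; 26 were written, the trigger was kept.
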