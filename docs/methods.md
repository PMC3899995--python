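# Methods

This note records the model as implemented, the parameter choices that
matter, and the design decisions taken where the model description leaves
room — in enough detail that every number the tests and
`scripts/acceptance.py` compute can be traced to a rule stated here.

## Development engine

Development runs on a bounded integer lattice (2-D or 3-D, hard walls, at
most one cell per site) for `n_stages` stages, default 15. The embryo starts
as a single driver cell at the grid center whose state code (MOC) is the
all-zero sequence, i.e. counter value 0 under the base-A positional encoding
`encode_counter_as_seq`. The counter increments for every driver ever
created and is never reused, so driver MOCs are pairwise distinct by
construction; `EngineConfig` verifies at construction that the code space
`A**L` can name the worst case `1 + n_sites * n_stages` drivers.

**Triggering.** At each stage, the set of firing (driver, unit) pairs is
computed once against the stage-entry state: a driver fires the lowest-index
unit that is active, MOS-matches its MOC, and has TM equal to the clock
(at most one event per driver per stage; lowest index is the tie-break).
Events then execute sequentially in lexicographic driver-position order.
Consequences of this snapshot semantics: drivers created mid-stage wait
until the next stage, later events may overwrite earlier ones within a
stage, and a driver deleted by an earlier same-stage apoptosis silently
loses its turn. All three rules exist to make development a deterministic
pure function of (genome, config); the brute-force reference interpreter in
`tests/reference_interpreter.py` implements the same rules independently
and agrees voxel-for-voxel on randomized genomes.

**Events.** The change volume is the max-norm ball of radius `r` (an
axis-aligned square/cube) clipped at the walls — chosen over a Euclidean
ball because its cell counts are exactly enumerable in tests. Proliferation
writes every non-driver position in the volume: positions whose offset from
the trigger is divisible by `driver_spacing` on every axis become new
drivers (codes assigned in lexicographic position order), the rest become
stem cells with the unit's color; pre-existing drivers, the trigger
included, are preserved, keeping the driver scaffold stable under regrowth.
Apoptosis deletes everything in the volume including the trigger.
Bookkeeping treats an overwritten cell as one removal plus one creation, so
the per-stage invariant `total = previous − removed + created` holds
exactly and is asserted on randomized genomes.

**Stem vs normal.** Non-driver cells are labeled stem at birth and relabeled
normal one stage later. The distinction is purely annotational — both are
passive — reflecting that the model gives differentiated cells no
computational role beyond occupying a colored voxel.

**Dormancy.** After development, a surviving driver is *dormant* when it
never fired and its MOC matches no MOS anywhere in the genome, active or
not. Drivers whose MOC is matched by a unit that merely failed its switch or
timer condition are excluded from the pool: a single ordinary germline
mutation can rescue those, so they need no new genetic material.

## Genome and variation

MOC/MOS length and alphabet default to L = 8, A = 10. The 10^8 code space
makes a spontaneous MOS↔MOC match through random initialization or mutation
astronomically unlikely, which is the premise the germline-penetration
mechanism rests on. Matching is exact equality; a graded match is deliberately
not implemented.

Mutation hits each field of each unit independently: SW toggles, TM/radius/
color/event-type resample uniformly from their ranges, and each MOS symbol
resamples at `p_mos_symbol`, which defaults to 0 (an immutable MOS keeps the
ablation interpretable: with penetration off, the set of MOS values in the
population is fixed forever). Default rates (0.02 for SW/TM/radius/color,
0.01 for event type) are desk-scale choices: high enough that an 8–40 unit
genome sees a switch flip every few offspring, low enough not to randomize
tuned right parts. Mutation never resizes a genome; recombination is
one-point crossover at a unit boundary drawn uniformly on
`[0, min(len_1, len_2)]`, truncated to `genome_max_units` (64). Genome
growth therefore happens only through penetration, and shrinkage only
through the cap.

`tm_max` (20) deliberately exceeds `n_stages` (15): a unit whose timer lies
beyond the last stage can never fire in this life, one of the dormancy
routes the engine must represent.

## Germline penetration

Penetration samples up to `k_max` (default 2) codes uniformly without
replacement from the dormant pool of the offspring's *fitter parent*,
skipping codes already present as a MOS. Each becomes a new appended unit
with SW inactive, TM uniform on `[1, n_stages]` (so activation can ever
matter), and a uniform right part; truncation past the genome cap drops the
oldest penetrated units first. Randomizing the right part at insertion
rather than at activation keeps activation a pure switch flip, performed by
ordinary mutation in a later generation — penetration itself is
phenotypically neutral, a contract enforced by a dedicated check that
develops both genomes and compares voxel-for-voxel. `k_max = 2` caps genome
bloat so the on/off ablation is not confounded by genome length. Using the
fitter parent's development record (rather than a population-wide pool) is
the simplest heredity-consistent choice; penetration events are logged per
generation for inspection.

## Fitness and targets

`fitness = (n_match + w_color·n_shape_only − w_spurious·n_spurious) / |T|`
with defaults `w_color = 0.5`, `w_spurious = 1`. Partial color credit
smooths the landscape (a body of the right shape but wrong color is worth
evolving); normalizing the spurious penalty by target size keeps the empty
phenotype at exactly 0 rather than making it optimal for small targets.
Driver cells score by position but carry no color, so they earn shape-only
credit; a color-blind mode scores any covering cell as a match. Targets are
Euclidean discs/balls, boxes, or 2-D bitmaps mapped to nearest palette
colors; files are plain CSV voxel lists.

## Evolution loop

Generational with elitism (default 2 of 40), tournament selection (size 3 —
robust to the negative fitness values the spurious penalty can produce,
unlike fitness-proportional schemes), crossover probability 0.5, then
mutation, then penetration. All randomness derives from one master seed via
`numpy.random.SeedSequence` spawning, one stream per offspring per
generation, so runs replay exactly and the penetration-off arm of an
ablation is bit-identical whether or not the on arm ran. With elitism the
per-generation best fitness is checked non-decreasing while the loop runs.

Initial genomes are 8 units with uniform fields — which at L = 8, A = 10
means no initial unit matches any reachable MOC, so generation 0 always
scores ≈ 0 and every later gain is attributable to penetration plus
selection. A `bootstrap_match` option (first unit guaranteed to fire in the
founder) exists for demos and is off everywhere results are reported.

## Ablation experiment

The standard benchmark: 2-D disc of radius 8 (197 voxels) centered in a
24×24 grid, population 40, 200 generations, 5 paired replicates per arm.
Per-replicate seeds derive from the master seed; the two arms of a pair
differ only in `penetration_enabled`. Reported: per-arm median of the final
champion fitness and a one-sided paired sign test (binomial on the
informative pairs) for on > off. The claim tested is a stochastic ordering,
not a specific fitness value. These problem sizes are the package's
benchmark conditions; they run in well under a minute on one CPU while
leaving the on/off separation unambiguous (the off arm is pinned at the
founder-only score of 0.5/197 ≈ 0.0025 because no match can ever arise).

## What the synthetic inputs do and do not show

All inputs are synthetic: geometric targets and randomized genomes whose MOS
fields are biased toward counter codes so that event cascades actually
occur. They exercise every engine rule (growth, carving, overwriting,
clipping, dormancy, cascades) but are far from the million-cell bodies and
10^4–10^5-generation runs the model family is known for; passing tests here
show correctness of the mechanism and the direction of the penetration
effect at desk scale, not morphological richness at full scale. No attempt
is made to reproduce any specific published morphology.

## Numerical and degenerate-input choices

- Coordinates are 0-based; volumes clip at walls, never wrap.
- Tournament and argmax ties break toward the lower population index;
  sorting keys are always explicit, so runs are platform-independent.
- `radius ≥ 1` is enforced (a zero-radius event is rejected as a config
  error rather than silently affecting one cell).
- An empty genome is valid and develops into the untouched founder; an
  empty dormant pool makes penetration the identity.
- File formats are plain text (JSON genomes, YAML configs, CSV tables),
  written atomically (temp + rename), and round-trip field-for-field.

## Known limitations

- Exact matching only; threshold/graded matching would change the dormancy
  structure and is out of scope.
- Proliferation fills its volume in one step; there are no growth dynamics
  within a stage, no physics, and no cell signaling beyond MOS/MOC matching.
- The stem/normal distinction carries no behavior.
- Single-threaded; the benchmark sizes are chosen to fit that budget.
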