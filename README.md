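# epitrack

`epitrack` is a simulator for studying how *development* and *evolution*
couple in abstract multicellular "bodies". It implements an epigenetic-
tracking style model: a deterministic, staged developmental program on a
voxel lattice, orchestrated by a small subset of **driver cells**, embedded
in an evolutionary algorithm whose distinguishing operator — **germline
penetration** — feeds the states of developmentally dormant drivers back
into offspring genomes. It is aimed at researchers in artificial embryology
/ computational evo-devo who want a compact, fully reproducible testbed for
questions about evolvability and genome growth.

## The model

**Development.** A body grows on a bounded 2-D or 3-D integer lattice from a
single driver cell over `n_stages` discrete stages (default 15), counted by a
global clock GC. Every driver cell carries a *mobile code* (MOC): a length-L
sequence over the integer alphabet `[0, A)` (defaults L = 8, A = 10),
assigned injectively from a strictly increasing counter. The genome is an
ordered list of *genetic units*; each unit has a left part — switch SW,
*mobile sequence* MOS (a length-L code), timer TM — and a right part encoding
one developmental event. A unit **fires** in a driver when

1. SW is active,
2. MOS = MOC (exact symbol-wise match), and
3. TM = GC.

A firing driver triggers either **proliferation** (fill the axis-aligned
change volume of half-side *r* around it with cells, seeding new drivers with
fresh MOCs on a spacing-*d* sublattice, everything else becoming colored
stem cells) or **apoptosis** (clear the change volume, trigger included).
Development is a pure function of (genome, config): there is no randomness
in the engine.

**Fitness.** A developed body is scored against a colored voxel target T:

    fitness = (n_match + 0.5 · n_shape_only − n_spurious) / |T|

with full credit for a covered target voxel of the right color, half credit
for the wrong color, and a penalty for every cell outside the target.

**Evolution and germline penetration.** A population of genomes evolves by
tournament selection, one-point crossover, per-field mutation and elitism.
Because matching is exact over a 10^8 code space, a random or mutated MOS
essentially never matches any driver's MOC — so ordinary variation cannot
extend development. Germline penetration copies the MOCs of *dormant*
drivers (those that never fired and match no MOS anywhere in the genome)
from the fitter parent's development into the offspring genome as new units
with SW initially **inactive** — phenotypically neutral at insertion, and
activatable only by a later ordinary mutation. Switching penetration off
stalls evolution; the package ships a paired ablation harness that
demonstrates exactly this.

## A worked example

`examples/05_mini_evolution.py` evolves toward a radius-8 disc in a 24×24
grid (population 40, 60 generations, seed 42):

```
gen   0: best fitness  0.0025, mean  0.0025, best genome 8 units
gen  10: best fitness  0.3883, mean  0.3558, best genome 9 units
gen  50: best fitness  0.5152, mean  0.4304, best genome 20 units
gen  59: best fitness  0.5609, mean  0.5153, best genome 22 units

champion fitness: 0.5609
champion genome: 22 units (6 penetrated)
penetration events logged: 1747
```

At generation 0 nothing develops (the founder alone happens to sit inside the
disc, worth 0.5/197 ≈ 0.0025). Once a penetrated unit matching the founder's
code is activated by mutation, development starts and fitness climbs; the
champion genome has grown from 8 to 22 units, 6 of them penetrated. The
other examples each exercise one capability — deterministic development
(`01`, `02`), dormancy and neutral penetration (`03`), targets and the
fitness decomposition (`04`), and the penetration ablation (`06`).

The same machinery is available from a shell:

```bash
epitrack fixtures --out fixtures --seed 0
epitrack make-target disc --extent 24,24 --radius 8 --color 1 --out disc.csv
epitrack develop --genome fixtures/one_unit_proliferation.json \
                 --config fixtures/engine_3d.yaml --out run
epitrack ablate --config run.yaml --target disc.csv --out ablation
```

Every `evolve`/`ablate` run directory contains a config snapshot with the
master seed, from which the run replays byte-for-byte.

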