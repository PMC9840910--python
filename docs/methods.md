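# Methods

## The model

`antsim` simulates open-ended evolution of foraging behaviour in a
population of virtual organisms whose only sense is vision and whose only
controller is a fixed-topology perceptron.

**World.** A bounded rectangular plane carries point food particles and
disc-shaped organisms with a heading and a scalar speed. Time advances in
fixed ticks of `dt` seconds. Each tick, every live organism (in ascending
id order, which makes runs exactly reproducible) renders its first-person
frame, runs its network, decodes a motor command, moves, eats, pays its
hunger cost, and possibly reproduces. Deaths are removed and eaten food
replaced at the end of the tick.

**Vision.** The world is planar, so the camera is a "2.5D" ray-caster:
one ray per pixel column spans the horizontal field of view `fov` centred
on the heading; the nearest intersected disc within `view_range` colours
the column, and the billboard's vertical extent on screen is its angular
half-height `atan(h / 2d)` against a vertical field of view `fov * H/W`,
with a half-row floor so that anything within range is at least one pixel
tall. Food is pure green, organisms carry a brown-toned lineage colour
drawn once per founder, the background is mid-grey, and intensities live
in [0, 1] (8-bit quantisation happens only in PPM output). The frame is
flattened channel-major (all red values row-major, then green, then blue)
into the network's sensory layer — 2700 elements at the default 30x30
resolution, which matches the spatial resolution of real ant compound
eyes.

**Nervous system.** A feed-forward perceptron
`result_k = sigma(A_k result_{k-1} + b_k)` whose weights and biases are
the genome. The default architecture [2700, 297, 3] totals 3000 units;
both the layer split and the logistic nonlinearity are package choices
(the classic perceptron family offers several; logistic keeps reacting
activations directly comparable to a 0.5 firing threshold, and `tanh` and
a Heaviside `step` are available via `activation`). The three reacting
units vote turn-left, turn-right and speed-up; a unit fires above
`action_threshold` (strict inequality), both-or-neither turn votes mean
no turn, and a silent speed unit brakes toward rest. Speed changes by
`speed_step * dt` per tick, clamped to [0, `max_speed`].

**Energy budget.** Satiety starts at 8, is capped at `max_satiety` = 15,
drops one unit per `hunger_period`, and rises `food_energy` = 1 per
particle eaten (particles within `eat_radius` are consumed nearest-first,
and are consumed even when the eater is already full). Death occurs at
satiety 0. At satiety ≥ 0.7 x 15 = 10.5 the organism reproduces by
parthenogenesis: satiety is halved exactly between parent and child (so a
newborn, at ≤ 7.5, can never reproduce on its birth tick), the child
inherits the parent's network with per-element mutation, its generation
counter increments, and it appears at the parent's position facing the
opposite way, at rest.

**Mutation.** One mutation probability ε ~ U[a, b] is drawn per
reproduction; independently for every weight and bias element, with
probability ε the element changes by ±δ with a fair sign coin and
δ ~ U[c, d] drawn per mutated element. The granularity (ε per birth, δ per
element) is a package decision; drawing δ per element rather than per
birth gives offspring a spectrum of perturbation sizes without changing
the expected change rate. Defaults a = 0.1, b = 0.3, c = 0.02, d = 0.5
mutate ~20 % of the parameters per birth. The rate is deliberately brisk:
in a survival-gated ecology, new lineages must discover vision-guided
steering within a founder's short lifetime, and behavioural innovation
scales with the per-birth perturbation; the cost is a heavier mutation
load on established lineages, i.e. sustained turnover.

## Numerical and procedural choices

- **Boundary policy:** positions are clamped to the arena; heading is
  unchanged. Neutral and simple, but note it parks a straight-ahead mover
  on the wall until its own (changing) view alters its command — blind
  ballistic motion is therefore not a viable long-term strategy, which
  sharpens selection for vision-guided steering.
- **Food respawn:** eaten particles reappear immediately at uniform
  random positions, keeping the active count constant and the fitness
  landscape stationary.
- **Population cap** (`max_population`, default unbounded): constant-count
  respawn makes per-capita intake almost density-independent, so a
  successful lineage would otherwise grow without bound; at the cap
  births are suppressed while deaths and selection continue, and births
  resume the moment a slot opens.
- **Random streams:** four generators (placement, mutation, food,
  tiebreak) spawned from the master seed, so e.g. extra mutation draws
  never perturb food placement. Runs are bit-reproducible; metrics CSVs
  from identical configs are byte-identical.
- **Hunger accumulator:** per-organism elapsed-time accumulator with a
  1 ns tolerance, so a hunger period spanning an integer number of ticks
  fires on the expected tick despite float summation drift.
- **Ties:** coincident ray hits resolve to the lowest object index;
  coincident food distances consume in index order (stable sort).
- **Collisions:** organisms pass through each other; only food
  interacts.

## Metrics

A `LifetimeRecord` is sampled every `sample_interval` ticks: population,
cumulative births/deaths, the maximum lifetime ever observed (running
maximum over ages at death *and* current ages of the living, hence
monotone), the age of the oldest living organism, and the mean and RMS
deviation of age-at-death over deaths since the previous sample (NaN when
the window had no deaths). Lifetime is death time minus birth time in
simulated seconds; organisms alive at run end enter only the "current"
statistics. Extinction is recorded, not raised, so multi-run aggregation
grids stay aligned. `aggregate_runs` averages each metric pointwise
across runs (NaN-aware) and reports the RMS deviation across runs;
plotting the three lifetime curves with their deviation band is optional
output, never part of the tested contract.

For the lifetime-growth experiment, a run's *final-quarter mean lifetime*
is the mean age-at-death over deaths in the last quarter of simulated
time; if that window has no deaths (a saturated population pinned at the
cap) the mean age of the living at run end is used — a deathless final
quarter means everyone is old, so the substitution is not generous. The
*founding-cohort mean lifetime* averages the lifetimes of the organisms
present at t = 0 (survivors contribute their final age as a lower bound).

## The scaled experiment

The shipped `configs/lifetime_growth.txt` (= `scaled_config()`) runs the
evolution experiment at desk scale: a 30x30 arena, 55 food particles,
20 founders, population cap 60, 10x10 vision into a [300, 24, 3] network,
`hunger_period` 3 s, `dt` 0.1 s, 20 000 ticks (2 000 s), ten independent
seeds. Food density gives an idealised straight full-speed mover about
2.5x break-even intake, but wall-clamping and path self-overlap cut blind
trajectories to around break-even in practice; sustained persistence
therefore requires steering toward seen food. The regime is a deliberate
sweet spot found while designing the ecology: with sparser food or slower
mutation, founding populations often die out before any lineage discovers
steering; with denser food or larger capture radii the founders
themselves live a large fraction of the run and the lifetime-growth
contrast collapses. Under the shipped conditions populations persist,
founding cohorts die young (a non-eater lives exactly 8 x 3 = 24 s),
final-quarter lifetimes exceed the founding cohort's in nearly all runs
(occasional early extinctions remain possible — the outcome is
stochastic by nature), and the max-ever curve grows throughout — the
qualitative lifetime-growth signature of selection. Problem sizes (vision
resolution, arena, run length) were fixed once when the scaled
configuration was designed; the full-size default configuration runs the
identical code paths.

## What the simulation does and does not show

The generator emulates the functional ecology — vision-limited foraging,
a hard energy budget, heritable control with small mutations — not any
particular animal. Passing tests show the *mechanism* (selection on
vision-guided behaviour lengthens lifetimes) operates in this closed
world; they say nothing about absolute lifetimes, about 3D embodiment,
articulated bodies, collision physics, shadows or stereo vision (none of
which are modelled), nor about richer network architectures (the brain
interface accepts any layer list, but topology never changes within or
between generations here). The mean-lifetime estimator depends on the
windowing choice above; alternative estimators (e.g. sliding mean age of
the living) would shift the red curve but not the qualitative growth.

## Known limitations

- The renderer ignores occlusion by partial overlap within a column
  (nearest-hit wins whole columns) and renders no floor or sky gradient.
- With `max_population` unbounded, well-adapted populations grow until
  wall-clock cost, not biology, limits the run.
- `hunger_elapsed` continuity across a birth is inherited as 0 for the
  child; the parent keeps its phase.
- Event logs record births and deaths but not eating events (only a
  cumulative counter), so food-intake time series cannot be reconstructed
  post hoc.
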