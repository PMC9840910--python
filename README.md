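# antsim

Neuroevolution of vision-guided foraging: a population of virtual
organisms lives on a plane scattered with food. Each organism's only
sense is a low-resolution first-person colour camera (30x30 pixels by
default, comparable to the spatial resolution of ant compound eyes), and
its only controller is its own feed-forward perceptron whose weights are
its genome. There is no explicit fitness function: organisms that fail
to reach food starve; organisms that keep their energy reserve high
reproduce by parthenogenesis, passing on a mutated copy of their
network. Over a run, selection on heritable steering behaviour lengthens
lifetimes across the population.

The package is for researchers and students in artificial life /
neuroevolution who want a small, fully deterministic, scriptable
testbed: every run is bit-reproducible from one seed, all inputs are
generated internally, and all outputs are plain text (CSV metrics,
JSON-lines event logs, P3 PPM frame dumps).

## Model in brief

- **Vision**: one ray per pixel column across a field of view `fov`
  centred on the heading; nearest disc within `view_range` colours the
  column with a distance-scaled vertical billboard. The frame flattens
  channel-major (R block, then G, then B, each row-major) into the input
  vector — 2700 elements at 30x30.
- **Brain**: `result_k = sigma(A_k result_{k-1} + b_k)`, logistic sigma by
  default; default layers [2700, 297, 3] total 3000 units. The three
  output units drive turn-left / turn-right / speed via a 0.5 threshold.
- **Energy**: satiety starts at 8, caps at 15, −1 per hunger period, +1
  per food particle; death at 0; at satiety ≥ 15 x 0.7 = 10.5 the
  organism splits its satiety equally with a descendant.
- **Mutation**: per birth, probability ε ~ U[a, b]; each weight/bias
  element then changes by ±δ (fair sign, δ ~ U[c, d] per element) with
  probability ε.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Run three short simulations under the shipped desk-scale evolution
configuration, then aggregate them:

```sh
antsim run -c configs/lifetime_growth.txt --seed 2 -o runs/s2
antsim run -c configs/lifetime_growth.txt --seed 3 -o runs/s3
antsim run -c configs/lifetime_growth.txt --seed 4 -o runs/s4
antsim aggregate runs/s2 runs/s3 runs/s4 -o curves.csv --plot curves.png
```

The first command prints (stderr progress omitted):

```
config digest 9e9f47af6eb8  seed 2
done: 20000 ticks, population 60, births 102, deaths 62, max lifetime ever 2000.0 s
```

meaning the run completed 20 000 ticks (2 000 simulated seconds), ended
with 60 live organisms (the configured cap), saw 102 births and 62
deaths after the 20 founders, and some individual lived the whole
2 000 s — two orders of magnitude beyond the 24 s a non-feeding organism
survives.
`runs/s2/metrics.csv` holds one row per 100 ticks with the population
size and the three lifetime statistics (max-ever, current-max, mean ± RMS
deviation of age at death); `curves.csv` carries their across-run mean
and deviation, and `curves.png` the three-curve plot.

The same machinery is available as a library:

```python
import antsim

cfg = antsim.scaled_config(seed=2)
result = antsim.run_simulation(cfg)
print(round(antsim.initial_cohort_mean_lifetime(result), 1),
      round(antsim.final_quarter_mean_lifetime(result), 1))
```

which prints `558.4 1314.0` — the founding random cohort lived ~560 s on
average (this seed's founders included some capable foragers), while
deaths in the final quarter of the run occurred at a mean age of
~1 310 s.

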