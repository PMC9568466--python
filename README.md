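# habgame

Population games with instantaneous habitat choice, instantiated on a
behaviorally modified Rosenzweig–MacArthur predator–prey model of a water
column. Zooplankton (consumers) and forage fish (predators) each distribute
themselves over depth to maximize individual instantaneous fitness; the
resulting mean-field Nash equilibrium is computed at every instant and
coupled to slow population dynamics.

## What it does

* **Habitat discretization** — the column `[0, depth_max]` carries the
  uniform probability measure; strategies are densities on a uniform node
  grid with trapezoidal quadrature (`habgame.grid`).
* **Model rates** — depth profiles (light-driven carrying capacity,
  visual-predation clearance), per-capita growth/mortality for both
  species, and the strategy gradients of the individual payoffs
  (`habgame.model`).
* **Nash solver** — the stacked KKT/complementarity system of the
  two-species instantaneous game, reformulated with a (smoothed)
  Fischer–Burmeister function and solved by damped semismooth Newton with
  analytic Jacobians, an active-set polish, and multistart fallbacks
  (`habgame.nash`). Independent oracles: consumer best response and a
  replicator-dynamics-based solver.
* **Population equilibrium** — the coupled population–Nash fixed point via
  an outer root solve on log-populations with warm-started inner game
  solves, plus continuation sweeps over carrying capacity `K` and predator
  competition `c` (`habgame.equilibrium`).
* **Dynamics** — forward-Euler transients with the game re-solved each
  step, the constant-behavior (uniform strategy) baseline, and oscillation
  diagnostics (`habgame.dynamics`).
* **Diagnostics** — ideal-free-distribution geometry, evolutionary
  stability against sampled mutants, and sampled pseudomonotonicity probes
  of the game operator (`habgame.diagnostics`).

## CLI

All subcommands accept `--config FILE` (YAML/JSON) plus flags that override
it, and write their outputs together with a `resolved_config.json`
provenance record into `--out`:

```sh
habgame equilibrium --K 3 --c 0 --out runs/eq            # fixed point + strategies
habgame nash --K 3 --c 0 --Nc 1 --Np 1 --out runs/nash   # instantaneous game
habgame simulate --K 40 --c 0 --mode constant --out runs/rm
habgame simulate --K 40 --c 0 --mode optimal --out runs/game
habgame sweep --sweep K --values 1,2,4,8,16 --c 0 --out runs/sweepK
habgame check --K 3 --c 0.2 --Nc 0.4 --Np 0.02 --out runs/check
```

Model parameters default to the published table (masses, Kleiber-law
scalings, light attenuation, etc.); `K` and `c` are the experiment knobs.

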