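# coopdyn

Cooperation dynamics in long-run finitely repeated Prisoner's Dilemma.

`coopdyn` is for researchers studying what happens to cooperation when the
same population plays a finitely repeated social dilemma many hundreds of
times: does end-game defection creep earlier and earlier until cooperation
*unravels* completely, or can a minority of determined conditional
cooperators stabilise it?  The package provides, as one tested pipeline:

* a deterministic engine for the ten-round Prisoner's Dilemma (payoffs
  T=7 > R=5 > P=3 > S=1, so the normalised temptation and loss are
  g = (T−R)/(R−P) = 1 and l = (P−S)/(R−P) = 1) over the 11-strategy set
  {T_1, …, T_10, CC}: threshold strategy T_x conditionally cooperates (with
  grim retaliation) through round x−1 and defects from round x; CC is the
  grim trigger; T_1 is ALLD;
* a **smoothed fictitious play** agent-based model: a fraction α of
  *resilient cooperators* always plays CC, while rational agents keep counts
  π_i(t) of the strategies past opponents played and choose
  s ~ P(s) ∝ exp(u_i(s)/β) with u_i(s) = Σ_t π̂_i(t)·U[s,t], where U is the
  closed-form 11×11 strategy payoff table;
* **strategy inference** from behavioural game logs: per-game consistency
  indicators resolved over time by the EWMA
  w_{i,s}(j) = 1_{i,s}(j) + γ·w_{i,s}(j−1) with γ = 0.818, argmax assignment
  with deterministic tie-breaks, and resilient-cooperator classification
  (≥ 80% CC in the stable phase);
* experiment analytics: cooperation trajectories, game and session restart
  effects, distributions of the round of first defection r_d (with a C bin
  for fully cooperative games), adjacent-day Kolmogorov–Smirnov tests for
  steady-state onset, and the random-pairing identity (a no-defection game
  rate q implies a conditional-cooperator fraction √q);
* a seeded **synthetic experiment generator** (two sessions, 94 players,
  20 days × 20 games × 10 rounds, planted types, drift-then-plateau
  thresholds, action noise, dropouts) so the whole pipeline runs and is
  testable with no external data.

## Worked example

```python
import numpy as np
from coopdyn import FictitiousPlayModel, SimConfig, sweep_alpha

model = FictitiousPlayModel(SimConfig(N=100, alpha=0.4, n_games=2000, seed=1))
res = model.simulate()
print(res.summary())
```

prints

```
Smoothed fictitious play simulation
-----------------------------------
N = 100  alpha = 0.400  (resilient: 40)
H = 10  beta = 0.005  games = 2000  seed = 1
r_inf (final 25% of games) = 8.677
modal rational strategy = T_9
rational strategy shares (whole run):
  T_8    28.9%
  T_9    54.1%
  T_10   17.0%
```

With 40% resilient cooperators, unravelling halts: the asymptotic round of
first defection among rational players, r_∞ ≈ 8.7, stays near the top of the
ten-round game, and the modal rational strategy is T_9 (defect from round 9)
with substantial T_10 and T_8 shares.  Setting `alpha=0` instead drives
r_∞ to 1 (complete unravelling, everyone at ALLD); a sweep

```python
sw = sweep_alpha(np.arange(0, 0.301, 0.025), reps=10,
                 cfg=SimConfig(N=100, n_games=2000, seed=42))
print(f"alpha* = {sw.alpha_star:.3f}")       # alpha* = 0.050
```

locates the critical mass: the largest resilient fraction still on the
complete-unravelling floor sits at 0.05 on this grid, with r_∞ rising
sharply just above it — a small committed minority (on the order of 10% of
the population) is enough to rescue cooperation for everyone.

The same analysis can run from the shell:

```
coopdyn generate --seed 1 --out-dir out          # synthetic experiment log
coopdyn infer    --log out/game_log.csv --out-dir out
coopdyn analyze  --log out/game_log.csv --out-dir out
coopdyn sweep    --alphas 0:0.3:0.025 --reps 10 --out-dir out
```

With `--seed 1`, `infer` reports 35 of 94 players as resilient cooperators
(the planted fraction is 40% = 38 players; the default 2% action noise makes
a handful of grim players fall just under the 80% criterion) and `analyze`
finds the steady-state onset at day 8, one day after the planted plateau.
On a noiseless log (`--eps 0`) the stable-phase no-defection game rate is
≈ 0.15 and the implied conditional-cooperator fraction √0.15 ≈ 0.39 recovers
the planted 40%; under action noise the raw rate is biased low (a single
tremble spoils a fully cooperative game), at 0.097 for this seed.

## Layout

```
src/coopdyn/payoffs.py    game engine and 11x11 payoff table
src/coopdyn/learning.py   smoothed fictitious play model, r_inf, alpha sweep
src/coopdyn/inference.py  consistency indicators, EWMA, resilient flags
src/coopdyn/stats.py      cooperation/restart/r_d analytics, KS onset tests
src/coopdyn/synth.py      synthetic experiment generator with ground truth
src/coopdyn/io.py         long-format log IO and validation
src/coopdyn/cli.py        command-line pipeline
docs/methods.md           model and design notes
```
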