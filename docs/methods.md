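# Methods and design notes

This note documents the models implemented in `coopdyn`, the parameters that
matter, the numerical choices behind them, and what the synthetic-data tests
do and do not establish.

## The game

Two players repeat a Prisoner's Dilemma for a fixed, known horizon of
H = 10 rounds.  Per-round payoffs default to T = 7, R = 5, P = 3, S = 1
(points), satisfying T > R > P > S and 2R > T + S, and giving normalised
temptation g = (T − R)/(R − P) = 1 and loss l = (P − S)/(R − P) = 1 — a
comparatively cooperation-friendly corner of the PD parameter space.  The
strategy set is the eleven pure strategies that dominate observed play in
such experiments:

* T_x (x = 1..10): conditionally cooperate through round x − 1, defect
  unilaterally from round x, and retaliate grimly (defect forever after the
  partner's first defection).  T_1 is unconditional defection (ALLD).
* CC: the grim trigger — cooperate until the partner defects, then defect
  forever.

"Conditional cooperation" is implemented as *grim*, not tit-for-tat; the
rare forgiving variant (briefly resuming cooperation after one's own
threshold defection) is handled in the inference layer, not the engine.
Every strategy reduces to an effective threshold e(s) ∈ {1..11} (the first
round of unilateral defection; 11 = never).  Between two such strategies the
playout is fully determined: with a = min(e1, e2) capped at H + 1, the pair
cooperates mutually through round a − 1, the lower-threshold player defects
at a (both, if tied), and both defect thereafter.  This yields the
closed-form 11×11 total-payoff table used throughout; it is verified
exactly, for every ordered strategy pair and every horizon H = 2..12,
against the independent round-by-round engine.

Rounds, games and days are 1-based.  A game in which nobody defects has
first-defection round r_d = none, encoded numerically as H + 1 everywhere a
number is needed (the "C" bin of histograms, the value 11 in test samples).

## The learning model

Smoothed fictitious play over the 11-strategy set, with two agent types:

* *resilient cooperators* (a fraction α of the N agents, round(αN) of them):
  play CC in every game, never update;
* *rational* agents: maintain a count vector π_i over the 11 strategies of
  what their past opponents played; before each game they compute expected
  utilities u_i(s) = Σ_t π̂_i(t) U[s, t] against the normalised counts and
  sample their strategy from P(s) ∝ exp((u_i(s)/u_scale)/β).

Each game is one uniform random perfect matching of the population; after
it, each rational agent increments the count of the strategy its partner
actually played (true label; a censored variant that splits the increment
over all strategies consistent with the observed actions is available but
not default — see "Design choices").

Parameters, defaults and units:

| parameter | default | meaning |
|---|---|---|
| N | 100 | population size (even) |
| α | — | resilient fraction; round(αN) planted |
| H | 10 | rounds per game |
| β | 0.005 | softmax temperature, in game points |
| u_scale | 1.0 | divisor applied to utilities before the softmax |
| prior | "cc" | one pseudo-count on CC (cooperative first impressions) |
| n_games | 2000 | run length |
| r_inf_window | 0.25 | final fraction of games used for r_∞ |

**Utility scaling.**  Utilities enter the softmax in raw game points
(u_scale = 1).  The smallest decision-relevant utility gaps in this system
are ≈ 0.4 points (e.g. T_9 vs T_10 against a 40% grim mixture), so
β = 0.005 makes the choice effectively a sharp best response, and the
model's predictions are insensitive to β across 0.001–0.1 — a robustness
property the model should have, since nothing in the science singles out a
particular temperature.  The alternative of rescaling utilities to [0, 1]
(u_scale = T·H = 70) was evaluated and rejected: it turns β = 0.005 into a
soft choice rule whose predictions swing strongly with β (the stabilised
first-defection round moves from 8.8 to 6.8 across the same β range) and
sit ≈ 0.3 rounds higher at α = 0.4.

**Sampling.**  Softmax draws use the Gumbel-max trick: argmax(z + Gumbel
noise) with z = u/(u_scale·β).  This is exactly softmax sampling and stable
for arbitrarily small β (no overflow, no explicit normalisation).  A single
seeded generator drives pairing and choice; identical configs reproduce
bit-identical results.

**The order parameter r_∞.**  r_∞ is the round of first defection averaged
over *rational players'* games — a pairing of two rational agents
contributes two observations, a rational–resilient pairing one, a
resilient–resilient pairing none — over the final 25% of a run of at least
2000 games (the population reaches its quasi-stationary strategy mixture
well before game 1500 for all α; at α = 0.4 the round-9 cooperation rate
changes by < 0.05 between games 2000–2500 and 3500–4000 of a 4000-game
run).  At α = 1 there are no rational players and r_∞ is undefined (raised
as an error rather than returned as a number).  Averaging per rational
player rather than per pairing matters only at intermediate α (8.67 vs 8.73
at α = 0.4); the per-pairing variant can be had by weighting manually from
the stored per-game sums.

**Critical mass.**  `sweep_alpha` estimates r_∞(α) on a grid with
independent replicates (seeds spawned deterministically from one root
seed).  α* is reported as the largest grid value whose mean r_∞ stays on
the complete-unravelling floor, operationalised as r_∞ ≤ 1 + ε with
ε = 0.5 — the floor sits at exactly 1.0 and the first departed grid point
jumps to ≈ 1.8, so any ε in (0.1, 0.7) gives the same answer on the default
grid.  With the default conditions the transition sits between α = 0.05
(last on the floor) and α = 0.125 (first fully stabilised point), i.e. a
committed minority of roughly a tenth of the population suffices.

**What the model omits.**  No session/day structure (a "day" is just 20
games for reporting), no dropouts, no session restart effect — the learning
model is not expected to reproduce that feature of experimental data — and
no fitting of β or the prior to data.

## Strategy inference

Observed play often cannot identify a strategy uniquely: a grim player
whose partner first defects at round 5 plays exactly as T_6..T_10 would
have.  The per-game *consistency indicator* therefore flags every strategy
whose simulation against the opponent's observed actions reproduces the
player's actions exactly (a strictest single-match variant is available
behind a flag).  A game consistent with nothing is flagged OTHER, which
participates in the recursion exactly like a named strategy.

The forgiving threshold variant — defect at x, then resume cooperating for
a round or two while the partner still cooperates — is folded into T_x: up
to 2 mismatched rounds are tolerated when they all follow the threshold
round, the player's excess actions are C, and the partner cooperated on
round x.  The window of 2 reflects how short-lived the observed forgiveness
is; setting it to 0 disables the tolerance.

Identity is resolved over time by the EWMA
w_{i,s}(j) = 1_{i,s}(j) + γ·w_{i,s}(j−1) with w(0) = 0 and γ = 0.818
(≈ a 10-game period, half an experimental day).  Weights are bounded by
1/(1−γ) ≈ 5.49; γ = 0 collapses the assignment to the current game.  The
per-game assignment is argmax_s w with deterministic tie-breaks: named
strategies beat OTHER; threshold strategies beat CC (so a single
ambiguous game never masquerades as grim commitment); among tied thresholds
the largest x — the most cooperative consistent reading — wins, which keeps
assignments stable as opponents' defection rounds vary.  Missing games skip
the recursion with weights carried over unchanged (a decay-across-gaps
variant is available).

A player is a *resilient cooperator* when ≥ 80% of their non-missing
stable-phase games (days 7–20 by default) are assigned CC; a player with no
classifiable stable games is reported as unclassifiable rather than
defaulted.

## Experiment analytics

* Cooperation rates are fractions of C among individual decisions under
  arbitrary session/day/game/round slices.
* The game restart effect on a day is the mean of
  coop(round 1, game j+1) − coop(round 10, game j); the session restart
  effect compares round-9/10 cooperation in the first game of day d+1
  against the last game of day d.
* r_d distributions per day run over {1..10, C}; fully cooperative games
  occupy the C bin and enter test samples as the value 11 (they are part of
  the distribution, not censored; an exclusion flag exists).
* Steady-state onset: two-sample KS tests (asymptotic p-values; the test is
  conservative on this discrete support) on pooled adjacent-day r_d
  samples, sessions pooled, one observation per pair-game.  The onset is
  the arrival day of the first non-significant adjacent pair at level 0.05.
  The stricter rule — require every later pair to be non-significant too —
  is available but not default: over k genuinely stable adjacent pairs it
  false-alarms with probability ≈ 1 − (1 − fp)^k (~14% over 13 stable days
  at the measured ~1% per-pair rate), pushing the reported onset many days
  late on a single spurious rejection, and measurably fails to recover a
  planted change point in ~1 run in 7.  A Mann–Whitney variant of the test
  and a permutation p-value (exact under ties) are provided as robustness
  options.
* The random-pairing identity: with partners assigned uniformly at random,
  a fully cooperative game requires two conditional cooperators, so a
  no-defection game rate q implies a conditional-cooperator fraction √q.

## Synthetic experiments

The generator emulates the *structure* of the long-run experiment — two
even-sized sessions (48 and 46 players by default), 20 days × 20 games × 10
rounds, uniform random within-session pairing — with planted ground truth:
round(αN) resilient players per session (α = 0.4 by default) playing CC
throughout, and rational players following scripted thresholds that drift
linearly from 11 (grim) on day 1 to 9 at day 7 and plateau there.
Fractional scheduled thresholds are realised by stochastic rounding and
perturbed by ±1 jitter with probability 0.2 per player-game, so the r_d
distribution shifts smoothly every drifting day and has realistic spread in
the plateau.  Intended actions are flipped independently with probability
ε = 0.02 (trembling hand, applied after strategy resolution — flips do not
trigger behavioural reactions within the game).  Optional per-day dropout
hazard removes players permanently; an odd survivor count benches one
random player per game.  A `learning` mode drives rational players with the
fictitious-play model instead of the script, for end-to-end realism; the
scripted mode is the default precisely so that inference tests do not
depend on the learning model's own behaviour.

Under the defaults this reproduces the qualitative shape of the real data:
day-1 round-1 cooperation ≈ 0.98, overall daily cooperation ≥ 0.84
throughout, steady-state onset recovered at day 7 ± 1, ~35–38 of 94 players
classified resilient, and (noiselessly) a stable-phase no-defection rate of
≈ 0.15 whose square root recovers the planted 40%.

**What passing these tests does not show.**  The generator's rational
players are *scripted*: recovery tests validate the inference and analytics
machinery, not any behavioural theory.  Real logs contain strategies
outside the 11-strategy set, non-stationary noise, and the session restart
effect, none of which the generator emulates; the OTHER rate on real data
is therefore expected to be higher and structured rather than noise-like.
Action noise biases two quantities in known directions: the no-defection
game rate (downward — one tremble spoils a fully cooperative game, a factor
(1−ε)^2H ≈ 0.67 at ε = 0.02) and hence the implied cooperator fraction, and
the resilient count (slightly downward via the 80% criterion).

## Problem sizes

Unit tests run on populations of 2–40 agents and logs of a few hundred
rows; the quantitative endpoint checks use the full study conditions
(N = 100, 2000–4000 games, 10 replicates; the α sweep is 13 grid points ×
10 replicates) and the experiment-scale synthetic log (94 players, 376 000
decisions; 50 replicates for the change-point recovery rate).  The whole
suite completes in a few minutes on one CPU.
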