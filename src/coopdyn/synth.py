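"""Experiment-shaped synthetic game logs with known ground truth.

Emulates the structure of the long-run virtual-lab experiment — two
sessions of ~47 players each, 20 days of 20 ten-round games with uniform
random within-session pairing — with planted player types so that the
inference and analytics modules can be validated without any external data:

* a fraction ``alpha`` of players are *resilient* and play the grim trigger
  (CC) in every game;
* the remaining *rational* players follow threshold strategies whose
  threshold drifts earlier over the first week and then plateaus
  (``scripted`` mode, the default: a deterministic drift schedule plus
  per-game jitter, decoupled from the learning model so the two test
  surfaces stay independent), or are driven by the smoothed fictitious play
  model (``learning`` mode);
* each intended action is flipped independently with probability ``eps``
  (trembling-hand noise, applied after the strategies are resolved);
* players may drop out (per-day hazard); when an odd number remains, one
  random player sits out the game.

The fractional drift schedule is realised by stochastic rounding: a
threshold of 9.4 means playing ``T_9`` with probability 0.6 and ``T_10``
with probability 0.4, so the population distribution of first defections
shifts a little every day during the unravelling phase rather than in
occasional unit jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .learning import Population, SimConfig, step_game
from .payoffs import STRATEGY_NAMES, strategy_payoff_table

__all__ = ["SynthConfig", "GroundTruth", "generate", "default_experiment_config"]

_CC_E = 11  # effective threshold of CC


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic experiment.

    ``session_sizes`` holds the player count of each session (must be even:
    the real experiment kept sessions pairable by design).  The scripted
    drift schedule moves every rational player's threshold linearly from
    ``start_threshold`` (11 = CC, never defect first) on day 1 to
    ``plateau_threshold`` on ``plateau_day`` and holds it there.
    """

    session_sizes: tuple[int, ...] = (48, 46)
    alpha: float = 0.4
    days: int = 20
    games_per_day: int = 20
    H: int = 10
    rational_mode: str = "scripted"
    start_threshold: float = 11.0
    plateau_day: int = 7
    plateau_threshold: int = 9
    jitter_prob: float = 0.2
    eps: float = 0.02
    dropout_prob: float = 0.0
    seed: int = 0
    learning: SimConfig | None = None  # template for rational_mode="learning"

    def __post_init__(self) -> None:
        if not self.session_sizes or any(n <= 0 or n % 2 for n in self.session_sizes):
            raise ValueError("session sizes must be positive and even")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.rational_mode not in ("scripted", "learning"):
            raise ValueError("rational_mode must be 'scripted' or 'learning'")
        if not 1 <= self.plateau_day <= self.days:
            raise ValueError("plateau_day must lie in 1..days")
        if not 1 <= self.plateau_threshold <= self.H:
            raise ValueError(f"plateau_threshold must lie in 1..{self.H}")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must lie in [0, 1]")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")

    def theta(self, day: int) -> float:
        """Scheduled mean threshold of rational players on a given day."""
        if self.plateau_day == 1:
            return float(self.plateau_threshold)
        frac = min(day - 1, self.plateau_day - 1) / (self.plateau_day - 1)
        return float(
            self.start_threshold
            - (self.start_threshold - self.plateau_threshold) * frac
        )


@dataclass
class GroundTruth:
    """Planted truth behind a synthetic log."""

    types: pd.Series  # player -> "resilient" / "rational"
    true_strategies: pd.DataFrame  # long: session, day, game, player, strategy
    plateau_day: int

    def resilient_players(self) -> pd.Index:
        return self.types.index[self.types == "resilient"]


def default_experiment_config(seed: int = 0) -> SynthConfig:
    """The experiment-scale default: 94 players in two sessions, 20x20 games,
    40% resilient cooperators, thresholds drifting to T_9 by day 7, 2% noise."""
    return SynthConfig(seed=seed)


def _scripted_thresholds(
    cfg: SynthConfig, n_rat: int, day: int, G: int, rng: np.random.Generator
) -> np.ndarray:
    """(G, n_rat) integer thresholds for one day of scripted play."""
    th = cfg.theta(day)
    base = np.floor(th) + (rng.random((G, n_rat)) < (th - np.floor(th)))
    jitter = np.zeros((G, n_rat))
    mask = rng.random((G, n_rat)) < cfg.jitter_prob
    jitter[mask] = rng.choice((-1.0, 1.0), size=int(mask.sum()))
    return np.clip(base + jitter, 1, _CC_E).astype(int)


def _emit_game(
    session: str,
    day: int,
    game: int,
    players: np.ndarray,
    e: np.ndarray,
    H: int,
    eps: float,
    rng: np.random.Generator,
    rows: list,
) -> None:
    """Append the long-format rows of one game (players already paired in order)."""
    n = players.size
    pairs = players.reshape(-1, 2)
    e_pairs = e.reshape(-1, 2)
    a = e_pairs.min(axis=1)
    rounds = np.arange(1, H + 1)
    # intended: C iff r <= a (nobody defected yet) and r < own threshold
    coop = (rounds[None, None, :] <= a[:, None, None]) & (
        rounds[None, None, :] < e_pairs[:, :, None]
    )  # (n/2, 2, H)
    coop = coop.reshape(n, H)
    if eps > 0:
        coop ^= rng.random(coop.shape) < eps
    partner = pairs[:, ::-1].reshape(n)
    rows.append(
        pd.DataFrame(
            {
                "session": session,
                "day": day,
                "game": game,
                "round": np.tile(rounds, n),
                "player": np.repeat(players, H),
                "partner": np.repeat(partner, H),
                "action": np.where(coop.reshape(-1), "C", "D"),
            }
        )
    )


def generate(cfg: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic experiment log with its ground-truth sidecar.

    Fully seeded: identical config (including seed) gives an identical log.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    types: dict[str, str] = {}

    for si, n_players in enumerate(cfg.session_sizes, start=1):
        session = f"s{si}"
        players = np.array([f"{session}p{k:02d}" for k in range(1, n_players + 1)])
        n_res = int(round(cfg.alpha * n_players))
        res_idx = rng.choice(n_players, size=n_res, replace=False)
        resilient = np.zeros(n_players, dtype=bool)
        resilient[res_idx] = True
        for p, r in zip(players, resilient):
            types[p] = "resilient" if r else "rational"

        if cfg.rational_mode == "learning":
            _generate_learning_session(cfg, session, players, resilient, rng, rows, truth_rows)
            continue

        exit_day = np.full(n_players, cfg.days + 1)
        if cfg.dropout_prob > 0:
            # per-day hazard; a player present on `day` iff day < exit_day
            draws = rng.random((n_players, cfg.days))
            dropped = draws < cfg.dropout_prob
            has = dropped.any(axis=1)
            exit_day[has] = dropped.argmax(axis=1)[has] + 1

        for day in range(1, cfg.days + 1):
            active = np.nonzero(day < exit_day)[0]
            rat_active = active[~resilient[active]]
            th_all = _scripted_thresholds(
                cfg, rat_active.size, day, cfg.games_per_day, rng
            )
            for g in range(1, cfg.games_per_day + 1):
                pool = active.copy()
                if pool.size % 2:
                    pool = np.delete(pool, rng.integers(pool.size))
                if pool.size == 0:
                    continue
                order = rng.permutation(pool)
                e = np.full(n_players, _CC_E)
                e[rat_active] = th_all[g - 1]
                e_order = e[order]
                _emit_game(
                    session, day, g, players[order], e_order, cfg.H, cfg.eps, rng, rows
                )
                truth_rows.append(
                    pd.DataFrame(
                        {
                            "session": session,
                            "day": day,
                            "game": g,
                            "player": players[order],
                            "strategy": [
                                "CC" if v == _CC_E else f"T_{v}" for v in e_order
                            ],
                        }
                    )
                )

    log = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return log, GroundTruth(
        types=pd.Series(types, name="type").rename_axis("player"),
        true_strategies=truth,
        plateau_day=cfg.plateau_day,
    )


def _generate_learning_session(
    cfg: SynthConfig,
    session: str,
    players: np.ndarray,
    resilient: np.ndarray,
    rng: np.random.Generator,
    rows: list,
    truth_rows: list,
) -> None:
    """Drive one session's play with the smoothed fictitious play model."""
    n = players.size
    base = cfg.learning if cfg.learning is not None else SimConfig(N=n, H=cfg.H)
    sim_cfg = replace(base, N=n, H=cfg.H, alpha=resilient.mean())
    U = strategy_payoff_table(H=cfg.H, M=sim_cfg.payoffs)
    pop = Population(
        resilient=resilient,
        beliefs=np.tile(sim_cfg.prior_counts(), (n, 1)),
        strategies=np.full(n, 10, dtype=np.int64),
    )
    e_lookup = np.minimum(np.arange(1, 12), cfg.H + 1)
    for day in range(1, cfg.days + 1):
        for g in range(1, cfg.games_per_day + 1):
            out = step_game(pop, U, sim_cfg, rng)
            order = out["pairs"].reshape(-1)
            e_order = e_lookup[pop.strategies[order]]
            _emit_game(
                session, day, g, players[order], e_order, cfg.H, cfg.eps, rng, rows
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "session": session,
                        "day": day,
                        "game": g,
                        "player": players[order],
                        "strategy": [STRATEGY_NAMES[s] for s in pop.strategies[order]],
                    }
                )
            )
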