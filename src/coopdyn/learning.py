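"""Smoothed fictitious play with a planted fraction of resilient cooperators.

The population holds ``N`` agents of two types.  *Resilient* agents play the
grim trigger (``CC``) in every game and never change.  *Rational* agents keep
a vector of counts ``pi_i`` over the 11 pure strategies, recording how often
past opponents played each one; before each game they compute the expected
utility of every strategy against the empirical opponent mixture,

    u_i(s) = sum_t  pihat_i(t) * U[s, t],

where ``U`` is the closed-form 11x11 strategy payoff table and ``pihat`` is
``pi`` normalised to a probability vector, and then sample a strategy from a
softmax,

    P(s)  proportional to  exp( (u_i(s) / u_scale) / beta ).

``beta -> 0`` is best response, ``beta -> inf`` is uniform choice.  By
default ``u_scale = 1``: utilities enter the softmax in raw game points, so
``beta`` is a temperature in points and the default ``beta = 0.005`` is an
effectively sharp best response.  This is the only scaling under which the
model's predictions are insensitive to ``beta`` across 0.001-0.1 (smallest
relevant utility gaps are ~0.4 points, two orders of magnitude above the
temperature), a robustness property the model is expected to have; dividing
by the maximum game payoff instead (``u_scale = T * H = 70``) makes the
choice rule soft and beta-sensitive and raises the stabilised first-defection
round by ~0.3.  Each game every agent is paired uniformly at random with one partner
(a random perfect matching of the population), and after the game each
rational agent's count for the partner's strategy is incremented by one.

The headline observable is ``r_inf``: the round of first defection averaged
over rational players (a pairing of two rational agents contributes two
observations, a rational-resilient pairing one, an all-resilient pairing
none), estimated over the final window of a long run.  Sweeping the resilient fraction ``alpha`` traces the
critical-mass transition: below a critical ``alpha*`` cooperation unravels
completely (``r_inf = 1``); above it ``r_inf`` rises sharply towards 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .payoffs import PayoffMatrix, STRATEGY_NAMES, strategy_payoff_table

__all__ = [
    "SimConfig",
    "Population",
    "SimulationResults",
    "FictitiousPlayModel",
    "expected_utilities",
    "softmax_choice",
    "step_game",
    "run_simulation",
    "estimate_r_inf",
    "sweep_alpha",
    "AlphaSweepResults",
]

_N_STRATS = 11
_CC = 10  # index of CC in the canonical order


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one agent-based run.

    Parameters
    ----------
    N : int
        Population size (even; each game is a perfect matching).
    alpha : float
        Fraction of resilient cooperators; ``round(alpha * N)`` agents are
        planted as unconditional grim players.
    H : int
        Rounds per game.
    n_games : int
        Number of games (matchings) to simulate.
    beta : float
        Softmax temperature, in the units utilities carry after division by
        ``u_scale`` (game points by default).
    prior : str or array-like
        Initial pseudo-counts: ``"cc"`` (one count on CC — agents start out
        believing others conditionally cooperate) or ``"uniform"`` (1/11 on
        each strategy), or an explicit length-11 nonnegative vector.
    u_scale : float
        Divisor applied to utilities before the softmax.  The default 1.0
        keeps utilities in raw game points (see the module docstring);
        ``T * H`` rescales them to [0, 1].
    seed : int
        Seed for the single generator driving pairing and choice.
    r_inf_window : float
        Fraction of final games over which ``r_inf`` is estimated.
    censored_updates : bool
        If True, beliefs are updated with every strategy *consistent* with
        the opponent's observed actions (split evenly) rather than the
        opponent's true sampled strategy label.
    """

    N: int = 100
    alpha: float = 0.0
    H: int = 10
    n_games: int = 2000
    beta: float = 0.005
    prior: object = "cc"
    u_scale: float = 1.0
    seed: int = 0
    r_inf_window: float = 0.25
    censored_updates: bool = False
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)

    def __post_init__(self) -> None:
        if self.N <= 0 or self.N % 2:
            raise ValueError(f"N must be positive and even, got {self.N}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.n_games < 1:
            raise ValueError(f"n_games must be >= 1, got {self.n_games}")
        if not 0.0 < self.r_inf_window <= 1.0:
            raise ValueError("r_inf_window must lie in (0, 1]")

    @property
    def n_resilient(self) -> int:
        return int(round(self.alpha * self.N))

    def prior_counts(self) -> np.ndarray:
        if isinstance(self.prior, str):
            if self.prior == "cc":
                p = np.zeros(_N_STRATS)
                p[_CC] = 1.0
            elif self.prior == "uniform":
                p = np.full(_N_STRATS, 1.0 / _N_STRATS)
            else:
                raise ValueError(f"unknown prior {self.prior!r}")
        else:
            p = np.asarray(self.prior, dtype=float)
            if p.shape != (_N_STRATS,) or (p < 0).any() or p.sum() <= 0:
                raise ValueError(
                    "explicit prior must be a length-11 nonnegative vector "
                    "with positive mass"
                )
        return p

    def utility_scale(self) -> float:
        return float(self.u_scale)


@dataclass
class Population:
    """Mutable state of the agent population during a run."""

    resilient: np.ndarray  # (N,) bool
    beliefs: np.ndarray  # (N, 11) float counts (rows of resilient agents unused)
    strategies: np.ndarray  # (N,) int, current strategy index

    @property
    def N(self) -> int:
        return self.resilient.size


def expected_utilities(pi: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Expected total-game utility of each strategy under belief counts ``pi``.

    ``pi`` may be a single length-11 count vector or an ``(m, 11)`` stack;
    counts are normalised to a probability vector per row.
    """
    pi = np.asarray(pi, dtype=float)
    single = pi.ndim == 1
    P = np.atleast_2d(pi)
    if (P < 0).any():
        raise ValueError("belief counts must be nonnegative")
    tot = P.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        raise ValueError("belief counts must have positive mass (check the prior)")
    u = (P / tot) @ U.T
    return u[0] if single else u


def softmax_choice(
    u: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    u_scale: float = 1.0,
    size: int | None = None,
) -> np.ndarray | int:
    """Sample strategy indices from the softmax over normalised utilities.

    Accepts a single utility vector or an ``(m, 11)`` stack (one draw per
    row).  Sampling uses the Gumbel-max trick, which is numerically stable
    for arbitrarily small ``beta`` (no overflow: the max is implicitly
    shifted out) and exactly equivalent to normalising shifted exponentials.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    z = np.atleast_2d(u) / (u_scale * beta)
    if single and size is not None:
        z = np.broadcast_to(z, (size, z.shape[1]))
    g = rng.gumbel(size=z.shape)
    idx = np.argmax(z + g, axis=1)
    if single and size is None:
        return int(idx[0])
    return idx


def _consistent_with_observed(opp_strat: np.ndarray, a: np.ndarray, H: int) -> np.ndarray:
    """Boolean (m, 11) mask of strategies consistent with each opponent's play.

    Between pure threshold strategies the opponent's observed actions are
    fully summarised by the pair (their threshold e_o, the joint first
    defection round a): the opponent cooperated on rounds 1..min(e_o - 1, a)
    and defected after.  A strategy index s (threshold e_s) is consistent iff
    it prescribes that same sequence against the player's observed actions.
    """
    e = np.arange(1, 12)
    e = np.minimum(e, H + 1)
    e_o = np.minimum(e[opp_strat], H + 1)[:, None]
    a_ = a[:, None]
    e_s = e[None, :]
    # observed first unilateral-defection round of the opponent, censored by a:
    # if e_o > a the opponent never defected first (indistinguishable for all
    # e_s > a); if e_o <= a, e_s must equal e_o exactly (defection observed).
    defected_first = e_o <= a_
    return np.where(defected_first, e_s == e_o, e_s > a_)


def step_game(
    pop: Population,
    U: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict:
    """Play one game (a random perfect matching) and update beliefs in place.

    Returns a dict with the pairing, per-pair first-defection round ``r_d``
    (no-defection encoded as H + 1), and the per-round population cooperation
    rate for the game.
    """
    N = pop.N
    e_all = np.minimum(np.arange(1, 12), cfg.H + 1)

    # strategies chosen BEFORE the game from current beliefs
    rational = ~pop.resilient
    n_rat = int(rational.sum())
    if n_rat:
        u = expected_utilities(pop.beliefs[rational], U)
        choice = softmax_choice(
            u, cfg.beta, rng, u_scale=cfg.utility_scale(), size=None
        )
        pop.strategies[rational] = choice
    pop.strategies[pop.resilient] = _CC

    perm = rng.permutation(N)
    pairs = perm.reshape(-1, 2)
    s1 = pop.strategies[pairs[:, 0]]
    s2 = pop.strategies[pairs[:, 1]]
    e1, e2 = e_all[s1], e_all[s2]
    a = np.minimum(e1, e2)  # joint first defection round; H+1 if none
    rd = np.minimum(a, cfg.H + 1)

    # per-round cooperation: player cooperates in round r iff r <= a and r < e_i
    rounds = np.arange(1, cfg.H + 1)
    coop1 = (rounds[None, :] <= a[:, None]) & (rounds[None, :] < e1[:, None])
    coop2 = (rounds[None, :] <= a[:, None]) & (rounds[None, :] < e2[:, None])
    coop_by_round = (coop1.sum(axis=0) + coop2.sum(axis=0)) / N

    # belief updates with the partner's strategy
    if cfg.censored_updates:
        m1 = _consistent_with_observed(s2, a, cfg.H)
        m2 = _consistent_with_observed(s1, a, cfg.H)
        upd = np.zeros((N, _N_STRATS))
        upd[pairs[:, 0]] = m1 / m1.sum(axis=1, keepdims=True)
        upd[pairs[:, 1]] = m2 / m2.sum(axis=1, keepdims=True)
        pop.beliefs[rational] += upd[rational]
    else:
        i1, i2 = pairs[:, 0], pairs[:, 1]
        r1 = rational[i1]
        r2 = rational[i2]
        np.add.at(pop.beliefs, (i1[r1], s2[r1]), 1.0)
        np.add.at(pop.beliefs, (i2[r2], s1[r2]), 1.0)

    pair_n_rational = rational[pairs[:, 0]].astype(int) + rational[pairs[:, 1]]
    return {
        "pairs": pairs,
        "r_d": rd,
        "pair_n_rational": pair_n_rational,
        "coop_by_round": coop_by_round,
    }


@dataclass
class SimulationResults:
    """Output of one run: strategy raster, r_d series and derived summaries."""

    config: SimConfig
    strategies: np.ndarray  # (n_games, N) int8 raster of chosen strategies
    resilient: np.ndarray  # (N,) bool
    rd_sum: np.ndarray  # (n_games,) sum of r_d weighted by rational players per pair
    rd_count: np.ndarray  # (n_games,) number of rational players paired
    coop_by_round: np.ndarray  # (n_games, H) population cooperation rate

    @property
    def n_games(self) -> int:
        return self.strategies.shape[0]

    def r_inf(self, window: float | None = None) -> float:
        """Asymptotic mean first-defection round per rational player."""
        return estimate_r_inf(self, window=window)

    def strategy_shares(self, games: slice | None = None, rational_only: bool = True) -> pd.Series:
        """Fraction of agent-games spent on each strategy over a game slice."""
        raster = self.strategies[games if games is not None else slice(None)]
        if rational_only:
            raster = raster[:, ~self.resilient]
        counts = np.bincount(raster.ravel(), minlength=_N_STRATS)
        total = counts.sum()
        if total == 0:  # all-resilient population with rational_only
            return pd.Series(np.zeros(_N_STRATS), index=list(STRATEGY_NAMES))
        return pd.Series(counts / total, index=list(STRATEGY_NAMES))

    def modal_strategy(self, games: slice | None = None, rational_only: bool = True) -> str:
        return str(self.strategy_shares(games, rational_only).idxmax())

    def cooperation_rate(self, round: int, games: slice) -> float:
        """Mean population cooperation rate in one round over a game slice."""
        return float(self.coop_by_round[games, round - 1].mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format (game, agent, type, strategy) table of the raster."""
        n_games, N = self.strategies.shape
        return pd.DataFrame(
            {
                "game": np.repeat(np.arange(1, n_games + 1), N),
                "agent": np.tile(np.arange(N), n_games),
                "type": np.tile(
                    np.where(self.resilient, "resilient", "rational"), n_games
                ),
                "strategy": [
                    STRATEGY_NAMES[s] for s in self.strategies.ravel()
                ],
            }
        )

    def plot_raster(self, ax=None):
        """Fig-style raster: agents (rows, resilient last) vs games, coloured
        by strategy index (darker = earlier defection threshold)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        order = np.argsort(self.resilient, kind="stable")
        ax.imshow(
            self.strategies[:, order].T,
            aspect="auto",
            interpolation="nearest",
            cmap="RdYlBu",
            vmin=0,
            vmax=10,
        )
        ax.set_xlabel("game")
        ax.set_ylabel("agent")
        return ax

    def summary(self) -> str:
        cfg = self.config
        shares = self.strategy_shares()
        lines = [
            "Smoothed fictitious play simulation",
            "-----------------------------------",
            f"N = {cfg.N}  alpha = {cfg.alpha:.3f}  (resilient: {cfg.n_resilient})",
            f"H = {cfg.H}  beta = {cfg.beta}  games = {self.n_games}  seed = {cfg.seed}",
        ]
        if cfg.alpha < 1.0:
            lines.append(
                f"r_inf (final {cfg.r_inf_window:.0%} of games) = {self.r_inf():.3f}"
            )
            lines.append(f"modal rational strategy = {self.modal_strategy()}")
        lines.append("rational strategy shares (whole run):")
        for name, v in shares.items():
            if v > 0.005:
                lines.append(f"  {name:<5} {v:6.1%}")
        return "\n".join(lines)


def run_simulation(cfg: SimConfig) -> SimulationResults:
    """Run one seeded simulation; bit-reproducible for a given config."""
    rng = np.random.default_rng(cfg.seed)
    U = strategy_payoff_table(H=cfg.H, M=cfg.payoffs)

    resilient = np.zeros(cfg.N, dtype=bool)
    if cfg.n_resilient:
        resilient[rng.choice(cfg.N, size=cfg.n_resilient, replace=False)] = True
    pop = Population(
        resilient=resilient,
        beliefs=np.tile(cfg.prior_counts(), (cfg.N, 1)),
        strategies=np.full(cfg.N, _CC, dtype=np.int64),
    )

    raster = np.empty((cfg.n_games, cfg.N), dtype=np.int8)
    rd_sum = np.zeros(cfg.n_games)
    rd_count = np.zeros(cfg.n_games, dtype=np.int64)
    coop = np.empty((cfg.n_games, cfg.H))
    for j in range(cfg.n_games):
        out = step_game(pop, U, cfg, rng)
        raster[j] = pop.strategies
        w = out["pair_n_rational"]
        rd_sum[j] = (out["r_d"] * w).sum()
        rd_count[j] = int(w.sum())
        coop[j] = out["coop_by_round"]
    return SimulationResults(
        config=cfg,
        strategies=raster,
        resilient=resilient,
        rd_sum=rd_sum,
        rd_count=rd_count,
        coop_by_round=coop,
    )


def estimate_r_inf(res: SimulationResults, window: float | None = None) -> float:
    """r_d averaged over rational players' games in the final window of a run."""
    if window is None:
        window = res.config.r_inf_window
    start = int(np.floor(res.n_games * (1.0 - window)))
    n = res.rd_count[start:].sum()
    if n == 0:
        raise ValueError(
            "r_inf is undefined: no games involving a rational player in the "
            "estimation window (alpha = 1?)"
        )
    return float(res.rd_sum[start:].sum() / n)


@dataclass
class AlphaSweepResults:
    """r_inf(alpha) curve with per-alpha dispersion and the critical mass."""

    alphas: np.ndarray
    r_inf_mean: np.ndarray
    r_inf_std: np.ndarray
    r_inf_runs: np.ndarray  # (n_alpha, reps)
    eps_transition: float

    @property
    def alpha_star(self) -> float:
        """Largest swept alpha still on the complete-unravelling floor."""
        floor = self.r_inf_mean <= 1.0 + self.eps_transition
        if not floor.any():
            return float(self.alphas[0])
        return float(self.alphas[np.nonzero(floor)[0].max()])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "r_inf_mean": self.r_inf_mean,
                "r_inf_std": self.r_inf_std,
            }
        )

    def plot(self, ax=None):
        """r_inf versus alpha with per-point spread and the alpha* marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.alphas, self.r_inf_mean, yerr=self.r_inf_std, marker="o")
        ax.axvline(self.alpha_star, ls="--", color="grey")
        ax.set_xlabel("resilient fraction alpha")
        ax.set_ylabel("asymptotic first-defection round r_inf")
        ax.set_ylim(0.5, 10.5)
        return ax

    def summary(self) -> str:
        lines = ["alpha sweep", "-----------", self.to_frame().to_string(index=False)]
        lines.append(f"alpha* (eps = {self.eps_transition}) = {self.alpha_star:.3f}")
        return "\n".join(lines)


def sweep_alpha(
    alphas,
    reps: int = 10,
    cfg: SimConfig | None = None,
    eps_transition: float = 0.5,
) -> AlphaSweepResults:
    """Estimate r_inf(alpha) over a grid, ``reps`` independent runs per point.

    Seeds for the individual runs are spawned deterministically from
    ``cfg.seed`` so the whole sweep is reproducible from one integer.
    """
    if cfg is None:
        cfg = SimConfig()
    alphas = np.asarray(list(alphas), dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(alphas.size * reps).reshape(alphas.size, reps)
    runs = np.empty((alphas.size, reps))
    for i, alpha in enumerate(alphas):
        for k in range(reps):
            sub = replace(cfg, alpha=float(alpha), seed=int(seeds[i, k] % (2**31)))
            runs[i, k] = run_simulation(sub).r_inf()
    return AlphaSweepResults(
        alphas=alphas,
        r_inf_mean=runs.mean(axis=1),
        r_inf_std=runs.std(axis=1),
        r_inf_runs=runs,
        eps_transition=eps_transition,
    )


class FictitiousPlayModel:
    """Model object wrapping :func:`run_simulation` and :func:`sweep_alpha`.

    Examples
    --------
    >>> model = FictitiousPlayModel(SimConfig(alpha=0.4, n_games=400, seed=7))
    >>> res = model.simulate()
    >>> res.modal_strategy()
    'T_9'
    """

    def __init__(self, config: SimConfig | None = None, **overrides):
        if config is None:
            config = SimConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        self.config = config
        self.payoff_table = strategy_payoff_table(H=config.H, M=config.payoffs)

    def simulate(self, seed: int | None = None) -> SimulationResults:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        return run_simulation(cfg)

    def sweep(self, alphas, reps: int = 10, eps_transition: float = 0.5) -> AlphaSweepResults:
        return sweep_alpha(alphas, reps=reps, cfg=self.config, eps_transition=eps_transition)
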