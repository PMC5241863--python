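"""Inferring strategies from observed play and classifying resilient cooperators.

A player's per-game behaviour is matched against the 11 pure strategies
(``T_1``..``T_10``, ``CC``).  Because many strategies are observationally
equivalent given a particular opponent (a grim player whose partner defects
at round 5 plays exactly like ``T_6``..``T_10`` would have), each game yields
a *consistency indicator* — one bit per strategy, set whenever simulating
that strategy against the opponent's observed actions reproduces the
player's actions — rather than a unique label.  A game consistent with no
strategy is flagged ``OTHER``.

Identity is then resolved over time by an exponentially weighted moving
average of the indicators,

    w_{i,s}(j) = 1_{i,s}(j) + gamma * w_{i,s}(j - 1),        w(0) = 0,

with discount ``gamma = 0.818`` by default (an EWMA with a period of about
10 games, half an experimental day).  The per-game assignment is the argmax
of ``w`` with deterministic tie-breaking: any named strategy beats OTHER, a
threshold strategy beats CC, and among tied thresholds the largest (most
cooperative) wins.

A player is classified *resilient* when at least 80% of their non-missing
stable-phase games (days 7-20 in the experimental layout) are assigned CC.

The module exposes both the low-level operations and a statsmodels-style
:class:`StrategyInferenceModel` that fits a whole long-format game log at
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .payoffs import COOPERATE, DEFECT, STRATEGY_NAMES

__all__ = [
    "OTHER",
    "consistent_strategies",
    "update_weights",
    "assign_strategy",
    "classify_resilient",
    "StrategyInferenceModel",
    "StrategyInferenceResults",
]

OTHER = "OTHER"
_LABELS = STRATEGY_NAMES + (OTHER,)
_N = 11


def _as_bits(seq, H: int) -> np.ndarray:
    """Action sequence -> boolean cooperation vector of length H."""
    seq = list(seq)
    if len(seq) != H:
        raise ValueError(f"action sequence has length {len(seq)}, expected {H}")
    out = np.empty(H, dtype=bool)
    for r, a in enumerate(seq):
        if a == COOPERATE:
            out[r] = True
        elif a == DEFECT:
            out[r] = False
        else:
            raise ValueError(f"invalid action {a!r} at round {r + 1}")
    return out


def _predicted_play(opp_coop: np.ndarray, H: int) -> np.ndarray:
    """(11, H) matrix of what each strategy would play against observed opp actions.

    Strategy with effective threshold e cooperates in round r iff r < e and
    the opponent has not defected in any round < r.
    """
    e = np.minimum(np.arange(1, 12), H + 1)
    opp_first_d = H + 1
    d = np.nonzero(~opp_coop)[0]
    if d.size:
        opp_first_d = int(d[0]) + 1
    rounds = np.arange(1, H + 1)
    return (rounds[None, :] < e[:, None]) & (rounds[None, :] <= opp_first_d)


def consistent_strategies(
    own,
    opp,
    H: int = 10,
    forgiving_window: int = 2,
    single_match: bool = False,
) -> dict[str, bool]:
    """Indicator of which strategies are consistent with one game's play.

    The indicator for strategy ``s`` is 1 iff simulating ``s`` against the
    opponent's observed actions reproduces the player's actions exactly.
    The rare *forgiving* variant of a threshold strategy — defecting at
    round x, then resuming cooperation for a round or two while the partner
    still cooperated — is coded as consistent with ``T_x``: up to
    ``forgiving_window`` mismatched rounds after x are tolerated when the
    player's excess action was C and the partner cooperated on round x.

    Returns a dict over ``T_1``..``T_10``, ``CC`` and ``OTHER``; ``OTHER``
    is set iff no strategy is consistent.  With ``single_match=True`` only
    the lowest-threshold consistent strategy is flagged (a stricter variant
    of the indicator; the default flags every consistent strategy).
    """
    own_c = _as_bits(own, H)
    opp_c = _as_bits(opp, H)
    pred = _predicted_play(opp_c, H)
    exact = (pred == own_c[None, :]).all(axis=1)

    ind = dict(zip(STRATEGY_NAMES, exact.tolist()))
    if forgiving_window:
        for x in range(1, min(10, H) + 1):
            if ind[f"T_{x}"]:
                continue
            mism = np.nonzero(pred[x - 1] != own_c)[0] + 1  # 1-based rounds
            if mism.size == 0 or mism.size > forgiving_window:
                continue
            # tolerated: player resumed C after their threshold defection at x
            # while the partner had cooperated on round x
            if (
                (mism > x).all()
                and own_c[mism - 1].all()
                and x <= H
                and opp_c[x - 1]
                and not own_c[x - 1]
            ):
                ind[f"T_{x}"] = True
    if single_match:
        first = next((k for k in _LABELS[:-1] if ind[k]), None)
        ind = {k: (k == first) for k in STRATEGY_NAMES}
    ind[OTHER] = not any(ind[k] for k in STRATEGY_NAMES)
    return ind


def update_weights(
    prev: np.ndarray | None,
    ind: dict[str, bool] | np.ndarray,
    gamma: float = 0.818,
) -> np.ndarray:
    """One step of the EWMA recursion ``w(j) = 1(j) + gamma * w(j - 1)``.

    ``prev`` is the length-12 weight vector (11 strategies + OTHER) from the
    previous game, or None for the all-zero initial state.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if isinstance(ind, dict):
        ind = np.array([ind[k] for k in _LABELS], dtype=float)
    else:
        ind = np.asarray(ind, dtype=float)
    if prev is None:
        prev = np.zeros_like(ind)
    return ind + gamma * np.asarray(prev, dtype=float)


def assign_strategy(w: np.ndarray | dict[str, float]) -> str:
    """Argmax assignment with the deterministic tie-breaks.

    Known strategies beat OTHER; a threshold strategy beats CC; among tied
    threshold strategies the largest x (most cooperative) wins.  All-zero
    weights (no game has matched anything yet) give OTHER.
    """
    if isinstance(w, dict):
        w = np.array([w[k] for k in _LABELS], dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (12,):
        raise ValueError("expected 12 weights (11 strategies + OTHER)")
    wmax = w.max()
    if wmax <= 0:
        return OTHER
    tied = np.nonzero(w == wmax)[0]
    named = tied[tied < _N]
    if named.size == 0:
        return OTHER
    thresholds = named[named < 10]
    if thresholds.size:
        return STRATEGY_NAMES[int(thresholds.max())]
    return "CC"


def classify_resilient(
    assignments: pd.Series | list,
    stable_games=None,
    threshold: float = 0.80,
) -> bool | None:
    """Resilient-cooperator flag from a player's per-game assignments.

    Parameters
    ----------
    assignments : sequence of labels indexed by game (NaN/None = missing).
    stable_games : index subset over which to evaluate (default: all).
    threshold : minimum fraction of non-missing stable games assigned CC.

    Returns None (unclassifiable) when the player has no non-missing game in
    the stable set.
    """
    s = pd.Series(assignments)
    if stable_games is not None:
        s = s.loc[s.index.intersection(pd.Index(stable_games))]
    s = s.dropna()
    if s.empty:
        return None
    return bool((s == "CC").mean() >= threshold)


# ---------------------------------------------------------------------------
# whole-log fitting


def _indicator_matrix(own: np.ndarray, opp: np.ndarray, H: int, forgiving_window: int) -> np.ndarray:
    """Vectorised consistency indicators for a stack of games.

    own, opp : (m, H) boolean cooperation arrays.  Returns (m, 12) floats.
    """
    m = own.shape[0]
    rounds = np.arange(1, H + 1)
    e = np.minimum(np.arange(1, 12), H + 1)

    any_d = ~opp.all(axis=1)
    first_d = np.where(any_d, opp.argmin(axis=1) + 1, H + 1)  # 1-based
    pred = (rounds[None, None, :] < e[None, :, None]) & (
        rounds[None, None, :] <= first_d[:, None, None]
    )  # (m, 11, H)
    mismatch = pred != own[:, None, :]
    exact = ~mismatch.any(axis=2)  # (m, 11)

    ind = exact.astype(float)
    if forgiving_window:
        n_mism = mismatch.sum(axis=2)
        after_x = rounds[None, None, :] > e[None, :, None]
        ok_pos = (~mismatch | (after_x & own[:, None, :])).all(axis=2)
        xs = np.arange(1, 11)
        opp_c_at_x = np.take_along_axis(
            np.broadcast_to(opp[:, None, :], (m, 10, H)),
            np.minimum(xs - 1, H - 1)[None, :, None],
            axis=2,
        )[:, :, 0]
        own_d_at_x = ~np.take_along_axis(
            np.broadcast_to(own[:, None, :], (m, 10, H)),
            np.minimum(xs - 1, H - 1)[None, :, None],
            axis=2,
        )[:, :, 0]
        valid_x = (xs <= H)[None, :]
        forgiven = (
            (n_mism[:, :10] > 0)
            & (n_mism[:, :10] <= forgiving_window)
            & ok_pos[:, :10]
            & opp_c_at_x
            & own_d_at_x
            & valid_x
        )
        ind[:, :10] = np.maximum(ind[:, :10], forgiven.astype(float))
    other = (ind.sum(axis=1) == 0).astype(float)
    return np.column_stack([ind, other])


@dataclass
class StrategyInferenceResults:
    """Fitted per-player per-game strategy assignments and summaries."""

    assignments: pd.DataFrame  # rows: players, cols: game sequence index
    weights_final: pd.DataFrame  # final EWMA weight vector per player
    game_index: pd.DataFrame  # (day, game) for each sequence index
    gamma: float
    stable_days: tuple[int, int]
    resilient_threshold: float

    @property
    def players(self) -> pd.Index:
        return self.assignments.index

    def stable_mask(self) -> np.ndarray:
        lo, hi = self.stable_days
        return (self.game_index["day"] >= lo).to_numpy() & (
            self.game_index["day"] <= hi
        ).to_numpy()

    def cc_fraction(self) -> pd.Series:
        """Per-player fraction of non-missing stable-phase games assigned CC."""
        stable = self.assignments.loc[:, self.stable_mask()]
        return (stable == "CC").sum(axis=1) / stable.notna().sum(axis=1)

    def resilient(self) -> pd.Series:
        """Boolean resilient flag per player (NaN when unclassifiable)."""
        frac = self.cc_fraction()
        return frac >= self.resilient_threshold

    def other_fraction(self) -> float:
        """Share of non-missing player-games assigned OTHER."""
        a = self.assignments
        return float((a == OTHER).sum().sum() / a.notna().sum().sum())

    def modal_strategy_by_day(self) -> pd.DataFrame:
        """Per player per day, the most frequently assigned strategy."""
        days = self.game_index["day"].to_numpy()
        recs = {}
        for d in np.unique(days):
            block = self.assignments.loc[:, days == d]
            recs[d] = block.apply(
                lambda r: r.value_counts().idxmax() if r.notna().any() else None,
                axis=1,
            )
        return pd.DataFrame(recs)

    def summary(self) -> str:
        res = self.resilient()
        frac = self.cc_fraction()
        lines = [
            "Strategy inference (EWMA over consistency indicators)",
            "-----------------------------------------------------",
            f"players = {len(self.players)}  games per player = {self.assignments.shape[1]}",
            f"gamma = {self.gamma}  stable phase = days {self.stable_days[0]}-{self.stable_days[1]}",
            f"resilient cooperators (>= {self.resilient_threshold:.0%} stable-phase CC): "
            f"{int(res.sum())} of {res.notna().sum()} classifiable "
            f"({res.mean():.1%})",
            f"median stable-phase CC fraction = {frac.median():.3f}",
            f"OTHER share of assignments = {self.other_fraction():.3%}",
        ]
        return "\n".join(lines)


class StrategyInferenceModel:
    """EWMA strategy inference over a long-format game log.

    Parameters
    ----------
    log : pandas.DataFrame
        Long-format log with columns session, day, game, round, player,
        partner, action (see :mod:`coopdyn.io`).
    gamma : float
        EWMA discount for past games.
    H : int
        Rounds per game.
    stable_days : (int, int)
        Inclusive day range treated as the stable phase for resilient
        classification.
    resilient_threshold : float
        Minimum stable-phase CC fraction for the resilient flag.
    forgiving_window : int
        Tolerated rounds of resumed cooperation for the forgiving threshold
        variant (0 disables).
    single_match : bool
        Use the strictest single-strategy indicator instead of flagging all
        consistent strategies.
    decay_missing : bool
        If True, the EWMA decays across a player's missing games; by default
        weights carry over unchanged (the recursion simply skips the gap).
    """

    def __init__(
        self,
        log: pd.DataFrame,
        gamma: float = 0.818,
        H: int = 10,
        stable_days: tuple[int, int] = (7, 20),
        resilient_threshold: float = 0.80,
        forgiving_window: int = 2,
        single_match: bool = False,
        decay_missing: bool = False,
    ):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
        self.log = log
        self.gamma = gamma
        self.H = H
        self.stable_days = tuple(stable_days)
        self.resilient_threshold = resilient_threshold
        self.forgiving_window = forgiving_window
        self.single_match = single_match
        self.decay_missing = decay_missing

    def fit(self) -> StrategyInferenceResults:
        log = self.log
        H = self.H
        # one row per (player, session, day, game): own and partner cooperation
        wide = (
            log.sort_values(["session", "day", "game", "player", "round"])
            .assign(coop=lambda d: d["action"].eq(COOPERATE))
            .groupby(["session", "day", "game", "player", "partner"], sort=True)[
                "coop"
            ]
            .apply(lambda s: np.asarray(s, dtype=bool))
            .reset_index()
        )
        lengths = wide["coop"].str.len()
        if (lengths != H).any():
            bad = wide[lengths != H].iloc[0]
            raise ValueError(
                f"player {bad['player']} has {len(bad['coop'])} rounds in "
                f"(session {bad['session']}, day {bad['day']}, game {bad['game']}); expected {H}"
            )
        own_map = {
            (r.session, r.day, r.game, r.player): r.coop
            for r in wide.itertuples(index=False)
        }
        opp = [
            own_map.get((r.session, r.day, r.game, r.partner))
            for r in wide.itertuples(index=False)
        ]
        if any(o is None for o in opp):
            i = next(i for i, o in enumerate(opp) if o is None)
            r = wide.iloc[i]
            raise ValueError(
                f"unpaired row: partner {r['partner']} of player {r['player']} "
                f"missing in (session {r['session']}, day {r['day']}, game {r['game']})"
            )
        own_arr = np.stack(wide["coop"].to_list())
        opp_arr = np.stack(opp)
        if self.single_match:
            ind = np.stack(
                [
                    np.array(
                        [
                            consistent_strategies(
                                ["C" if c else "D" for c in o],
                                ["C" if c else "D" for c in p],
                                H,
                                self.forgiving_window,
                                single_match=True,
                            )[k]
                            for k in _LABELS
                        ],
                        dtype=float,
                    )
                    for o, p in zip(own_arr, opp_arr)
                ]
            )
        else:
            ind = _indicator_matrix(own_arr, opp_arr, H, self.forgiving_window)

        wide = wide.reset_index(drop=True)
        wide["seq"] = list(
            zip(wide["day"].astype(int), wide["game"].astype(int))
        )
        game_seq = sorted(set(wide["seq"]))
        seq_pos = {g: i for i, g in enumerate(game_seq)}
        players = sorted(set(wide["player"]))
        p_pos = {p: i for i, p in enumerate(players)}
        n_p, n_g = len(players), len(game_seq)

        ind_grid = np.full((n_p, n_g, 12), np.nan)
        rows = wide["player"].map(p_pos).to_numpy()
        cols = wide["seq"].map(seq_pos).to_numpy()
        ind_grid[rows, cols] = ind

        w = np.zeros((n_p, 12))
        labels = np.full((n_p, n_g), None, dtype=object)
        for g in range(n_g):
            present = ~np.isnan(ind_grid[:, g, 0])
            if self.decay_missing:
                w[~present] *= self.gamma
            w[present] = ind_grid[present, g] + self.gamma * w[present]
            for i in np.nonzero(present)[0]:
                labels[i, g] = assign_strategy(w[i])

        assignments = pd.DataFrame(labels, index=pd.Index(players, name="player"))
        return StrategyInferenceResults(
            assignments=assignments,
            weights_final=pd.DataFrame(w, index=assignments.index, columns=list(_LABELS)),
            game_index=pd.DataFrame(game_seq, columns=["day", "game"]),
            gamma=self.gamma,
            stable_days=self.stable_days,
            resilient_threshold=self.resilient_threshold,
        )
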