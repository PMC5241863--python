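"""One-shot payoffs, threshold strategies and deterministic game playouts.

The building block of the package is a finitely repeated Prisoner's Dilemma
(PD) of ``H`` rounds (default 10) between two *pure* strategies drawn from an
11-strategy set:

* threshold strategies ``T_1 ... T_10`` — conditionally cooperate (with grim
  retaliation) through round ``x - 1``, then defect unconditionally from round
  ``x``.  ``T_1`` is unconditional defection (ALLD).
* ``CC`` — full conditional cooperation, i.e. the grim trigger: cooperate
  until the partner defects, then defect forever.

Every strategy therefore has an *effective threshold* ``e(s)``: the first
round on which it would defect unilaterally (``x`` for ``T_x``, ``H + 1`` for
``CC``).  Between two such strategies the playout is fully determined by the
pair of thresholds, which gives a closed form for the 11x11 payoff table used
by the learning model; :func:`play_game` is the independent round-by-round
engine the closed form is checked against.

Rounds are indexed 1-based throughout.  A game with no defection has
``r_d = None``; wherever a numeric value is required the package-wide
convention is ``r_d = H + 1`` (see :func:`rd_numeric`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COOPERATE",
    "DEFECT",
    "PayoffMatrix",
    "Strategy",
    "STRATEGY_NAMES",
    "GamePlayout",
    "round_payoff",
    "play_game",
    "first_defection_round",
    "strategy_payoff_table",
    "rd_numeric",
]

COOPERATE = "C"
DEFECT = "D"
_ACTIONS = frozenset((COOPERATE, DEFECT))

#: canonical strategy order used everywhere (indices 0..10)
STRATEGY_NAMES: tuple[str, ...] = tuple(f"T_{x}" for x in range(1, 11)) + ("CC",)


@dataclass(frozen=True)
class PayoffMatrix:
    """One-round PD payoffs (T, R, P, S) with the usual orderings enforced.

    The default instance (7, 5, 3, 1) gives the normalised temptation and
    loss parameters g = (T - R)/(R - P) = 1 and l = (P - S)/(R - P) = 1.
    """

    T: float = 7.0
    R: float = 5.0
    P: float = 3.0
    S: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"PD ordering T > R > P > S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError(
                f"2R > T + S violated: 2R={2 * self.R}, T+S={self.T + self.S}"
            )

    @property
    def g(self) -> float:
        """Normalised temptation to defect against a cooperator."""
        return (self.T - self.R) / (self.R - self.P)

    @property
    def l(self) -> float:
        """Normalised loss from cooperating against a defector."""
        return (self.P - self.S) / (self.R - self.P)


@dataclass(frozen=True)
class Strategy:
    """A pure strategy from the 11-strategy set: ``T_1``..``T_10`` or ``CC``."""

    kind: str
    H: int = 10

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {self.kind!r}; expected one of {STRATEGY_NAMES}"
            )
        if self.H < 1:
            raise ValueError(f"H must be >= 1, got {self.H}")

    @property
    def effective_threshold(self) -> int:
        """First round of unilateral defection: x for T_x, H + 1 for CC.

        A threshold beyond the horizon never fires, so for H < 10 the value is
        capped at H + 1 (T_x with x > H is observationally identical to CC).
        """
        if self.kind == "CC":
            return self.H + 1
        return min(int(self.kind.split("_")[1]), self.H + 1)

    @property
    def index(self) -> int:
        """Position in the canonical strategy order (T_1..T_10, CC)."""
        return STRATEGY_NAMES.index(self.kind)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.kind


@dataclass
class GamePlayout:
    """Complete record of one H-round game between two pure strategies."""

    H: int
    actions1: list[str]
    actions2: list[str]
    payoffs1: list[float] = field(repr=False)
    payoffs2: list[float] = field(repr=False)

    @property
    def total1(self) -> float:
        return float(sum(self.payoffs1))

    @property
    def total2(self) -> float:
        return float(sum(self.payoffs2))

    @property
    def r_d(self) -> int | None:
        """Round of first defection by either player; None if all-C."""
        return first_defection_round(self)


def rd_numeric(r_d: int | None, H: int = 10) -> int:
    """Numeric encoding of the round of first defection (no-defection -> H + 1)."""
    return H + 1 if r_d is None else int(r_d)


def round_payoff(
    a1: str, a2: str, M: PayoffMatrix | None = None
) -> tuple[float, float]:
    """Payoff pair for one round given the two actions.

    Parameters
    ----------
    a1, a2 : {"C", "D"}
        Actions of the row and column player.
    M : PayoffMatrix, optional
        Defaults to the (7, 5, 3, 1) matrix.
    """
    if M is None:
        M = PayoffMatrix()
    for a in (a1, a2):
        if a not in _ACTIONS:
            raise ValueError(f"invalid action {a!r}; actions must be 'C' or 'D'")
    if a1 == COOPERATE:
        return (M.R, M.R) if a2 == COOPERATE else (M.S, M.T)
    return (M.T, M.S) if a2 == COOPERATE else (M.P, M.P)


def play_game(
    s1: Strategy | str,
    s2: Strategy | str,
    H: int = 10,
    M: PayoffMatrix | None = None,
) -> GamePlayout:
    """Deterministic round-by-round playout of two pure strategies.

    Player ``i`` cooperates in round ``r`` iff ``r < e(s_i)`` and the opponent
    has not defected in any earlier round (grim retaliation); otherwise they
    defect.
    """
    if M is None:
        M = PayoffMatrix()
    if H < 1:
        raise ValueError(f"H must be >= 1, got {H}")
    if isinstance(s1, str):
        s1 = Strategy(s1, H=H)
    if isinstance(s2, str):
        s2 = Strategy(s2, H=H)
    e1, e2 = s1.effective_threshold, s2.effective_threshold

    a1: list[str] = []
    a2: list[str] = []
    p1: list[float] = []
    p2: list[float] = []
    opp1_defected = False  # has player 2 defected so far
    opp2_defected = False  # has player 1 defected so far
    for r in range(1, H + 1):
        act1 = COOPERATE if (r < e1 and not opp1_defected) else DEFECT
        act2 = COOPERATE if (r < e2 and not opp2_defected) else DEFECT
        pay1, pay2 = round_payoff(act1, act2, M)
        a1.append(act1)
        a2.append(act2)
        p1.append(pay1)
        p2.append(pay2)
        opp1_defected = opp1_defected or act2 == DEFECT
        opp2_defected = opp2_defected or act1 == DEFECT
    return GamePlayout(H=H, actions1=a1, actions2=a2, payoffs1=p1, payoffs2=p2)


def first_defection_round(p: GamePlayout) -> int | None:
    """Smallest round containing a D by either player; None if fully cooperative."""
    for r in range(p.H):
        if p.actions1[r] == DEFECT or p.actions2[r] == DEFECT:
            return r + 1
    return None


def strategy_payoff_table(H: int = 10, M: PayoffMatrix | None = None) -> np.ndarray:
    """Closed-form 11x11 table ``U[s, t]``: total payoff to the s-player.

    With ``a = min(e(s), e(t))`` and ``b = max(e(s), e(t))``:

    * ``a = b = H + 1``: both cooperate throughout and earn ``R * H``;
    * ``a = b <= H``: simultaneous first defection at round ``a``, each earns
      ``(a - 1) R + (H - a + 1) P``;
    * ``a < b``: the earlier defector earns ``(a - 1) R + T + (H - a) P`` and
      the later one ``(a - 1) R + S + (H - a) P``.

    Rows and columns follow :data:`STRATEGY_NAMES`.
    """
    if M is None:
        M = PayoffMatrix()
    e = np.array([Strategy(k, H=H).effective_threshold for k in STRATEGY_NAMES])
    es = e[:, None].astype(float)
    et = e[None, :].astype(float)
    a = np.minimum(es, et)
    U = np.where(
        es == et,
        np.where(es == H + 1, M.R * H, (a - 1) * M.R + (H - a + 1) * M.P),
        np.where(
            es < et,
            (a - 1) * M.R + M.T + (H - a) * M.P,
            (a - 1) * M.R + M.S + (H - a) * M.P,
        ),
    )
    return U
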