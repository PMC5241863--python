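"""Descriptive and inferential analytics over long-format game logs.

Covers the experiment-level summaries: cooperation rates under arbitrary
slices, the game and session restart effects, per-day distributions of the
round of first defection ``r_d`` (with a ``C`` bin for games where nobody
defected), two-sample tests between adjacent days, steady-state onset
detection, and the random-pairing argument that converts the share of
fully cooperative games into an implied fraction of conditional cooperators
(sqrt of the share, by independence of the two partners).

Games with no defection enter the test samples with ``r_d = H + 1`` by
default — they are part of the distribution, not censored observations; an
exclusion variant is available.  Sessions are pooled unless a session filter
is given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .payoffs import COOPERATE, DEFECT

__all__ = [
    "cooperation_rate",
    "pair_first_defections",
    "rd_distribution",
    "game_restart_effect",
    "session_restart_effect",
    "two_sample_ks",
    "steady_state_onset",
    "SteadyStateReport",
    "implied_cc_fraction",
]


def _filter(
    log: pd.DataFrame,
    session=None,
    day=None,
    game=None,
    round=None,
) -> pd.DataFrame:
    out = log
    for col, val in (("session", session), ("day", day), ("game", game), ("round", round)):
        if val is None:
            continue
        if np.iterable(val) and not isinstance(val, str):
            out = out[out[col].isin(list(val))]
        else:
            out = out[out[col] == val]
    return out


def cooperation_rate(log: pd.DataFrame, session=None, day=None, game=None, round=None) -> float:
    """Fraction of C among all individual decisions in the selection."""
    sel = _filter(log, session, day, game, round)
    if sel.empty:
        raise ValueError("empty selection: no decisions match the given filters")
    return float(sel["action"].eq(COOPERATE).mean())


def pair_first_defections(log: pd.DataFrame, H: int = 10) -> pd.DataFrame:
    """Per pair-game round of first defection.

    Returns a frame with columns session, day, game, p1, p2, r_d where
    ``r_d`` is the smallest round on which either partner defected, or
    ``H + 1`` for fully cooperative games.  Each 10-round pairing within a
    (session, day, game) slot is one observation.
    """
    df = log.copy()
    a = np.minimum(df["player"].to_numpy(), df["partner"].to_numpy())
    b = np.maximum(df["player"].to_numpy(), df["partner"].to_numpy())
    # player ids may be strings: order lexicographically in that case
    if df["player"].dtype == object:
        pl = df["player"].astype(str).to_numpy()
        pa = df["partner"].astype(str).to_numpy()
        a = np.minimum(pl, pa)
        b = np.maximum(pl, pa)
    df["p1"], df["p2"] = a, b
    d_rounds = df.loc[df["action"].eq(DEFECT)]
    grp = ["session", "day", "game", "p1", "p2"]
    first_d = d_rounds.groupby(grp, sort=False)["round"].min()
    all_pairs = df[grp].drop_duplicates().set_index(grp).index
    rd = first_d.reindex(all_pairs).fillna(H + 1).astype(int)
    rd.name = "r_d"
    return rd.reset_index()


def rd_distribution(log: pd.DataFrame, day=None, H: int = 10, session=None) -> pd.Series:
    """Counts of the round of first defection over {1..H, C} for a selection.

    The ``C`` bin collects games where neither player defected.  Counts sum
    to the number of pair-games in the selection.
    """
    sel = _filter(log, session=session, day=day)
    if sel.empty:
        raise ValueError("empty selection")
    rd = pair_first_defections(sel, H=H)["r_d"]
    bins = list(range(1, H + 1)) + [H + 1]
    counts = rd.value_counts().reindex(bins, fill_value=0)
    counts.index = [str(b) for b in range(1, H + 1)] + ["C"]
    counts.name = "games"
    return counts


def game_restart_effect(log: pd.DataFrame, day, session=None, H: int = 10) -> float:
    """Mean jump in cooperation from the last round of one game to the first of the next.

    For one day: mean over j of coop(round 1, game j+1) - coop(round H, game j).
    """
    sel = _filter(log, session=session, day=day)
    games = sorted(sel["game"].unique())
    if len(games) < 2:
        raise ValueError(f"need at least 2 games in day {day!r} to measure a restart")
    diffs = [
        cooperation_rate(sel, game=g2, round=1) - cooperation_rate(sel, game=g1, round=H)
        for g1, g2 in zip(games[:-1], games[1:])
    ]
    return float(np.mean(diffs))


def session_restart_effect(
    log: pd.DataFrame, rounds=(9, 10), session=None
) -> pd.DataFrame:
    """Across-day jump in late-round cooperation.

    For each day boundary d -> d+1 and each requested round r:
    coop(r, first game of day d+1) - coop(r, last game of day d).
    Returns a tidy frame (day, round, diff); empty (with a warning-free
    empty result) for single-day logs.
    """
    sel = _filter(log, session=session)
    days = sorted(sel["day"].unique())
    recs = []
    for d1, d2 in zip(days[:-1], days[1:]):
        day1 = sel[sel["day"] == d1]
        day2 = sel[sel["day"] == d2]
        g_last = day1["game"].max()
        g_first = day2["game"].min()
        for r in rounds:
            recs.append(
                {
                    "day": d1,
                    "round": r,
                    "diff": cooperation_rate(day2, game=g_first, round=r)
                    - cooperation_rate(day1, game=g_last, round=r),
                }
            )
    return pd.DataFrame(recs, columns=["day", "round", "diff"])


def two_sample_ks(x, y, method: str = "asymp", n_permutations: int = 2000, seed: int = 0):
    """Two-sample Kolmogorov-Smirnov test on (discrete) r_d samples.

    D is the maximum absolute gap between the two empirical CDFs over the
    pooled support; the p-value is the asymptotic two-sample value by
    default.  ``method="permutation"`` estimates the p-value by randomly
    re-splitting the pooled sample, which is exact in distribution for
    discrete data where the asymptotic formula is conservative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    D = float(res.statistic)
    if method == "asymp":
        return D, float(res.pvalue)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n = x.size
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        d = sps.ks_2samp(pooled[:n], pooled[n:], method="asymp").statistic
        if d >= D - 1e-12:
            count += 1
    return D, (count + 1) / (n_permutations + 1)


@dataclass
class SteadyStateReport:
    """Adjacent-day distribution-shift tests and the inferred onset day."""

    tests: pd.DataFrame  # day, next_day, n1, n2, statistic, pvalue, significant
    onset_day: int | None
    test: str
    level: float
    rule: str

    def summary(self) -> str:
        lines = [
            f"Steady-state onset ({self.test} test, level {self.level}, rule {self.rule!r})",
            "-" * 60,
            self.tests.to_string(index=False),
            (
                f"onset day = {self.onset_day}"
                if self.onset_day is not None
                else "onset day undefined (no stable tail)"
            ),
        ]
        return "\n".join(lines)


def steady_state_onset(
    log: pd.DataFrame,
    test: str = "ks",
    level: float = 0.05,
    H: int = 10,
    include_c_bin: bool = True,
    rule: str = "first_nonsignificant",
    session=None,
) -> SteadyStateReport:
    """Detect the first stable day from adjacent-day shifts in r_d.

    Pools sessions, computes one r_d observation per pair-game (no-defection
    games entering as ``H + 1`` unless ``include_c_bin=False``), tests each
    adjacent day pair, and reports the onset: the arrival day of the first
    non-significant adjacent pair (default).  The stricter
    ``rule="all_subsequent"`` additionally requires every later pair to be
    non-significant; note that over many genuinely stable days that rule
    inherits a family-wise false-alarm floor of roughly ``1 - (1 - fp)^k``
    for k remaining pairs, so a single spurious rejection late in the
    experiment discards an otherwise clear onset.  Onset is None when no
    qualifying pair exists.
    """
    sel = _filter(log, session=session)
    days = sorted(sel["day"].unique())
    if len(days) < 3:
        raise ValueError("need at least 3 days to locate a steady state")
    rd = pair_first_defections(sel, H=H)
    if not include_c_bin:
        rd = rd[rd["r_d"] <= H]
    samples = {d: rd.loc[rd["day"] == d, "r_d"].to_numpy() for d in days}

    recs = []
    for d1, d2 in zip(days[:-1], days[1:]):
        x, y = samples[d1], samples[d2]
        if test == "ks":
            stat, p = two_sample_ks(x, y)
        elif test == "mw":
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
            stat = float(stat)
            p = float(p)
        else:
            raise ValueError(f"unknown test {test!r}; use 'ks' or 'mw'")
        recs.append(
            {
                "day": d1,
                "next_day": d2,
                "n1": x.size,
                "n2": y.size,
                "statistic": stat,
                "pvalue": p,
                "significant": p < level,
            }
        )
    tests = pd.DataFrame(recs)

    sig = tests["significant"].to_numpy()
    onset: int | None
    if rule == "all_subsequent":
        # first day on the plateau: the day after the last significant shift,
        # provided no later pair is significant; day 2 if nothing ever shifts
        if not sig.any():
            onset = int(tests.loc[0, "next_day"])
        elif sig[-1]:
            onset = None
        else:
            onset = int(tests.loc[np.nonzero(sig)[0].max(), "next_day"])
    elif rule == "first_nonsignificant":
        idx = np.nonzero(~sig)[0]
        onset = int(tests.loc[idx[0], "next_day"]) if idx.size else None
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return SteadyStateReport(tests=tests, onset_day=onset, test=test, level=level, rule=rule)


def implied_cc_fraction(no_defection_game_rate: float) -> float:
    """Implied conditional-cooperator share from the no-defection game rate.

    With random pairing a fully cooperative game requires two conditional
    cooperators, so a no-defection rate q implies a cooperator fraction
    sqrt(q).
    """
    q = float(no_defection_game_rate)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {q}")
    return float(np.sqrt(q))
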