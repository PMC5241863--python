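"""Reading, writing and validating long-format game logs.

The canonical log is a pandas DataFrame with one row per decision:

======== =======================================================
column   meaning
======== =======================================================
session  session identifier (string)
day      1-based day index
game     1-based game index within the day
round    1-based round index within the game (1..H)
player   player identifier
partner  the player's partner in this game
action   "C" or "D"
payoff   optional per-round payoff; recomputable from the actions
======== =======================================================

Files are CSV or JSON-lines; a *dialect* (column-name mapping) adapts
external exports — including the study's deposited data, whose layout is
configured rather than hard-coded — to the canonical schema.  Validation
checks the schema, the action alphabet, that every (session, day, game)
block pairs up by mutual partner ids, and that any stored payoffs match the
payoff matrix applied to the stored actions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .payoffs import COOPERATE, DEFECT, PayoffMatrix

__all__ = ["REQUIRED_COLUMNS", "read_log", "write_log", "validate_log", "LogFormatError"]

REQUIRED_COLUMNS = ("session", "day", "game", "round", "player", "partner", "action")


class LogFormatError(ValueError):
    """A game log violated the schema or its pairing invariants."""


def validate_log(
    log: pd.DataFrame,
    H: int = 10,
    payoffs: PayoffMatrix | None = None,
    check_payoffs: bool = True,
) -> pd.DataFrame:
    """Validate (and lightly normalise) a long-format game log.

    Raises :class:`LogFormatError` with row numbers on schema violations,
    unpairable rows, or stored payoffs inconsistent with the actions.
    Returns the validated frame (with integer day/game/round).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in log.columns]
    if missing:
        raise LogFormatError(f"missing required columns: {missing}")
    log = log.copy()
    for c in ("day", "game", "round"):
        try:
            log[c] = log[c].astype(int)
        except (TypeError, ValueError) as exc:
            raise LogFormatError(f"column {c!r} is not integer-valued: {exc}") from None

    bad_action = ~log["action"].isin([COOPERATE, DEFECT])
    if bad_action.any():
        rows = log.index[bad_action][:5].tolist()
        raise LogFormatError(
            f"invalid actions (must be 'C' or 'D') at rows {rows}"
        )
    if ((log["round"] < 1) | (log["round"] > H)).any():
        rows = log.index[(log["round"] < 1) | (log["round"] > H)][:5].tolist()
        raise LogFormatError(f"round outside 1..{H} at rows {rows}")

    # pairing: within each (session, day, game, round), every row's
    # (player, partner) must be mirrored by a (partner, player) row
    key = ["session", "day", "game", "round"]
    fwd = log.set_index(key + ["player", "partner"]).index
    rev = log.set_index(key + ["partner", "player"]).index
    unpaired = ~fwd.isin(rev)
    if unpaired.any():
        rows = log.index[unpaired][:5].tolist()
        r = log.loc[rows[0]]
        raise LogFormatError(
            f"unpaired rows at {rows}: e.g. player {r['player']!r} lists partner "
            f"{r['partner']!r} in (session {r['session']}, day {r['day']}, "
            f"game {r['game']}, round {r['round']}) but no mirror row exists"
        )

    if check_payoffs and "payoff" in log.columns and log["payoff"].notna().any():
        M = payoffs or PayoffMatrix()
        merged = log.merge(
            log[key + ["player", "partner", "action"]].rename(
                columns={"player": "partner", "partner": "player", "action": "partner_action"}
            ),
            on=key + ["player", "partner"],
            how="left",
        )
        own_c = merged["action"].eq(COOPERATE).to_numpy()
        opp_c = merged["partner_action"].eq(COOPERATE).to_numpy()
        expected = np.select(
            [own_c & opp_c, own_c & ~opp_c, ~own_c & opp_c],
            [M.R, M.S, M.T],
            default=M.P,
        )
        stored = merged["payoff"].to_numpy(dtype=float)
        bad = np.nonzero(~np.isclose(stored, expected))[0]
        if bad.size:
            i = int(bad[0])
            raise LogFormatError(
                f"stored payoff {stored[i]} at row {i} does not match the payoff "
                f"matrix (T={M.T}, R={M.R}, P={M.P}, S={M.S}) value {expected[i]} "
                f"for actions ({merged['action'].iat[i]}, {merged['partner_action'].iat[i]})"
            )
    return log


def read_log(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    H: int = 10,
    validate: bool = True,
    **validate_kwargs,
) -> pd.DataFrame:
    """Read a game log from CSV or JSON-lines.

    ``dialect`` maps external column names to canonical ones, e.g.
    ``{"subject_id": "player", "opponent_id": "partner"}``.
    """
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    if validate:
        df = validate_log(df, H=H, **validate_kwargs)
    return df


def write_log(log: pd.DataFrame, path: str | Path) -> Path:
    """Write a game log as CSV (or JSON-lines for a .jsonl/.ndjson path)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in REQUIRED_COLUMNS if c in log.columns] + [
        c for c in log.columns if c not in REQUIRED_COLUMNS
    ]
    out = log[cols]
    if path.suffix in (".jsonl", ".ndjson"):
        out.to_json(path, orient="records", lines=True)
    else:
        out.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    """Write a summary/ground-truth object as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
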