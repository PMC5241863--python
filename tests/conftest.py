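import numpy as np
import pandas as pd
import pytest

from coopdyn import PayoffMatrix, play_game, strategy_payoff_table


@pytest.fixture(scope="session")
def M():
    return PayoffMatrix()


@pytest.fixture(scope="session")
def U(M):
    return strategy_payoff_table(H=10, M=M)


def log_from_pairings(pairings, H=10, session="s1"):
    """Build a long-format log from [(day, game, p1, s1, p2, s2), ...] playouts."""
    rows = []
    for day, game, p1, s1, p2, s2 in pairings:
        po = play_game(s1, s2, H=H)
        for r in range(H):
            rows.append((session, day, game, r + 1, p1, p2, po.actions1[r]))
            rows.append((session, day, game, r + 1, p2, p1, po.actions2[r]))
    return pd.DataFrame(
        rows, columns=["session", "day", "game", "round", "player", "partner", "action"]
    )


@pytest.fixture(scope="session")
def tiny_log():
    """Two days x two games of mixed pairings among four players."""
    return log_from_pairings(
        [
            (1, 1, "a", "CC", "b", "CC"),
            (1, 1, "c", "T_8", "d", "T_5"),
            (1, 2, "a", "CC", "c", "T_8"),
            (1, 2, "b", "CC", "d", "T_5"),
            (2, 1, "a", "CC", "d", "T_5"),
            (2, 1, "b", "CC", "c", "T_8"),
            (2, 2, "a", "CC", "b", "CC"),
            (2, 2, "c", "T_8", "d", "T_5"),
        ]
    )
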