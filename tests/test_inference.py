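"""Strategy inference: consistency indicators, EWMA weights and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopdyn import (
    OTHER,
    STRATEGY_NAMES,
    StrategyInferenceModel,
    assign_strategy,
    classify_resilient,
    consistent_strategies,
    update_weights,
)

GAMMA = 0.818


def grim_response(e, opp, H=10):
    """Independent oracle: what a threshold-e strategy plays against opp actions."""
    out = []
    defected = False
    for r in range(1, H + 1):
        out.append("C" if (r < e and not defected) else "D")
        if opp[r - 1] == "D":
            defected = True
    return out


def oracle_consistent(own, opp, H=10):
    """Enumerate all 11 strategies against the observed opponent actions."""
    names = set()
    for name in STRATEGY_NAMES:
        e = H + 1 if name == "CC" else min(int(name.split("_")[1]), H + 1)
        if grim_response(e, opp, H) == list(own):
            names.add(name)
    return names


class TestConsistency:
    def test_all_defection_is_alld_only(self):
        ind = consistent_strategies("D" * 10, "C" * 10)
        assert {k for k, v in ind.items() if v} == {"T_1"}

    def test_mutual_cooperation_is_grim_only(self):
        ind = consistent_strategies("C" * 10, "C" * 10)
        assert {k for k, v in ind.items() if v} == {"CC"}

    def test_observational_equivalence_after_opponent_defects(self):
        """Retaliation from round 6 is consistent with CC and T_6..T_10 alike."""
        opp = "C" * 4 + "D" * 6
        own = "C" * 5 + "D" * 5
        ind = consistent_strategies(own, opp)
        assert {k for k, v in ind.items() if v} == {"CC", "T_6", "T_7", "T_8", "T_9", "T_10"}

    def test_forgiving_threshold_variant_recoded(self):
        """Defect at x, resume C for two rounds while the partner cooperated -> T_x."""
        own = list("CCCCCDCCDD")  # T_6 defecting at 6 then briefly forgiving
        opp = list("CCCCCCCCDD")
        ind = consistent_strategies(own, opp)
        assert ind["T_6"]
        assert not ind[OTHER]
        # with forgiveness disabled the play matches nothing
        strict = consistent_strategies(own, opp, forgiving_window=0)
        assert strict[OTHER]

    def test_unmatchable_play_is_other(self):
        ind = consistent_strategies("DCDCDCDCDC", "C" * 10)
        assert ind[OTHER]
        assert not any(ind[k] for k in STRATEGY_NAMES)

    def test_malformed_actions_rejected(self):
        with pytest.raises(ValueError, match="invalid action"):
            consistent_strategies("CX" + "C" * 8, "C" * 10)
        with pytest.raises(ValueError, match="length"):
            consistent_strategies("CC", "C" * 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        own=st.lists(st.sampled_from("CD"), min_size=10, max_size=10),
        opp=st.lists(st.sampled_from("CD"), min_size=10, max_size=10),
    )
    def test_matches_enumeration_oracle(self, own, opp):
        """Without forgiveness, the indicator equals brute-force enumeration."""
        ind = consistent_strategies(own, opp, forgiving_window=0)
        assert {k for k, v in ind.items() if v and k != OTHER} == oracle_consistent(own, opp)


class TestWeights:
    def test_gamma_zero_reduces_to_indicator(self):
        ind = {k: k == "T_3" for k in list(STRATEGY_NAMES) + [OTHER]}
        w = update_weights(None, ind, gamma=0.0)
        w = update_weights(w, ind, gamma=0.0)
        assert w[2] == 1.0 and w.sum() == 1.0

    def test_constant_indicator_geometric_series(self):
        """w(j) = (1 - gamma^j) / (1 - gamma); -> 5.4945 as j grows."""
        ind = np.zeros(12)
        ind[10] = 1.0
        w = None
        for j in range(1, 60):
            w = update_weights(w, ind, gamma=GAMMA)
            assert w[10] == pytest.approx((1 - GAMMA**j) / (1 - GAMMA))
        assert w[10] == pytest.approx(1 / (1 - GAMMA), abs=1e-4)
        assert w[10] == pytest.approx(5.4945, abs=1e-3)
        assert (w <= 1 / (1 - GAMMA) + 1e-12).all()  # geometric bound

    def test_single_spike_decays_geometrically(self):
        ind = np.zeros(12)
        ind[0] = 1.0
        w = update_weights(None, ind, gamma=GAMMA)
        w = update_weights(w, np.zeros(12), gamma=GAMMA)
        w = update_weights(w, np.zeros(12), gamma=GAMMA)
        assert w[0] == pytest.approx(0.669124)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            update_weights(None, np.zeros(12), gamma=1.5)


class TestAssignment:
    def make_w(self, **kv):
        w = {k: 0.0 for k in list(STRATEGY_NAMES) + [OTHER]}
        w.update(kv)
        return w

    def test_threshold_beats_grim_on_tie(self):
        assert assign_strategy(self.make_w(T_9=3.0, CC=3.0)) == "T_9"

    def test_known_beats_unidentified_on_tie(self):
        assert assign_strategy(self.make_w(T_3=2.0, OTHER=2.0)) == "T_3"

    def test_all_zero_is_other(self):
        assert assign_strategy(self.make_w()) == OTHER

    def test_largest_threshold_wins_among_tied(self):
        assert assign_strategy(self.make_w(T_6=1.0, T_9=1.0)) == "T_9"

    def test_unique_max_wins(self):
        assert assign_strategy(self.make_w(CC=4.0, T_9=3.0)) == "CC"
        assert assign_strategy(self.make_w(OTHER=5.0, T_9=3.0)) == OTHER


class TestClassifyResilient:
    def test_threshold_boundary(self):
        games = list(range(20))
        all_cc = pd.Series(["CC"] * 20, index=games)
        assert classify_resilient(all_cc, games) is True
        mostly = pd.Series(["CC"] * 15 + ["T_9"] * 5, index=games)  # 75%
        assert classify_resilient(mostly, games) is False
        exactly = pd.Series(["CC"] * 16 + ["T_9"] * 4, index=games)  # 80%
        assert classify_resilient(exactly, games) is True

    def test_missing_games_ignored(self):
        s = pd.Series(["CC", None, "CC", None, "CC"])
        assert classify_resilient(s) is True

    def test_unclassifiable_player(self):
        assert classify_resilient(pd.Series([None, None])) is None


class TestModelFit:
    def test_resilient_grim_player_assigned_cc_despite_exploitation(self, tiny_log):
        res = StrategyInferenceModel(tiny_log, stable_days=(1, 2)).fit()
        # players a and b play CC in every game; c (T_8) and d (T_5) do not
        flags = res.resilient()
        assert bool(flags["a"]) and bool(flags["b"])
        assert not bool(flags["c"]) and not bool(flags["d"])

    def test_fixed_strategy_always_in_consistent_set(self, tiny_log):
        """Assignments for a pure T_5 player are observationally equivalent to T_5."""
        res = StrategyInferenceModel(tiny_log).fit()
        for label in res.assignments.loc["d"].dropna():
            # d defects first at 5 in every game -> only T_5 ever matches exactly
            assert label == "T_5"

    def test_unpaired_log_rejected(self, tiny_log):
        broken = tiny_log[
            ~((tiny_log.player == "b") & (tiny_log.day == 1) & (tiny_log.game == 1))
        ]
        with pytest.raises(ValueError, match="unpaired"):
            StrategyInferenceModel(broken).fit()

    def test_single_match_variant_runs(self, tiny_log):
        res = StrategyInferenceModel(tiny_log, single_match=True).fit()
        assert res.assignments.shape == (4, 4)
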