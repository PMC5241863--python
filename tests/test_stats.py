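"""Experiment analytics: cooperation rates, restart effects, r_d tests, onset."""

import numpy as np
import pandas as pd
import pytest

from coopdyn import (
    SynthConfig,
    cooperation_rate,
    game_restart_effect,
    generate,
    implied_cc_fraction,
    pair_first_defections,
    rd_distribution,
    session_restart_effect,
    steady_state_onset,
    two_sample_ks,
)
from conftest import log_from_pairings


def brute_force_ks_d(x, y):
    support = sorted(set(x) | set(y))
    gaps = [
        abs(np.mean([v <= s for v in x]) - np.mean([v <= s for v in y]))
        for s in support
    ]
    return max(gaps)


class TestCooperationRate:
    def test_playout_log_rate(self):
        """T_8 vs CC: 15 cooperative decisions out of 20."""
        log = log_from_pairings([(1, 1, "a", "T_8", "b", "CC")])
        assert cooperation_rate(log) == pytest.approx(0.75)

    def test_round_filter(self):
        log = log_from_pairings([(1, 1, "a", "T_8", "b", "CC")])
        assert cooperation_rate(log, round=1) == 1.0
        assert cooperation_rate(log, round=8) == 0.5
        assert cooperation_rate(log, round=10) == 0.0

    def test_all_cooperative_log(self):
        log = log_from_pairings([(1, 1, "a", "CC", "b", "CC")])
        assert cooperation_rate(log) == 1.0

    def test_empty_selection_signalled(self, tiny_log):
        with pytest.raises(ValueError, match="empty selection"):
            cooperation_rate(tiny_log, day=99)


class TestRestartEffects:
    def test_constant_cooperation_has_no_restart(self):
        log = log_from_pairings([(1, g, "a", "CC", "b", "CC") for g in (1, 2, 3)])
        assert game_restart_effect(log, day=1) == 0.0

    def test_full_reset_restart_is_one(self):
        """Round 10 always defected, round 1 always cooperative."""
        log = log_from_pairings([(1, g, "a", "T_5", "b", "T_5") for g in (1, 2)])
        # r10 coop = 0, r1 coop = 1 in every game
        assert game_restart_effect(log, day=1) == 1.0

    def test_single_game_day_undefined(self):
        log = log_from_pairings([(1, 1, "a", "CC", "b", "CC")])
        with pytest.raises(ValueError, match="at least 2 games"):
            game_restart_effect(log, day=1)

    def test_time_homogeneous_session_restart_is_zero(self):
        log = log_from_pairings(
            [(d, g, "a", "T_8", "b", "T_8") for d in (1, 2, 3) for g in (1, 2)]
        )
        eff = session_restart_effect(log)
        assert len(eff) == 4  # 2 boundaries x rounds {9, 10}
        assert (eff["diff"] == 0.0).all()

    def test_planted_across_day_reset_recovered(self):
        """Day 1 ends at T_9, day 2 restarts at CC: round-9/10 jumps match."""
        log = log_from_pairings(
            [(1, 1, "a", "CC", "b", "CC"), (1, 2, "a", "T_9", "b", "T_9"),
             (2, 1, "a", "CC", "b", "CC"), (2, 2, "a", "CC", "b", "CC")]
        )
        eff = session_restart_effect(log)
        # game (1,2): both defect from 9 -> coop 0 in rounds 9, 10; day 2 game 1 all C
        assert eff.loc[eff["round"] == 9, "diff"].tolist() == [1.0]
        assert eff.loc[eff["round"] == 10, "diff"].tolist() == [1.0]

    def test_single_day_gives_empty_result(self):
        log = log_from_pairings([(1, 1, "a", "CC", "b", "CC")])
        assert session_restart_effect(log).empty


class TestRdDistribution:
    def test_fully_cooperative_mass_in_c_bin(self):
        log = log_from_pairings([(1, g, "a", "CC", "b", "CC") for g in (1, 2, 3)])
        dist = rd_distribution(log, day=1)
        assert dist["C"] == 3 and dist.sum() == 3

    def test_threshold_pairings_concentrate_at_threshold(self):
        log = log_from_pairings(
            [(1, g, "a", "T_5", "b", "CC") for g in (1, 2)]
            + [(1, 3, "c", "T_5", "d", "T_9")]
        )
        dist = rd_distribution(log, day=1)
        assert dist["5"] == 3
        assert dist.sum() == 3  # mass conservation

    def test_pair_first_defections_values(self, tiny_log):
        rd = pair_first_defections(tiny_log)
        assert len(rd) == 8
        # CC-CC pairs -> 11; any pairing involving d (T_5) -> 5; c vs CC -> 8
        merged = dict(zip(zip(rd.day, rd.game, rd.p1, rd.p2), rd.r_d))
        assert merged[(1, 1, "a", "b")] == 11
        assert merged[(1, 1, "c", "d")] == 5
        assert merged[(1, 2, "a", "c")] == 8


class TestKS:
    def test_identical_samples(self):
        d, p = two_sample_ks([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = two_sample_ks([1] * 5, [10] * 5)
        assert d == 1.0

    def test_shifted_discrete_sample(self):
        d, _ = two_sample_ks([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 12, size=rng.integers(3, 20))
        y = rng.integers(1, 12, size=rng.integers(3, 20))
        d, p = two_sample_ks(x, y)
        assert d == pytest.approx(brute_force_ks_d(x, y))
        assert 0.0 <= p <= 1.0

    def test_p_decreases_with_d_at_fixed_n(self):
        base = list(range(1, 11)) * 3
        _, p_small = two_sample_ks(base, base[:-1] + [11])
        _, p_large = two_sample_ks(base, [11] * 30)
        assert p_large < p_small

    def test_permutation_variant(self):
        d, p = two_sample_ks([1, 2, 3, 4], [1, 2, 3, 4], method="permutation")
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ks([], [1])


class TestSteadyState:
    def stationary_cfg(self, seed=0):
        return SynthConfig(
            session_sizes=(40,), days=6, games_per_day=10, plateau_day=1,
            plateau_threshold=9, eps=0.0, seed=seed,
        )

    def test_stationary_generator_stable_from_day_two(self):
        log, _ = generate(self.stationary_cfg())
        rep = steady_state_onset(log)
        assert rep.onset_day == 2

    def test_monotone_drift_never_stabilises(self):
        cfg = SynthConfig(
            session_sizes=(60,), days=6, games_per_day=20, plateau_day=6,
            plateau_threshold=1, start_threshold=11, jitter_prob=0.0,
            eps=0.0, seed=1,
        )
        log, _ = generate(cfg)
        rep = steady_state_onset(log)
        assert rep.onset_day is None
        assert rep.tests["significant"].all()

    def test_mann_whitney_variant_agrees_on_strong_drift(self):
        log, _ = generate(self.stationary_cfg(seed=3))
        rep = steady_state_onset(log, test="mw")
        assert rep.onset_day == 2

    def test_too_few_days_rejected(self, tiny_log):
        with pytest.raises(ValueError, match="at least 3 days"):
            steady_state_onset(tiny_log)


class TestImpliedCCFraction:
    @pytest.mark.parametrize(
        "rate,expected", [(0.16, 0.40), (0.0, 0.0), (1.0, 1.0), (0.25, 0.5)]
    )
    def test_square_root_rule(self, rate, expected):
        assert implied_cc_fraction(rate) == pytest.approx(expected)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            implied_cc_fraction(1.2)
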