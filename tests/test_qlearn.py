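"""Q-learning updates, the no-action-biased policy, and table persistence."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from assistrl.mdp import Action, RewardOutcome
from assistrl.qlearn import (
    LearnerConfig,
    QTable,
    QTableLoadError,
    double_q_update,
    greedy_action,
    load_qtable,
    q_update,
    save_qtable,
    select_action,
)

S0, S1 = (0, 0), (1, 1)


class TestQUpdate:
    def test_zero_reward_is_fixed_point_of_zero_table(self):
        q = QTable()
        q_update(q, S0, Action.NOP, RewardOutcome(0.0), S1,
                 LearnerConfig(alpha=0.5, gamma=0.9))
        assert len(q) == 1 and q.get(S0, Action.NOP) == 0.0

    def test_single_update_from_zero_table(self):
        # Q <- 0 + 0.5 * (10 + 0.9*0 - 0) = 5
        q = QTable()
        q_update(q, S0, Action.HELP, RewardOutcome(10.0), S1,
                 LearnerConfig(alpha=0.5, gamma=0.9))
        assert q.get(S0, Action.HELP) == pytest.approx(5.0)

    def test_retro_credit_updates_help_too(self):
        # primary: Q(s,ASK) = 0.5*(-10) = -5; retro: Q(s,HELP) = 0.5*10 = 5
        q = QTable()
        out = RewardOutcome(-10.0, Action.HELP, 10.0)
        q_update(q, S0, Action.ASK, out, S1, LearnerConfig(alpha=0.5, gamma=0.9))
        assert q.get(S0, Action.ASK) == pytest.approx(-5.0)
        assert q.get(S0, Action.HELP) == pytest.approx(5.0)
        assert q.get(S0, Action.NOP) == 0.0

    def test_bootstrap_uses_max_over_next_state(self):
        q = QTable()
        q.set(S1, Action.HELP, 10.0)
        q.set(S1, Action.ASK, -5.0)
        q_update(q, S0, Action.NOP, RewardOutcome(0.0), S1,
                 LearnerConfig(alpha=1.0, gamma=0.5))
        assert q.get(S0, Action.NOP) == pytest.approx(0.5 * 10.0)

    def test_only_touched_entries_change(self):
        q = QTable()
        q.set(S1, Action.NOP, 3.0)
        before = {(S1, a): q.get(S1, a) for a in Action}
        q_update(q, S0, Action.HELP, RewardOutcome(10.0), S1,
                 LearnerConfig(alpha=0.5, gamma=0.9))
        assert {(S1, a): q.get(S1, a) for a in Action} == before

    @given(st.lists(st.sampled_from([0.0, -200.0, 10.0, -20.0, -10.0]),
                    min_size=1, max_size=300),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_values_bounded_by_rmax_over_one_minus_gamma(self, rewards, seed):
        """|Q| stays within 200/(1-gamma) for any reward-table sequence."""
        cfg = LearnerConfig(alpha=0.3, gamma=0.9)
        bound = 200.0 / (1.0 - cfg.gamma)
        rng = np.random.default_rng(seed)
        states = [(0,), (1,), (2,)]
        q = QTable()
        for r in rewards:
            s = states[rng.integers(3)]
            s_next = states[rng.integers(3)]
            a = list(Action)[rng.integers(3)]
            retro = rng.random() < 0.3
            out = (RewardOutcome(r, Action.HELP, 10.0) if retro
                   else RewardOutcome(r))
            q_update(q, s, a, out, s_next, cfg)
        for s in states:
            for a in Action:
                assert abs(q.get(s, a)) <= bound


class TestDoubleQUpdate:
    def test_zero_reward_leaves_both_tables_zero(self, rng):
        pair = (QTable(), QTable())
        double_q_update(pair, S0, Action.NOP, RewardOutcome(0.0), S1,
                        LearnerConfig(alpha=0.5, gamma=0.9,
                                      algorithm="double_q"), rng)
        assert len(pair[0]) + len(pair[1]) == 1
        assert pair[0].get(S0, Action.NOP) == pair[1].get(S0, Action.NOP) == 0.0

    def test_one_table_updated_other_untouched(self, rng):
        pair = (QTable(), QTable())
        double_q_update(pair, S0, Action.HELP, RewardOutcome(7.0), S1,
                        LearnerConfig(alpha=1.0, gamma=0.0,
                                      algorithm="double_q"), rng)
        vals = sorted([pair[0].get(S0, Action.HELP),
                       pair[1].get(S0, Action.HELP)])
        assert vals == [0.0, 7.0]
        updated = pair[0] if pair[0].get(S0, Action.HELP) == 7.0 else pair[1]
        other = pair[1] if updated is pair[0] else pair[0]
        assert len(other) == 0

    def test_coin_is_fair_over_many_updates(self):
        rng = np.random.default_rng(7)
        cfg = LearnerConfig(alpha=1.0, gamma=0.0, algorithm="double_q")
        n = 2000
        count_a = 0
        for _ in range(n):
            pair = (QTable(), QTable())
            double_q_update(pair, S0, Action.NOP, RewardOutcome(1.0), S1,
                            cfg, rng)
            count_a += int(pair[0].get(S0, Action.NOP) == 1.0)
        # binomial(2000, 0.5): 5 sigma ~ 112
        assert abs(count_a - n / 2) < 120

    def test_bootstrap_decouples_selection_and_evaluation(self, rng):
        qa, qb = QTable(), QTable()
        # selected table's argmax at s_next is HELP, but value comes from other
        qa.set(S1, Action.HELP, 100.0)
        qb.set(S1, Action.HELP, 2.0)
        qb.set(S1, Action.ASK, 50.0)
        cfg = LearnerConfig(alpha=1.0, gamma=1.0 - 1e-9, algorithm="double_q")
        # force selection of table A via a coin-rigged generator
        class Rigged:
            def integers(self, *_a, **_k):
                return 0
        double_q_update((qa, qb), S0, Action.NOP, RewardOutcome(0.0), S1,
                        cfg, Rigged())
        assert qa.get(S0, Action.NOP) == pytest.approx(2.0, rel=1e-6)


class TestSelectAction:
    def test_unseen_state_yields_nop_for_any_epsilon(self, rng):
        q = QTable()
        for eps in (0.0, 0.5, 1.0):
            cfg = LearnerConfig(epsilon=eps, epsilon_final=None)
            assert select_action(q, S0, cfg, rng) is Action.NOP

    def test_unique_argmax_is_exploited(self, rng):
        q = QTable()
        q.set(S0, Action.HELP, 5.0)
        cfg = LearnerConfig(epsilon=0.0, epsilon_final=None)
        assert select_action(q, S0, cfg, rng) is Action.HELP

    def test_nonnop_tie_breaks_help_before_ask(self, rng):
        q = QTable()
        q.set(S0, Action.HELP, 3.0)
        q.set(S0, Action.ASK, 3.0)
        q.set(S0, Action.NOP, -1.0)
        cfg = LearnerConfig(epsilon=0.0, epsilon_final=None)
        assert select_action(q, S0, cfg, rng) is Action.HELP

    def test_nop_preferred_when_tied_with_best(self, rng):
        q = QTable()
        q.set(S0, Action.NOP, 3.0)
        q.set(S0, Action.HELP, 3.0)
        assert greedy_action(q, S0) is Action.NOP

    def test_epsilon_one_is_constantly_nop(self, rng):
        q = QTable()
        q.set(S0, Action.HELP, 100.0)  # greedy would say HELP
        cfg = LearnerConfig(epsilon=1.0, epsilon_final=None)
        assert all(select_action(q, S0, cfg, rng) is Action.NOP
                   for _ in range(50))

    def test_exploration_rate_decays_linearly(self):
        cfg = LearnerConfig(epsilon=0.1, epsilon_final=0.01)
        eps = [cfg.epsilon_at(k, 150) for k in range(150)]
        assert eps[0] == pytest.approx(0.1)
        assert eps[-1] == pytest.approx(0.01)
        assert all(a >= b for a, b in zip(eps, eps[1:]))


class TestPersistence:
    def _table(self):
        q = QTable()
        q.set(S0, Action.NOP, -1.5)
        q.set(S0, Action.HELP, 2.0)
        q.set(S1, Action.ASK, 0.25)
        return q

    def test_single_table_round_trip(self, tmp_path):
        path = tmp_path / "q.json"
        cfg = LearnerConfig(alpha=0.2, gamma=0.8, epsilon=0.05, seed=9)
        save_qtable(self._table(), path, config=cfg)
        loaded, loaded_cfg = load_qtable(path)
        assert loaded == self._table()
        assert (loaded_cfg.alpha, loaded_cfg.gamma, loaded_cfg.seed) == (0.2, 0.8, 9)

    def test_double_pair_round_trip(self, tmp_path):
        path = tmp_path / "q.json"
        qb = QTable()
        qb.set(S1, Action.HELP, 4.0)
        save_qtable((self._table(), qb), path,
                    config=LearnerConfig(algorithm="double_q"))
        loaded, _ = load_qtable(path)
        assert isinstance(loaded, tuple)
        assert loaded[0] == self._table() and loaded[1] == qb

    def test_empty_table_round_trips_to_empty(self, tmp_path):
        path = tmp_path / "q.json"
        save_qtable(QTable(), path)
        loaded, _ = load_qtable(path)
        assert len(loaded) == 0

    def test_unknown_action_name_rejected(self, tmp_path):
        path = tmp_path / "q.json"
        save_qtable(self._table(), path)
        obj = json.loads(path.read_text())
        key = next(iter(obj["tables"][0]))
        obj["tables"][0][key]["RETREAT"] = 1.0
        path.write_text(json.dumps(obj))
        with pytest.raises(QTableLoadError):
            load_qtable(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "q.json"
        save_qtable(self._table(), path)
        obj = json.loads(path.read_text())
        obj["version"] = 99
        path.write_text(json.dumps(obj))
        with pytest.raises(QTableLoadError):
            load_qtable(path)
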