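"""Tabular Q-learning and double Q-learning with a no-action-biased policy.

The action-value table defaults to zero for unseen (state, action) pairs.
The behavior policy is a modified ε-greedy: instead of exploring with a
uniformly random action, the agent takes the "no action" option (NOP) with
probability ε, and also breaks exploitation ties in favour of NOP — so a
fresh, all-zero state always yields NOP. This keeps help tools and dialogs
from popping up at unsought times while the agent still has no evidence the
user is confused. Remaining ties resolve HELP before ASK for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mdp import Action, RewardOutcome
from .windows import DiscreteState

__all__ = [
    "LearnerConfig",
    "QTable",
    "QTableLoadError",
    "q_update",
    "double_q_update",
    "select_action",
    "greedy_action",
    "save_qtable",
    "load_qtable",
]

_ACTIONS: Tuple[Action, ...] = (Action.NOP, Action.HELP, Action.ASK)
#: tie order after the NOP preference
_TIE_ORDER: Tuple[Action, ...] = (Action.HELP, Action.ASK)

QTABLE_FORMAT_VERSION = 1


class QTableLoadError(ValueError):
    """Q-table file has an unknown shape, version, or action name."""


@dataclass
class LearnerConfig:
    """Hyperparameters of the tabular learner.

    epsilon_final enables a linear decay of the exploration rate from
    ``epsilon`` to ``epsilon_final`` over a training run; ``None`` keeps
    epsilon constant.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.1
    epsilon_final: Optional[float] = 0.01
    algorithm: str = "q"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must be in [0, 1]")
        if self.epsilon_final is not None and not (0.0 <= self.epsilon_final <= 1.0):
            raise ValueError("epsilon_final must be in [0, 1]")
        if self.algorithm not in ("q", "double_q"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def epsilon_at(self, step: int, n_steps: int) -> float:
        """Exploration rate at a given training step under linear decay."""
        if self.epsilon_final is None or n_steps <= 1:
            return self.epsilon
        frac = min(max(step / (n_steps - 1), 0.0), 1.0)
        return self.epsilon + (self.epsilon_final - self.epsilon) * frac


class QTable:
    """Action-value table q(s, a), zero for never-updated pairs.

    For double Q-learning two instances are kept (see
    :func:`double_q_update`); a single table is the plain Q-learning case.
    """

    def __init__(self) -> None:
        self._values: Dict[Tuple[DiscreteState, Action], float] = {}

    def get(self, state: DiscreteState, action: Action) -> float:
        return self._values.get((state, action), 0.0)

    def set(self, state: DiscreteState, action: Action, value: float) -> None:
        self._values[(state, action)] = float(value)

    def max_value(self, state: DiscreteState) -> float:
        return max(self.get(state, a) for a in _ACTIONS)

    def argmax_actions(self, state: DiscreteState) -> List[Action]:
        """All actions attaining the maximal value in ``state``."""
        vals = {a: self.get(state, a) for a in _ACTIONS}
        best = max(vals.values())
        return [a for a in _ACTIONS if vals[a] == best]

    def states(self) -> List[DiscreteState]:
        return sorted({s for s, _ in self._values})

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        # unseen pairs read as zero, so explicit zeros don't distinguish tables
        if not isinstance(other, QTable):
            return NotImplemented
        mine = {k: v for k, v in self._values.items() if v != 0.0}
        theirs = {k: v for k, v in other._values.items() if v != 0.0}
        return mine == theirs

    def copy(self) -> "QTable":
        q = QTable()
        q._values = dict(self._values)
        return q


def _td_update(q: QTable, s: DiscreteState, a: Action, r: float,
               target_next: float, alpha: float) -> None:
    q.set(s, a, q.get(s, a) + alpha * (r + target_next - q.get(s, a)))


def q_update(
    q: QTable,
    s: DiscreteState,
    a: Action,
    outcome: RewardOutcome,
    s_next: DiscreteState,
    config: LearnerConfig,
) -> QTable:
    """One Q-learning update, in place; returns the table for chaining.

    Q(s,a) ← Q(s,a) + α · (r + γ·max_a' Q(s',a') − Q(s,a)). When the outcome
    carries retroactive credit (a dialog or manual trigger revealed that HELP
    was correct), an identical-form update with the retroactive reward is
    applied to (s, HELP) against the same successor state.
    """
    target = config.gamma * q.max_value(s_next)
    _td_update(q, s, a, outcome.reward, target, config.alpha)
    if outcome.has_retro:
        target = config.gamma * q.max_value(s_next)
        _td_update(q, s, outcome.retro_action, outcome.retro_reward,
                   target, config.alpha)
    return q


def double_q_update(
    q_pair: Tuple[QTable, QTable],
    s: DiscreteState,
    a: Action,
    outcome: RewardOutcome,
    s_next: DiscreteState,
    config: LearnerConfig,
    rng: np.random.Generator,
) -> Tuple[QTable, QTable]:
    """One double Q-learning update on a fair-coin-selected table.

    The selected table is updated toward r + γ·Q_other(s', argmax_a'
    Q_selected(s', a')), decoupling action selection from evaluation to
    reduce maximization bias. Retroactive credit updates the same selected
    table in the same form.
    """
    qa, qb = q_pair
    sel, other = (qa, qb) if rng.integers(2) == 0 else (qb, qa)

    def bootstrap() -> float:
        a_star = max(_ACTIONS, key=lambda act: sel.get(s_next, act))
        return config.gamma * other.get(s_next, a_star)

    _td_update(sel, s, a, outcome.reward, bootstrap(), config.alpha)
    if outcome.has_retro:
        _td_update(sel, s, outcome.retro_action, outcome.retro_reward,
                   bootstrap(), config.alpha)
    return q_pair


def greedy_action(q: QTable, s: DiscreteState) -> Action:
    """Greedy action with the NOP-preferring tie rule (no exploration)."""
    best = q.argmax_actions(s)
    if Action.NOP in best:
        return Action.NOP
    for a in _TIE_ORDER:
        if a in best:
            return a
    return best[0]


def select_action(
    q: QTable,
    s: DiscreteState,
    config: LearnerConfig,
    rng: np.random.Generator,
    epsilon: Optional[float] = None,
) -> Action:
    """Modified ε-greedy action selection.

    With probability ε the agent takes NOP (not a uniformly random action);
    otherwise it acts greedily, preferring NOP on value ties and breaking
    remaining ties HELP before ASK. ``epsilon`` overrides the config value,
    e.g. for a decay schedule.
    """
    eps = config.epsilon if epsilon is None else epsilon
    if eps > 0 and rng.random() < eps:
        return Action.NOP
    return greedy_action(q, s)


def _table_json(q: QTable) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for state in q.states():
        key = ",".join(map(str, state))
        out[key] = {a.value: q.get(state, a) for a in _ACTIONS}
    return out


def save_qtable(
    q: "QTable | Tuple[QTable, QTable]",
    path,
    config: Optional[LearnerConfig] = None,
) -> None:
    """Serialize one table (Q-learning) or a pair (double Q-learning)."""
    tables = [q] if isinstance(q, QTable) else list(q)
    config = config or LearnerConfig()
    obj = {
        "version": QTABLE_FORMAT_VERSION,
        "algorithm": "q" if len(tables) == 1 else "double_q",
        "config": {
            "alpha": config.alpha,
            "gamma": config.gamma,
            "epsilon": config.epsilon,
            "seed": config.seed,
        },
        "tables": [_table_json(t) for t in tables],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_qtable(path) -> "tuple[QTable | Tuple[QTable, QTable], LearnerConfig]":
    """Load a saved table (or pair) and the config metadata stored with it."""
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict) or "tables" not in obj:
        raise QTableLoadError("not a q-table file")
    if obj.get("version") != QTABLE_FORMAT_VERSION:
        raise QTableLoadError(f"unsupported q-table version {obj.get('version')!r}")
    tables: List[QTable] = []
    for tj in obj["tables"]:
        q = QTable()
        for key, actions in tj.items():
            try:
                state = tuple(int(x) for x in key.split(","))
            except ValueError:
                raise QTableLoadError(f"bad state key {key!r}")
            for aname, val in actions.items():
                try:
                    action = Action(aname)
                except ValueError:
                    raise QTableLoadError(f"unknown action name {aname!r}")
                q.set(state, action, float(val))
        tables.append(q)
    if len(tables) not in (1, 2):
        raise QTableLoadError(f"expected 1 or 2 tables, found {len(tables)}")
    cfg_obj = obj.get("config", {})
    config = LearnerConfig(
        alpha=float(cfg_obj.get("alpha", 0.1)),
        gamma=float(cfg_obj.get("gamma", 0.9)),
        epsilon=float(cfg_obj.get("epsilon", 0.1)),
        algorithm=obj.get("algorithm", "q"),
        seed=int(cfg_obj.get("seed", 0)),
    )
    return (tables[0] if len(tables) == 1 else (tables[0], tables[1])), config
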