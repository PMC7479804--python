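"""Model/Results interface for training and evaluating the help reasoner.

:class:`HelpReasonerModel` bundles a synthetic user, window geometry,
binning configuration and learner hyperparameters; :meth:`fit` runs the full
interaction loop — emit a window, aggregate, discretize, select an action
under the modified ε-greedy policy, sample the user's feedback, compute the
reward and apply the (double) Q-learning update — and returns a
:class:`HelpReasonerResults` carrying the learned table, the per-step
training log, a text ``summary()`` and greedy evaluation.

Accuracy is defined as greedy agreement with the oracle action derived from
the latent confusion state (HELP when confused, NOP when calm); ASK matches
no oracle action and always counts as incorrect. Evaluation runs with
exploration off and learning frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import qlearn
from .mdp import Action, StepController, reward
from .qlearn import LearnerConfig, QTable
from .simulate import (LatentState, UserModel, emit_window, feedback_response,
                       latent_step, oracle_action)
from .windows import (DEFAULT_STATE_FEATURES, BinningScheme, WindowConfig,
                      aggregate_window, discretize, fit_bins)

__all__ = [
    "BinningConfig",
    "HelpReasonerModel",
    "HelpReasonerResults",
    "EvaluationResult",
    "run_training",
    "evaluate",
]

LOG_COLUMNS = [
    "step", "latent", "state", "action", "feedback", "reward",
    "mean_reward", "running_accuracy",
]


@dataclass
class BinningConfig:
    """How the discretization scheme is fitted before training."""

    n_bins: int = 4
    strategy: str = "quantile"
    state_features: Tuple[str, ...] = DEFAULT_STATE_FEATURES
    n_calibration_windows: int = 40


def _state_key(state: Tuple[int, ...]) -> str:
    return ",".join(map(str, state))


class HelpReasonerModel:
    """Help-triggering reasoner trained against a (synthetic) user.

    Parameters default to the reference scenario: 120 s windows of 12
    sub-samples, 4 quantile bins per physiological state feature, Q-learning
    with α=0.1, γ=0.9 and ε decaying linearly from 0.1 to 0.01.
    """

    def __init__(
        self,
        user_model: Optional[UserModel] = None,
        window: Optional[WindowConfig] = None,
        binning: Optional[BinningConfig] = None,
        learner: Optional[LearnerConfig] = None,
    ) -> None:
        self.user_model = user_model or UserModel()
        self.window = window or WindowConfig()
        self.binning = binning or BinningConfig()
        self.learner = learner or LearnerConfig()

    @classmethod
    def from_config(cls, config: "RunConfig") -> "HelpReasonerModel":
        # local import to avoid a cycle at module load
        return cls(user_model=config.user_model, window=config.window,
                   binning=config.binning, learner=config.learner)

    # -- simulation helpers -------------------------------------------------

    def _calibrate_bins(self, rng: np.random.Generator) -> BinningScheme:
        """Fit the quantile/uniform scheme on windows simulated up front."""
        latent = LatentState.CALM
        batches = []
        t = 0.0
        for _ in range(self.binning.n_calibration_windows):
            latent = latent_step(self.user_model, latent, rng)
            samples = emit_window(self.user_model, latent, t, self.window, rng)
            batches.append(aggregate_window(samples, self.window, t))
            t += self.window.window_s
        return fit_bins(batches, n_bins=self.binning.n_bins,
                        strategy=self.binning.strategy,
                        features=self.binning.state_features)

    def _observe(self, latent: LatentState, t: float,
                 scheme: BinningScheme, rng: np.random.Generator):
        samples = emit_window(self.user_model, latent, t, self.window, rng)
        batch = aggregate_window(samples, self.window, t)
        return discretize(batch, scheme), batch

    # -- fitting ------------------------------------------------------------

    def fit(self, n_steps: int = 150,
            seed: Optional[int] = None) -> "HelpReasonerResults":
        """Train for ``n_steps`` interaction steps and return the results."""
        if n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        seed = self.learner.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        scheme = self._calibrate_bins(rng)

        double = self.learner.algorithm == "double_q"
        qa, qb = QTable(), QTable()

        controller = StepController()
        latent = LatentState.CALM
        t = 0.0
        rows: List[dict] = []
        total_reward = 0.0
        n_correct = 0

        latent = latent_step(self.user_model, latent, rng)
        state, _ = self._observe(latent, t, scheme, rng)
        controller.begin(state)

        for step in range(n_steps):
            eps = self.learner.epsilon_at(step, n_steps)
            q_behave = self._combined(qa, qb) if double else qa
            action = qlearn.select_action(q_behave, state, self.learner,
                                          rng, epsilon=eps)
            controller.act(action)
            feedback = feedback_response(self.user_model, latent, action, rng)
            outcome = controller.give_feedback(feedback)

            # the next window reflects the user's reaction to a_t and starts
            # only after the feedback timeout has elapsed
            t += self.window.window_s + self.window.feedback_timeout_s
            next_latent = latent_step(self.user_model, latent, rng)
            next_state, _ = self._observe(next_latent, t, scheme, rng)
            controller.advance(next_state)

            if double:
                qlearn.double_q_update((qa, qb), state, action, outcome,
                                       next_state, self.learner, rng)
            else:
                qlearn.q_update(qa, state, action, outcome, next_state,
                                self.learner)

            total_reward += outcome.reward
            n_correct += int(action is oracle_action(latent))
            rows.append({
                "step": step,
                "latent": latent.value,
                "state": _state_key(state),
                "action": action.value,
                "feedback": feedback.value,
                "reward": outcome.reward,
                "mean_reward": total_reward / (step + 1),
                "running_accuracy": n_correct / (step + 1),
            })
            latent, state = next_latent, next_state

        log = pd.DataFrame(rows, columns=LOG_COLUMNS)
        qtable: Union[QTable, Tuple[QTable, QTable]] = (qa, qb) if double else qa
        return HelpReasonerResults(model=self, qtable=qtable, scheme=scheme,
                                   log=log, records=controller.records,
                                   seed=seed)

    @staticmethod
    def _combined(qa: QTable, qb: QTable) -> QTable:
        """Mean of the double-Q pair, used for action selection."""
        q = QTable()
        for s in set(qa.states()) | set(qb.states()):
            for a in Action:
                q.set(s, a, 0.5 * (qa.get(s, a) + qb.get(s, a)))
        return q


@dataclass
class EvaluationResult:
    accuracy: float
    n_steps: int
    log: pd.DataFrame


@dataclass
class HelpReasonerResults:
    """Learned policy plus training diagnostics."""

    model: HelpReasonerModel
    qtable: Union[QTable, Tuple[QTable, QTable]]
    scheme: BinningScheme
    log: pd.DataFrame
    records: list = field(default_factory=list)
    seed: int = 0

    @property
    def greedy_table(self) -> QTable:
        if isinstance(self.qtable, QTable):
            return self.qtable
        return HelpReasonerModel._combined(*self.qtable)

    def greedy_action(self, state) -> Action:
        return qlearn.greedy_action(self.greedy_table, tuple(state))

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, n_steps: int = 500,
                 seed: Optional[int] = None) -> EvaluationResult:
        """Greedy evaluation: ε = 0, no learning, fresh user trajectory.

        Accuracy is the fraction of steps whose greedy action equals the
        oracle action for the latent state (ASK never matches).
        """
        seed = (self.seed + 1_000_003) if seed is None else seed
        rng = np.random.default_rng(seed)
        m = self.model
        q = self.greedy_table
        latent = LatentState.CALM
        t = 0.0
        rows = []
        n_correct = 0
        for step in range(n_steps):
            latent = latent_step(m.user_model, latent, rng)
            state, _ = m._observe(latent, t, self.scheme, rng)
            action = qlearn.greedy_action(q, state)
            correct = action is oracle_action(latent)
            n_correct += int(correct)
            rows.append({"step": step, "latent": latent.value,
                         "state": _state_key(state), "action": action.value,
                         "correct": correct})
            t += m.window.window_s + m.window.feedback_timeout_s
        acc = n_correct / n_steps if n_steps else float("nan")
        return EvaluationResult(accuracy=acc, n_steps=n_steps,
                                log=pd.DataFrame(rows))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the training run."""
        n = len(self.log)
        lines = [
            "Help Reasoner Training Results",
            "=" * 46,
            f"{'algorithm':<28}{self.model.learner.algorithm}",
            f"{'training steps':<28}{n}",
            f"{'seed':<28}{self.seed}",
            f"{'alpha':<28}{self.model.learner.alpha}",
            f"{'gamma':<28}{self.model.learner.gamma}",
            f"{'epsilon (start)':<28}{self.model.learner.epsilon}",
            f"{'epsilon (final)':<28}{self.model.learner.epsilon_final}",
            f"{'states visited':<28}{self.log['state'].nunique() if n else 0}",
        ]
        if n:
            lines += [
                f"{'mean reward':<28}{self.log['reward'].mean():.3f}",
                f"{'total reward':<28}{self.log['reward'].sum():.1f}",
                f"{'training accuracy':<28}"
                f"{self.log['running_accuracy'].iloc[-1]:.3f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_learning_curve(self, ax=None):
        """Mean per-step reward and running accuracy over training."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["step"], self.log["mean_reward"], label="mean reward")
        ax2 = ax.twinx()
        ax2.plot(self.log["step"], self.log["running_accuracy"], color="C1",
                 label="running accuracy")
        ax2.set_ylim(0, 1)
        ax.set_xlabel("training step")
        ax.set_ylabel("cumulative mean reward")
        ax2.set_ylabel("running accuracy")
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, out_dir) -> None:
        """Write qtable.json, bins.json, metrics.csv, records.jsonl, summary.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qlearn.save_qtable(self.qtable, out / "qtable.json",
                           config=self.model.learner)
        self.scheme.save(out / "bins.json")
        self.log.to_csv(out / "metrics.csv", index=False)
        with open(out / "records.jsonl", "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_json_obj()) + "\n")
        summary = {
            "n_steps": int(len(self.log)),
            "seed": int(self.seed),
            "total_reward": float(self.log["reward"].sum()) if len(self.log) else 0.0,
            "final_training_accuracy": (
                float(self.log["running_accuracy"].iloc[-1])
                if len(self.log) else None),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)


# -- functional wrappers ------------------------------------------------------

def run_training(config: "RunConfig") -> HelpReasonerResults:
    """Train a reasoner as specified by a run configuration."""
    config.validate()
    model = HelpReasonerModel.from_config(config)
    return model.fit(n_steps=config.n_train_steps, seed=config.learner.seed)


def evaluate(results: HelpReasonerResults, n_steps: Optional[int] = None,
             seed: Optional[int] = None) -> float:
    """Greedy-policy accuracy of a trained reasoner (convenience wrapper)."""
    n = n_steps if n_steps is not None else 500
    return results.evaluate(n_steps=n, seed=seed).accuracy


def mean_reference_accuracy(
    n_seeds: int = 20,
    n_train_steps: int = 150,
    n_eval_steps: int = 500,
    master_seed: int = 1,
    config: "RunConfig | None" = None,
) -> Tuple[float, List[float]]:
    """Mean greedy accuracy of the reference scenario over several seeds.

    Trains a fresh reasoner per seed on the default (or supplied) scenario,
    evaluates greedily, and returns the mean accuracy together with the
    per-seed values. Per-run seeds are spawned from ``master_seed``.
    """
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(2**31, size=n_seeds)
    accs: List[float] = []
    for s in seeds:
        if config is not None:
            model = HelpReasonerModel.from_config(config)
        else:
            model = HelpReasonerModel()
        res = model.fit(n_steps=n_train_steps, seed=int(s))
        accs.append(res.evaluate(n_steps=n_eval_steps).accuracy)
    return float(np.mean(accs)), accs
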