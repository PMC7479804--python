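"""Action space, user-feedback events, reward function, and step protocol.

The agent observes one discretized window state per time step and takes one
of three actions: do nothing (NOP), trigger a support tool automatically
(HELP), or ask the user via an onscreen dialog (ASK). The user's reaction —
implicit (no reaction within a timeout, manually triggering a tool) or
explicit (accepting/rejecting automatic help, answering the dialog) — maps
to a scalar reward. Failing to help a user who then triggers a tool manually
is penalized heavily (−200); asking always costs a small negative reward so
the agent does not pester the user; dialog answers and manual triggers after
an ASK additionally reveal that HELP was the right call, earning retroactive
credit of +10 assigned to (state, HELP).

The step controller enforces the collect → act → await-feedback → reward
workflow: samples arriving between action emission and feedback resolution
are discarded and never enter the next state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

from .windows import DiscreteState, RawSample

__all__ = [
    "Action",
    "FeedbackEvent",
    "RewardOutcome",
    "StepRecord",
    "InvalidFeedbackError",
    "ProtocolError",
    "reward",
    "resolve_implicit_feedback",
    "StepController",
    "RETRO_REWARD",
]


class Action(Enum):
    NOP = "NOP"
    HELP = "HELP"
    ASK = "ASK"


class FeedbackEvent(Enum):
    NO_REACTION = "NO_REACTION"
    MANUAL_TOOL_TRIGGER = "MANUAL_TOOL_TRIGGER"
    ACCEPT_AUTO_HELP = "ACCEPT_AUTO_HELP"
    REJECT_AUTO_HELP = "REJECT_AUTO_HELP"
    DIALOG_REQUEST_HELP = "DIALOG_REQUEST_HELP"
    DIALOG_REJECT_HELP = "DIALOG_REJECT_HELP"


class InvalidFeedbackError(ValueError):
    """The (action, feedback) pair is not a defined cell of the reward table."""


class ProtocolError(RuntimeError):
    """Step protocol violated (e.g. feedback without a pending action)."""


RETRO_REWARD: float = 10.0


@dataclass(frozen=True)
class RewardOutcome:
    """Primary scalar reward plus optional retroactive credit to (s, HELP)."""

    reward: float
    retro_action: Optional[Action] = None
    retro_reward: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.retro_action is None) != (self.retro_reward is None):
            raise ValueError("retro_action and retro_reward must come together")
        if self.retro_action is not None and self.retro_action is not Action.HELP:
            raise ValueError("retroactive credit only applies to HELP")

    @property
    def has_retro(self) -> bool:
        return self.retro_action is not None


# Defined cells of the reward table; every other (action, feedback) pair is a
# protocol impossibility and raises InvalidFeedbackError.
_REWARD_TABLE: Dict[Tuple[Action, FeedbackEvent], RewardOutcome] = {
    (Action.NOP, FeedbackEvent.NO_REACTION): RewardOutcome(0.0),
    (Action.NOP, FeedbackEvent.MANUAL_TOOL_TRIGGER): RewardOutcome(-200.0),
    (Action.HELP, FeedbackEvent.NO_REACTION): RewardOutcome(10.0),
    (Action.HELP, FeedbackEvent.ACCEPT_AUTO_HELP): RewardOutcome(10.0),
    (Action.HELP, FeedbackEvent.REJECT_AUTO_HELP): RewardOutcome(-20.0),
    (Action.ASK, FeedbackEvent.NO_REACTION): RewardOutcome(-10.0),
    (Action.ASK, FeedbackEvent.MANUAL_TOOL_TRIGGER): RewardOutcome(
        -10.0, Action.HELP, RETRO_REWARD),
    (Action.ASK, FeedbackEvent.DIALOG_REQUEST_HELP): RewardOutcome(
        -10.0, Action.HELP, RETRO_REWARD),
    (Action.ASK, FeedbackEvent.DIALOG_REJECT_HELP): RewardOutcome(-10.0),
}


def reward(action: Action, feedback: FeedbackEvent) -> RewardOutcome:
    """Reward for an (action, user-feedback) pair.

    Raises :class:`InvalidFeedbackError` on undefined combinations (the GUI
    cannot produce them, so they indicate a protocol bug rather than a zero
    reward).
    """
    try:
        return _REWARD_TABLE[(action, feedback)]
    except KeyError:
        raise InvalidFeedbackError(
            f"feedback {feedback.value} is impossible after action {action.value}"
        ) from None


_EXPLICIT_EVENTS = frozenset(FeedbackEvent) - {FeedbackEvent.NO_REACTION}


def resolve_implicit_feedback(
    pending_action: Action,
    events_within_timeout: Iterable[FeedbackEvent],
) -> FeedbackEvent:
    """Resolve observed events into one feedback for the pending action.

    Any explicit event observed before the timeout wins; with none, the user
    "browsed as usual" and the feedback is NO_REACTION. Events that form no
    defined reward cell for the pending action cannot be reactions to it and
    are ignored.
    """
    for ev in events_within_timeout:
        if ev in _EXPLICIT_EVENTS and (pending_action, ev) in _REWARD_TABLE:
            return ev
    return FeedbackEvent.NO_REACTION


@dataclass
class StepRecord:
    """One complete transition: (s_t, a_t, feedback, r_{t+1}, s_{t+1})."""

    state: DiscreteState
    action: Action
    feedback: FeedbackEvent
    outcome: RewardOutcome
    next_state: Optional[DiscreteState]

    def to_json_obj(self) -> dict:
        return {
            "state": list(self.state),
            "action": self.action.value,
            "feedback": self.feedback.value,
            "reward": self.outcome.reward,
            "retro_action": (self.outcome.retro_action.value
                             if self.outcome.has_retro else None),
            "retro_reward": self.outcome.retro_reward,
            "next_state": (None if self.next_state is None
                           else list(self.next_state)),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "StepRecord":
        retro_a = obj.get("retro_action")
        return cls(
            state=tuple(obj["state"]),
            action=Action(obj["action"]),
            feedback=FeedbackEvent(obj["feedback"]),
            outcome=RewardOutcome(
                reward=float(obj["reward"]),
                retro_action=None if retro_a is None else Action(retro_a),
                retro_reward=obj.get("retro_reward"),
            ),
            next_state=(None if obj.get("next_state") is None
                        else tuple(obj["next_state"])),
        )


class StepController:
    """Enforces collect → act → await-feedback → next-state sequencing.

    Samples offered via :meth:`observe` while an action is pending (i.e.
    after :meth:`act`, before :meth:`give_feedback`) are discarded, matching
    the rule that data incoming during processing of s_t never contaminates
    s_{t+1}.
    """

    def __init__(self) -> None:
        self._state: Optional[DiscreteState] = None
        self._action: Optional[Action] = None
        self._outcome: Optional[RewardOutcome] = None
        self._feedback: Optional[FeedbackEvent] = None
        self._collected: List[RawSample] = []
        self.discarded: List[RawSample] = []
        self.records: List[StepRecord] = []

    @property
    def awaiting_feedback(self) -> bool:
        return self._action is not None and self._feedback is None

    def begin(self, state: DiscreteState) -> None:
        if self.awaiting_feedback:
            raise ProtocolError("cannot begin a new state while awaiting feedback")
        self._state = state
        self._collected = []

    def observe(self, sample: RawSample) -> bool:
        """Offer a raw sample; returns True if kept for the next state."""
        if self.awaiting_feedback:
            self.discarded.append(sample)
            return False
        self._collected.append(sample)
        return True

    @property
    def collected(self) -> List[RawSample]:
        return list(self._collected)

    def act(self, action: Action) -> None:
        if self._state is None:
            raise ProtocolError("no pending state to act on")
        if self.awaiting_feedback:
            raise ProtocolError("previous action still awaiting feedback")
        self._action = action
        self._feedback = None

    def give_feedback(self, feedback: FeedbackEvent) -> RewardOutcome:
        if self._action is None:
            raise ProtocolError("feedback delivered with no pending action")
        if self._feedback is not None:
            raise ProtocolError("feedback already consumed for this action")
        self._feedback = feedback
        self._outcome = reward(self._action, feedback)
        return self._outcome

    def advance(self, next_state: Optional[DiscreteState]) -> StepRecord:
        """Close the step with the post-feedback state s_{t+1}."""
        if self._action is None or self._feedback is None:
            raise ProtocolError("cannot advance before action and feedback")
        rec = StepRecord(
            state=self._state,
            action=self._action,
            feedback=self._feedback,
            outcome=self._outcome,
            next_state=next_state,
        )
        self.records.append(rec)
        self._state = next_state
        self._action = None
        self._feedback = None
        self._outcome = None
        self._collected = []
        return rec

    def step(
        self,
        action: Action,
        feedback: FeedbackEvent,
        next_state: Optional[DiscreteState],
    ) -> StepRecord:
        """Convenience: act, resolve feedback, and advance in one call."""
        self.act(action)
        self.give_feedback(feedback)
        return self.advance(next_state)
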