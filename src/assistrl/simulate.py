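"""Synthetic user: latent confusion process, signal emission, and feedback.

Training the reasoner against real devices and subjects is slow (one time
step per two-minute window) and ethically fraught to iterate on, so this
module provides a configurable stand-in: a two-state Markov chain over a
latent CONFUSED/CALM affect, state-conditional emission distributions for
each physiological signal, and a probabilistic feedback model producing the
same implicit/explicit events a real user would.

The confusion state shifts the emissions the way the affective-computing
literature reports for poor comprehension and cognitive load: bursts of
rapid serial blinks (higher blink rate), longer eye fixations, depressed
heart-rate variability and a mildly elevated heart rate. The default
"reference user" is clearly separable — at least two spread-units between
the state means on blink rate and fixation duration — so the learning
problem is solvable within a short training session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .mdp import Action, FeedbackEvent
from .windows import RawSample, WindowConfig

__all__ = [
    "LatentState",
    "Emission",
    "UserModel",
    "latent_step",
    "emit_window",
    "feedback_response",
    "oracle_action",
]


class LatentState(Enum):
    CONFUSED = "CONFUSED"
    CALM = "CALM"


@dataclass(frozen=True)
class Emission:
    """Location/spread of one signal under one latent state."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("spread must be non-negative")


def _default_emissions() -> Dict[str, Dict[LatentState, Emission]]:
    # spreads are between-window (slow autonomic drift); confusion raises
    # fixation duration and heart rate and depresses HRV
    return {
        "hr_bpm": {LatentState.CALM: Emission(70.0, 5.0),
                   LatentState.CONFUSED: Emission(76.0, 5.0)},
        "hrv_ms": {LatentState.CALM: Emission(60.0, 12.0),
                   LatentState.CONFUSED: Emission(45.0, 12.0)},
        "fixation_duration_ms": {LatentState.CALM: Emission(250.0, 50.0),
                                 LatentState.CONFUSED: Emission(360.0, 50.0)},
        "gaze_x_px": {LatentState.CALM: Emission(640.0, 200.0),
                      LatentState.CONFUSED: Emission(640.0, 200.0)},
        "gaze_y_px": {LatentState.CALM: Emission(360.0, 150.0),
                      LatentState.CONFUSED: Emission(360.0, 150.0)},
    }


def _default_blink() -> Dict[LatentState, Emission]:
    # blinks per minute; confused users show rapid serial blink bursts
    return {LatentState.CALM: Emission(6.0, 2.5),
            LatentState.CONFUSED: Emission(13.0, 2.5)}


def _default_p_text() -> Dict[LatentState, float]:
    return {LatentState.CALM: 0.7, LatentState.CONFUSED: 0.7}


@dataclass
class UserModel:
    """Generative model of one synthetic user.

    Probabilities are per 120 s window (latent transitions) or per feedback
    opportunity (behavior). A calm user rejects unneeded automatic help with
    probability ``p_reject_help_ok`` and never requests help in a dialog.
    """

    p_enter: float = 0.15            # CALM -> CONFUSED per window
    p_exit: float = 0.5              # CONFUSED -> CALM per window
    emissions: Dict[str, Dict[LatentState, Emission]] = field(
        default_factory=_default_emissions)
    blink_rate_per_min: Dict[LatentState, Emission] = field(
        default_factory=_default_blink)
    p_text: Dict[LatentState, float] = field(default_factory=_default_p_text)
    p_manual_when_ignored: float = 0.8   # confused, not helped -> manual trigger
    p_accept_help: float = 0.9           # confused -> accepts automatic help
    p_reject_help_ok: float = 0.9        # calm -> rejects unneeded help
    p_dialog_request: float = 0.9        # confused -> answers "help" in dialog
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_enter", "p_exit", "p_manual_when_ignored",
                     "p_accept_help", "p_reject_help_ok", "p_dialog_request"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for st, p in self.p_text.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_text[{st}]={p} outside [0, 1]")

    @property
    def stationary_confused_fraction(self) -> float:
        """Long-run fraction of windows spent confused."""
        if self.p_enter + self.p_exit == 0:
            return 0.0
        return self.p_enter / (self.p_enter + self.p_exit)

    # -- config (de)serialization ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "p_enter": self.p_enter,
            "p_exit": self.p_exit,
            "emissions": {
                feat: {st.value.lower(): {"mean": e.mean, "sd": e.sd}
                       for st, e in per_state.items()}
                for feat, per_state in self.emissions.items()
            },
            "blink_rate_per_min": {
                st.value.lower(): {"mean": e.mean, "sd": e.sd}
                for st, e in self.blink_rate_per_min.items()
            },
            "p_text": {st.value.lower(): p for st, p in self.p_text.items()},
            "p_manual_when_ignored": self.p_manual_when_ignored,
            "p_accept_help": self.p_accept_help,
            "p_reject_help_ok": self.p_reject_help_ok,
            "p_dialog_request": self.p_dialog_request,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "UserModel":
        kwargs: dict = {}
        for key in ("p_enter", "p_exit", "p_manual_when_ignored",
                    "p_accept_help", "p_reject_help_ok", "p_dialog_request",
                    "seed"):
            if key in obj:
                kwargs[key] = obj[key]

        def _per_state(d: Mapping) -> Dict[LatentState, Emission]:
            return {LatentState[k.upper()]: Emission(float(v["mean"]),
                                                     float(v["sd"]))
                    for k, v in d.items()}

        if "emissions" in obj:
            base = _default_emissions()
            for feat, per_state in obj["emissions"].items():
                base[feat] = _per_state(per_state)
            kwargs["emissions"] = base
        if "blink_rate_per_min" in obj:
            kwargs["blink_rate_per_min"] = _per_state(obj["blink_rate_per_min"])
        if "p_text" in obj:
            kwargs["p_text"] = {LatentState[k.upper()]: float(v)
                                for k, v in obj["p_text"].items()}
        return cls(**kwargs)


def latent_step(model: UserModel, current: LatentState,
                rng: np.random.Generator) -> LatentState:
    """Advance the two-state confusion chain by one window."""
    u = rng.random()
    if current is LatentState.CALM:
        return LatentState.CONFUSED if u < model.p_enter else LatentState.CALM
    return LatentState.CALM if u < model.p_exit else LatentState.CONFUSED


def emit_window(
    model: UserModel,
    latent: LatentState,
    t_start: float,
    config: WindowConfig,
    rng: np.random.Generator,
) -> List[RawSample]:
    """Draw one window of raw samples conditioned on the latent state.

    One sample per sub-sample period for each continuous signal and the
    content-type dwell stream. Emission spreads act between windows: each
    window draws a slow "level" for every continuous signal from the state's
    distribution, and sub-samples jitter around that level with half the
    spread (fast measurement noise averages out under aggregation, the slow
    drift does not). Blink events are spread uniformly over the window at a
    per-window rate drawn from the state's blink distribution.
    """
    period = config.sample_period_s
    n = config.n_subsamples
    times = t_start + period * np.arange(n, dtype=float)
    out: List[RawSample] = []

    for feat, per_state in model.emissions.items():
        em = per_state[latent]
        if em.sd > 0:
            level = rng.normal(em.mean, em.sd)
            vals = rng.normal(level, 0.5 * em.sd, size=n)
        else:
            vals = np.full(n, em.mean)
        for t, v in zip(times, vals):
            out.append(RawSample(timestamp=float(t), feature=feat,
                                 value=float(v)))

    em = model.blink_rate_per_min[latent]
    rate = max(0.0, float(rng.normal(em.mean, em.sd))) if em.sd > 0 else em.mean
    per_period = rate * period / 60.0
    for t in times:
        out.append(RawSample(timestamp=float(t), feature="blink_count",
                             value=per_period))

    p_text = model.p_text[latent]
    for t in times:
        ct = "text" if rng.random() < p_text else "image"
        out.append(RawSample(timestamp=float(t), feature="dwell_content_type",
                             value=ct))
    return out


def feedback_response(
    model: UserModel,
    latent: LatentState,
    action: Action,
    rng: np.random.Generator,
) -> FeedbackEvent:
    """Sample the user's feedback to an agent action.

    Every returned event forms a defined cell of the reward table for the
    given action, so the simulated loop can never hit a protocol error.
    """
    confused = latent is LatentState.CONFUSED
    if action is Action.NOP:
        if confused and rng.random() < model.p_manual_when_ignored:
            return FeedbackEvent.MANUAL_TOOL_TRIGGER
        return FeedbackEvent.NO_REACTION
    if action is Action.HELP:
        if confused:
            return (FeedbackEvent.ACCEPT_AUTO_HELP
                    if rng.random() < model.p_accept_help
                    else FeedbackEvent.REJECT_AUTO_HELP)
        return (FeedbackEvent.REJECT_AUTO_HELP
                if rng.random() < model.p_reject_help_ok
                else FeedbackEvent.NO_REACTION)
    # ASK
    if confused:
        return (FeedbackEvent.DIALOG_REQUEST_HELP
                if rng.random() < model.p_dialog_request
                else FeedbackEvent.DIALOG_REJECT_HELP)
    return FeedbackEvent.DIALOG_REJECT_HELP


def oracle_action(latent: LatentState) -> Action:
    """Ground-truth action: HELP a confused user, otherwise do nothing."""
    return Action.HELP if latent is LatentState.CONFUSED else Action.NOP
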