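"""Run configuration: one YAML/JSON file describing a whole experiment.

Sections: ``window`` (window geometry), ``binning`` (discretization),
``learner`` (hyperparameters), ``user_model`` (synthetic user), ``run``
(step counts, seeds, output directory). Every section is optional and
defaults to the reference scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import BinningConfig
from .qlearn import LearnerConfig
from .simulate import UserModel
from .windows import WindowConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    window: WindowConfig = field(default_factory=WindowConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    user_model: UserModel = field(default_factory=UserModel)
    n_train_steps: int = 150
    n_eval_steps: int = 500
    n_seeds: int = 20
    out_dir: Optional[str] = None

    def validate(self) -> "RunConfig":
        if self.n_train_steps < 0:
            raise ConfigError("n_train_steps must be non-negative")
        if self.n_eval_steps <= 0:
            raise ConfigError("n_eval_steps must be positive")
        if self.n_seeds <= 0:
            raise ConfigError("n_seeds must be positive")
        return self

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        try:
            window = WindowConfig(**obj.get("window", {}))
            binning_obj = dict(obj.get("binning", {}))
            if "state_features" in binning_obj:
                binning_obj["state_features"] = tuple(binning_obj["state_features"])
            binning = BinningConfig(**binning_obj)
            learner = LearnerConfig(**obj.get("learner", {}))
            user_model = UserModel.from_dict(obj.get("user_model", {}))
            run = obj.get("run", {})
            return cls(
                window=window, binning=binning, learner=learner,
                user_model=user_model,
                n_train_steps=int(run.get("n_train_steps", 150)),
                n_eval_steps=int(run.get("n_eval_steps", 500)),
                n_seeds=int(run.get("n_seeds", 20)),
                out_dir=run.get("out_dir"),
            ).validate()
        except (TypeError, ValueError, KeyError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".json",):
            obj = json.loads(text)
        else:
            obj = yaml.safe_load(text)
        if obj is None:
            obj = {}
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(obj)
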