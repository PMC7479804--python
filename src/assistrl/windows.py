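"""Windowed aggregation and discretization of raw physiological signals.

Asynchronous per-device samples (heart rate, heart-rate variability, blink
events, eye-fixation duration, gaze coordinates, per-content-type gaze dwell)
are aggregated over fixed tumbling windows into feature batches, then binned
into a small discrete state set suitable for a tabular learner.

Aggregation conventions: continuous physiological features use the arithmetic
mean over the window; blink events are converted to a blinks-per-minute rate;
the content-type dwell stream yields cumulative per-type dwell milliseconds
(one sub-sample period attributed to the type gazed at) and a modal type.
Features with no samples in a window are kept as an explicit missing marker
rather than imputed, so the learner can adapt when a device is absent.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CONTENT_TYPES",
    "CONTINUOUS_FEATURES",
    "BATCH_FEATURES",
    "DEFAULT_STATE_FEATURES",
    "RawSample",
    "WindowConfig",
    "FeatureBatch",
    "BinningScheme",
    "DiscreteState",
    "WindowBoundsError",
    "DegenerateFeatureError",
    "BatchFormatError",
    "aggregate_window",
    "fit_bins",
    "discretize",
    "read_batches",
    "write_batches",
]

CONTENT_TYPES: Tuple[str, ...] = ("text", "image")

#: raw features aggregated by arithmetic mean
CONTINUOUS_FEATURES: Tuple[str, ...] = (
    "hr_bpm",
    "hrv_ms",
    "fixation_duration_ms",
    "gaze_x_px",
    "gaze_y_px",
)

#: keys present in every aggregated batch (blink events become a rate)
BATCH_FEATURES: Tuple[str, ...] = (
    "hr_bpm",
    "hrv_ms",
    "blink_rate_per_min",
    "fixation_duration_ms",
    "gaze_x_px",
    "gaze_y_px",
)

#: features entering the learner's state by default; gaze coordinates feed
#: dwell computation only and are excluded here (configurable).
DEFAULT_STATE_FEATURES: Tuple[str, ...] = (
    "hr_bpm",
    "hrv_ms",
    "blink_rate_per_min",
    "fixation_duration_ms",
)

#: a discrete state is an ordered tuple of per-feature bin indices
DiscreteState = Tuple[int, ...]


class WindowBoundsError(ValueError):
    """A sample's timestamp falls outside the window being aggregated."""


class DegenerateFeatureError(ValueError):
    """A feature has too few distinct values to fit the requested bins."""


class BatchFormatError(ValueError):
    """A batch file record is malformed; message carries the line number."""


@dataclass(frozen=True)
class RawSample:
    """One timestamped reading of one physiological feature.

    ``value`` is a real number, except for ``dwell_content_type`` samples
    where it is a content-type label (``"text"`` or ``"image"``).
    """

    timestamp: float
    feature: str
    value: object
    source: str = "sim"

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp {self.timestamp}")
        if self.feature == "dwell_content_type" and self.value not in CONTENT_TYPES:
            raise ValueError(f"unknown content type {self.value!r}")


@dataclass(frozen=True)
class WindowConfig:
    """Collection timing: 120 s tumbling windows of 12 × 10 s sub-samples.

    ``feedback_timeout_s`` is how long the agent waits for implicit feedback
    after acting; the next window starts only once feedback has resolved, so
    one time step spans ``window_s + feedback_timeout_s`` of session time.
    """

    window_s: int = 120
    sample_period_s: int = 10
    feedback_timeout_s: float = 30.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.sample_period_s <= 0:
            raise ValueError("window_s and sample_period_s must be positive")
        if self.feedback_timeout_s < 0:
            raise ValueError("feedback_timeout_s must be non-negative")
        if self.window_s % self.sample_period_s != 0:
            raise ValueError(
                f"window_s={self.window_s} is not a multiple of "
                f"sample_period_s={self.sample_period_s}"
            )

    @property
    def n_subsamples(self) -> int:
        return self.window_s // self.sample_period_s


@dataclass
class FeatureBatch:
    """One window's aggregated feature values (``None`` marks missing)."""

    t_start: float
    t_end: float
    features: Dict[str, Optional[float]]
    dwell_ms: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct in CONTENT_TYPES:
            self.dwell_ms.setdefault(ct, 0.0)

    @property
    def modal_content_type(self) -> str:
        """Content type gazed at the longest within the window (tie: text)."""
        return max(CONTENT_TYPES, key=lambda ct: (self.dwell_ms.get(ct, 0.0),
                                                  ct == "text"))

    def to_json_obj(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_end": self.t_end,
            "features": {k: self.features.get(k) for k in BATCH_FEATURES},
            "dwell_ms": {ct: self.dwell_ms.get(ct, 0.0) for ct in CONTENT_TYPES},
        }


def aggregate_window(
    samples: Sequence[RawSample],
    config: WindowConfig,
    t_start: float,
) -> FeatureBatch:
    """Aggregate raw samples falling in ``[t_start, t_start + window_s)``.

    Raises :class:`WindowBoundsError` if any sample lies outside the window.
    """
    t_end = t_start + config.window_s
    for s in samples:
        if not (t_start <= s.timestamp < t_end):
            raise WindowBoundsError(
                f"sample at t={s.timestamp} outside window [{t_start}, {t_end})"
            )

    by_feature: Dict[str, List[RawSample]] = {}
    for s in samples:
        by_feature.setdefault(s.feature, []).append(s)

    features: Dict[str, Optional[float]] = {}
    for feat in CONTINUOUS_FEATURES:
        vals = [float(s.value) for s in by_feature.get(feat, [])]
        features[feat] = float(np.mean(vals)) if vals else None

    blink = by_feature.get("blink_count", [])
    if blink:
        total = sum(float(s.value) for s in blink)
        features["blink_rate_per_min"] = total / (config.window_s / 60.0)
    else:
        features["blink_rate_per_min"] = None

    dwell_ms = {ct: 0.0 for ct in CONTENT_TYPES}
    for s in by_feature.get("dwell_content_type", []):
        dwell_ms[str(s.value)] += config.sample_period_s * 1000.0

    return FeatureBatch(t_start=t_start, t_end=t_end, features=features,
                        dwell_ms=dwell_ms)


@dataclass
class BinningScheme:
    """Per-feature bin edges mapping real values to discrete bin indices.

    For a feature with edges ``[e_0, ..., e_n]`` there are ``n`` value bins,
    assigned by the half-open convention ``[e_i, e_{i+1})`` with clamping
    below ``e_0`` and at/above ``e_n``; bin index ``n`` is reserved for
    missing values.
    """

    edges: Dict[str, List[float]]

    @property
    def features(self) -> Tuple[str, ...]:
        return tuple(self.edges)

    def n_bins(self, feature: str) -> int:
        return len(self.edges[feature]) - 1

    def missing_bin(self, feature: str) -> int:
        return self.n_bins(feature)

    def bin_value(self, feature: str, value: Optional[float]) -> int:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.missing_bin(feature)
        interior = self.edges[feature][1:-1]
        return int(np.searchsorted(interior, value, side="right"))

    def to_json_obj(self) -> dict:
        return {f: list(map(float, e)) for f, e in self.edges.items()}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BinningScheme":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(edges={f: [float(x) for x in e] for f, e in obj.items()})


def fit_bins(
    batches: Sequence[FeatureBatch],
    n_bins: int = 4,
    strategy: str = "quantile",
    features: Sequence[str] = DEFAULT_STATE_FEATURES,
) -> BinningScheme:
    """Fit per-feature bin edges from observed batches.

    ``quantile`` equalizes per-bin counts; ``uniform`` equalizes bin widths.
    Each feature needs at least ``n_bins`` distinct non-missing values,
    otherwise :class:`DegenerateFeatureError` is raised naming the feature.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if strategy not in ("quantile", "uniform"):
        raise ValueError(f"unknown binning strategy {strategy!r}")
    if not batches:
        raise DegenerateFeatureError("no batches to fit bins from")

    edges: Dict[str, List[float]] = {}
    for feat in features:
        vals = np.asarray(
            [b.features[feat] for b in batches if b.features.get(feat) is not None],
            dtype=float,
        )
        if len(np.unique(vals)) < max(n_bins, 2):
            raise DegenerateFeatureError(
                f"feature {feat!r} has fewer than {max(n_bins, 2)} distinct values"
            )
        if strategy == "uniform":
            e = np.linspace(vals.min(), vals.max(), n_bins + 1)
        else:
            e = np.quantile(vals, np.linspace(0.0, 1.0, n_bins + 1))
        if np.any(np.diff(e) <= 0):
            raise DegenerateFeatureError(
                f"feature {feat!r} yields non-increasing edges (ties in data)"
            )
        edges[feat] = [float(x) for x in e]
    return BinningScheme(edges=edges)


def discretize(batch: FeatureBatch, scheme: BinningScheme) -> DiscreteState:
    """Map a batch to its discrete state tuple; total and deterministic."""
    return tuple(
        scheme.bin_value(f, batch.features.get(f)) for f in scheme.features
    )


def write_batches(batches: Iterable[FeatureBatch], path) -> None:
    """Write batches as JSON-lines, one window object per line."""
    with open(path, "w") as fh:
        for b in batches:
            fh.write(json.dumps(b.to_json_obj()) + "\n")


def read_batches(path) -> List[FeatureBatch]:
    """Read a JSON-lines batch file; malformed records raise with line number."""
    out: List[FeatureBatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise BatchFormatError(f"line {lineno}: invalid JSON ({exc})")
            try:
                feats = obj["features"]
                batch = FeatureBatch(
                    t_start=float(obj["t_start"]),
                    t_end=float(obj["t_end"]),
                    features={
                        k: (None if feats.get(k) is None else float(feats[k]))
                        for k in BATCH_FEATURES
                    },
                    dwell_ms={
                        ct: float(obj.get("dwell_ms", {}).get(ct, 0.0))
                        for ct in CONTENT_TYPES
                    },
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise BatchFormatError(f"line {lineno}: bad record ({exc})")
            out.append(batch)
    return out
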