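"""Session timeline: Baseline / Task / Recovery phases and stimulus windows.

A session consists of a seated baseline, an odor-presentation task in which
``n_stimuli`` model solutions are each smelled for ``stimulus_s`` seconds with
an inter-stimulus pause of ``isi_s`` seconds, and a recovery phase. All
windows are half-open ``[start, end)`` in seconds from record start; the
pause after the last stimulus is counted as part of the task, so with the
default 10 stimuli x (10 s + 30 s) the task spans exactly 400 s (6'40'').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

#: Descriptors of the ten odorous model solutions presented during the task.
DEFAULT_STIMULUS_LABELS: tuple[str, ...] = (
    "Raspberry",
    "Grapefruit",
    "Orange",
    "Pineapple",
    "Fig",
    "Asparagus",
    "Peach",
    "Green pepper",
    "Mango",
    "Rose",
)

PHASES: tuple[str, str, str] = ("Baseline", "Task", "Recovery")


@dataclass(frozen=True)
class StimulusWindow:
    """One odor-presentation window inside the task phase."""

    index: int  # 1-based
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SessionProtocol:
    """Phase boundaries and stimulus onsets of one recording session.

    Defaults encode the study protocol: 180 s baseline, 10 stimuli of 10 s
    at a 30 s inter-stimulus interval (task 400 s), 180 s recovery.
    """

    baseline_s: float = 180.0
    n_stimuli: int = 10
    stimulus_s: float = 10.0
    isi_s: float = 30.0
    recovery_s: float = 180.0
    labels: tuple[str, ...] = field(default=DEFAULT_STIMULUS_LABELS)

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.recovery_s <= 0 or self.stimulus_s <= 0:
            raise ConfigurationError("phase and stimulus durations must be positive")
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")
        if self.isi_s < 0:
            raise ConfigurationError(
                "negative inter-stimulus interval makes stimulus windows overlap"
            )
        labels = tuple(self.labels)[: self.n_stimuli]
        if len(labels) < self.n_stimuli:
            labels = labels + tuple(
                f"stimulus-{i}" for i in range(len(labels) + 1, self.n_stimuli + 1)
            )
        object.__setattr__(self, "labels", labels)

    # -- timeline arithmetic -------------------------------------------------

    @property
    def task_s(self) -> float:
        """Task span: n stimuli, each followed by its pause."""
        return self.n_stimuli * (self.stimulus_s + self.isi_s)

    @property
    def task_start(self) -> float:
        return self.baseline_s

    @property
    def task_end(self) -> float:
        return self.baseline_s + self.task_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.task_s + self.recovery_s

    @property
    def stimulus_onsets(self) -> np.ndarray:
        i = np.arange(self.n_stimuli)
        return self.task_start + i * (self.stimulus_s + self.isi_s)

    def stimulus_windows(self, extension_s: float = 0.0) -> list[StimulusWindow]:
        """Per-stimulus windows, optionally extended past stimulus offset.

        ``extension_s`` accommodates response latency (electrodermal
        responses lag their stimulus by 1-3 s); it may not exceed the
        inter-stimulus interval, which would make windows overlap.
        """
        if extension_s < 0 or extension_s > self.isi_s:
            raise ConfigurationError(
                f"window extension {extension_s} s must lie in [0, isi_s={self.isi_s}]"
            )
        return [
            StimulusWindow(
                index=i + 1,
                start=float(onset),
                end=float(onset + self.stimulus_s + extension_s),
                label=self.labels[i],
            )
            for i, onset in enumerate(self.stimulus_onsets)
        ]

    def phase_spans(self) -> dict[str, tuple[float, float]]:
        return {
            "Baseline": (0.0, self.baseline_s),
            "Task": (self.task_start, self.task_end),
            "Recovery": (self.task_end, self.total_s),
        }

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "baseline_s": self.baseline_s,
            "task": {
                "n_stimuli": self.n_stimuli,
                "stimulus_s": self.stimulus_s,
                "isi_s": self.isi_s,
                "labels": list(self.labels),
            },
            "recovery_s": self.recovery_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionProtocol":
        try:
            task = d["task"]
            return cls(
                baseline_s=float(d["baseline_s"]),
                n_stimuli=int(task["n_stimuli"]),
                stimulus_s=float(task["stimulus_s"]),
                isi_s=float(task["isi_s"]),
                recovery_s=float(d["recovery_s"]),
                labels=tuple(task.get("labels", DEFAULT_STIMULUS_LABELS)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid protocol description: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_protocol(**kwargs) -> SessionProtocol:
    """Construct and validate a :class:`SessionProtocol` from keyword parameters."""
    return SessionProtocol(**kwargs)


def phase_windows(
    protocol: SessionProtocol, extension_s: float = 0.0
) -> tuple[dict[str, tuple[float, float]], list[StimulusWindow]]:
    """Whole-phase spans plus the per-stimulus windows of the task."""
    return protocol.phase_spans(), protocol.stimulus_windows(extension_s)


def average_over_stimuli(
    per_window_features: Sequence[Mapping[str, float]],
) -> tuple[dict[str, float], dict[str, int]]:
    """Arithmetic mean per feature over stimulus windows, skipping missing values.

    Missing values are NaN (or absent keys). Returns the per-feature means
    and the count of windows that contributed to each; a feature missing in
    every window is absent from the output.
    """
    if not per_window_features:
        raise ConfigurationError("average_over_stimuli needs at least one window")
    names: list[str] = []
    for w in per_window_features:
        for k in w:
            if k not in names:
                names.append(k)
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name in names:
        vals = [
            float(w[name])
            for w in per_window_features
            if name in w and np.isfinite(w[name])
        ]
        if vals:
            means[name] = float(np.mean(vals))
            counts[name] = len(vals)
    return means, counts
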