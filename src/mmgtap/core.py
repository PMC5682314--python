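"""Domain types shared across the pipeline.

A :class:`Recording` carries multi-channel acceleration samples at a fixed
sampling rate; an :class:`EventTable` carries tapping intervals, detected or
annotated.  Sample indexing is 0-based throughout and intervals are half-open
``[start, end)``; time is carried in samples internally and converted to
seconds only at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["GestureLabel", "Recording", "Event", "EventTable", "GESTURES"]


class GestureLabel(enum.IntEnum):
    """The five finger-tap gestures, ordered thumb to little finger."""

    thumb = 0
    index = 1
    middle = 2
    ring = 3
    little = 4

    @classmethod
    def from_name(cls, name: str) -> "GestureLabel":
        try:
            return cls[name.strip().lower()]
        except KeyError:
            valid = ", ".join(g.name for g in cls)
            raise ValueError(
                f"unknown gesture label {name!r}; valid labels are: {valid}"
            ) from None


GESTURES: tuple[GestureLabel, ...] = tuple(GestureLabel)


@dataclass
class Recording:
    """A uniformly sampled multi-channel MMG recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, acceleration in arbitrary
        units.
    sampling_rate
        Samples per second [Hz]; must be positive.
    subject_id
        Opaque identifier of the recorded subject.
    baseline_interval
        ``(T_s1, T_s2)`` sample indices of a known rest period used to
        calibrate detector thresholds, or ``None`` if unknown.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = "unknown"
    baseline_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.baseline_interval is not None:
            t1, t2 = self.baseline_interval
            if not (0 <= t1 < t2 <= self.n_samples):
                raise ValueError(
                    f"baseline_interval {self.baseline_interval} outside "
                    f"[0, {self.n_samples}]"
                )
            self.baseline_interval = (int(t1), int(t2))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True, order=True)
class Event:
    """One tapping interval ``[start, end)`` in sample indices.

    ``channel_scope`` is ``None`` for events spanning all channels, or a
    channel index for single-channel events.
    """

    start: int
    end: int
    label: Optional[GestureLabel] = field(default=None, compare=False)
    channel_scope: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"event start {self.start} must be < end {self.end}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> int:
        return self.end - self.start


class EventTable:
    """A validated, start-sorted sequence of :class:`Event` rows.

    Rows sharing a ``channel_scope`` must not overlap.
    """

    def __init__(self, events: Sequence[Event]):
        self._events = tuple(sorted(events, key=lambda e: (e.start, e.end)))
        by_scope: dict[Optional[int], Event] = {}
        for ev in self._events:
            prev = by_scope.get(ev.channel_scope)
            if prev is not None and ev.start < prev.end:
                raise ValueError(
                    f"overlapping events [{prev.start},{prev.end}) and "
                    f"[{ev.start},{ev.end}) in channel scope {ev.channel_scope}"
                )
            by_scope[ev.channel_scope] = ev

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i: int) -> Event:
        return self._events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self._events == other._events and [e.label for e in self] == [
            e.label for e in other
        ]

    def __repr__(self) -> str:
        return f"EventTable({len(self)} events)"

    @property
    def starts(self) -> np.ndarray:
        return np.array([e.start for e in self._events], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([e.end for e in self._events], dtype=np.int64)

    @property
    def labels(self) -> list[Optional[GestureLabel]]:
        return [e.label for e in self._events]

    def midpoints(self) -> np.ndarray:
        return np.array([e.midpoint for e in self._events], dtype=np.float64)
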