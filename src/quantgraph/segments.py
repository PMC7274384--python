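"""Containers for EEG segments and cohorts.

A *segment* is one channel's samples for one subject under one recording
condition.  A *cohort* is the collection of segments for a study: groups
(e.g. healthy controls vs patients, eyes open vs closed) x subjects x
channels, each of fixed length ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system used here.
#: F/C/P/O/T denote frontal, central, parietal, occipital and temporal lobes.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T3", "T4",
    "Pz", "P3", "P4", "T5", "T6",
    "O1", "O2",
)


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class TimeSeriesSegment:
    """A univariate time-series segment with cohort metadata.

    Parameters
    ----------
    values
        The samples, in signal units (e.g. microvolts).  Must be finite and
        contain at least two samples.
    sampling_rate
        Samples per second; EEG segments here default to 128 Hz.
    channel
        Electrode label (10-20 system) or any user-defined channel name.
    group
        Cohort group label, e.g. ``"A"``/``"B"`` (controls, eyes open/closed)
        and ``"C"``/``"D"`` (patients, eyes open/closed).
    subject_id
        Identifier of the recorded subject within its group.
    """

    values: np.ndarray
    sampling_rate: float = 128.0
    channel: str = "F7"
    group: str = "A"
    subject_id: str = "s01"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError("segment values must be one-dimensional")
        if arr.size < 2:
            raise InvalidInputError("segment must contain at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("segment values must all be finite")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def T(self) -> int:
        """Number of samples."""
        return int(self.values.size)

    def with_values(self, values: Sequence[float]) -> "TimeSeriesSegment":
        """Copy of this segment with replaced samples (metadata kept)."""
        return TimeSeriesSegment(
            values=np.asarray(values, dtype=float),
            sampling_rate=self.sampling_rate,
            channel=self.channel,
            group=self.group,
            subject_id=self.subject_id,
        )


@dataclass
class Cohort:
    """A flat collection of segments with group/channel/subject lookup."""

    segments: list[TimeSeriesSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def add(self, segment: TimeSeriesSegment) -> None:
        self.segments.append(segment)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.group)
        return tuple(seen)

    @property
    def channels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.channel)
        return tuple(seen)

    def subjects(self, group: str) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            if s.group == group:
                seen.setdefault(s.subject_id)
        return tuple(seen)

    def select(
        self,
        group: str | None = None,
        channel: str | None = None,
        subject_id: str | None = None,
    ) -> list[TimeSeriesSegment]:
        """Segments matching all given criteria, in insertion order."""
        out = []
        for s in self.segments:
            if group is not None and s.group != group:
                continue
            if channel is not None and s.channel != channel:
                continue
            if subject_id is not None and s.subject_id != subject_id:
                continue
            out.append(s)
        return out

    def common_length(self) -> int:
        """The shared segment length T, or raise listing the offenders."""
        if not self.segments:
            raise InvalidInputError("cohort is empty")
        lengths = {s.T for s in self.segments}
        if len(lengths) > 1:
            offenders = sorted(
                {(s.group, s.subject_id, s.channel, s.T) for s in self.segments},
                key=lambda r: r[3],
            )
            raise InvalidInputError(
                "segments have unequal lengths; offenders (group, subject, "
                f"channel, T): {offenders[:10]}"
            )
        return lengths.pop()


def make_cohort(segments: Iterable[TimeSeriesSegment]) -> Cohort:
    return Cohort(list(segments))
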