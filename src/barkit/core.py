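"""Core domain types shared across the pipeline.

The segmentation hierarchy is: *element* (a continuous sound bounded by
silence) -> *call* (elements separated by gaps below the bout-derived
threshold) -> *bout* (an extended calling sequence from one male).

Time convention: element labels are in seconds over half-open intervals
``[onset, offset)``; inter-element gaps and call durations are reported in
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Waveform",
    "ElementLabel",
    "CallRecord",
    "ELEMENT_TYPES",
    "BarkitError",
    "TooShortError",
    "NoBreakpointError",
]

#: Recognised element types: first exhalation, within-call exhalation,
#: inhalation, and not-yet-typed.
ELEMENT_TYPES = ("Ex1", "Ex2", "Inhal", "unknown")


class BarkitError(Exception):
    """Base class for pipeline errors."""


class TooShortError(BarkitError):
    """Raised when a waveform is shorter than one analysis frame."""


class NoBreakpointError(BarkitError):
    """Raised when a log-survivor curve has no defensible slope break,
    i.e. the interval distribution is unimodal and no intra/inter-call
    threshold can be estimated."""


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio.

    Parameters
    ----------
    samples : float array, shape (n,)
        Amplitude values (any consistent linear scale).
    rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(
                f"waveform must be mono (1-D); got shape {samples.shape}"
            )
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    def slice(self, onset: float, offset: float) -> "Waveform":
        """Extract ``[onset, offset)`` seconds as a new waveform."""
        i0 = max(0, int(round(onset * self.rate)))
        i1 = min(len(self.samples), int(round(offset * self.rate)))
        return Waveform(self.samples[i0:i1], self.rate)


@dataclass(frozen=True)
class ElementLabel:
    """One continuous-sound unit: ``[onset, offset)`` in seconds."""

    onset: float
    offset: float
    type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if self.type not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {self.type!r}")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


def validate_labels(labels: list[ElementLabel]) -> None:
    """Check that labels are time-ordered and non-overlapping."""
    for a, b in zip(labels, labels[1:]):
        if b.onset < a.offset:
            raise ValueError(
                f"labels overlap or are out of order: "
                f"[{a.onset}, {a.offset}) then [{b.onset}, {b.offset})"
            )


@dataclass
class CallRecord:
    """A call: one or more elements grouped by the gap threshold.

    ``duration_ms`` runs from the first element's onset to the last
    element's offset; ``ex1_duration_ms`` is the duration of the first
    exhalation element (the unit all spectral analysis is performed on).
    """

    elements: list[ElementLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a call must contain at least one element")
        validate_labels(self.elements)

    @property
    def onset(self) -> float:
        return self.elements[0].onset

    @property
    def offset(self) -> float:
        return self.elements[-1].offset

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0

    @property
    def element_number(self) -> int:
        return len(self.elements)

    @property
    def ex1(self) -> ElementLabel:
        """The first exhalation element."""
        for el in self.elements:
            if el.type in ("Ex1", "unknown"):
                return el
        raise ValueError("call has no exhalation (Ex1) element")

    @property
    def ex1_duration_ms(self) -> float:
        return self.ex1.duration_ms
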