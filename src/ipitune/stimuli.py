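"""Acoustic stimulus descriptions for the imaging arm.

Pulse songs are trains of 20 near-impulsive pulses separated by a fixed
inter-pulse interval (IPI); the tested IPIs run from 15 to 105 ms in 10-ms
steps.  Pure tones (100-300 Hz, 3 s) probe frequency tuning.  Pulse widths
are far below the IPIs and the 100-ms frame exposure, so pulses are treated
as impulses and a pulse song's duration is n_pulses * IPI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusSpec",
    "DEFAULT_IPIS_MS",
    "PULSE_FIT_WINDOWS",
    "TONE_FIT_WINDOWS",
    "default_pulse_stimuli",
]

#: IPIs (ms) of the standard pulse-song stimulus set.
DEFAULT_IPIS_MS = tuple(float(v) for v in range(15, 106, 10))

#: quiet windows (s from trace start) used for the photobleaching fit.
PULSE_FIT_WINDOWS = ((0.0, 1.0), (4.0, 5.0))
TONE_FIT_WINDOWS = ((0.0, 2.0), (13.0, 15.0))

#: trace lengths (s) that leave the bleach-fit windows inside the trace.
PULSE_TRACE_DURATION_S = 6.0
TONE_TRACE_DURATION_S = 16.0


@dataclass(frozen=True)
class StimulusSpec:
    """One acoustic stimulus: a pulse song (by IPI) or a pure tone."""

    kind: str  # "pulse_song" | "pure_tone"
    onset_s: float = 1.0
    ipi_ms: float | None = None
    n_pulses: int = 20
    ipf_hz: float | None = None
    tone_hz: float | None = None
    tone_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("pulse_song", "pure_tone"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "pulse_song":
            if self.ipi_ms is None or self.ipi_ms <= 0:
                raise ValueError("pulse_song requires a positive ipi_ms")
            if self.n_pulses < 1:
                raise ValueError("n_pulses must be >= 1")
        else:
            if self.tone_hz is None or self.tone_hz <= 0:
                raise ValueError("pure_tone requires a positive tone_hz")
        if self.onset_s < 1.0:
            raise ValueError("stimulus onset must leave >= 1 s of baseline")

    @property
    def duration_s(self) -> float:
        if self.kind == "pulse_song":
            return self.n_pulses * self.ipi_ms / 1000.0
        return self.tone_duration_s

    @property
    def label(self) -> str:
        if self.kind == "pulse_song":
            return f"pulse_ipi{self.ipi_ms:g}ms"
        return f"tone_{self.tone_hz:g}Hz"

    @property
    def trace_duration_s(self) -> float:
        return PULSE_TRACE_DURATION_S if self.kind == "pulse_song" else TONE_TRACE_DURATION_S

    @classmethod
    def from_row(cls, row) -> "StimulusSpec":
        """Rebuild a spec from a stimulus-table row (NaN = absent)."""

        def get(name, default=None):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return default
            return v

        kind = row.kind
        if kind == "pulse_song":
            return cls(
                kind=kind,
                onset_s=float(get("onset_s", 1.0)),
                ipi_ms=float(row.ipi_ms),
                n_pulses=int(get("n_pulses", 20)),
                ipf_hz=get("ipf_hz"),
            )
        return cls(
            kind=kind,
            onset_s=float(get("onset_s", 2.0)),
            tone_hz=float(row.tone_hz),
            tone_duration_s=float(get("tone_duration_s", 3.0)),
        )


def default_pulse_stimuli(ipis_ms=DEFAULT_IPIS_MS, n_pulses: int = 20, onset_s: float = 1.0):
    """The standard ten-IPI pulse-song stimulus set."""
    return [
        StimulusSpec(kind="pulse_song", ipi_ms=float(ipi), n_pulses=n_pulses, onset_s=onset_s)
        for ipi in ipis_ms
    ]
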