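"""Calcium-trace processing: from raw ROI fluorescence to IPI tuning curves.

The chain mirrors a standard GCaMP analysis of auditory responses sampled at
10 frames/s:

1. three-frame centered moving average (:func:`moving_average`);
2. photobleaching removal by a linear fit over two quiet windows,
   re-centered so the pre-stimulus baseline level is preserved
   (:func:`bleach_correct`);
3. dF/F = (F - F_base) / F_base with F_base the mean corrected fluorescence
   over the second before stimulus onset (:func:`compute_dff`);
4. peak extraction over the stimulus period (:func:`peak_response`),
   trial averaging (:func:`aggregate_trials`) and normalization by the sum
   of the peaks over all tested IPIs (:func:`normalize_peaks`).

Frames are timestamped at frame start; all windows are half-open
``[start, end)`` in seconds relative to trace start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSpec, DEFAULT_IPIS_MS, PULSE_FIT_WINDOWS, TONE_FIT_WINDOWS

__all__ = [
    "FluorescenceTrace",
    "ProcessedTrace",
    "TuningCurve",
    "moving_average",
    "bleach_correct",
    "compute_dff",
    "peak_response",
    "aggregate_trials",
    "normalize_peaks",
    "delta_responses",
    "process_trace",
    "process_dataset",
]

#: extra time (s) past the nominal stimulus end kept in the peak-search
#: window, absorbing the calcium-indicator lag for pulse trains.
PEAK_GRACE_S = 0.5

#: IPI (ms) used as the reference when computing response drops.
REFERENCE_IPI_MS = 25.0


@dataclass(frozen=True)
class FluorescenceTrace:
    """One ROI-mean fluorescence time series plus its stimulus metadata."""

    values: np.ndarray
    stim: StimulusSpec
    individual_id: str
    species: str
    trial: int = 0
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite fluorescence in trace {self.individual_id!r}")
        if self.onset_index < self.frame_rate_hz:
            raise ValueError(
                f"trace {self.individual_id!r} has <1 s of pre-stimulus baseline"
            )

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate_hz

    @property
    def onset_index(self) -> int:
        return int(round(self.stim.onset_s * self.frame_rate_hz))


@dataclass(frozen=True)
class ProcessedTrace:
    """dF/F series derived from one trace."""

    dff: np.ndarray
    f_base: float
    correction_windows: tuple[tuple[float, float], ...]
    trace: FluorescenceTrace

    def __post_init__(self) -> None:
        if self.f_base <= 0:
            raise ValueError("f_base must be positive")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("non-finite dF/F")


@dataclass(frozen=True)
class TuningCurve:
    """Per-individual normalized peak responses at the tested IPIs."""

    individual_id: str
    species: str
    ipis_ms: np.ndarray
    normalized_peaks: np.ndarray
    raw_peaks: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        ipis = np.asarray(self.ipis_ms, dtype=float)
        norm = np.asarray(self.normalized_peaks, dtype=float)
        object.__setattr__(self, "ipis_ms", ipis)
        object.__setattr__(self, "normalized_peaks", norm)
        if self.raw_peaks is not None:
            object.__setattr__(self, "raw_peaks", np.asarray(self.raw_peaks, dtype=float))
        if ipis.size != norm.size:
            raise ValueError("ipis_ms and normalized_peaks differ in length")
        if not np.all(np.diff(ipis) > 0):
            raise ValueError("ipis_ms must be strictly increasing")
        if abs(norm.sum() - 1.0) > 1e-9:
            raise ValueError(f"normalized peaks sum to {norm.sum():.12f}, expected 1")


def moving_average(values, window: int = 3) -> np.ndarray:
    """Centered moving mean with shrunken windows at the edges.

    At the boundaries the mean is taken over the frames that exist (no
    padding is invented), so the output has the same length as the input.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if values.size < window:
        raise ValueError(f"series of length {values.size} shorter than window {window}")
    if window == 1:
        return values.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(values.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, values.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _window_mask(times: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for start, end in windows:
        mask |= (times >= start) & (times < end)
    return mask


def bleach_correct(trace: FluorescenceTrace, windows=None, values=None) -> np.ndarray:
    """Remove the linear photobleaching trend, preserving baseline level.

    An ordinary least-squares line is fitted to the frames whose times fall
    in the union of ``windows`` (defaults to the stimulus-kind-specific quiet
    windows).  The returned series is

        raw - (line(t) - mean of line over the pre-onset baseline second)

    i.e. the fitted trend is removed but the series keeps its absolute
    pre-stimulus level, so the downstream dF/F denominator stays positive.

    ``values`` optionally substitutes a pre-smoothed series for the trace's
    raw values.
    """
    raw = np.asarray(values, dtype=float) if values is not None else trace.values
    if windows is None:
        windows = PULSE_FIT_WINDOWS if trace.stim.kind == "pulse_song" else TONE_FIT_WINDOWS
    times = trace.times_s
    mask = _window_mask(times, windows)
    if mask.sum() < 2:
        raise ValueError("bleach-correction windows contain fewer than 2 frames")
    t_fit = times[mask]
    if np.ptp(t_fit) == 0:
        raise ValueError("degenerate bleach fit: all window times identical")
    slope, intercept = np.polyfit(t_fit, raw[mask], 1)
    line = intercept + slope * times
    base_mask = _baseline_mask(trace)
    return raw - (line - line[base_mask].mean())


def _baseline_mask(trace: FluorescenceTrace) -> np.ndarray:
    times = trace.times_s
    onset = trace.stim.onset_s
    return (times >= onset - 1.0) & (times < onset)


def compute_dff(corrected, trace: FluorescenceTrace, windows=None) -> ProcessedTrace:
    """dF/F of a bleach-corrected series.

    F_base is the mean of the corrected fluorescence over the 1 s before
    stimulus onset; dF/F = (F - F_base) / F_base elementwise.
    """
    corrected = np.asarray(corrected, dtype=float)
    base = corrected[_baseline_mask(trace)]
    if base.size < trace.frame_rate_hz:
        raise ValueError("fewer than 1 s of frames before stimulus onset")
    f_base = base.mean()
    if f_base <= 0:
        raise ValueError(
            f"non-positive baseline fluorescence ({f_base:.4g}) in trace "
            f"{trace.individual_id!r} trial {trace.trial}, stimulus {trace.stim.label}"
        )
    dff = (corrected - f_base) / f_base
    if windows is None:
        windows = PULSE_FIT_WINDOWS if trace.stim.kind == "pulse_song" else TONE_FIT_WINDOWS
    return ProcessedTrace(dff=dff, f_base=f_base, correction_windows=tuple(windows), trace=trace)


def peak_response(proc: ProcessedTrace) -> float:
    """Highest dF/F during the stimulus period.

    The period runs from stimulus onset to onset + duration, extended by
    ``PEAK_GRACE_S`` for pulse trains to absorb indicator lag (pure tones use
    their nominal 3 s duration as-is).
    """
    trace = proc.trace
    stim = trace.stim
    grace = PEAK_GRACE_S if stim.kind == "pulse_song" else 0.0
    times = trace.times_s
    mask = (times >= stim.onset_s) & (times < stim.onset_s + stim.duration_s + grace)
    if not mask.any():
        raise ValueError("empty stimulus period")
    return float(proc.dff[mask].max())


def aggregate_trials(peaks_by_trial: dict) -> dict:
    """Mean of per-trial peak responses for each stimulus IPI."""
    missing = [ipi for ipi, peaks in peaks_by_trial.items() if len(peaks) == 0]
    if missing:
        raise ValueError(f"no trials for IPIs: {sorted(missing)}")
    return {ipi: float(np.mean(peaks)) for ipi, peaks in peaks_by_trial.items()}


def normalize_peaks(raw_peaks, ipis_ms, individual_id: str = "", species: str = "") -> TuningCurve:
    """Normalize peak responses by their sum over the tested IPIs."""
    raw = np.asarray(raw_peaks, dtype=float)
    ipis = np.asarray(ipis_ms, dtype=float)
    order = np.argsort(ipis)
    raw, ipis = raw[order], ipis[order]
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"sum of peak responses is {total:.4g}; cannot normalize")
    return TuningCurve(
        individual_id=individual_id,
        species=species,
        ipis_ms=ipis,
        normalized_peaks=raw / total,
        raw_peaks=raw,
    )


def delta_responses(curve: TuningCurve, reference_ipi_ms: float = REFERENCE_IPI_MS) -> pd.DataFrame:
    """Response drops from the reference IPI to every other tested IPI.

    delta(ipi) = normalized_peak(reference) - normalized_peak(ipi).
    """
    ipis = curve.ipis_ms
    at_ref = np.isclose(ipis, reference_ipi_ms)
    if not at_ref.any():
        raise ValueError(f"reference IPI {reference_ipi_ms} ms not among {ipis.tolist()}")
    ref_val = float(curve.normalized_peaks[at_ref][0])
    others = ~at_ref
    return pd.DataFrame(
        {
            "individual_id": curve.individual_id,
            "species": curve.species,
            "ipi_ms": ipis[others],
            "delta_response": ref_val - curve.normalized_peaks[others],
        }
    )


def process_trace(trace: FluorescenceTrace, windows=None, smooth_window: int = 3) -> ProcessedTrace:
    """Run smoothing, bleach correction and dF/F on one trace."""
    smoothed = moving_average(trace.values, smooth_window)
    corrected = bleach_correct(trace, windows=windows, values=smoothed)
    return compute_dff(corrected, trace, windows=windows)


def process_dataset(
    traces_df: pd.DataFrame,
    stim_df: pd.DataFrame,
    expected_ipis=DEFAULT_IPIS_MS,
    smooth_window: int = 3,
) -> list[TuningCurve]:
    """Long-format trace table + stimulus table -> per-individual tuning curves.

    ``traces_df`` columns: individual_id, species, trial, stimulus_id,
    frame_index, fluorescence.  ``stim_df`` is the stimulus table as written
    by the synthetic-data module (one row per stimulus_id).
    """
    stims = {row.stimulus_id: StimulusSpec.from_row(row) for row in stim_df.itertuples()}
    curves = []
    for (ind, species), group in traces_df.groupby(["individual_id", "species"], sort=True):
        peaks_by_ipi: dict[float, list[float]] = {}
        for (stim_id, trial), tgroup in group.groupby(["stimulus_id", "trial"]):
            stim = stims[stim_id]
            if stim.kind != "pulse_song":
                continue
            tgroup = tgroup.sort_values("frame_index")
            trace = FluorescenceTrace(
                values=tgroup["fluorescence"].to_numpy(),
                stim=stim,
                individual_id=str(ind),
                species=str(species),
                trial=int(trial),
            )
            proc = process_trace(trace, smooth_window=smooth_window)
            peaks_by_ipi.setdefault(stim.ipi_ms, []).append(peak_response(proc))
        expected = set(float(v) for v in expected_ipis)
        missing = expected - set(peaks_by_ipi)
        if missing:
            raise ValueError(
                f"individual {ind!r} lacks pulse stimuli at IPIs {sorted(missing)}"
            )
        agg = aggregate_trials(peaks_by_ipi)
        ipis = sorted(agg)
        curves.append(
            normalize_peaks(
                [agg[i] for i in ipis], ipis, individual_id=str(ind), species=str(species)
            )
        )
    return curves


def curves_to_frame(curves) -> pd.DataFrame:
    """Tidy CSV-ready table of tuning curves."""
    rows = []
    for c in curves:
        raw = c.raw_peaks if c.raw_peaks is not None else np.full_like(c.ipis_ms, np.nan)
        for ipi, norm, r in zip(c.ipis_ms, c.normalized_peaks, raw):
            rows.append((c.individual_id, c.species, ipi, r, norm))
    return pd.DataFrame(
        rows, columns=["individual_id", "species", "ipi_ms", "raw_peak", "normalized_peak"]
    )
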