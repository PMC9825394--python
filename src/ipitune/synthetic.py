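"""Synthetic imaging and behavioural data with the structure the analysis assumes.

Every downstream stage (trace processing, hierarchical tuning fit, group
statistics, survival analysis) can be exercised without external recordings:

* individual tuning parameters are drawn log-normally around species means
  (:func:`sample_individual_params`), with the default means and spreads
  calibrated to published per-individual estimates;
* ROI-mean fluorescence traces are a linearly bleaching baseline plus a
  GCaMP-like double-exponential transient scaled by the individual's
  normalized tuning value at the stimulus IPI, plus Gaussian noise
  (:func:`simulate_trace`);
* copulation assays draw exponential event times under species-by-IPI
  constant hazards with administrative censoring at the observation limit
  (:func:`simulate_copulation_records`).

All functions are pure in (inputs, seed).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .stimuli import DEFAULT_IPIS_MS, StimulusSpec, default_pulse_stimuli
from .traces import FluorescenceTrace, TuningCurve
from .tuning import TuningParams, tuning_value

__all__ = [
    "SpeciesProfile",
    "BehaviorProfile",
    "load_default_profiles",
    "sample_individual_params",
    "simulate_trace",
    "simulate_tuning_curves",
    "simulate_imaging_dataset",
    "simulate_copulation_records",
    "records_to_frame",
]

PARAM_NAMES = ("a", "tau_b", "c", "tau_d")

#: GCaMP-like indicator kernel time constants (s): fast rise, slow decay.
#: The indicator itself is not modelled in the source analyses; these values
#: put the transient peak ~0.26 s after onset, inside every stimulus window
#: at 10 frames/s.
KERNEL_RISE_S = 0.1
KERNEL_DECAY_S = 1.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative description of one species' imaging cohort."""

    species_label: str
    param_means: tuple[float, float, float, float]
    param_cv: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    trace_noise_sd: float = 0.5
    bleach_slope_range: tuple[float, float] = (-0.5, -0.1)
    baseline_f0: float = 100.0
    response_gain: float = 400.0

    def __post_init__(self) -> None:
        a, tau_b, c, tau_d = self.param_means
        if min(self.param_means) <= 0:
            raise ValueError("param_means must be positive")
        if tau_b <= tau_d:
            raise ValueError("mean tau_b must exceed mean tau_d")
        if c * tau_b <= a * tau_d:
            raise ValueError("profile means admit no interior tuning peak")
        if min(self.param_cv) < 0:
            raise ValueError("param_cv must be non-negative")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")

    @property
    def mean_params(self) -> TuningParams:
        return TuningParams(*self.param_means)


@dataclass(frozen=True)
class BehaviorProfile:
    """Constant copulation hazards per (species, stimulus IPI) cell."""

    hazard_per_min: dict
    observation_limit_min: float = 35.0
    n_pairs_per_cell: int = 45

    def __post_init__(self) -> None:
        for key, h in self.hazard_per_min.items():
            if h < 0:
                raise ValueError(f"negative hazard for cell {key}")
        if self.observation_limit_min <= 0:
            raise ValueError("observation_limit_min must be positive")


def load_default_profiles():
    """Calibrated default profiles shipped with the package.

    Returns ``(species_profiles: dict, behavior_profile, stimulus_config)``.
    """
    with resources.files("ipitune.data").joinpath("default_profiles.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    species = {}
    for name, spec in cfg["species_profiles"].items():
        species[name] = SpeciesProfile(
            species_label=name,
            param_means=tuple(spec["param_means"][p] for p in PARAM_NAMES),
            param_cv=tuple(spec["param_cv"][p] for p in PARAM_NAMES),
            trace_noise_sd=float(spec["trace_noise_sd"]),
            bleach_slope_range=tuple(spec["bleach_slope_range"]),
            baseline_f0=float(spec["baseline_f0"]),
            response_gain=float(spec["response_gain"]),
        )
    beh = cfg["behavior_profile"]
    hazards = {
        (sp, float(ipi)): float(h)
        for sp, by_ipi in beh["hazard_per_min"].items()
        for ipi, h in by_ipi.items()
    }
    behavior = BehaviorProfile(
        hazard_per_min=hazards,
        observation_limit_min=float(beh["observation_limit_min"]),
        n_pairs_per_cell=int(beh["n_pairs_per_cell"]),
    )
    return species, behavior, cfg["stimulus"]


def sample_individual_params(
    profile: SpeciesProfile, n: int, seed, max_retries: int = 1000
) -> list[TuningParams]:
    """Draw ``n`` individual parameter sets around the profile means.

    Each coordinate is log-normal with the profile's natural-scale mean and
    coefficient of variation, independent across coordinates.  Draws that
    violate the tuning-parameter invariants (tau_b > tau_d, c*tau_b > a*tau_d)
    are rejected and redrawn, up to ``max_retries`` per individual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.asarray(profile.param_means)
    cv = np.asarray(profile.param_cv)
    # log-normal with mean m and CV v: sigma^2 = ln(1+v^2), mu = ln m - sigma^2/2
    sigma2 = np.log1p(cv**2)
    mu = np.log(means) - sigma2 / 2
    sigma = np.sqrt(sigma2)

    out: list[TuningParams] = []
    for _ in range(n):
        for attempt in range(max_retries):
            draw = np.exp(mu + sigma * rng.standard_normal(4))
            try:
                out.append(TuningParams(*draw))
                break
            except ValueError as err:
                last_err = err
        else:
            raise RuntimeError(
                f"could not draw valid tuning parameters after {max_retries} "
                f"retries; last violation: {last_err}"
            )
    return out


def _normalized_tuning(params: TuningParams, ipis_ms=DEFAULT_IPIS_MS) -> np.ndarray:
    y = tuning_value(params, np.asarray(ipis_ms, dtype=float))
    total = y.sum()
    if total <= 0:
        raise ValueError("tuning function sums to a non-positive value over the IPI set")
    return y / total


def _kernel(t_since_onset: np.ndarray) -> np.ndarray:
    """Unit-amplitude double-exponential indicator kernel, zero before onset."""
    t = np.maximum(t_since_onset, 0.0)
    raw = np.exp(-t / KERNEL_DECAY_S) - np.exp(-t / KERNEL_RISE_S)
    t_pk = (
        KERNEL_RISE_S * KERNEL_DECAY_S / (KERNEL_DECAY_S - KERNEL_RISE_S)
        * np.log(KERNEL_DECAY_S / KERNEL_RISE_S)
    )
    peak = np.exp(-t_pk / KERNEL_DECAY_S) - np.exp(-t_pk / KERNEL_RISE_S)
    out = np.where(t_since_onset >= 0, raw / peak, 0.0)
    return out


def simulate_trace(
    params: TuningParams,
    stim: StimulusSpec,
    profile: SpeciesProfile,
    seed,
    individual_id: str = "sim",
    trial: int = 0,
    frame_rate_hz: float = 10.0,
    ipis_ms=DEFAULT_IPIS_MS,
) -> FluorescenceTrace:
    """Simulate one ROI-mean fluorescence trace for one stimulus.

    trace(t) = f0 + slope*t + gain * y_norm * k(t - onset) + noise, where
    y_norm is the individual's tuning value at the stimulus IPI normalized
    over the standard IPI set, and k is the unit-amplitude indicator kernel.
    The bleach slope is drawn uniformly from the profile's range; pure tones
    drive a transient proportional to 1 (tone frequency tuning is not
    modelled here).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(stim.trace_duration_s * frame_rate_hz))
    if stim.onset_s + stim.duration_s + 0.5 > stim.trace_duration_s:
        raise ValueError(
            f"stimulus {stim.label} (onset {stim.onset_s}s, duration "
            f"{stim.duration_s:.2f}s) does not fit in a {stim.trace_duration_s}s trace"
        )
    times = np.arange(n_frames) / frame_rate_hz
    lo, hi = profile.bleach_slope_range
    slope = rng.uniform(min(lo, hi), max(lo, hi))
    if stim.kind == "pulse_song":
        matches = np.isclose(stim.ipi_ms, np.asarray(ipis_ms, dtype=float))
        if not matches.any():
            raise ValueError(f"stimulus IPI {stim.ipi_ms} ms not in the tuning IPI set")
        y = _normalized_tuning(params, ipis_ms)[int(np.argmax(matches))]
    else:
        y = 1.0
    signal = profile.response_gain * y * _kernel(times - stim.onset_s)
    noise = profile.trace_noise_sd * rng.standard_normal(n_frames)
    values = profile.baseline_f0 + slope * times + signal + noise
    return FluorescenceTrace(
        values=values,
        stim=stim,
        individual_id=individual_id,
        species=profile.species_label,
        trial=trial,
        frame_rate_hz=frame_rate_hz,
    )


def simulate_tuning_curves(
    profile: SpeciesProfile,
    n_individuals: int,
    seed,
    noise_sd: float = 0.005,
    ipis_ms=DEFAULT_IPIS_MS,
) -> tuple[list[TuningCurve], list[TuningParams]]:
    """Directly simulate normalized tuning curves (no trace stage).

    Observation noise is Gaussian on the normalized peaks, matching the
    likelihood of the hierarchical model.  Returns the curves and the true
    generating parameters.
    """
    rng = np.random.default_rng(seed)
    params = sample_individual_params(profile, n_individuals, rng.integers(2**31))
    ipis = np.asarray(ipis_ms, dtype=float)
    curves = []
    for i, p in enumerate(params):
        y = _normalized_tuning(p, ipis) + noise_sd * rng.standard_normal(ipis.size)
        curves.append(
            TuningCurve(
                individual_id=f"{profile.species_label}_{i + 1:02d}",
                species=profile.species_label,
                ipis_ms=ipis,
                normalized_peaks=y / y.sum(),
                raw_peaks=y,
            )
        )
    return curves, params


def simulate_imaging_dataset(
    profiles,
    n_individuals,
    seed,
    n_trials: int = 3,
    ipis_ms=DEFAULT_IPIS_MS,
    n_pulses: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full imaging experiment: traces CSV + stimulus table + true parameters.

    ``profiles`` maps species name -> SpeciesProfile; ``n_individuals`` maps
    species name -> cohort size (or an int applied to all).  Returns
    ``(traces_df, stim_df, true_params)`` in the long CSV schema consumed by
    :func:`ipitune.traces.process_dataset`.
    """
    rng = np.random.default_rng(seed)
    stimuli = default_pulse_stimuli(ipis_ms, n_pulses=n_pulses)
    stim_rows = []
    for k, stim in enumerate(stimuli):
        stim_rows.append(
            {
                "stimulus_id": f"stim{k:02d}",
                "kind": stim.kind,
                "ipi_ms": stim.ipi_ms,
                "n_pulses": stim.n_pulses,
                "ipf_hz": np.nan,
                "tone_hz": np.nan,
                "tone_duration_s": np.nan,
                "onset_s": stim.onset_s,
            }
        )
    stim_df = pd.DataFrame(stim_rows)

    frames = []
    true_params: dict[str, dict[str, TuningParams]] = {}
    for species in sorted(profiles):
        profile = profiles[species]
        n = n_individuals[species] if isinstance(n_individuals, dict) else int(n_individuals)
        params = sample_individual_params(profile, n, rng.integers(2**31))
        true_params[species] = {}
        for i, p in enumerate(params):
            ind = f"{species}_{i + 1:02d}"
            true_params[species][ind] = p
            for srow, stim in zip(stim_rows, stimuli):
                for trial in range(n_trials):
                    trace = simulate_trace(
                        p, stim, profile, rng.integers(2**31),
                        individual_id=ind, trial=trial, ipis_ms=ipis_ms,
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "individual_id": ind,
                                "species": species,
                                "trial": trial,
                                "stimulus_id": srow["stimulus_id"],
                                "frame_index": np.arange(trace.values.size),
                                "fluorescence": trace.values,
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True), stim_df, true_params


def simulate_copulation_records(profile: BehaviorProfile, seed) -> list:
    """Exponential copulation times per cell, censored at the assay limit.

    Returns a list of :class:`ipitune.survival.CopulationRecord`.
    """
    from .survival import CopulationRecord

    rng = np.random.default_rng(seed)
    limit = profile.observation_limit_min
    records = []
    pair = 0
    for (species, ipi), hazard in sorted(profile.hazard_per_min.items()):
        for _ in range(profile.n_pairs_per_cell):
            t = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
            event = t <= limit
            records.append(
                CopulationRecord(
                    pair_id=f"pair{pair:05d}",
                    species=species,
                    ipi_ms=float(ipi),
                    time_min=float(t) if event else limit,
                    event=bool(event),
                )
            )
            pair += 1
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in records],
            "species": [r.species for r in records],
            "ipi_ms": [r.ipi_ms for r in records],
            "time_min": [r.time_min for r in records],
            "event": [int(r.event) for r in records],
        }
    )
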