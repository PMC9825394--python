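"""End-to-end pipeline: simulate -> process -> fit -> compare -> behavior.

Every stage reads and writes plain CSV/JSON under one output directory, all
randomness flows from the single config seed, and a manifest records inputs,
config and per-stage status.  Identical config + seed reproduce byte-identical
tabular outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hierarchical import SamplerConfig, fit_hierarchical, species_peak_table
from .stats import bonferroni_t, exact_wilcoxon
from .stimuli import DEFAULT_IPIS_MS
from .survival import (
    CopulationRecord,
    cox_interaction,
    cumulative_rate,
    hazard_rows_to_frame,
    rmtl,
)
from .synthetic import (
    load_default_profiles,
    records_to_frame,
    simulate_copulation_records,
    simulate_imaging_dataset,
)
from .traces import curves_to_frame, delta_responses, process_dataset

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

STAGES = ("simulate", "process", "fit", "compare", "behavior")


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    stages: tuple = STAGES
    n_individuals: dict = field(default_factory=lambda: {"melanogaster": 12, "simulans": 13})
    n_trials: int = 3
    traces_csv: str | None = None      # optional external inputs
    stimuli_csv: str | None = None
    behavior_csv: str | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    bonferroni_family: int | None = None
    equal_var_t: bool = False
    rmtl_tau_min: float = 35.0
    cox_window_min: tuple = (0.0, 7.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sampler = SamplerConfig(**raw.pop("sampler", {}))
        stages = tuple(raw.pop("stages", STAGES))
        return cls(sampler=sampler, stages=stages, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "simulate" not in config.stages:
        for stage, path in (("process", config.traces_csv), ("behavior", config.behavior_csv)):
            if stage in config.stages and path is not None and not Path(path).exists():
                raise FileNotFoundError(f"declared input for stage {stage!r} missing: {path}")
    manifest = {
        "config": _config_dict(config),
        "versions": {"ipitune": __version__, "python": platform.python_version()},
        "stages": {},
        "outputs": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {stage: int(rng.integers(2**31)) for stage in STAGES}
    profiles, behavior_profile, _ = load_default_profiles()

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = "skipped"
            continue
        try:
            _run_stage(stage, config, state, stage_seeds[stage], profiles, behavior_profile, out)
            manifest["stages"][stage] = "ok"
        except Exception as err:
            manifest["stages"][stage] = f"failed: {err}"
            _write_manifest(manifest, state, out)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    _write_manifest(manifest, state, out)
    return manifest


def _run_stage(stage, config, state, seed, profiles, behavior_profile, out: Path):
    if stage == "simulate":
        traces_df, stim_df, _ = simulate_imaging_dataset(
            profiles, config.n_individuals, seed, n_trials=config.n_trials
        )
        _save(state, out, "traces", traces_df, float_format="%.6f")
        _save(state, out, "stimuli", stim_df)
        records = simulate_copulation_records(behavior_profile, seed + 1)
        _save(state, out, "behavior", records_to_frame(records))

    elif stage == "process":
        traces_df, stim_df = _load_imaging(config, state)
        curves = process_dataset(traces_df, stim_df)
        state["curves"] = curves
        _save(state, out, "tuning_curves", curves_to_frame(curves))
        deltas = pd.concat([delta_responses(c) for c in curves], ignore_index=True)
        _save(state, out, "delta_responses", deltas)

    elif stage == "fit":
        curves = state.get("curves")
        if curves is None:
            raise RuntimeError("fit stage requires the process stage (no curves in state)")
        fits = {}
        diagnostics = {}
        for k, species in enumerate(sorted({c.species for c in curves})):
            sp_curves = [c for c in curves if c.species == species]
            fit = fit_hierarchical(sp_curves, config.sampler, seed=seed + k)
            fits[species] = fit
            diagnostics[species] = fit.diagnostics
        state["fits"] = fits
        table = species_peak_table(fits)
        _save(state, out, "fitted_params", table, float_format="%.6f")
        diag_path = out / "fit_diagnostics.json"
        diag_path.write_text(json.dumps(diagnostics, indent=2))
        state.setdefault("extra_outputs", []).append(diag_path)

    elif stage == "compare":
        fits = state.get("fits")
        if fits is None:
            raise RuntimeError("compare stage requires the fit stage")
        rows = []
        species = sorted(fits)
        tables = {
            sp: pd.DataFrame([p.as_tuple() for p in fits[sp].individual_params.values()],
                             columns=["a", "tau_b", "c", "tau_d"])
            for sp in species
        }
        for sp in species:
            tables[sp]["peak_ipi_ms"] = [
                fits[sp].individual_params[i].peak_ipi_ms for i in fits[sp].individual_ids
            ]
        for quantity in ("a", "tau_b", "c", "tau_d", "peak_ipi_ms"):
            res = exact_wilcoxon(tables[species[0]][quantity], tables[species[1]][quantity])
            rows.append(
                {
                    "comparison": f"{quantity}:{species[0]}_vs_{species[1]}",
                    "statistic": res.statistic,
                    "p_raw": res.p_two_sided,
                    "p_adjusted": res.p_two_sided,
                    "method": f"wilcoxon-{res.method}",
                }
            )
        deltas = pd.concat([delta_responses(c) for c in state["curves"]], ignore_index=True)
        groups = {
            sp: {
                ipi: g["delta_response"].to_numpy()
                for ipi, g in deltas[deltas.species == sp].groupby("ipi_ms")
            }
            for sp in species
        }
        ttable = bonferroni_t(
            groups[species[0]], groups[species[1]],
            equal_var=config.equal_var_t, family_size=config.bonferroni_family,
        )
        for r in ttable.itertuples():
            rows.append(
                {
                    "comparison": f"delta_response@{r.ipi_ms:g}ms",
                    "statistic": r.t_statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "method": "welch-t-bonferroni" if not config.equal_var_t else "t-bonferroni",
                }
            )
        _save(state, out, "comparisons", pd.DataFrame(rows))

    elif stage == "behavior":
        records = _load_behavior(config, state)
        rows = []
        df = records_to_frame(records)
        for (sp, ipi), g in df.groupby(["species", "ipi_ms"]):
            recs = [
                CopulationRecord(r.pair_id, r.species, r.ipi_ms, r.time_min, bool(r.event))
                for r in g.itertuples()
            ]
            rows.append(
                {
                    "species": sp,
                    "ipi_ms": ipi,
                    "n_pairs": len(recs),
                    "n_events": int(g["event"].sum()),
                    "rmtl_min": rmtl(cumulative_rate(recs), config.rmtl_tau_min),
                    "tau_min": config.rmtl_tau_min,
                }
            )
        _save(state, out, "rmtl", pd.DataFrame(rows))
        recs = [
            CopulationRecord(r.pair_id, r.species, r.ipi_ms, r.time_min, bool(r.event))
            for r in df.itertuples()
        ]
        hr_rows = cox_interaction(recs, window_min=tuple(config.cox_window_min))
        _save(state, out, "cox_hazard_ratios", hazard_rows_to_frame(hr_rows))


def _load_imaging(config, state):
    if "traces_df" in state:
        return state["traces_df"], state["stim_df"]
    if config.traces_csv is None or config.stimuli_csv is None:
        raise RuntimeError(
            "process stage needs simulated data or traces_csv + stimuli_csv inputs"
        )
    traces_df = pd.read_csv(config.traces_csv)
    stim_df = pd.read_csv(config.stimuli_csv)
    state["traces_df"], state["stim_df"] = traces_df, stim_df
    return traces_df, stim_df


def _load_behavior(config, state):
    if "behavior_records" in state:
        return state["behavior_records"]
    if config.behavior_csv is None:
        raise RuntimeError("behavior stage needs simulated data or a behavior_csv input")
    df = pd.read_csv(config.behavior_csv)
    return [
        CopulationRecord(str(r.pair_id), str(r.species), float(r.ipi_ms),
                         float(r.time_min), bool(r.event))
        for r in df.itertuples()
    ]


def _save(state, out: Path, name: str, df: pd.DataFrame, float_format=None):
    path = out / f"{name}.csv"
    df.to_csv(path, index=False, float_format=float_format)
    state.setdefault("csv_outputs", {})[name] = path
    if name == "traces":
        state["traces_df"] = df
    if name == "stimuli":
        state["stim_df"] = df
    if name == "behavior":
        state["behavior_records"] = [
            CopulationRecord(str(r.pair_id), str(r.species), float(r.ipi_ms),
                             float(r.time_min), bool(r.event))
            for r in df.itertuples()
        ]


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["sampler"] = asdict(config.sampler)
    d["stages"] = list(config.stages)
    d["cox_window_min"] = list(config.cox_window_min)
    return d


def _write_manifest(manifest, state, out: Path):
    for name, path in state.get("csv_outputs", {}).items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def validate_inputs(
    traces_csv=None, stimuli_csv=None, behavior_csv=None, observation_limit_min: float = 35.0
) -> pd.DataFrame:
    """Schema and consistency checks on input tables; never mutates inputs.

    Returns a tidy report with one row per check (name, passed, detail).
    """
    checks = []

    def check(name, passed, detail=""):
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    if traces_csv is not None:
        try:
            df = pd.read_csv(traces_csv)
        except Exception as err:
            raise IOError(f"unreadable traces file {traces_csv}: {err}") from err
        required = {"individual_id", "species", "trial", "stimulus_id", "frame_index", "fluorescence"}
        missing = required - set(df.columns)
        check("traces: required columns", not missing, f"missing: {sorted(missing)}")
        if not missing:
            check(
                "traces: fluorescence finite",
                np.isfinite(df["fluorescence"]).all(),
                "non-finite values present" if not np.isfinite(df["fluorescence"]).all() else "",
            )
            check("traces: row count", len(df) > 0, f"{len(df)} rows")
        if stimuli_csv is not None and not missing:
            stim = pd.read_csv(stimuli_csv)
            pulse_ipis = set(stim.loc[stim.kind == "pulse_song", "ipi_ms"].astype(float))
            need = set(float(v) for v in DEFAULT_IPIS_MS)
            check(
                "stimuli: ten pulse IPIs",
                need <= pulse_ipis,
                f"missing IPIs: {sorted(need - pulse_ipis)}",
            )
            ref_ok = 25.0 in pulse_ipis
            check(
                "stimuli: 25 ms reference present (delta-response prerequisite)",
                ref_ok,
                "" if ref_ok else "25-ms IPI stimulus absent",
            )
            per_ind = df.merge(stim[["stimulus_id", "ipi_ms"]], on="stimulus_id")
            got = per_ind.groupby("individual_id")["ipi_ms"].nunique()
            check(
                "traces: all IPIs per individual",
                bool((got >= len(need)).all()),
                f"min IPIs per individual: {got.min() if len(got) else 0}",
            )
    if behavior_csv is not None:
        try:
            df = pd.read_csv(behavior_csv)
        except Exception as err:
            raise IOError(f"unreadable behavior file {behavior_csv}: {err}") from err
        required = {"pair_id", "species", "ipi_ms", "time_min", "event"}
        missing = required - set(df.columns)
        check("behavior: required columns", not missing, f"missing: {sorted(missing)}")
        if not missing:
            bad = df[(df.time_min < 0) | (df.time_min > observation_limit_min)]
            check(
                "behavior: times within [0, limit]",
                bad.empty,
                f"{len(bad)} rows outside [0, {observation_limit_min}] min",
            )
            censored = df[df.event == 0]
            ok = np.allclose(censored["time_min"], observation_limit_min)
            check(
                "behavior: censored at the limit",
                ok,
                "" if ok else "censored rows with time != observation limit",
            )
    return pd.DataFrame(checks)
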