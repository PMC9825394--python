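"""Published reference estimates of the AMMC-B1 IPI tuning parameters.

The packaged table holds the MCMC point estimates of (a, tau_b, c, tau_d)
and the derived peak IPI for each imaged individual (12 D. melanogaster,
13 D. simulans) together with the species-average rows.  It is an *input*
to the interspecific comparison statistics — the raw recordings behind it
were never deposited, so the synthetic-data module stands in for them.
"""

from __future__ import annotations

import importlib.resources as resources

import pandas as pd

__all__ = ["load_reference_params", "reference_individuals", "reference_average"]

PARAM_COLS = ["a", "tau_b", "c", "tau_d"]


def load_reference_params() -> pd.DataFrame:
    """Full reference table: species, individual_id ('Average' or 1..N),
    a, tau_b, c, tau_d, peak_ipi_ms."""
    with resources.files("ipitune.data").joinpath("reference_params.csv").open() as fh:
        return pd.read_csv(fh, dtype={"individual_id": str})


def reference_individuals(species: str) -> pd.DataFrame:
    df = load_reference_params()
    out = df[(df["species"] == species) & (df["individual_id"] != "Average")]
    if out.empty:
        raise KeyError(f"no reference individuals for species {species!r}")
    return out.reset_index(drop=True)


def reference_average(species: str) -> pd.Series:
    df = load_reference_params()
    out = df[(df["species"] == species) & (df["individual_id"] == "Average")]
    if out.empty:
        raise KeyError(f"no reference average for species {species!r}")
    return out.iloc[0]
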