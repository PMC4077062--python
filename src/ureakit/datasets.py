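"""Packaged reference tables and kinetic-truth presets.

``load_allele_table`` returns the transcribed mutant characterization table
(per-allele localization, growth scores, V%, Km and Ki constants);
``kinetic_truth_for`` turns one of its rows into generating parameters for
the synthetic assay simulators.

Rate-scale convention: the wild type is assigned Vmax = 100 (pmol·min⁻¹
per 10⁷ conidiospores as an arbitrary linear scale); every other allele's
Vmax is anchored so that its initial rate at the 1.0 µM tracer
concentration equals its tabulated V% of the wild-type rate.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .containers import CensoredValue, parse_maybe_censored
from .synthetic import KineticTruth, michaelis_menten_rate

__all__ = ["load_allele_table", "kinetic_truth_for", "WT_VMAX", "TRACER_CONC"]

WT_VMAX = 100.0
TRACER_CONC = 1.0  # µM labelled urea

_KI_COLUMNS = {
    "2-thiourea": "Ki_thiourea_uM",
    "acetamide": "Ki_acetamide_uM",
    "guanidine": "Ki_guanidine_uM",
}


def load_allele_table() -> pd.DataFrame:
    """The packaged per-allele characterization table, indexed by allele."""
    ref = resources.files("ureakit.data").joinpath("urea_alleles.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("allele")


def _row_value(row: pd.Series, col: str) -> float | CensoredValue | None:
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    return parse_maybe_censored(raw)


def kinetic_truth_for(
    allele: str, noise_cv: float = 0.15, seed: int = 0
) -> KineticTruth:
    """Generating parameters for an allele of the packaged table.

    Km and the Ki map come straight from the table; Vmax is anchored so the
    allele's initial rate at the 1.0 µM tracer equals its tabulated V% of
    the wild-type rate (wild-type Vmax = 100). Alleles without measurable
    transport (V% ``"<2"``) cannot be simulated as carriers.
    """
    table = load_allele_table()
    if allele not in table.index:
        raise KeyError(f"allele {allele!r} not in the packaged table")
    row = table.loc[allele]
    km = _row_value(row, "Km_uM")
    v_pct = _row_value(row, "V_percent")
    if km is None or isinstance(km, CensoredValue):
        raise ValueError(f"allele {allele!r} has no measurable Km; cannot simulate")
    if v_pct is None or isinstance(v_pct, CensoredValue):
        raise ValueError(f"allele {allele!r} has no measurable V%; cannot simulate")
    wt_km = float(_row_value(table.loc["wt"], "Km_uM"))
    wt_rate = michaelis_menten_rate(TRACER_CONC, wt_km, WT_VMAX)
    target_rate = wt_rate * v_pct / 100.0
    vmax = target_rate * (km + TRACER_CONC) / TRACER_CONC
    ki_map = {}
    for substrate, col in _KI_COLUMNS.items():
        val = _row_value(row, col)
        if val is not None:
            ki_map[substrate] = val
    return KineticTruth(
        Km=km, Vmax=vmax, Ki_map=ki_map, L=TRACER_CONC, noise_cv=noise_cv, seed=seed
    )
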