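"""Packaged experimental induction-time tables.

Two published CNT summary tables for FDPNa3 anti-solvent crystallization ship
with the package: one recorded under a 100 W ultrasound bath, one silent.
Each row carries the measurement (S, t_ind) plus the published derived
parameters (gamma, N_c, dG_c, r_c) for cross-checking the CNT identities,
and a flag marking rows whose printed ln t_ind is not the correctly rounded
value (typographic quirks are preserved, not repaired).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cnt import InductionRecord

__all__ = ["load_induction_table", "induction_records"]

_FILES = {
    "ultrasound": "induction_ultrasound_100W.csv",
    "silent": "induction_silent.csv",
}


def load_induction_table(condition: str = "ultrasound") -> pd.DataFrame:
    """Load a packaged induction table ('ultrasound' or 'silent').

    Returns the full table including the published gamma/N_c/dG_c/r_c columns
    and the ln_t_printed(_ok) provenance columns.
    """
    try:
        fname = _FILES[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; choose from {sorted(_FILES)}"
        ) from None
    with resources.files("sonocryst.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, comment="#")


def induction_records(condition: str = "ultrasound") -> list[InductionRecord]:
    """Packaged table as InductionRecord objects ready for fitting."""
    df = load_induction_table(condition)
    return [
        InductionRecord(
            supersaturation=float(r.S), induction_time=float(r.t_ind_s),
            temperature=float(r.T_K), ultrasound_power=float(r.ultrasound_W),
        )
        for r in df.itertuples()
    ]
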