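"""Two-phase (oiling-out) ternary system bookkeeping.

Anti-solvent crystallization of a hydrophilic solute from water with ethanol
can split the liquid into a solute-rich dense ("oil") phase and a light
phase.  This module validates measured splits against per-component mass
balance, computes relative supersaturation sigma = (C - C*)/C*, applies the
lever rule on tie-lines, and interpolates oiling-out / nucleation boundary
curves.  It performs no thermodynamic modelling: measured splits are
validated and transformed, never predicted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TernaryComposition",
    "Phase",
    "PhaseSplit",
    "SolubilityTable",
    "BoundaryCurve",
    "supersaturation_sigma",
    "check_mass_balance",
    "lever_fractions",
    "volume_ratio_to_fraction",
    "boundary_interp",
    "read_phase_split_csv",
    "read_boundary_csv",
]

COMPONENTS = ("water", "ethanol", "solute")


@dataclass(frozen=True)
class TernaryComposition:
    """Mass fractions of water/ethanol/solute; must close to 1 within 1e-9."""

    w_water: float
    w_ethanol: float
    w_solute: float

    def __post_init__(self) -> None:
        for w in (self.w_water, self.w_ethanol, self.w_solute):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mass fraction {w} outside [0, 1]")
        total = self.w_water + self.w_ethanol + self.w_solute
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {"water": self.w_water, "ethanol": self.w_ethanol,
                "solute": self.w_solute}

    def __getitem__(self, component: str) -> float:
        return self.as_dict()[component]


@dataclass(frozen=True)
class Phase:
    composition: TernaryComposition
    mass: float               # g
    volume: float | None = None  # mL, optional

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("phase mass must be non-negative")


@dataclass(frozen=True)
class PhaseSplit:
    """Overall mixture plus its dense (oil) and light phases."""

    overall: Phase
    dense: Phase
    light: Phase


@dataclass(frozen=True)
class SolubilityTable:
    """Saturation concentration C* (g solute / g solvent) on a
    (temperature K, ethanol mass fraction of solvent) grid.

    Lookup is exact-grid / nearest within a tight tolerance; queries outside
    the grid raise rather than extrapolate.
    """

    temperatures: tuple[float, ...]
    ethanol_fractions: tuple[float, ...]
    c_star: tuple[tuple[float, ...], ...]  # [i_temp][j_ethanol]

    def __post_init__(self) -> None:
        arr = np.asarray(self.c_star, dtype=float)
        if arr.shape != (len(self.temperatures), len(self.ethanol_fractions)):
            raise ValueError("c_star grid shape mismatch")
        if np.any(arr <= 0):
            raise ValueError("C* must be positive")
        # solubility of a hydrophilic solute falls as anti-solvent is added
        if np.any(np.diff(arr, axis=1) > 1e-12):
            raise ValueError("C* must be non-increasing in ethanol fraction")

    def lookup(self, temperature: float, ethanol_fraction: float) -> float:
        """C* by bilinear interpolation inside the grid; outside -> error."""
        t = np.asarray(self.temperatures)
        e = np.asarray(self.ethanol_fractions)
        if not (t[0] <= temperature <= t[-1]) or not (e[0] <= ethanol_fraction <= e[-1]):
            raise ValueError(
                f"query (T={temperature}, w_eth={ethanol_fraction}) outside "
                f"solubility grid; refusing to extrapolate"
            )
        arr = np.asarray(self.c_star)
        i = int(np.clip(np.searchsorted(t, temperature) - 1, 0, len(t) - 2)) if len(t) > 1 else 0
        j = int(np.clip(np.searchsorted(e, ethanol_fraction) - 1, 0, len(e) - 2)) if len(e) > 1 else 0
        if len(t) == 1 and len(e) == 1:
            return float(arr[0, 0])
        if len(t) == 1:
            return float(np.interp(ethanol_fraction, e, arr[0]))
        if len(e) == 1:
            return float(np.interp(temperature, t, arr[:, 0]))
        ft = (temperature - t[i]) / (t[i + 1] - t[i])
        fe = (ethanol_fraction - e[j]) / (e[j + 1] - e[j])
        return float(
            arr[i, j] * (1 - ft) * (1 - fe) + arr[i + 1, j] * ft * (1 - fe)
            + arr[i, j + 1] * (1 - ft) * fe + arr[i + 1, j + 1] * ft * fe
        )


@dataclass(frozen=True)
class BoundaryCurve:
    """Oiling-out or nucleation boundary at fixed T and ultrasound power."""

    kind: Literal["oiling-out", "nucleation"]
    x: tuple[float, ...]  # e.g. solute concentration
    y: tuple[float, ...]  # e.g. anti-solvent amount at onset
    temperature: float = 298.15
    ultrasound_power: float = 0.0

    def __post_init__(self) -> None:
        if len(self.x) < 2 or len(self.x) != len(self.y):
            raise ValueError("boundary curve needs >= 2 (x, y) points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("boundary abscissa must be strictly increasing")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def supersaturation_sigma(C: float, C_star: float) -> float:
    """Relative supersaturation sigma = (C - C*)/C* (same units for both).

    Negative values indicate undersaturation.
    """
    if C_star <= 0:
        raise ValueError("saturation concentration C* must be positive")
    if C < 0:
        raise ValueError("concentration C must be non-negative")
    return (C - C_star) / C_star


def check_mass_balance(split: PhaseSplit, tol: float = 1e-6) -> dict:
    """Per-component relative mass-balance residuals of a two-phase split.

    residual_c = |overall_c*M - dense_c*M_d - light_c*M_l| / (overall_c*M);
    a zero overall component with non-zero phase content reports an infinite
    residual (not an exception).  ``passed`` requires every residual and the
    total-mass residual <= tol.
    """
    m, md, ml = split.overall.mass, split.dense.mass, split.light.mass
    residuals: dict[str, float] = {}
    for c in COMPONENTS:
        target = split.overall.composition[c] * m
        got = split.dense.composition[c] * md + split.light.composition[c] * ml
        if target == 0.0:
            residuals[c] = 0.0 if got == 0.0 else math.inf
        else:
            residuals[c] = abs(target - got) / target
    mass_resid = abs(m - md - ml) / m if m > 0 else (0.0 if md + ml == 0 else math.inf)
    passed = mass_resid <= tol and all(r <= tol for r in residuals.values())
    return {"residuals": residuals, "mass_residual": mass_resid,
            "tol": tol, "passed": passed}


def lever_fractions(
    overall: TernaryComposition,
    dense: TernaryComposition,
    light: TernaryComposition,
    component: str = "solute",
) -> tuple[float, float, bool]:
    """Lever rule on a tie-line: mass fractions of total in each phase.

    f_dense = (overall - light) / (dense - light) on the chosen component.
    Returns (f_dense, f_light, consistent) where ``consistent`` is False when
    the fractions fall outside [0, 1] (overall not on the tie-line segment);
    values are returned unclamped so the inconsistency is visible.
    """
    d, l, o = dense[component], light[component], overall[component]
    if abs(d - l) <= 1e-12:
        raise ValueError(
            f"degenerate tie-line: phases identical in component {component!r}"
        )
    f_dense = (o - l) / (d - l)
    f_light = 1.0 - f_dense
    consistent = -1e-12 <= f_dense <= 1.0 + 1e-12
    return f_dense, f_light, consistent


def volume_ratio_to_fraction(
    ethanol_to_water_volume_ratio: float,
    rho_ethanol: float = 0.789,
    rho_water: float = 0.997,
) -> float:
    """Ethanol mass fraction of the mixed solvent from a volume ratio.

    Ideal (additive) volumes: w = r*rho_e / (r*rho_e + rho_w).  Densities in
    g/mL at the working temperature.
    """
    r = ethanol_to_water_volume_ratio
    if r < 0:
        raise ValueError("volume ratio must be non-negative")
    if rho_ethanol <= 0 or rho_water <= 0:
        raise ValueError("densities must be positive")
    return r * rho_ethanol / (r * rho_ethanol + rho_water)


def boundary_interp(curve: BoundaryCurve, x: float) -> float:
    """Piecewise-linear interpolation on a boundary curve; exact at knots.

    Out-of-range queries raise (no silent extrapolation).
    """
    if not (curve.x[0] <= x <= curve.x[-1]):
        raise ValueError(
            f"query x={x} outside curve range [{curve.x[0]}, {curve.x[-1]}]"
        )
    return float(np.interp(x, curve.x, curve.y))


def curve_shift_area(silent: BoundaryCurve, treated: BoundaryCurve,
                     n: int = 201) -> float:
    """Signed area between a treated and a silent boundary curve.

    Trapezoidal integral of (treated - silent) over the overlap of their
    abscissa ranges; negative when the treated curve sits below the silent
    one (onset at lower anti-solvent amounts — the forward shift).
    """
    lo = max(silent.x[0], treated.x[0])
    hi = min(silent.x[-1], treated.x[-1])
    if hi <= lo:
        raise ValueError("curves do not overlap in abscissa")
    xs = np.linspace(lo, hi, n)
    diff = np.interp(xs, treated.x, treated.y) - np.interp(xs, silent.x, silent.y)
    return float(np.trapezoid(diff, xs))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_phase_split_csv(path: str | Path) -> PhaseSplit:
    """Read a phase-split measurement CSV.

    Columns: phase (overall|dense|light), mass_g, w_water, w_ethanol,
    w_solute, volume_mL (optional).
    """
    df = pd.read_csv(path)
    phases = {}
    for _, row in df.iterrows():
        name = str(row["phase"]).strip().lower()
        comp = TernaryComposition(float(row["w_water"]), float(row["w_ethanol"]),
                                  float(row["w_solute"]))
        vol = float(row["volume_mL"]) if "volume_mL" in df.columns and pd.notna(row.get("volume_mL")) else None
        phases[name] = Phase(comp, float(row["mass_g"]), vol)
    missing = {"overall", "dense", "light"} - set(phases)
    if missing:
        raise ValueError(f"phase rows missing: {sorted(missing)}")
    return PhaseSplit(overall=phases["overall"], dense=phases["dense"],
                      light=phases["light"])


def read_boundary_csv(path: str | Path) -> list[BoundaryCurve]:
    """Read boundary curves from CSV with columns kind, temperature_K,
    ultrasound_W, x, y; one curve per (kind, T, power) group."""
    df = pd.read_csv(path)
    curves = []
    for (kind, t, p), grp in df.groupby(["kind", "temperature_K", "ultrasound_W"]):
        grp = grp.sort_values("x")
        curves.append(BoundaryCurve(
            kind=str(kind), x=tuple(grp["x"]), y=tuple(grp["y"]),
            temperature=float(t), ultrasound_power=float(p),
        ))
    return curves
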