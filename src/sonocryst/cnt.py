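"""Classical-nucleation-theory kinetics from induction-time data.

The central model: for a homogeneously nucleating solution at supersaturation
ratio S = C/C*, the induction time follows

    ln t_ind = A + B / (ln S)^2,        B = 16 pi gamma^3 v^2 / (3 k^3 T^3)

so a plot of y = ln t_ind against x = (ln S)^-2 is linear with slope B, from
which the solid-solution interfacial energy gamma is recovered:

    gamma = (3 B k^3 T^3 / (16 pi v^2))^(1/3)

Oiling-out systems typically show *two* slope regimes (a low-S and a high-S
branch with distinct gamma), so the fit is a two-branch changepoint OLS over
partitions contiguous in S.  Per-supersaturation CNT parameters follow from
gamma:

    r_c   = 2 gamma v / (k T ln S)                     critical radius, m
    dG_c  = 16 pi gamma^3 v^2 / (3 (k T ln S)^2) * N_A  barrier, J/mol
    N_c   = (4 pi / 3) r_c^3 / v                        molecules in nucleus

``InductionTimeModel`` / ``InductionTimeResults`` wrap the procedure in the
statsmodels idiom; the module-level functions are the individual operations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS, MolecularParams

__all__ = [
    "InductionRecord",
    "CNTBranchFit",
    "CNTPointParams",
    "transform_axes",
    "fit_two_branch",
    "interfacial_energy",
    "slope_from_gamma",
    "point_params",
    "radius_from_barrier",
    "cnt_table",
    "read_induction_csv",
    "InductionTimeModel",
    "InductionTimeResults",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InductionRecord:
    """One induction-time measurement.

    supersaturation : ratio S = C/C*, dimensionless, > 1
    induction_time  : seconds, > 0
    temperature     : kelvin, > 0
    ultrasound_power: watts (0 = silent condition)
    """

    supersaturation: float
    induction_time: float
    temperature: float = 298.15
    ultrasound_power: float = 0.0

    def __post_init__(self) -> None:
        if not self.supersaturation > 1.0:
            raise ValueError(
                f"supersaturation must exceed 1 (got S={self.supersaturation})"
            )
        if not self.induction_time > 0:
            raise ValueError("induction_time must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class CNTBranchFit:
    """OLS fit of one supersaturation branch: ln t = A + B * (ln S)^-2."""

    intercept: float  # A, ln seconds
    slope: float      # B, dimensionless
    gamma: float | None  # J/m^2, None if molecular params were not supplied
    s_range: tuple[float, ...]
    rss: float
    n: int

    @property
    def gamma_mJ_per_m2(self) -> float | None:
        return None if self.gamma is None else self.gamma * 1e3


@dataclass(frozen=True)
class CNTPointParams:
    """Per-supersaturation CNT parameters (SI units)."""

    S: float
    r_c: float          # m
    dG_c_molar: float   # J/mol
    N_c: float          # molecules


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def transform_axes(
    records: Sequence[InductionRecord],
) -> list[tuple[float, float]]:
    """Map records to the CNT fitting plane: x = (ln S)^-2, y = ln t_ind.

    Order is preserved.  Raises ``ValueError`` naming the offending row for
    S <= 1 (which would make x undefined).
    """
    out = []
    for i, r in enumerate(records):
        if r.supersaturation <= 1.0:
            raise ValueError(f"record {i}: supersaturation {r.supersaturation} <= 1")
        ln_s = math.log(r.supersaturation)
        out.append((ln_s ** -2, math.log(r.induction_time)))
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b*x; returns (a, b, rss)."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_two_branch(
    points: Sequence[tuple[float, float]],
    s_values: Sequence[float],
    split: float | str = "auto",
) -> tuple[CNTBranchFit, CNTBranchFit, dict]:
    """Two-branch OLS of y = A + B*x with a changepoint contiguous in S.

    Parameters
    ----------
    points : (x, y) pairs from :func:`transform_axes`.
    s_values : supersaturation of each point (defines branch contiguity).
    split : explicit S threshold (points with S <= split go to the low-S
        branch) or ``"auto"`` to choose the contiguous split minimising total
        RSS with >= 2 points per side.

    Returns (low_S_branch, high_S_branch, info) where ``info`` records the
    chosen split and an RSS-tie flag.
    """
    pts = np.asarray(points, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if pts.shape[0] != s.shape[0]:
        raise ValueError("points and s_values length mismatch")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points for a two-branch fit")

    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    x_sorted, y_sorted = pts[order, 0], pts[order, 1]

    def branch(mask: np.ndarray) -> CNTBranchFit:
        a, b, rss = _ols(x_sorted[mask], y_sorted[mask])
        return CNTBranchFit(
            intercept=a, slope=b, gamma=None,
            s_range=tuple(np.unique(s_sorted[mask])),
            rss=rss, n=int(mask.sum()),
        )

    n = len(s_sorted)
    if split == "auto":
        best = None
        rss_by_cut = []
        for cut in range(2, n - 1):  # low branch = first `cut` sorted points
            # keep replicates of one S on the same side
            if s_sorted[cut - 1] == s_sorted[cut]:
                continue
            low = np.zeros(n, bool)
            low[:cut] = True
            _, _, r1 = _ols(x_sorted[low], y_sorted[low])
            _, _, r2 = _ols(x_sorted[~low], y_sorted[~low])
            rss_by_cut.append((r1 + r2, cut))
        if not rss_by_cut:
            raise ValueError("no admissible contiguous split with >=2 points per side")
        rss_by_cut.sort()
        total_rss, cut = rss_by_cut[0]
        # flag indifferent splits (degenerate single-branch data)
        tie = len(rss_by_cut) > 1 and math.isclose(
            total_rss, rss_by_cut[1][0], rel_tol=1e-9, abs_tol=1e-12
        )
        split_s = 0.5 * (s_sorted[cut - 1] + s_sorted[cut])
    else:
        split_s = float(split)
        cut = int(np.searchsorted(s_sorted, split_s, side="right"))
        tie = False
        if cut < 2 or n - cut < 2:
            raise ValueError(
                f"explicit split at S={split_s} leaves a branch with < 2 points"
            )

    low_mask = np.zeros(n, bool)
    low_mask[:cut] = True
    low, high = branch(low_mask), branch(~low_mask)
    info = {"split_S": float(split_s), "rss_tie": bool(tie),
            "total_rss": low.rss + high.rss}
    return low, high, info


def interfacial_energy(B: float, mol: MolecularParams, T: float) -> float:
    """Interfacial energy gamma (J/m^2) from the CNT slope B.

    gamma = (3 B k^3 T^3 / (16 pi v^2))^(1/3); monotone increasing in B and
    T, decreasing in v.
    """
    if B < 0:
        raise ValueError("non-physical slope")
    if T <= 0:
        raise ValueError("temperature must be positive")
    k = CONSTANTS.boltzmann
    v = mol.molecular_volume
    return (3.0 * B * (k * T) ** 3 / (16.0 * math.pi * v * v)) ** (1.0 / 3.0)


def slope_from_gamma(gamma: float, mol: MolecularParams, T: float) -> float:
    """Inverse of :func:`interfacial_energy`: B = 16 pi gamma^3 v^2/(3 k^3 T^3)."""
    k = CONSTANTS.boltzmann
    v = mol.molecular_volume
    return 16.0 * math.pi * gamma ** 3 * v * v / (3.0 * (k * T) ** 3)


def point_params(
    gamma: float, mol: MolecularParams, T: float, S: float
) -> CNTPointParams:
    """Critical radius, molar barrier and nucleus size at supersaturation S."""
    if S <= 1.0:
        raise ValueError(f"supersaturation must exceed 1 (got {S})")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    k, n_a = CONSTANTS.boltzmann, CONSTANTS.avogadro
    v = mol.molecular_volume
    kt_ln_s = k * T * math.log(S)
    r_c = 2.0 * gamma * v / kt_ln_s
    dg_c = 16.0 * math.pi * gamma ** 3 * v * v / (3.0 * kt_ln_s ** 2) * n_a
    n_c = (4.0 * math.pi / 3.0) * r_c ** 3 / v
    return CNTPointParams(S=S, r_c=r_c, dG_c_molar=dg_c, N_c=n_c)


def radius_from_barrier(gamma: float, dG_c_molar: float) -> float:
    """Critical radius (m) back-computed from gamma (J/m^2) and dG_c (J/mol).

    Inverts dG_c = (4 pi / 3) gamma r_c^2 N_A:  r_c = sqrt(3 dG_c/(4 pi gamma N_A)).
    """
    if gamma <= 0 or dG_c_molar <= 0:
        raise ValueError("gamma and dG_c must be positive")
    return math.sqrt(3.0 * dG_c_molar / (4.0 * math.pi * gamma * CONSTANTS.avogadro))


def cnt_table(
    records: Sequence[InductionRecord],
    mol: MolecularParams,
    T: float | None = None,
    split: float | str = "auto",
) -> pd.DataFrame:
    """Per-supersaturation CNT parameter table (the Model/Results shortcut)."""
    res = InductionTimeModel(records, mol, temperature=T).fit(split=split)
    return res.cnt_table()


def read_induction_csv(path: str | Path) -> list[InductionRecord]:
    """Read induction records from CSV with columns S, t_ind_s, T_K, ultrasound_W.

    Extra columns are ignored (preserved by the caller if needed); decimal
    point ".", no thousands separators.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"S", "t_ind_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    recs = []
    for _, row in df.iterrows():
        recs.append(InductionRecord(
            supersaturation=float(row["S"]),
            induction_time=float(row["t_ind_s"]),
            temperature=float(row.get("T_K", 298.15)),
            ultrasound_power=float(row.get("ultrasound_W", 0.0)),
        ))
    return recs


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class InductionTimeModel:
    """Two-branch CNT induction-time model.

    Parameters
    ----------
    records : sequence of InductionRecord, or a DataFrame with columns
        S, t_ind_s (and optionally T_K, ultrasound_W).
    molecular_params : MolecularParams, optional
        Needed to convert slopes to interfacial energies; a fit without it
        still returns (A, B) per branch.
    temperature : float, optional
        Kelvin; overrides per-record temperatures for the CNT conversion.
        Defaults to the (unique) record temperature.
    """

    def __init__(
        self,
        records: Sequence[InductionRecord] | pd.DataFrame,
        molecular_params: MolecularParams | None = None,
        temperature: float | None = None,
    ) -> None:
        if isinstance(records, pd.DataFrame):
            records = [
                InductionRecord(
                    supersaturation=float(r["S"]),
                    induction_time=float(r["t_ind_s"]),
                    temperature=float(r.get("T_K", 298.15)),
                    ultrasound_power=float(r.get("ultrasound_W", 0.0)),
                )
                for _, r in records.iterrows()
            ]
        self.records = list(records)
        if not self.records:
            raise ValueError("no records")
        self.mol = molecular_params
        if temperature is None:
            temps = {r.temperature for r in self.records}
            if len(temps) > 1:
                raise ValueError(
                    "records carry multiple temperatures; pass temperature= explicitly"
                )
            temperature = temps.pop()
        self.temperature = float(temperature)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "InductionTimeModel":
        return cls(read_induction_csv(path), **kwargs)

    def fit(self, split: float | str = "auto") -> "InductionTimeResults":
        pts = transform_axes(self.records)
        s_vals = [r.supersaturation for r in self.records]
        low, high, info = fit_two_branch(pts, s_vals, split=split)
        if self.mol is not None:
            low = CNTBranchFit(
                intercept=low.intercept, slope=low.slope,
                gamma=interfacial_energy(max(low.slope, 0.0), self.mol, self.temperature),
                s_range=low.s_range, rss=low.rss, n=low.n,
            )
            high = CNTBranchFit(
                intercept=high.intercept, slope=high.slope,
                gamma=interfacial_energy(max(high.slope, 0.0), self.mol, self.temperature),
                s_range=high.s_range, rss=high.rss, n=high.n,
            )
        return InductionTimeResults(self, low, high, info)


@dataclass
class InductionTimeResults:
    """Results of a two-branch induction-time fit."""

    model: InductionTimeModel
    low_branch: CNTBranchFit
    high_branch: CNTBranchFit
    split_info: dict = field(default_factory=dict)

    @property
    def split_S(self) -> float:
        return self.split_info["split_S"]

    def _branch_of(self, S: float) -> CNTBranchFit:
        # ties at the split go to the low-S branch
        return self.low_branch if S <= self.split_S else self.high_branch

    def cnt_table(self) -> pd.DataFrame:
        """Table mirroring the experimental CNT summaries.

        Columns: S, t_ind_s, ln_t_ind, branch, gamma_mJ_per_m2, N_c,
        dG_c_J_per_mol, r_c_nm.  Requires molecular parameters on the model.
        """
        if self.model.mol is None:
            raise ValueError("cnt_table requires molecular_params on the model")
        rows = []
        for r in self.model.records:
            br = self._branch_of(r.supersaturation)
            pp = point_params(br.gamma, self.model.mol,
                              self.model.temperature, r.supersaturation)
            rows.append({
                "S": r.supersaturation,
                "t_ind_s": r.induction_time,
                "ln_t_ind": math.log(r.induction_time),
                "branch": "low-S" if br is self.low_branch else "high-S",
                "gamma_mJ_per_m2": br.gamma * 1e3,
                "N_c": pp.N_c,
                "dG_c_J_per_mol": pp.dG_c_molar,
                "r_c_nm": pp.r_c * 1e9,
            })
        return pd.DataFrame(rows)

    def bootstrap_ci(
        self, n_boot: int = 500, alpha: float = 0.05, seed: int | None = None
    ) -> dict:
        """Pairs-bootstrap percentile CIs on (A, B, gamma) per branch.

        Resamples records within each branch (the split is held fixed).
        """
        rng = np.random.default_rng(seed)
        out = {}
        for name, br in (("low", self.low_branch), ("high", self.high_branch)):
            recs = [r for r in self.model.records
                    if self._branch_of(r.supersaturation) is br]
            pts = np.asarray(transform_axes(recs))
            stats = []
            for _ in range(n_boot):
                idx = rng.integers(0, len(pts), len(pts))
                xb, yb = pts[idx, 0], pts[idx, 1]
                if np.ptp(xb) < 1e-12:
                    continue  # degenerate resample
                a, b, _ = _ols(xb, yb)
                g = (interfacial_energy(max(b, 0.0), self.model.mol,
                                        self.model.temperature)
                     if self.model.mol is not None else np.nan)
                stats.append((a, b, g))
            arr = np.asarray(stats)
            qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
            out[name] = {
                "A_ci": list(np.percentile(arr[:, 0], qs)),
                "B_ci": list(np.percentile(arr[:, 1], qs)),
                "gamma_ci": list(np.percentile(arr[:, 2], qs)),
            }
        return out

    def fit_report(self) -> dict:
        """JSON-serialisable fit report (A, B, gamma, RSS, split, units)."""
        def b2d(br: CNTBranchFit) -> dict:
            return {
                "A": br.intercept, "B": br.slope,
                "gamma_J_per_m2": br.gamma,
                "gamma_mJ_per_m2": br.gamma_mJ_per_m2,
                "s_range": list(br.s_range), "rss": br.rss, "n": br.n,
            }
        return {
            "model": "ln t_ind = A + B / (ln S)^2, two-branch OLS",
            "temperature_K": self.model.temperature,
            "split_S": self.split_S,
            "rss_tie": self.split_info.get("rss_tie", False),
            "low_branch": b2d(self.low_branch),
            "high_branch": b2d(self.high_branch),
            "units": {"A": "ln(s)", "B": "dimensionless",
                      "gamma": "J/m^2 (also mJ/m^2)"},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.fit_report(), indent=2))

    def summary(self) -> str:
        """Human-readable fit summary table."""
        rep = self.fit_report()
        lines = [
            "Two-branch CNT induction-time fit",
            "=" * 54,
            f"  model: ln t_ind = A + B/(ln S)^2   T = {rep['temperature_K']:.2f} K",
            f"  split at S = {rep['split_S']:.4g}"
            + ("  (RSS tie: split indifferent)" if rep["rss_tie"] else ""),
            "-" * 54,
            f"  {'branch':<8}{'n':>3}{'A':>10}{'B':>10}{'gamma mJ/m^2':>16}{'RSS':>10}",
        ]
        for name in ("low_branch", "high_branch"):
            b = rep[name]
            g = "-" if b["gamma_mJ_per_m2"] is None else f"{b['gamma_mJ_per_m2']:.3f}"
            lines.append(
                f"  {name.split('_')[0]:<8}{b['n']:>3}{b['A']:>10.4f}"
                f"{b['B']:>10.4f}{g:>16}{b['rss']:>10.3e}"
            )
        lines.append("=" * 54)
        return "\n".join(lines)
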