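"""Gaussian-enveloped sinusoidal pulsed electric field.

The ultrasound surrogate applied in the molecular simulations is a pulsed
field along one box axis,

    E(t) = E0 * exp(-(t - t0)^2 / (2 sigma_t^2)) * cos(omega * (t - t0))

with peak amplitude E0 (V/nm), pulse centre t0 (ps), Gaussian envelope width
sigma_t (ps) and angular frequency omega (rad/ps).  Omega may be given
directly or derived from a wavelength as omega = 2*pi*c/lambda with c the
speed of light.  The envelope width is named ``sigma_t`` throughout to avoid
collision with the relative supersaturation sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import integrate

from .constants import SPEED_OF_LIGHT_NM_PER_PS

__all__ = ["PulsedField", "field_at", "sample_field", "pulse_fluence",
           "write_field_table", "read_field_table"]


@dataclass(frozen=True)
class PulsedField:
    """Pulsed-field parameters; exactly one of (lambda_nm, omega) is supplied.

    Attributes
    ----------
    E0 : peak field, V/nm (>= 0)
    t0 : time of peak, ps
    sigma_t : Gaussian envelope width, ps (> 0)
    lambda_nm : wavelength, nm; sets omega = 2*pi*c/lambda
    omega : angular frequency, rad/ps
    axis : field direction label (metadata for the toy simulator)
    """

    E0: float
    t0: float
    sigma_t: float
    lambda_nm: float | None = None
    omega: float | None = None
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.E0 < 0:
            raise ValueError("E0 must be non-negative")
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be positive")
        if (self.lambda_nm is None) == (self.omega is None):
            raise ValueError("supply exactly one of lambda_nm or omega")
        if self.lambda_nm is not None:
            if self.lambda_nm <= 0:
                raise ValueError("lambda_nm must be positive")
            object.__setattr__(
                self, "omega",
                2.0 * math.pi * SPEED_OF_LIGHT_NM_PER_PS / self.lambda_nm,
            )

    def __call__(self, t):
        return field_at(self, t)


def field_at(pf: PulsedField, t):
    """E(t) in V/nm; accepts scalars or arrays. Even about t0, |E| <= E0."""
    tau = np.asarray(t, dtype=float) - pf.t0
    val = pf.E0 * np.exp(-tau * tau / (2.0 * pf.sigma_t ** 2)) * np.cos(pf.omega * tau)
    return float(val) if np.isscalar(t) else val


def sample_field(pf: PulsedField, t_start: float, t_end: float, dt: float):
    """Sample E on the half-open grid [t_start, t_end) with step dt.

    Returns (t, E) arrays; each value equals field_at exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n = int(math.ceil((t_end - t_start) / dt - 1e-12))
    t = t_start + dt * np.arange(n)
    return t, field_at(pf, t)


def pulse_fluence(pf: PulsedField) -> float:
    """Energy-delivery proxy: integral of E(t)^2 dt over t0 +/- 8 sigma_t.

    Units (V/nm)^2 * ps.  Closed form of the full-line integral:
    E0^2 * sigma_t * sqrt(pi)/2 * (1 + exp(-omega^2 sigma_t^2)); quadrature
    agrees to <= 1e-8 relative (the +/- 8 sigma truncation is far below that).
    """
    if pf.E0 == 0.0:
        return 0.0
    val, _ = integrate.quad(
        lambda t: field_at(pf, t) ** 2,
        pf.t0 - 8.0 * pf.sigma_t, pf.t0 + 8.0 * pf.sigma_t,
        epsabs=0.0, epsrel=1e-11, limit=400,
    )
    return val


def fluence_closed_form(pf: PulsedField) -> float:
    """Analytic full-line fluence (Gaussian-times-cosine squared integral)."""
    w, s = pf.omega, pf.sigma_t
    return pf.E0 ** 2 * s * math.sqrt(math.pi) / 2.0 * (1.0 + math.exp(-(w * s) ** 2))


def write_field_table(pf: PulsedField, t_start: float, t_end: float, dt: float,
                      path: str | Path) -> Path:
    """Write a two-column (t_ps, E_V_per_nm) table for MD-engine input.

    '#'-prefixed header records all pulse parameters; values are printed at
    17 significant digits so a read-back reproduces them bit-exactly.
    """
    path = Path(path)
    t, e = sample_field(pf, t_start, t_end, dt) if t_end > t_start else (
        np.empty(0), np.empty(0))
    lines = [
        "# pulsed-field table: E(t) = E0 exp(-(t-t0)^2/(2 sigma_t^2)) cos(omega (t-t0))",
        f"# E0_V_per_nm = {pf.E0!r}",
        f"# t0_ps = {pf.t0!r}",
        f"# sigma_ps = {pf.sigma_t!r}",
        f"# omega_rad_per_ps = {pf.omega!r}",
        f"# lambda_nm = {pf.lambda_nm!r}",
        f"# axis = {pf.axis}",
        "# columns: t_ps E_V_per_nm",
    ]
    for ti, ei in zip(t, e):
        lines.append(f"{ti:.17g} {ei:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_field_table(path: str | Path) -> tuple[dict, np.ndarray, np.ndarray]:
    """Read a field table back: (header params, t array, E array)."""
    params: dict[str, str] = {}
    ts, es = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                params[key.strip()] = val.strip()
            continue
        a, b = line.split()
        ts.append(float(a))
        es.append(float(b))
    return params, np.asarray(ts), np.asarray(es)
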