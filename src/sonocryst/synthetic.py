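"""Synthetic-data generators for every pipeline stage.

The wet-lab and MD-engine inputs of an oiling-out crystallization study are
emulated here so the full analysis chain is testable without instruments or
an MD engine:

* ``gen_induction_dataset`` — induction-time tables with the two-slope
  ln t vs (ln S)^-2 structure and lognormal noise;
* ``gen_phase_split`` — ternary two-phase splits that close mass balance
  exactly, with the solute partitioned into the dense phase;
* ``gen_counts_series`` — FBRM-like particle-count signals with a known
  onset;
* ``toy_simulate`` — a desk-scale overdamped Brownian-dynamics simulator of
  labelled soft particles whose attractive solute–solute interactions drive
  demixing and whose charged solute couples to an applied pulsed field,
  emitting frames and Coul-SR/LJ-SR energy series in the exact formats the
  analysis modules read.

Every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnt import InductionRecord, slope_from_gamma
from .constants import MolecularParams
from .field import PulsedField, field_at
from .md import EnergySeries, ParticleFrame
from .phase import Phase, PhaseSplit, TernaryComposition, COMPONENTS

__all__ = [
    "InductionGenSpec", "gen_induction_dataset", "induction_spec_from_gamma",
    "write_induction_csv", "gen_phase_split", "gen_counts_series",
    "ToySimSpec", "toy_simulate", "demixing_sim_spec", "pair_potential",
    "field_response",
]


# ---------------------------------------------------------------------------
# Induction-time datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InductionGenSpec:
    """Two-branch induction-time generator spec.

    ln t = A_branch + B_branch / (ln S)^2 + Normal(0, noise_sd), with the
    low-S branch (A1, B1) used for S <= split_S.
    """

    A1: float
    B1: float
    A2: float
    B2: float
    split_S: float
    s_grid: tuple[float, ...]
    noise_sd: float = 0.05
    replicates: int = 1
    temperature: float = 298.15
    ultrasound_power: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(s <= 1.0 for s in self.s_grid):
            raise ValueError("all grid supersaturations must exceed 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def gen_induction_dataset(
    spec: InductionGenSpec,
) -> tuple[list[InductionRecord], dict]:
    """Generate induction records plus the embedded ground truth."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for s in spec.s_grid:
        a, b = (spec.A1, spec.B1) if s <= spec.split_S else (spec.A2, spec.B2)
        x = math.log(s) ** -2
        for _ in range(spec.replicates):
            ln_t = a + b * x + rng.normal(0.0, spec.noise_sd)
            records.append(InductionRecord(
                supersaturation=s, induction_time=math.exp(ln_t),
                temperature=spec.temperature,
                ultrasound_power=spec.ultrasound_power,
            ))
    truth = {"A1": spec.A1, "B1": spec.B1, "A2": spec.A2, "B2": spec.B2,
             "split_S": spec.split_S, "noise_sd": spec.noise_sd,
             "seed": spec.seed}
    return records, truth


def induction_spec_from_gamma(
    gamma_low: float, gamma_high: float, mol: MolecularParams,
    temperature: float = 298.15, A: float = 2.0, split_S: float = 2.05,
    s_grid: Sequence[float] | None = None, **kwargs,
) -> InductionGenSpec:
    """Build a generator spec whose branch slopes correspond to target
    interfacial energies (J/m^2) through B = 16 pi gamma^3 v^2/(3 k^3 T^3)."""
    if s_grid is None:
        s_grid = tuple(np.round(np.linspace(1.6, 2.05, 8), 4)) + \
                 tuple(np.round(np.linspace(2.1, 2.6, 8), 4))
    return InductionGenSpec(
        A1=A, B1=slope_from_gamma(gamma_low, mol, temperature),
        A2=A, B2=slope_from_gamma(gamma_high, mol, temperature),
        split_S=split_S, s_grid=tuple(s_grid), temperature=temperature,
        **kwargs,
    )


def write_induction_csv(records: Sequence[InductionRecord],
                        path: str | Path, spec: InductionGenSpec | None = None,
                        ) -> Path:
    """Write records as CSV (columns S, t_ind_s, T_K, ultrasound_W); the
    generator spec and seed are recorded in '#' header comments."""
    path = Path(path)
    lines = []
    if spec is not None:
        lines.append(f"# generator: {spec!r}")
    lines.append("S,t_ind_s,T_K,ultrasound_W")
    for r in records:
        lines.append(f"{r.supersaturation:.10g},{r.induction_time:.10g},"
                     f"{r.temperature:.10g},{r.ultrasound_power:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Phase splits
# ---------------------------------------------------------------------------

def gamma_recovery_study(
    gamma_low: float,
    gamma_high: float,
    mol: MolecularParams,
    temperature: float = 298.15,
    noise_sd: float = 0.05,
    replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Monte-Carlo recovery of interfacial energies from synthetic data.

    Each replicate draws a two-branch induction dataset (8 supersaturation
    levels per branch, lognormal noise on t_ind), refits it with the
    automatic changepoint, and converts branch slopes back to gamma.
    Returns median relative errors (percent) per branch and the fraction of
    replicates whose recovered changepoint lies between the generating
    branches.
    """
    from .cnt import fit_two_branch, interfacial_energy

    low_grid = tuple(np.round(np.linspace(1.6, 2.0, 8), 4))
    high_grid = tuple(np.round(np.linspace(2.1, 2.6, 8), 4))
    split_true = 2.05
    b1 = slope_from_gamma(gamma_low, mol, temperature)
    b2 = slope_from_gamma(gamma_high, mol, temperature)
    rng = np.random.default_rng(seed)
    err_low, err_high, split_hits = [], [], 0
    for _ in range(replicates):
        spec = InductionGenSpec(
            A1=2.0, B1=b1, A2=2.0, B2=b2, split_S=split_true,
            s_grid=low_grid + high_grid, noise_sd=noise_sd,
            temperature=temperature, seed=int(rng.integers(2**31)),
        )
        records, _ = gen_induction_dataset(spec)
        pts = [(math.log(r.supersaturation) ** -2,
                math.log(r.induction_time)) for r in records]
        s = [r.supersaturation for r in records]
        low, high, info = fit_two_branch(pts, s, split="auto")
        g1 = interfacial_energy(max(low.slope, 0.0), mol, temperature)
        g2 = interfacial_energy(max(high.slope, 0.0), mol, temperature)
        err_low.append(abs(g1 - gamma_low) / gamma_low)
        err_high.append(abs(g2 - gamma_high) / gamma_high)
        if low_grid[-1] < info["split_S"] < high_grid[0]:
            split_hits += 1
    return {
        "median_error_low_pct": 100 * float(np.median(err_low)),
        "median_error_high_pct": 100 * float(np.median(err_high)),
        "changepoint_rate": split_hits / replicates,
        "replicates": replicates,
    }


def gen_phase_split(
    overall: TernaryComposition,
    total_mass: float,
    partition: dict[str, float],
    dense_mass_fraction: float,
) -> PhaseSplit:
    """Construct a two-phase split that closes mass balance exactly.

    Each component's mass is allocated to the dense phase with share
    phi*K_c / (phi*K_c + 1 - phi), where K_c is the component's dense:light
    distribution ratio and phi the nominal dense mass fraction; K_c = 1 for
    every component reproduces the overall composition in both phases, and
    K_solute > 1 enriches the dense phase in solute.
    """
    if not 0.0 < dense_mass_fraction < 1.0:
        raise ValueError(
            f"dense_mass_fraction must lie strictly in (0, 1), got "
            f"{dense_mass_fraction}"
        )
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    phi = dense_mass_fraction
    masses_dense, masses_light = {}, {}
    for c in COMPONENTS:
        k = partition.get(c, 1.0)
        if k <= 0:
            raise ValueError(f"partition coefficient for {c!r} must be > 0, got {k}")
        m_c = overall[c] * total_mass
        share = phi * k / (phi * k + (1.0 - phi))
        masses_dense[c] = m_c * share
        masses_light[c] = m_c - masses_dense[c]
    m_dense = sum(masses_dense.values())
    m_light = sum(masses_light.values())
    if m_dense <= 0 or m_light <= 0:
        raise ValueError("degenerate split: a phase received zero mass")

    def comp(masses: dict[str, float], m: float) -> TernaryComposition:
        return TernaryComposition(masses["water"] / m, masses["ethanol"] / m,
                                  masses["solute"] / m)

    return PhaseSplit(
        overall=Phase(overall, total_mass),
        dense=Phase(comp(masses_dense, m_dense), m_dense),
        light=Phase(comp(masses_light, m_light), m_light),
    )


# ---------------------------------------------------------------------------
# FBRM-like count series
# ---------------------------------------------------------------------------

def gen_counts_series(
    onset_index: int, baseline: float, noise_sd: float, step: float,
    slope: float, n: int, seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Noisy step-plus-ramp count signal with a known onset.

    counts_i = baseline + noise, plus step + slope*(i - onset) for
    i >= onset_index; clipped at zero (counts are non-negative).
    """
    if not 0 <= onset_index <= n:
        raise ValueError("onset_index must lie within the series")
    rng = np.random.default_rng(seed)
    c = baseline + rng.normal(0.0, noise_sd, n)
    i = np.arange(n)
    ramp = (i >= onset_index) * (step + slope * (i - onset_index))
    counts = np.clip(c + ramp, 0.0, None)
    return counts, {"onset_index": onset_index, "baseline": baseline,
                    "noise_sd": noise_sd, "step": step, "slope": slope,
                    "seed": seed}


# ---------------------------------------------------------------------------
# Toy Brownian-dynamics simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySimSpec:
    """Desk-scale overdamped Langevin simulation spec.

    counts : particles per species, e.g. {"solute": 48, "ion": 144,
        "ethanol": 96, "water": 96}; total capped at 2000.
    epsilon : symmetric species-pair attraction depths (energy units) keyed
        by (a, b) tuples; missing pairs default to 0.
    repulsion : global soft-core repulsion strength (all pairs), so even
        non-attracting species have excluded volume.
    box : orthorhombic periodic box lengths, nm.
    dt / n_steps : step size (time units ~ ps) and step count.
    temperature : noise amplitude T; displacement noise sd = sqrt(2 T dt).
    charge : per-species charge; charged species couple to the field and to
        each other through the screened-charge term.
    charge_levels : optional per-species tuple of dissociation-state charges
        assigned round-robin to that species' particles (overrides
        ``charge`` for those particles), emulating a solute with several
        coexisting dissociation states.
    field_pulse : optional PulsedField applied along ``field_pulse.axis``.
    field_heating : local-heating coefficient eta; a charged particle in the
        field dissipates power ~ (q*E)^2 into its surroundings (overdamped
        drift against friction), modelled as an additive contribution
        eta*(q_i*E(t))^2 to that particle's noise temperature.
    sigma_lj / cutoff / soft_core : pair-potential length scales, nm.
    coulomb_coupling / screening_length : screened-charge term parameters.
    sample_every : frames/energy rows logged every this many steps.
    """

    counts: dict[str, int]
    epsilon: dict[tuple[str, str], float]
    repulsion: float = 1.0
    box: tuple[float, float, float] = (5.0, 5.0, 5.0)
    dt: float = 0.005
    n_steps: int = 5000
    temperature: float = 0.1
    charge: dict[str, float] = field(
        default_factory=lambda: {"solute": -3.0, "ion": 1.0})
    charge_levels: dict[str, tuple[float, ...]] | None = None
    field_pulse: PulsedField | None = None
    sigma_lj: float = 0.35
    cutoff: float = 1.2
    soft_core: float | None = None  # defaults to sigma_lj
    coulomb_coupling: float = 0.05
    screening_length: float = 0.5
    field_heating: float = 0.45
    sample_every: int = 20
    initial_positions: tuple | None = None  # (n, 3) rows; default random
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("particle counts must be non-negative")
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError("no particles")
        if total > 2000:
            raise ValueError(f"{total} particles exceeds the desk-scale cap of 2000")
        if self.dt <= 0 or self.n_steps <= 0:
            raise ValueError("dt and n_steps must be positive")
        for (a, b), e in self.epsilon.items():
            if self.epsilon.get((b, a), e) != e:
                raise ValueError(f"epsilon not symmetric for pair ({a}, {b})")

    def eps(self, a: str, b: str) -> float:
        return self.epsilon.get((a, b), self.epsilon.get((b, a), 0.0))


def demixing_sim_spec(field_amplitude: float = 0.0, seed: int = 0,
                      **overrides) -> ToySimSpec:
    """The standard demixing scenario: strongly self-attracting charged
    solute with its counterion shell in an ethanol/water bath, with an
    optional pulsed field along x.

    The charged solute (q = -3, with a bath of +1 counterions) aggregates
    through its pair attraction.  The pulsed field couples to the charged
    species two ways: the deterministic q*E drift along x, and local
    heating — the power a charged particle dissipates by drifting against
    friction raises its noise temperature by eta*(q*E(t))^2.  Heating above
    the pair binding melts clusters; in the troughs of the slow carrier
    (omega = 0.5, period ~ 13 time units) the heated species cools and
    partially re-aggregates, so the cycle-averaged cluster content — and
    with it the demixing index and the solute-solute interaction-energy
    magnitude — decreases *gradually* with amplitude rather than switching:
    the toy analogue of cavitation bursts disrupting the shell around the
    solute.

    ``field_amplitude`` is a scenario label in field units (force per unit
    charge); 0 disables the field.  The pulse peaks late in the run
    (t0 = 3/4 of the run, sigma_t = run/4) so clusters first form undisturbed
    and the closing quarter of the trajectory — the steady-state analysis
    window — lies under the pulse.

    Demixing against the solvent should be measured along an axis
    *perpendicular* to the field (see :func:`field_response`): along the
    field axis the coherent q*E sloshing displaces the solute distribution
    without de-clustering it.
    """
    base = dict(
        counts={"solute": 72, "ion": 168, "ethanol": 96, "water": 96},
        epsilon={("solute", "solute"): 1.2, ("solute", "ion"): 0.8,
                 ("solute", "water"): 0.1, ("ethanol", "ethanol"): 0.2,
                 ("water", "water"): 0.2, ("ethanol", "water"): 0.1,
                 ("ion", "water"): 0.2},
        seed=seed,
    )
    base.update(overrides)
    spec = ToySimSpec(**base)
    if field_amplitude > 0.0:
        t_total = spec.dt * spec.n_steps
        pulse = PulsedField(E0=field_amplitude, t0=0.75 * t_total,
                            sigma_t=t_total / 4.0, omega=0.5, axis="x")
        spec = replace(spec, field_pulse=pulse)
    return spec


def field_response(
    amplitudes: Sequence[float] = (0.0, 1.0, 2.0),
    seed: int = 0,
    **overrides,
) -> "pd.DataFrame":
    """Run the demixing scenario across field amplitudes with a matched seed.

    For each amplitude the same seed (hence the same noise stream and
    initial placement) is used; the returned frame has one row per
    amplitude with

    * ``demix_tail`` — demixing index (solute vs ethanol) averaged over the
      last quarter of frames, measured along y, perpendicular to the field
      so coherent sloshing does not masquerade as mixing;
    * ``ss_tail_energy`` — tail-mean solute-solute interaction energy
      (Coul-SR + LJ-SR) over the last quarter of the energy series;
    * ``final_demix`` — same index on the final frame alone.
    """
    from .md import demixing_index, density_profile, pair_energy

    rows = []
    for amp in amplitudes:
        spec = demixing_sim_spec(field_amplitude=amp, seed=seed, **overrides)
        frames, energies = toy_simulate(spec)
        tail = frames[-max(1, len(frames) // 4):]
        demix = float(np.mean([
            demixing_index(density_profile(f, "y", 8), "solute", "ethanol")
            for f in tail
        ]))
        final = demixing_index(density_profile(frames[-1], "y", 8),
                               "solute", "ethanol")
        _, ss_tail = pair_energy(energies, "solute-solute")
        rows.append({"amplitude": amp, "demix_tail": demix,
                     "final_demix": final, "ss_tail_energy": ss_tail})
    return pd.DataFrame(rows)


def pair_potential(r: float, eps_attr: float, qq: float,
                   spec: ToySimSpec) -> tuple[float, float]:
    """Closed-form (u_LJ, u_Coul) of one particle pair at distance r.

    The Lennard-Jones-type term is a soft-core generalised LJ,
    u = 4*(eps_rep*s^12 - eps_ab*s^6) with s^2 = sigma^2/(r^2 + delta^2)
    (delta = soft core), truncated at the cutoff and energy-shifted so it
    vanishes there; the screened-charge term is
    k_c*q_i*q_j*exp(-r_eff/L)/r_eff, truncated at the same cutoff.
    Reference implementation used by the simulator kernel and the tests.
    """
    if r > spec.cutoff:
        return 0.0, 0.0
    delta = spec.soft_core if spec.soft_core is not None else spec.sigma_lj
    s2 = spec.sigma_lj ** 2 / (r * r + delta * delta)
    s6 = s2 ** 3
    s2c = spec.sigma_lj ** 2 / (spec.cutoff ** 2 + delta * delta)
    s6c = s2c ** 3
    u_lj = 4.0 * (spec.repulsion * s6 * s6 - eps_attr * s6) \
        - 4.0 * (spec.repulsion * s6c * s6c - eps_attr * s6c)
    r_eff = math.sqrt(r * r + delta * delta)
    u_c = spec.coulomb_coupling * qq * math.exp(-r_eff / spec.screening_length) / r_eff
    return u_lj, u_c


def _pair_tables(spec: ToySimSpec, species: np.ndarray):
    """Per-particle interaction tables and species-pair slot bookkeeping."""
    names = sorted(spec.counts)
    idx = {s: i for i, s in enumerate(names)}
    si = np.array([idx[s] for s in species], dtype=np.int64)
    eps_sp = np.array([[spec.eps(a, b) for b in names] for a in names])
    # per-particle charges: round-robin dissociation states where given
    q_particle = np.array([spec.charge.get(s, 0.0) for s in species])
    if spec.charge_levels:
        for s, levels in spec.charge_levels.items():
            sel = np.flatnonzero(species == s)
            q_particle[sel] = np.asarray(levels)[np.arange(len(sel)) % len(levels)]
    n_sp = len(names)
    # species-pair -> slot index (unordered)
    slot_of = np.zeros((n_sp, n_sp), dtype=np.int64)
    pair_keys = []
    for i, a in enumerate(names):
        for j in range(i, n_sp):
            slot = len(pair_keys)
            slot_of[i, j] = slot_of[j, i] = slot
            pair_keys.append(f"{a}-{names[j]}")
    return si, eps_sp, q_particle, slot_of, pair_keys


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba ships with the target stack
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=False)
def _kernel(pos, box, si, eps_sp, qp, slot_of, n_slots, sigma, delta, cutoff,
            eps_rep, kc, screen_len):  # pragma: no cover - exercised via wrapper
    """Pair forces plus per-species-pair LJ/Coulomb energy sums."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    e_lj = np.zeros(n_slots)
    e_c = np.zeros(n_slots)
    cutoff2 = cutoff * cutoff
    d2 = delta * delta
    s2c = sigma * sigma / (cutoff2 + d2)
    s6c = s2c * s2c * s2c
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            a, b = si[i], si[j]
            eps_ab = eps_sp[a, b]
            qq = qp[i] * qp[j]
            u = r2 + d2
            s2 = sigma * sigma / u
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            # du/d(r^2) of the generalised LJ
            g = (-24.0 * eps_rep * s12 + 12.0 * eps_ab * s6) / u
            r_eff = math.sqrt(u)
            kq = kc * qq
            if kq != 0.0:
                screen = math.exp(-r_eff / screen_len)
                g += kq * screen * (-(r_eff / screen_len) - 1.0) / (2.0 * u * r_eff)
                e_c[slot_of[a, b]] += kq * screen / r_eff
            fx = -2.0 * g * dx
            fy = -2.0 * g * dy
            fz = -2.0 * g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            shift = 4.0 * (eps_rep * s6c * s6c - eps_ab * s6c)
            e_lj[slot_of[a, b]] += 4.0 * (eps_rep * s12 - eps_ab * s6) - shift
    return forces, e_lj, e_c


def toy_simulate(spec: ToySimSpec) -> tuple[list[ParticleFrame], EnergySeries]:
    """Run the overdamped Langevin toy simulation.

    Update rule per particle: x <- x + dt*(F_pair + q*E(t)*e_axis)
    + sqrt(2*T*dt)*Normal(0,1), with periodic wrapping.  Frames and
    per-species-pair energy sums (split into "LJ-SR" and "Coul-SR" terms so
    :mod:`sonocryst.md` consumes them unchanged) are logged every
    ``sample_every`` steps plus the final step.  Fully reproducible from the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.counts)
    species = np.concatenate([
        np.full(spec.counts[s], s, dtype=object) for s in names
    ]).astype(str)
    n = len(species)
    box = np.asarray(spec.box, dtype=float)
    if spec.initial_positions is not None:
        pos = np.array(spec.initial_positions, dtype=float).reshape(n, 3)
        if np.any(pos < 0) or np.any(pos >= box):
            raise ValueError("initial_positions must lie in [0, box)")
    else:
        pos = rng.uniform(0.0, box, size=(n, 3))
    # resolve exact overlaps (measure-zero but cheap to guard) by jitter
    for _ in range(3 if spec.initial_positions is None else 0):
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(r2, np.inf)
        clash = np.unique(np.where(r2 < 1e-8)[0])
        if len(clash) == 0:
            break
        pos[clash] = np.mod(pos[clash] + rng.normal(0, 0.05, (len(clash), 3)), box)
        pos[pos >= box[None, :]] = 0.0

    si, eps_sp, q_particle, slot_of, pair_keys = _pair_tables(spec, species)
    delta = spec.soft_core if spec.soft_core is not None else spec.sigma_lj
    axis = {"x": 0, "y": 1, "z": 2}[
        spec.field_pulse.axis if spec.field_pulse is not None else "x"]
    noise_scale = math.sqrt(2.0 * spec.temperature * spec.dt)
    half_min_box = 0.5 * float(box.min())

    def eval_pairs():
        return _kernel(pos, box, si, eps_sp, q_particle, slot_of,
                       len(pair_keys), spec.sigma_lj, delta, spec.cutoff,
                       spec.repulsion, spec.coulomb_coupling,
                       spec.screening_length)

    frames: list[ParticleFrame] = []
    times: list[float] = []
    energy_rows: dict[tuple[str, str], list[float]] = {
        (key, term): [] for key in pair_keys for term in ("LJ-SR", "Coul-SR")
    }

    def log_sample(t, e_lj, e_c) -> None:
        frames.append(ParticleFrame(positions=pos.copy(),
                                    species=species.copy(), box=box.copy()))
        times.append(t)
        for slot, key in enumerate(pair_keys):
            energy_rows[(key, "LJ-SR")].append(float(e_lj[slot]))
            energy_rows[(key, "Coul-SR")].append(float(e_c[slot]))

    for step in range(spec.n_steps):
        t = step * spec.dt
        forces, e_lj, e_c = eval_pairs()
        if step % spec.sample_every == 0:
            log_sample(t, e_lj, e_c)
        e_now = 0.0
        if spec.field_pulse is not None:
            e_now = field_at(spec.field_pulse, t)
            forces[:, axis] += q_particle * e_now
        max_step = float(np.abs(forces).max()) * spec.dt
        if max_step > half_min_box:
            raise RuntimeError(
                f"step-size error: |F|*dt = {max_step:.3g} nm exceeds half "
                f"the box at step {step}; reduce dt or soften the potential"
            )
        pos += spec.dt * forces
        # local heating: dissipated field power adds to a charged particle's
        # noise temperature
        t_eff = spec.temperature + spec.field_heating * (q_particle * e_now) ** 2
        if np.any(t_eff > 0):
            sd = np.sqrt(2.0 * t_eff * spec.dt)
            pos += sd[:, None] * rng.standard_normal((n, 3))
        pos = np.mod(pos, box)
        pos[pos >= box[None, :]] = 0.0  # mod can round up to the box edge

    _, e_lj, e_c = eval_pairs()
    log_sample(spec.n_steps * spec.dt, e_lj, e_c)
    series = EnergySeries(
        time=np.asarray(times),
        columns={k: np.asarray(v) for k, v in energy_rows.items()},
        metadata={"spec": repr(spec), "seed": spec.seed,
                  "units": "kJ/mol-labelled toy energy units"},
    )
    return frames, series
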