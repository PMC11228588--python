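"""Post-processing of MD-style outputs.

Consumes the two artefacts a GROMACS-style workflow leaves behind — XVG
energy tables from ``gmx energy`` and GRO coordinate frames — and computes
the analyses the oiling-out mechanism study needs:

* per-group-pair interaction energies as the sum Coul-SR + LJ-SR (kJ/mol),
  with a steady-state tail mean;
* axis density profiles per species;
* a demixing index (half total-variation distance between two species'
  normalised axis distributions) quantifying phase separation;
* distance-cutoff single-linkage clustering with periodic minimum image;
* onset detection on particle-count series (FBRM-like signals).

Boxes are orthorhombic and periodic; triclinic boxes are rejected.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "EnergySeries", "ParticleFrame", "DensityProfile", "ClusterSet",
    "read_energy_table", "write_energy_table", "pair_energy",
    "density_profile", "demixing_index", "cluster_by_cutoff", "onset_time",
    "read_gro", "write_gro",
]

ENERGY_TERMS = ("Coul-SR", "LJ-SR")

#: GRO residue-name <-> species mapping used by the toy pipeline.
RESNAME_TO_SPECIES = {"FDP": "solute", "ETH": "ethanol", "SOL": "water",
                      "ION": "ion", "NA": "ion"}
SPECIES_TO_RESNAME = {"solute": "FDP", "ethanol": "ETH", "water": "SOL",
                      "ion": "ION"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EnergySeries:
    """Time series of per-group-pair energy terms (kJ/mol).

    ``columns`` maps (group_pair, term) -> array, term in {"Coul-SR",
    "LJ-SR"}; legends that do not parse as term:pair are kept verbatim in
    ``other``.
    """

    time: np.ndarray  # ps, strictly increasing
    columns: dict[tuple[str, str], np.ndarray]
    other: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for key, col in {**self.columns, **self.other}.items():
            if len(col) != len(self.time):
                raise ValueError(f"column {key} length mismatch")

    @property
    def pairs(self) -> list[str]:
        return sorted({p for p, _ in self.columns})


@dataclass
class ParticleFrame:
    """One coordinate frame: positions (nm), per-particle species, periodic
    orthorhombic box (nm).  Positions must be wrapped into [0, box)."""

    positions: np.ndarray  # (n, 3)
    species: np.ndarray    # (n,) str labels
    box: np.ndarray        # (3,)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("frame must contain at least one particle")
        if len(self.species) != len(self.positions):
            raise ValueError("species/positions length mismatch")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (orthorhombic)")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box):
            raise ValueError("positions not wrapped into [0, box); wrap first")

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class DensityProfile:
    """Per-species number density (count/nm^3) binned along one box axis."""

    axis: str
    bin_edges: np.ndarray                 # nm, len n_bins + 1
    density: dict[str, np.ndarray]        # species -> (n_bins,) count/nm^3
    counts: dict[str, np.ndarray]         # species -> raw counts
    bin_volume: float                     # nm^3

    def probability(self, species: str) -> np.ndarray:
        """Bin-probability vector of one species (counts normalised to 1)."""
        c = self.counts[species].astype(float)
        total = c.sum()
        if total == 0:
            raise ValueError(f"species {species!r} has no particles in profile")
        return c / total


@dataclass
class ClusterSet:
    """Single-linkage clusters of one species under a distance cutoff."""

    labels: np.ndarray        # per selected particle, cluster id
    sizes: np.ndarray         # size per cluster id
    cutoff: float             # nm
    species: str
    indices: np.ndarray       # original particle indices of the selection

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest(self) -> int:
        return int(self.sizes.max()) if len(self.sizes) else 0


# ---------------------------------------------------------------------------
# XVG energy tables
# ---------------------------------------------------------------------------

_LEGEND_RE = re.compile(r'@\s*s(\d+)\s+legend\s+"([^"]*)"')


def _parse_legend(legend: str) -> tuple[str, str] | None:
    """Split 'Coul-SR:FDP-FDP' into ('FDP-FDP', 'Coul-SR'); None if foreign."""
    if ":" in legend:
        term, _, pair = legend.partition(":")
        if term in ENERGY_TERMS:
            return pair, term
    return None


def read_energy_table(path: str | Path) -> EnergySeries:
    """Read an XVG-dialect energy table ('#' comments, '@' directives).

    Legends of the form ``<term>:<pair>`` with term Coul-SR or LJ-SR become
    mapped columns; other legends are preserved verbatim under ``other``.
    Files without legends fall back to columns named col1..colN.
    """
    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    title = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            m = _LEGEND_RE.match(line)
            if m:
                legends[int(m.group(1))] = m.group(2)
            elif "title" in line:
                title = line
            continue
        try:
            vals = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: unparseable row: {line!r}") from exc
        if rows and len(vals) != len(rows[0]):
            raise ValueError(
                f"{path}: line {lineno}: ragged row ({len(vals)} fields, "
                f"expected {len(rows[0])})"
            )
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty data section")
    data = np.asarray(rows)
    time, ycols = data[:, 0], data[:, 1:]

    columns: dict[tuple[str, str], np.ndarray] = {}
    other: dict[str, np.ndarray] = {}
    for j in range(ycols.shape[1]):
        legend = legends.get(j)
        if legend is None:
            other[f"col{j + 1}"] = ycols[:, j]
            continue
        parsed = _parse_legend(legend)
        if parsed is None:
            other[legend] = ycols[:, j]
        else:
            columns[parsed] = ycols[:, j]
    meta = {"path": str(path)}
    if title:
        meta["title"] = title
    return EnergySeries(time=time, columns=columns, other=other, metadata=meta)


def write_energy_table(series: EnergySeries, path: str | Path,
                       title: str = "Energies") -> Path:
    """Write an EnergySeries in the XVG dialect ``read_energy_table`` reads."""
    path = Path(path)
    keys = list(series.columns) + list(series.other)
    lines = [f'@    title "{title}"',
             '@    xaxis  label "Time (ps)"',
             '@    yaxis  label "(kJ/mol)"']
    for j, key in enumerate(keys):
        legend = f"{key[1]}:{key[0]}" if isinstance(key, tuple) else key
        lines.append(f'@ s{j} legend "{legend}"')
    cols = [series.columns.get(k, series.other.get(k)) for k in keys]
    for i, t in enumerate(series.time):
        vals = " ".join(f"{c[i]:.10g}" for c in cols)
        lines.append(f"{t:.10g} {vals}")
    path.write_text("\n".join(lines) + "\n")
    return path


def pair_energy(series: EnergySeries, pair: str,
                tail_fraction: float = 0.25) -> tuple[np.ndarray, float]:
    """Total interaction energy of a group pair: Coul-SR + LJ-SR (kJ/mol).

    Returns the summed series and its mean over the final ``tail_fraction``
    of frames (steady-state estimate).  A missing term raises; it is never
    silently treated as zero.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    missing = [t for t in ENERGY_TERMS if (pair, t) not in series.columns]
    if missing:
        raise KeyError(f"pair {pair!r}: missing term(s) {missing} in energy table")
    total = series.columns[(pair, "Coul-SR")] + series.columns[(pair, "LJ-SR")]
    n_tail = int(math.ceil(tail_fraction * len(total)))
    return total, float(total[-n_tail:].mean())


# ---------------------------------------------------------------------------
# Frames: density, demixing, clustering
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def density_profile(frame: ParticleFrame, axis: str = "x",
                    n_bins: int = 20) -> DensityProfile:
    """Per-species number density along a box axis.

    Uniform half-open bins [edge_i, edge_{i+1}) over [0, L_axis); density is
    count / (bin_width * cross-section area) so summed density * bin volume
    returns the exact per-species particle count.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ax = _AXES[axis]
    length = frame.box[ax]
    edges = np.linspace(0.0, length, n_bins + 1)
    cross_section = float(np.prod(np.delete(frame.box, ax)))
    bin_volume = (length / n_bins) * cross_section
    coords = frame.positions[:, ax]
    # positions invariant guarantees [0, L); floor gives half-open binning
    idx = np.minimum((coords / (length / n_bins)).astype(int), n_bins - 1)
    counts: dict[str, np.ndarray] = {}
    density: dict[str, np.ndarray] = {}
    for sp in np.unique(frame.species):
        c = np.bincount(idx[frame.species == sp], minlength=n_bins).astype(float)
        counts[str(sp)] = c
        density[str(sp)] = c / bin_volume
    return DensityProfile(axis=axis, bin_edges=edges, density=density,
                          counts=counts, bin_volume=bin_volume)


def demixing_index(profile: DensityProfile, species_a: str,
                   species_b: str) -> float:
    """Half total-variation distance between two species' axis distributions.

    d = 0.5 * sum_bins |p_a - p_b| with p_s the species' bin-probability
    vector.  d = 0 for identical distributions, 1 for disjoint support;
    symmetric in its arguments.
    """
    for sp in (species_a, species_b):
        if sp not in profile.counts:
            raise ValueError(f"species {sp!r} absent from profile")
    p_a = profile.probability(species_a)
    p_b = profile.probability(species_b)
    return float(0.5 * np.abs(p_a - p_b).sum())


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> float:
    """Periodic minimum-image distance between two points (orthorhombic)."""
    d = np.abs(np.asarray(a) - np.asarray(b))
    d = np.minimum(d, box - d)
    return float(np.sqrt((d * d).sum()))


def cluster_by_cutoff(frame: ParticleFrame, species: str,
                      cutoff: float) -> ClusterSet:
    """Single-linkage clusters of one species under a periodic distance cutoff.

    Two particles are linked when their minimum-image distance <= cutoff;
    clusters are the connected components, with ids assigned in order of the
    lowest original particle index they contain (deterministic).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sel = np.flatnonzero(frame.species == species)
    if len(sel) == 0:
        return ClusterSet(labels=np.empty(0, int), sizes=np.empty(0, int),
                          cutoff=cutoff, species=species, indices=sel)
    pos = frame.positions[sel]
    tree = cKDTree(pos, boxsize=frame.box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    n = len(sel)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        _, raw = connected_components(adj, directed=False)
    else:
        raw = np.arange(n)
    # relabel so ids follow the lowest member index
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel)
        labels[i] = relabel[c]
    sizes = np.bincount(labels)
    return ClusterSet(labels=labels, sizes=sizes, cutoff=cutoff,
                      species=species, indices=sel)


# ---------------------------------------------------------------------------
# Onset detection on count series
# ---------------------------------------------------------------------------

def onset_time(counts: Sequence[float], times: Sequence[float] | None = None,
               k: float = 5.0, m: int = 3,
               baseline_fraction: float = 0.10) -> float | int | None:
    """First sustained excursion of a count signal above its baseline.

    The baseline is the first ``baseline_fraction`` of the series; onset is
    the first index whose value exceeds baseline_mean + k * baseline_sd for
    ``m`` consecutive samples.  Returns the onset time (or index when no
    times are given); None when the rule is never satisfied.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n = len(c)
    n_base = int(math.floor(baseline_fraction * n))
    if n_base < 2 or n <= n_base:
        raise ValueError(
            f"series of length {n} shorter than usable baseline window"
        )
    mean = c[:n_base].mean()
    sd = c[:n_base].std(ddof=0)
    above = c > mean + k * sd
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= m:
            onset_idx = i - m + 1
            return (times[onset_idx] if times is not None else onset_idx)
    return None


# ---------------------------------------------------------------------------
# GRO frame I/O (via MDAnalysis; nm <-> Angstrom handled here)
# ---------------------------------------------------------------------------

def read_gro(path: str | Path) -> ParticleFrame:
    """Read a GRO coordinate file into a ParticleFrame (positions in nm).

    Species are inferred from residue names (FDP/ETH/SOL/ION); unknown
    residue names become lowercase species labels.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    box = u.dimensions[:3] / 10.0  # Angstrom -> nm
    pos = u.atoms.positions / 10.0
    pos = np.mod(pos, box)  # GRO files may hold slightly unwrapped coords
    pos[pos >= box[None, :]] = 0.0
    species = np.array([
        RESNAME_TO_SPECIES.get(rn.upper(), rn.lower())
        for rn in u.atoms.resnames
    ])
    return ParticleFrame(positions=pos, species=species, box=np.asarray(box))


def write_gro(frame: ParticleFrame, path: str | Path,
              title: str = "sonocryst frame") -> Path:
    """Write a ParticleFrame as a GRO file (one atom per particle)."""
    import MDAnalysis as mda

    n = frame.n
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int),
                           trajectory=True)
    resnames = [SPECIES_TO_RESNAME.get(str(sp), str(sp)[:4].upper())
                for sp in frame.species]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("names", [rn[:1] for rn in resnames])
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))
    return Path(path)
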