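"""Domain types and file I/O for conjugate-ensemble analyses.

Containers
----------
:class:`Trajectory` holds per-snapshot coordinates over a shared atom
table; :class:`SelectionSet` names the atom groups every downstream
analysis operates on (chromophore rings, backbone fit atoms, H-bond
triples).  :class:`TransitionRecord` carries one vertical electronic
transition of one chromophore in one snapshot — the interface between
the (external or synthetic) excited-state calculations and the
photophysics here.

Formats
-------
Geometries: multi-model PDB (via biotite) and multi-frame XYZ.
Transitions: CSV with columns
``frame,chromophore,kind,state,energy_ev,osc_strength,mu_x,mu_y,mu_z``.
Cluster summaries: TSV in the conventional FRET-table column order.
Configuration: YAML mirroring :class:`PhotophysicsConfig`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import FORSTER_PREFACTOR, wavelength_nm_from_ev

__all__ = [
    "Frame",
    "Trajectory",
    "SelectionSet",
    "TransitionRecord",
    "PhotophysicsConfig",
    "FRETSnapshotResult",
    "SpectrumProfile",
    "ClusterSummary",
    "read_frames",
    "write_frames",
    "read_transitions",
    "write_transitions",
    "write_summary_table",
    "read_config",
    "write_config",
]

SUMMARY_FIELDS = ("r", "kappa2", "R0", "efficiency", "k_T_rel", "k_r")


class ValidationError(ValueError):
    """Input fails a domain invariant."""


# ---------------------------------------------------------------------------
# Geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """One snapshot: 0-based index, time in ps, (n_atoms, 3) coords in A."""

    index: int
    time: float
    coords: np.ndarray


class Trajectory:
    """Ordered snapshots over a shared atom table.

    Parameters
    ----------
    atoms:
        DataFrame with columns ``name, element, res_id, res_name, chain``,
        one row per atom, shared by every frame.
    coords:
        Array of shape (n_frames, n_atoms, 3), Angstrom.
    times:
        Per-frame times in ps, non-decreasing.  Defaults to the frame
        index (one arbitrary time unit per snapshot) when the source
        format carries no time information.
    """

    ATOM_COLUMNS = ("name", "element", "res_id", "res_name", "chain")

    def __init__(self, atoms: pd.DataFrame, coords: np.ndarray,
                 times: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        if len(atoms) != coords.shape[1]:
            raise ValidationError(
                f"atom table has {len(atoms)} rows but coords have "
                f"{coords.shape[1]} atoms")
        for col in self.ATOM_COLUMNS:
            if col not in atoms.columns:
                raise ValidationError(f"atom table missing column {col!r}")
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValidationError("times must have one entry per frame")
        if np.any(np.diff(times) < 0):
            raise ValidationError("times must be non-decreasing")
        self.atoms = atoms.reset_index(drop=True)
        self.coords = coords
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(index=i, time=float(self.times[i]), coords=self.coords[i])

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def __repr__(self) -> str:
        return f"<Trajectory: {self.n_frames} frames, {self.n_atoms} atoms>"


@dataclass
class SelectionSet:
    """Named 0-based atom-index selections over a trajectory's atom table.

    ``donor_center``/``acceptor_center`` default to the ring selections:
    the donor-acceptor distance is measured between the geometric centers
    of the chromophore ring atoms unless overridden.
    """

    donor_ring: list[int] = field(default_factory=list)
    acceptor_ring: list[int] = field(default_factory=list)
    backbone_fit: list[int] = field(default_factory=list)
    donor_center: list[int] | None = None
    acceptor_center: list[int] | None = None
    extra: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.donor_center is None:
            self.donor_center = list(self.donor_ring)
        if self.acceptor_center is None:
            self.acceptor_center = list(self.acceptor_ring)
        for nm, sel in self.items():
            if len(set(sel)) != len(sel):
                raise ValidationError(f"selection {nm!r} repeats an index")

    def items(self):
        yield "donor_ring", self.donor_ring
        yield "acceptor_ring", self.acceptor_ring
        yield "backbone_fit", self.backbone_fit
        yield "donor_center", self.donor_center
        yield "acceptor_center", self.acceptor_center
        for nm, sel in self.extra.items():
            yield nm, sel

    def validate(self, n_atoms: int) -> None:
        for nm, sel in self.items():
            arr = np.asarray(sel, dtype=int)
            if arr.size and (arr.min() < 0 or arr.max() >= n_atoms):
                raise ValidationError(
                    f"selection {nm!r} has indices outside [0, {n_atoms})")

    def to_dict(self) -> dict:
        d = {nm: list(map(int, sel)) for nm, sel in self.items()
             if nm not in ("donor_center", "acceptor_center")}
        if self.donor_center != self.donor_ring:
            d["donor_center"] = list(map(int, self.donor_center))
        if self.acceptor_center != self.acceptor_ring:
            d["acceptor_center"] = list(map(int, self.acceptor_center))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionSet":
        known = {"donor_ring", "acceptor_ring", "backbone_fit",
                 "donor_center", "acceptor_center"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extra = {k: v for k, v in d.items() if k not in known}
        return cls(extra=extra, **kwargs)


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionRecord:
    """One vertical electronic transition of one chromophore in one frame.

    ``kind`` is ``"absorption"`` (S0 -> Si) or ``"emission"``; emission
    records describe the S1 -> S0 transition only.  Energy in eV, dipole
    in Debye.
    """

    frame_index: int
    chromophore: str
    kind: str
    state_label: str
    energy_ev: float
    osc_strength: float
    dipole: tuple[float, float, float]

    def __post_init__(self):
        if self.kind not in ("absorption", "emission"):
            raise ValidationError(f"unknown transition kind {self.kind!r}")
        if not self.energy_ev > 0:
            raise ValidationError(f"energy must be > 0 eV, got {self.energy_ev}")
        if self.osc_strength < 0:
            raise ValidationError(
                f"oscillator strength must be >= 0, got {self.osc_strength}")
        if self.kind == "emission" and self.state_label.upper() != "S1":
            raise ValidationError(
                f"emission records must be S1->S0, got state {self.state_label!r}")

    @property
    def wavelength_nm(self) -> float:
        return wavelength_nm_from_ev(self.energy_ev)

    @property
    def dipole_vector(self) -> np.ndarray:
        return np.asarray(self.dipole, dtype=float)

    @property
    def dipole_magnitude(self) -> float:
        return float(np.linalg.norm(self.dipole))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PhotophysicsConfig:
    """Photophysical parameters of the donor-acceptor pair.

    q_d : donor fluorescence quantum yield (dimensionless).
    j_overlap : spectral overlap integral J, nm^4 M^-1 cm^-1.
    refractive_index : medium refractive index n (aqueous buffer default).
    fwhm_ev / bin_width_ev : Gaussian broadening and energy binning of
        assembled ensemble spectra.
    delta_e_cutoff_ev : maximum donor-emission/acceptor-absorption energy
        gap accepted when selecting the resonant acceptor transition.
    forster_constant_mode : "eq3" (0.211 sixth-root prefactor) or "eq4"
        (8.79e-5 sixth-power prefactor); both printed conventions of the
        same constant, differing ~0.07% in R0.
    distance_threshold : donor-acceptor distance (A) above which the
        point-dipole approximation is considered valid; defines the
        far-cluster pool in summaries.
    """

    q_d: float = 0.099
    j_overlap: float = 1.044e15
    refractive_index: float = 1.333
    fwhm_ev: float = 0.04
    bin_width_ev: float = 0.01
    delta_e_cutoff_ev: float = 0.75
    forster_constant_mode: str = "eq4"
    distance_threshold: float = 20.0

    _MODE_ALIASES = {"eq3": "eq3", "eq3_0211": "eq3",
                     "eq4": "eq4", "eq4_879e-5": "eq4"}

    def __post_init__(self):
        for nm in ("q_d", "j_overlap", "refractive_index", "fwhm_ev",
                   "bin_width_ev", "delta_e_cutoff_ev", "distance_threshold"):
            if not getattr(self, nm) > 0:
                raise ValidationError(f"{nm} must be positive")
        try:
            self.forster_constant_mode = self._MODE_ALIASES[self.forster_constant_mode]
        except KeyError:
            raise ValidationError(
                f"forster_constant_mode must be one of "
                f"{sorted(self._MODE_ALIASES)}, got {self.forster_constant_mode!r}")

    @property
    def forster_prefactor(self) -> float:
        return FORSTER_PREFACTOR[self.forster_constant_mode]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FRETSnapshotResult:
    """Per-snapshot FRET quantities.

    ``k_T_rel = kappa2 / r^6`` (relative units, A^-6); ``k_r`` is the
    Einstein A coefficient of the donor emission (s^-1).  Frames where no
    acceptor transition qualified carry NaN FRET fields and a ``None``
    ``selected_acceptor_state``.
    """

    frame_index: int
    r: float
    kappa2: float = np.nan
    theta_T: float = np.nan
    theta_D: float = np.nan
    theta_A: float = np.nan
    R0: float = np.nan
    efficiency: float = np.nan
    k_T_rel: float = np.nan
    k_r: float = np.nan
    selected_acceptor_state: str | None = None

    @property
    def has_fret(self) -> bool:
        return self.selected_acceptor_state is not None


@dataclass
class SpectrumProfile:
    """Broadened ensemble spectrum on parallel wavelength/energy grids."""

    wavelength_nm: np.ndarray
    energy_ev: np.ndarray
    intensity: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.asarray(self.intensity) < -1e-12):
            raise ValidationError("spectrum intensity must be non-negative")

    def energy_axis_area(self) -> float:
        order = np.argsort(self.energy_ev)
        return float(np.trapezoid(self.intensity[order], self.energy_ev[order]))

    def wavelength_axis_area(self) -> float:
        order = np.argsort(self.wavelength_nm)
        return float(np.trapezoid(self.intensity[order], self.wavelength_nm[order]))


@dataclass
class ClusterSummary:
    """One row of the cluster FRET table: counts plus mean +/- SD of the
    per-snapshot quantities (population standard deviations)."""

    cluster_id: str
    n_snapshots: int
    fraction: float
    mean: dict[str, float]
    sd: dict[str, float]


# ---------------------------------------------------------------------------
# Geometry I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("pdb", "xyz"):
            raise ValueError(f"unknown trajectory format {fmt!r} (pdb|xyz)")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer trajectory format from {path.name!r}; "
                     "pass format='pdb' or 'xyz'")


def read_frames(path, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file into a Trajectory.

    PDB MODEL numbers (1-based on disk) become 0-based frame indices.
    Raises a parse error naming the offending model/frame when atom
    counts differ between snapshots.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    return _read_xyz(path)


def _read_pdb(path: Path) -> Trajectory:
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged models
        raise ValidationError(
            f"{path.name}: inconsistent models in multi-model PDB "
            f"({exc})") from exc
    atoms = pd.DataFrame({
        "name": stack.atom_name,
        "element": stack.element,
        "res_id": stack.res_id.astype(int),
        "res_name": stack.res_name,
        "chain": stack.chain_id,
    })
    return Trajectory(atoms, np.asarray(stack.coord, dtype=float))


def _read_xyz(path: Path) -> Trajectory:
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValidationError(
                f"{path.name}: frame {frame_no}: expected atom count, "
                f"got {lines[pos]!r}") from exc
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise ValidationError(
                f"{path.name}: frame {frame_no} truncated "
                f"({len(block)}/{n} atom lines)")
        elems, xyz = [], []
        for ln in block:
            parts = ln.split()
            elems.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = elems
        elif elems != elements:
            raise ValidationError(
                f"{path.name}: frame {frame_no} has a different atom list "
                f"than frame 0 ({len(elems)} vs {len(elements)} atoms)")
        frames.append(np.asarray(xyz))
        pos += 2 + n
        frame_no += 1
    if not frames:
        raise ValidationError(f"{path.name}: no frames found")
    atoms = pd.DataFrame({
        "name": [f"{el}{i + 1}" for i, el in enumerate(elements)],
        "element": elements,
        "res_id": np.ones(len(elements), dtype=int),
        "res_name": ["UNK"] * len(elements),
        "chain": ["A"] * len(elements),
    })
    return Trajectory(atoms, np.stack(frames))


def write_frames(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a Trajectory as multi-model PDB or multi-frame XYZ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    else:
        _write_xyz(traj, path)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coords
    stack.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
    stack.element = traj.atoms["element"].to_numpy(dtype="U2")
    stack.res_id = traj.atoms["res_id"].to_numpy(dtype=int)
    stack.res_name = traj.atoms["res_name"].to_numpy(dtype="U5")
    stack.chain_id = traj.atoms["chain"].to_numpy(dtype="U4")
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _write_xyz(traj: Trajectory, path: Path) -> None:
    elements = traj.atoms["element"].tolist()
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {fr.index} t={fr.time:.3f} ps\n")
            for el, (x, y, z) in zip(elements, fr.coords):
                fh.write(f"{el:<3s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


# ---------------------------------------------------------------------------
# Transition tables
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = ["frame", "chromophore", "kind", "state",
                      "energy_ev", "osc_strength", "mu_x", "mu_y", "mu_z"]


def read_transitions(path) -> list[TransitionRecord]:
    """Read a transition-table CSV; validation errors carry the CSV row."""
    df = pd.read_csv(path)
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{Path(path).name}: missing transition columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(TransitionRecord(
                frame_index=int(row.frame),
                chromophore=str(row.chromophore),
                kind=str(row.kind),
                state_label=str(row.state),
                energy_ev=float(row.energy_ev),
                osc_strength=float(row.osc_strength),
                dipole=(float(row.mu_x), float(row.mu_y), float(row.mu_z)),
            ))
        except ValidationError as exc:
            raise ValidationError(
                f"{Path(path).name}, data row {i + 1}: {exc}") from exc
    return records


def write_transitions(records: list[TransitionRecord], path) -> None:
    df = pd.DataFrame(
        [(r.frame_index, r.chromophore, r.kind, r.state_label, r.energy_ev,
          r.osc_strength, *r.dipole) for r in records],
        columns=TRANSITION_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def write_summary_table(summaries: list[ClusterSummary], path) -> None:
    """Write cluster summaries as TSV in the conventional column order.

    Per-cluster rows are ordered by descending snapshot count; pooled
    rows (cluster_id containing "," or named "all") follow.
    """
    single = [s for s in summaries
              if "," not in s.cluster_id and s.cluster_id != "all"]
    pooled = [s for s in summaries if s not in single]
    single.sort(key=lambda s: -s.n_snapshots)
    header = ["Cluster", "#Snapshots", "Fraction"]
    for fld, label in zip(SUMMARY_FIELDS,
                          ["<r>[A]", "<kappa2>", "<R0>[A]", "<E>",
                           "<kT_rel>", "<k_r>[s-1]"]):
        header += [label, "+/-"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s in single + pooled:
            row = [s.cluster_id, str(s.n_snapshots), f"{s.fraction:.2f}"]
            for fld in SUMMARY_FIELDS:
                row += [f"{s.mean[fld]:.6g}", f"{s.sd[fld]:.6g}"]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

def read_config(path) -> PhotophysicsConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PhotophysicsConfig)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys {sorted(unknown)}")
    return PhotophysicsConfig(**{k: v for k, v in data.items() if k in known})


def write_config(config: PhotophysicsConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
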