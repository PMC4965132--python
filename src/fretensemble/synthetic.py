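"""Synthetic two-chromophore conjugate ensembles.

Stands in for the MD + excited-state machinery so every downstream stage
(geometry analysis, clustering, spectra, FRET) is testable end-to-end.
The generator emulates the statistical structure of a dye-labeled DNA
conjugate ensemble: a dominant close-contact (pi-stacked) population and
minor solvent-separated populations of donor-acceptor distances,
isotropic or orientation-restricted transition dipoles, and acceptor
band structure with a strong high-energy (Soret-like) and a weak
low-energy (Q-like) absorption band.

All geometry is deliberately non-chemical: chromophores are rigid planar
hexagons (well-defined centroid, normal and long axis), the duplex is a
static two-strand ladder, linkers are jittered pseudo-atom chains.
Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import dipole_debye_from_osc_strength
from .ensemble_io import SelectionSet, Trajectory, TransitionRecord

__all__ = [
    "ConjugateModelParams",
    "SpectralModelParams",
    "gen_isotropic_pairs",
    "gen_conjugate_trajectory",
    "gen_transitions",
    "gen_toy_duplex",
]

HEXAGON_RADIUS = 1.39  # A, aromatic C-C ring circumradius
RISE_PER_RUNG = 3.4    # A, ladder step


@dataclass
class ConjugateModelParams:
    """Geometry-ensemble parameters.

    ``r_modes`` lists (mean A, sd A, weight) donor-acceptor distance
    populations; the default two-mode structure (10 +/- 1 A at 90%,
    30 +/- 3 A at 10%) mimics a dominant close-contact cluster plus a
    minor solvent-separated one.  ``orientation_mode`` controls the
    per-frame rigid-body orientation of each chromophore: "isotropic"
    (uniform random rotations), "cone" (long axis within
    ``cone_half_angle_deg`` of its reference direction) or "fixed".
    """

    n_frames: int = 1000
    r_modes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 1.0, 0.9), (30.0, 3.0, 0.1)])
    orientation_mode: str = "isotropic"
    cone_half_angle_deg: float = 20.0
    placement_jitter_deg: float = 15.0
    linker_length: int = 4
    n_rungs: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        w = sum(m[2] for m in self.r_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1, got {w}")
        if any(m[0] <= 0 for m in self.r_modes):
            raise ValueError("mode mean distances must be positive")
        if self.orientation_mode not in ("isotropic", "cone", "fixed"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")


@dataclass
class SpectralModelParams:
    """Band-structure parameters for synthetic vertical transitions.

    Donor: one S1 emission band (mean eV, sd eV, mean |mu| Debye).
    Acceptor: absorption bands (mean eV, sd eV, mean f); defaults give a
    Soret-like strong band at 3.0 eV and a Q-like weak band at 1.9 eV,
    placing the Q band ~0.5 eV below the 2.4 eV donor emission.
    """

    donor_emission: tuple[float, float, float] = (2.4, 0.05, 4.0)
    acceptor_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(3.0, 0.05, 1.0), (1.9, 0.05, 0.1)])
    seed: int = 0

    def __post_init__(self):
        if self.donor_emission[1] < 0 or any(b[1] < 0 for b in self.acceptor_bands):
            raise ValueError("band sds must be >= 0")
        means = [self.donor_emission[0]] + [b[0] for b in self.acceptor_bands]
        if len(set(means)) != len(means):
            raise ValueError("band means must be distinct")


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform unit vectors: normalized standard-normal triples (no
    polar-angle bias)."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _cone_vectors(rng: np.random.Generator, n: int, axis: np.ndarray,
                  half_angle_deg: float) -> np.ndarray:
    """Uniform unit vectors within a cone about ``axis``."""
    cos_max = np.cos(np.radians(half_angle_deg))
    cosang = rng.uniform(cos_max, 1.0, size=n)
    sinang = np.sqrt(1.0 - cosang ** 2)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    local = np.stack([sinang * np.cos(phi), sinang * np.sin(phi), cosang], -1)
    # rotate local z onto axis
    axis = axis / np.linalg.norm(axis)
    if abs(axis[2] - 1.0) < 1e-12:
        return local
    if abs(axis[2] + 1.0) < 1e-12:
        return local * np.array([1.0, 1.0, -1.0])
    v = np.cross([0.0, 0.0, 1.0], axis)
    s = np.linalg.norm(v)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + k + k @ k * ((1 - axis[2]) / s ** 2)
    return local @ rot.T


def _hexagon(center: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rigid planar hexagon; local frame: plane = xy, long axis = x."""
    ang = np.radians(np.arange(6) * 60.0)
    local = HEXAGON_RADIUS * np.stack(
        [np.cos(ang), np.sin(ang), np.zeros(6)], axis=-1)
    return local @ rotation.T + center


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_isotropic_pairs(n: int, r: float, seed: int = 0,
                        orientation_mode: str = "isotropic",
                        fixed_direction=(0.0, 0.0, 1.0)):
    """Point donor/acceptor pair at fixed separation with random dipoles.

    The null model behind the isotropic orientation-factor average
    <kappa^2> = 2/3: donor and acceptor unit dipoles drawn independently
    and uniformly on the sphere.  ``orientation_mode="fixed"`` pins both
    dipoles to ``fixed_direction`` instead (e.g. both perpendicular to
    the separation axis gives kappa^2 = 1 in every frame).

    Returns (trajectory, donor_dipoles (n,3), acceptor_dipoles (n,3));
    the trajectory has one donor and one acceptor pseudo-atom per frame,
    separated by ``r`` along +x.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if r <= 0:
        raise ValueError(f"separation r must be positive, got {r}")
    rng = np.random.default_rng(seed)
    if orientation_mode == "isotropic":
        mu_d = unit_sphere(rng, n)
        mu_a = unit_sphere(rng, n)
    elif orientation_mode == "fixed":
        d = np.asarray(fixed_direction, dtype=float)
        d /= np.linalg.norm(d)
        mu_d = np.tile(d, (n, 1))
        mu_a = np.tile(d, (n, 1))
    else:
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = r
    atoms = pd.DataFrame({
        "name": ["D", "A"], "element": ["X", "X"], "res_id": [1, 2],
        "res_name": ["DON", "ACC"], "chain": ["D", "A"]})
    return Trajectory(atoms, coords), mu_d, mu_a


def gen_conjugate_trajectory(params: ConjugateModelParams):
    """Synthetic conjugate ensemble with multimodal donor-acceptor distances.

    Each frame holds a static two-strand ladder scaffold, a fixed-center
    donor hexagon and an acceptor hexagon placed at a distance drawn from
    the mixture ``r_modes`` along a direction jittered within
    ``placement_jitter_deg`` of +y (a tethered-dye constraint); hexagon
    orientations follow ``orientation_mode``.  Jittered pseudo-linker
    chains connect scaffold -> donor -> acceptor.

    Returns (trajectory, selections, labels) where ``labels`` gives each
    frame's ground-truth mode index.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_frames

    weights = np.array([m[2] for m in p.r_modes])
    labels = rng.choice(len(p.r_modes), size=n, p=weights)
    means = np.array([m[0] for m in p.r_modes])
    sds = np.array([m[1] for m in p.r_modes])
    r = rng.normal(means[labels], sds[labels])
    r = np.clip(r, 0.1, None)

    directions = _cone_vectors(rng, n, np.array([0.0, 1.0, 0.0]),
                               p.placement_jitter_deg)
    donor_center = np.zeros(3)
    acceptor_centers = donor_center + r[:, None] * directions

    if p.orientation_mode == "isotropic":
        rot_d = _random_rotations(rng, n)
        rot_a = _random_rotations(rng, n)
    elif p.orientation_mode == "fixed":
        rot_d = np.tile(np.eye(3), (n, 1, 1))
        rot_a = np.tile(np.eye(3), (n, 1, 1))
    else:  # cone: long axis (local x) within cone of +x, roll random
        rot_d = _cone_axis_rotations(rng, n, p.cone_half_angle_deg)
        rot_a = _cone_axis_rotations(rng, n, p.cone_half_angle_deg)

    # static ladder scaffold well away from the chromophores
    zs = np.arange(p.n_rungs) * RISE_PER_RUNG
    strand_a = np.stack([np.full(p.n_rungs, -10.0), np.full(p.n_rungs, -2.0), zs], -1)
    strand_b = np.stack([np.full(p.n_rungs, -10.0), np.full(p.n_rungs, 2.0), zs], -1)
    scaffold = np.concatenate([strand_a, strand_b])
    anchor = strand_a[-1]

    nl = p.linker_length
    n_atoms = len(scaffold) + nl + 6 + nl + 6
    coords = np.empty((n, n_atoms, 3))
    for i in range(n):
        frac1 = np.linspace(0, 1, nl + 2)[1:-1, None]
        link1 = anchor + frac1 * (donor_center - anchor) + rng.normal(0, 0.3, (nl, 3))
        frac2 = np.linspace(0, 1, nl + 2)[1:-1, None]
        link2 = donor_center + frac2 * (acceptor_centers[i] - donor_center) \
            + rng.normal(0, 0.3, (nl, 3))
        coords[i] = np.concatenate([
            scaffold,
            link1,
            _hexagon(donor_center, rot_d[i]),
            link2,
            _hexagon(acceptor_centers[i], rot_a[i]),
        ])

    rows = []
    for s, strand in (("A", strand_a), ("B", strand_b)):
        for j in range(p.n_rungs):
            rows.append((f"P{j + 1}", "P", j + 1, "SCF", s))
    for j in range(nl):
        rows.append((f"L{j + 1}", "C", 100, "LN1", "L"))
    for j in range(6):
        rows.append((f"CD{j + 1}", "C", 101, "DON", "D"))
    for j in range(nl):
        rows.append((f"L{j + 1}", "C", 102, "LN2", "L"))
    for j in range(6):
        rows.append((f"CA{j + 1}", "C", 103, "ACC", "A"))
    atoms = pd.DataFrame(rows, columns=list(Trajectory.ATOM_COLUMNS))

    off_d = len(scaffold) + nl
    off_a = off_d + 6 + nl
    selections = SelectionSet(
        donor_ring=list(range(off_d, off_d + 6)),
        acceptor_ring=list(range(off_a, off_a + 6)),
        backbone_fit=list(range(len(scaffold))),
    )
    traj = Trajectory(atoms, coords)
    selections.validate(traj.n_atoms)
    return traj, selections, labels


def _cone_axis_rotations(rng: np.random.Generator, n: int,
                         half_angle_deg: float) -> np.ndarray:
    """Rotations whose local x axis lies within a cone of global +x."""
    axes = _cone_vectors(rng, n, np.array([1.0, 0.0, 0.0]), half_angle_deg)
    roll = rng.uniform(0, 2 * np.pi, size=n)
    out = np.empty((n, 3, 3))
    for i in range(n):
        x = axes[i]
        helper = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        y = np.cross(helper, x)
        y /= np.linalg.norm(y)
        z = np.cross(x, y)
        cr, sr = np.cos(roll[i]), np.sin(roll[i])
        out[i] = np.stack([x, cr * y + sr * z, -sr * y + cr * z], axis=-1)
    return out


def ring_axes(frame_coords: np.ndarray, ring_selection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(long_axis, in_plane_perpendicular, normal) of a hexagon ring,
    long axis pointing from centroid to the ring's first atom."""
    sel = np.asarray(ring_selection, dtype=int)
    pts = np.asarray(frame_coords)[sel]
    centroid = pts.mean(axis=0)
    long_axis = pts[0] - centroid
    long_axis /= np.linalg.norm(long_axis)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    perp = np.cross(normal, long_axis)
    perp /= np.linalg.norm(perp)
    return long_axis, perp, normal


def gen_transitions(traj: Trajectory, selections: SelectionSet,
                    params: SpectralModelParams) -> list[TransitionRecord]:
    """Synthetic vertical-transition records for every frame.

    One donor S1 emission plus one record per acceptor band per frame.
    Energies are Gaussian about the band means; dipoles lie in the
    pseudo-chromophore plane (long axis for even-indexed bands, the
    in-plane perpendicular for odd ones, mimicking orthogonal band
    polarizations); acceptor dipole magnitudes follow from each band's
    oscillator strength and sampled energy.
    """
    rng = np.random.default_rng(params.seed)
    d_mean, d_sd, d_mu = params.donor_emission
    records: list[TransitionRecord] = []
    for i in range(traj.n_frames):
        d_long, d_perp, _ = ring_axes(traj.coords[i], selections.donor_ring)
        a_long, a_perp, _ = ring_axes(traj.coords[i], selections.acceptor_ring)
        e_d = max(rng.normal(d_mean, d_sd), 0.05)
        mu_vec = d_long * d_mu
        records.append(TransitionRecord(
            frame_index=i, chromophore="donor", kind="emission",
            state_label="S1", energy_ev=e_d,
            osc_strength=0.0, dipole=tuple(mu_vec)))
        for b, (mean_e, sd_e, mean_f) in enumerate(params.acceptor_bands):
            e_a = max(rng.normal(mean_e, sd_e), 0.05)
            mu_mag = dipole_debye_from_osc_strength(mean_f, e_a) if mean_f > 0 else 0.0
            axis = a_long if b % 2 == 0 else a_perp
            records.append(TransitionRecord(
                frame_index=i, chromophore="acceptor", kind="absorption",
                state_label=f"S{b + 1}", energy_ev=e_a,
                osc_strength=mean_f, dipole=tuple(axis * mu_mag)))
    return records


def gen_toy_duplex(n_bp: int, fray_spec: dict[int, float] | None = None,
                   seed: int = 0, n_frames: int = 100):
    """Idealized ladder duplex with one pseudo Watson-Crick H-bond triple
    per base pair.

    Per pair: strand-A donor heavy atom, its hydrogen 1.0 A toward the
    strand-B acceptor heavy atom at 2.9 A (collinear D-H...A).
    ``fray_spec`` maps base-pair index -> fraction of frames in which
    that pair is open (strand-B side displaced 20 A, far beyond any
    H-bond criterion); naming a non-terminal pair is allowed but logged.

    Returns (trajectory, triples) with triples[i] = (D, H, A) atom
    indices of pair i.
    """
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    fray_spec = fray_spec or {}
    for bp in fray_spec:
        if not 0 <= bp < n_bp:
            raise ValueError(f"fray_spec pair {bp} outside [0, {n_bp})")
        if bp not in (0, n_bp - 1):
            warnings.warn(f"fray_spec opens non-terminal pair {bp}")
    rng = np.random.default_rng(seed)

    # per pair: A:D, A:H, B:A, B:C1 (a backbone-ish strand-B atom)
    base = np.zeros((n_bp * 4, 3))
    rows = []
    triples = []
    for i in range(n_bp):
        z = i * RISE_PER_RUNG
        o = i * 4
        base[o + 0] = (0.0, 0.0, z)
        base[o + 1] = (1.0, 0.0, z)
        base[o + 2] = (2.9, 0.0, z)
        base[o + 3] = (4.4, 0.0, z)
        rows += [("N1", "N", i + 1, "DA", "A"), ("H1", "H", i + 1, "DA", "A"),
                 ("N3", "N", i + 1, "DT", "B"), ("C1", "C", i + 1, "DT", "B")]
        triples.append((o, o + 1, o + 2))
    atoms = pd.DataFrame(rows, columns=list(Trajectory.ATOM_COLUMNS))

    coords = np.tile(base, (n_frames, 1, 1))
    for bp, fraction in fray_spec.items():
        open_frames = rng.random(n_frames) < fraction
        o = bp * 4
        coords[open_frames, o + 2:o + 4, 1] += 20.0
    return Trajectory(atoms, coords), triples
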