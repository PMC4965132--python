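"""Geometric trajectory analyses.

Superposition follows the two-selection protocol used throughout the
package: every frame is rigidly fitted to a single reference on the
*fit* selection (typically the duplex backbone), and metrics are then
evaluated on a separate *eval* selection (typically chromophore ring
heavy atoms) without refitting.  All RMSD/RMSF values are
mass-unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import Trajectory

__all__ = [
    "RigidTransform",
    "HBondCriteria",
    "StackingCriteria",
    "kabsch_fit",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "ring_plane",
    "stacking_series",
    "hbond_occupancy",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; maps mobile coords onto a reference."""

    rotation: np.ndarray    # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Conventional values: heavy-atom donor-acceptor distance <= 3.5 A and
    D-H...A angle >= 135 deg; a base pair counts as paired when its
    occupancy reaches ``paired_threshold``.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 135.0
    paired_threshold: float = 0.5

    def __post_init__(self):
        if not self.max_da_distance > 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class StackingCriteria:
    """Ring-ring contact: centroid distance and inter-normal angle limits."""

    max_centroid_distance: float = 4.5
    max_normal_angle: float = 30.0


class DegenerateGeometryError(ValueError):
    """Point set too small or collinear for the requested operation."""


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, ref: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Returns the proper-rotation transform mapping ``mobile`` onto ``ref``
    and the post-fit RMSD.  Reflections are excluded by flipping the sign
    of the smallest singular vector when det < 0.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and ref must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points for a rigid fit")
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    x = mobile - mc
    y = ref - rc
    if np.linalg.matrix_rank(x, tol=1e-9) < 2:
        raise DegenerateGeometryError("fit points are collinear")
    u, s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = (u @ corr @ vt).T
    transform = RigidTransform(rotation=rot, translation=rc - rot @ mc)
    fitted = transform.apply(mobile)
    return transform, rmsd(fitted, ref)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain mass-unweighted RMSD, no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _ref_coords(traj: Trajectory, ref_frame) -> np.ndarray:
    if isinstance(ref_frame, (int, np.integer)):
        return traj.coords[int(ref_frame)]
    return np.asarray(ref_frame, dtype=float)


def fit_trajectory(traj: Trajectory, ref_frame, fit_selection) -> np.ndarray:
    """Fit every frame to the reference on the fit selection.

    Returns an (n_frames, n_atoms, 3) array of transformed coordinates;
    the whole frame is moved by each frame's fit transform.
    """
    fit_sel = np.asarray(fit_selection, dtype=int)
    if fit_sel.size == 0:
        raise ValueError("fit selection is empty")
    ref = _ref_coords(traj, ref_frame)
    out = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        transform, _ = kabsch_fit(traj.coords[i][fit_sel], ref[fit_sel])
        out[i] = transform.apply(traj.coords[i])
    return out


def rmsd_series(traj: Trajectory, ref_frame, fit_selection,
                eval_selection) -> np.ndarray:
    """Per-frame RMSD on ``eval_selection`` after fitting on ``fit_selection``.

    The evaluation is done in the common reference frame without a second
    superposition, so rigid displacement of the eval atoms relative to a
    static fit scaffold shows up at full magnitude.
    """
    eval_sel = np.asarray(eval_selection, dtype=int)
    if eval_sel.size == 0:
        raise ValueError("eval selection is empty")
    ref = _ref_coords(traj, ref_frame)
    fitted = fit_trajectory(traj, ref_frame, fit_selection)
    diffs = fitted[:, eval_sel] - ref[eval_sel]
    return np.sqrt(np.mean(np.sum(diffs ** 2, axis=-1), axis=-1))


def rmsf(traj: Trajectory, ref_frame, fit_selection,
         group_by: str = "atom") -> np.ndarray:
    """Root-mean-square fluctuation about the time-averaged position.

    Frames are first fitted to the reference on ``fit_selection`` so that
    whole-body motion does not contribute.  ``group_by="residue"``
    averages atomic RMSFs over each residue (order of first appearance).
    """
    if group_by not in ("atom", "residue"):
        raise ValueError("group_by must be 'atom' or 'residue'")
    if traj.n_frames < 2:
        warnings.warn("RMSF of a single frame is identically zero")
        per_atom = np.zeros(traj.n_atoms)
    else:
        fitted = fit_trajectory(traj, ref_frame, fit_selection)
        mean_pos = fitted.mean(axis=0)
        per_atom = np.sqrt(
            np.mean(np.sum((fitted - mean_pos) ** 2, axis=-1), axis=0))
    if group_by == "atom":
        return per_atom
    res_keys = list(zip(traj.atoms["chain"], traj.atoms["res_id"]))
    seen: dict = {}
    for key in res_keys:
        seen.setdefault(key, len(seen))
    out = np.zeros(len(seen))
    counts = np.zeros(len(seen))
    for atom_i, key in enumerate(res_keys):
        g = seen[key]
        out[g] += per_atom[atom_i]
        counts[g] += 1
    return out / counts


# ---------------------------------------------------------------------------
# Ring geometry and stacking
# ---------------------------------------------------------------------------

def ring_plane(frame_coords: np.ndarray, ring_selection) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring atom set.

    The normal is the smallest-variance principal axis of the ring atoms;
    its sign is fixed toward positive z (callers needing frame-to-frame
    continuity should re-sign against the previous frame's normal).
    """
    sel = np.asarray(ring_selection, dtype=int)
    if sel.size < 3:
        raise DegenerateGeometryError("ring needs at least 3 atoms")
    pts = np.asarray(frame_coords, dtype=float)[sel]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError("ring atoms are collinear")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and (normal[1] < 0 or
                         (normal[1] == 0 and normal[0] < 0))):
        normal = -normal
    return centroid, normal


def stacking_series(traj: Trajectory, ring_a, ring_b,
                    criteria: StackingCriteria | None = None) -> np.ndarray:
    """Per-frame ring-ring geometry: centroid distance, inter-normal angle
    folded to [0, 90] deg, and the pi-stacking contact flag.

    Returns a structured array with fields ``distance``, ``angle``,
    ``contact``.  Normal signs are made continuous along the trajectory
    before the angle is computed (the fold makes the result
    sign-independent, continuity keeps raw series plottable).
    """
    criteria = criteria or StackingCriteria()
    out = np.zeros(traj.n_frames,
                   dtype=[("distance", float), ("angle", float), ("contact", bool)])
    prev_na = prev_nb = None
    for i in range(traj.n_frames):
        ca, na = ring_plane(traj.coords[i], ring_a)
        cb, nb = ring_plane(traj.coords[i], ring_b)
        if prev_na is not None and np.dot(na, prev_na) < 0:
            na = -na
        if prev_nb is not None and np.dot(nb, prev_nb) < 0:
            nb = -nb
        prev_na, prev_nb = na, nb
        dist = float(np.linalg.norm(ca - cb))
        cosang = np.clip(abs(np.dot(na, nb)), -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cosang)))  # folded to [0, 90]
        out[i] = (dist, angle,
                  dist <= criteria.max_centroid_distance
                  and angle <= criteria.max_normal_angle)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds and fraying
# ---------------------------------------------------------------------------

def hbond_occupancy(traj: Trajectory, triples, criteria: HBondCriteria | None = None,
                    pairs: dict[str, list[int]] | None = None):
    """Hydrogen-bond occupancies and per-base-pair fraying.

    Parameters
    ----------
    triples:
        list of (donor_heavy, hydrogen, acceptor_heavy) atom-index tuples.
    pairs:
        optional mapping base-pair name -> indices into ``triples``; a
        pair is *frayed* in a frame iff none of its triples is formed.
        Defaults to one pair per triple.

    Returns
    -------
    occupancy : (n_triples,) array, fraction of frames each triple is formed.
    frayed : dict pair name -> boolean (n_frames,) series, True = frayed.
    """
    criteria = criteria or HBondCriteria()
    triples = [tuple(map(int, t)) for t in triples]
    if pairs is None:
        pairs = {f"pair{j}": [j] for j in range(len(triples))}
    formed = np.zeros((traj.n_frames, len(triples)), dtype=bool)
    for j, (d, h, a) in enumerate(triples):
        dh = np.linalg.norm(traj.coords[0, h] - traj.coords[0, d])
        if dh > 1.5:
            warnings.warn(
                f"triple {j}: hydrogen {h} is {dh:.2f} A from donor {d} "
                "(> 1.5 A) — check the triple definition")
        dvec = traj.coords[:, d]
        hvec = traj.coords[:, h]
        avec = traj.coords[:, a]
        da = np.linalg.norm(avec - dvec, axis=1)
        u = dvec - hvec
        v = avec - hvec
        denom = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.where(denom > 0, np.sum(u * v, axis=1) / denom, 1.0)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        formed[:, j] = (da <= criteria.max_da_distance) & \
                       (ang >= criteria.min_dha_angle)
    occupancy = formed.mean(axis=0)
    frayed = {name: ~formed[:, idx].any(axis=1)
              for name, idx in pairs.items()}
    return occupancy, frayed
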