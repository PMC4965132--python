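"""Per-snapshot FRET quantities and cluster-level summaries.

For every snapshot: the donor-acceptor distance r between the geometric
centers of the chromophore ring atoms, the orientation factor

    kappa^2 = (cos Theta_T - 3 cos Theta_D cos Theta_A)^2,

the relative transfer rate k_T,rel = kappa^2 / r^6 (no absolute
prefactor), the per-snapshot Foerster radius

    R0^6 = C * kappa^2 * n^-4 * Q_D * J        (R0 in A for J in
                                                nm^4 M^-1 cm^-1),

the transfer efficiency E = R0^6 / (R0^6 + r^6), and the donor radiative
rate k_r (Einstein A of the S1 emission).  The acceptor transition
entering kappa^2 is chosen per frame by the resonance rule: the most
intense acceptor absorption at longer wavelength than the donor emission
and within the configured energy-difference window.
"""

from __future__ import annotations

import numpy as np

from .ensemble_io import (SUMMARY_FIELDS, ClusterSummary, FRETSnapshotResult,
                          PhotophysicsConfig, SelectionSet, Trajectory,
                          TransitionRecord)
from .photophysics import einstein_coefficient

__all__ = [
    "donor_acceptor_distance",
    "orientation_factor",
    "select_acceptor_transition",
    "relative_rate",
    "forster_radius",
    "fret_efficiency",
    "analyze_ensemble",
    "summarize_clusters",
]


def donor_acceptor_distance(frame_coords: np.ndarray,
                            selections: SelectionSet) -> tuple[float, np.ndarray]:
    """Distance r (A) between the unweighted geometric centers of the
    donor and acceptor center selections, plus the donor->acceptor unit
    separation vector (zero vector when centers coincide)."""
    coords = np.asarray(frame_coords, dtype=float)
    d_sel = np.asarray(selections.donor_center, dtype=int)
    a_sel = np.asarray(selections.acceptor_center, dtype=int)
    if d_sel.size == 0 or a_sel.size == 0:
        raise ValueError("empty center selection")
    vec = coords[a_sel].mean(axis=0) - coords[d_sel].mean(axis=0)
    r = float(np.linalg.norm(vec))
    return r, (vec / r if r > 0 else vec)


def orientation_factor(mu_d, mu_a, separation):
    """Orientation factor kappa^2 and its angles (degrees).

    kappa^2 = (cos Theta_T - 3 cos Theta_D cos Theta_A)^2 where Theta_T
    is the donor-acceptor inter-dipole angle and Theta_D, Theta_A the
    angles of each dipole to the separation line.  Independent of all
    vector magnitudes and signs; always in [0, 4].

    Inputs may be single 3-vectors or (n, 3) batches (broadcast against
    each other); batched inputs return arrays.
    """
    mu_d = np.atleast_2d(np.asarray(mu_d, dtype=float))
    mu_a = np.atleast_2d(np.asarray(mu_a, dtype=float))
    sep = np.atleast_2d(np.asarray(separation, dtype=float))
    scalar = max(mu_d.shape[0], mu_a.shape[0], sep.shape[0]) == 1
    nd = np.linalg.norm(mu_d, axis=-1, keepdims=True)
    na = np.linalg.norm(mu_a, axis=-1, keepdims=True)
    ns = np.linalg.norm(sep, axis=-1, keepdims=True)
    if np.any(nd == 0) or np.any(na == 0) or np.any(ns == 0):
        raise ValueError("kappa^2 undefined for zero-length dipole or separation")
    d, a, s = mu_d / nd, mu_a / na, sep / ns
    cos_t = np.sum(d * a, axis=-1)
    cos_d = np.sum(d * s, axis=-1)
    cos_a = np.sum(a * s, axis=-1)
    kappa2 = np.minimum((cos_t - 3.0 * cos_d * cos_a) ** 2, 4.0)
    angles = tuple(np.degrees(np.arccos(np.clip(x, -1, 1)))
                   for x in (cos_t, cos_d, cos_a))
    if scalar:
        return float(kappa2[0]), tuple(float(x[0]) for x in angles)
    return kappa2, angles


def select_acceptor_transition(donor_emission: TransitionRecord,
                               acceptor_records: list[TransitionRecord],
                               delta_e_cutoff: float) -> TransitionRecord | None:
    """Resonant acceptor absorption for one frame, or None.

    Candidates must lie strictly below the donor emission energy (i.e.
    at longer wavelength) and within ``delta_e_cutoff`` of it; among
    candidates the largest oscillator strength wins, ties going to the
    lowest energy.  ``None`` marks a frame with no resonant acceptor
    transition (excluded from FRET averages downstream).
    """
    if delta_e_cutoff <= 0:
        raise ValueError("delta_e_cutoff must be positive")
    e_d = donor_emission.energy_ev
    candidates = [rec for rec in acceptor_records
                  if rec.kind == "absorption"
                  and rec.energy_ev < e_d
                  and (e_d - rec.energy_ev) <= delta_e_cutoff]
    if not candidates:
        return None
    return max(candidates, key=lambda rec: (rec.osc_strength, -rec.energy_ev))


def relative_rate(kappa2: float, r: float) -> float:
    """Relative FRET rate k_T,rel = kappa^2 / r^6 (A^-6 units, no
    absolute prefactor)."""
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    return kappa2 / r ** 6


def forster_radius(kappa2: float, config: PhotophysicsConfig) -> float:
    """Per-snapshot Foerster radius (A) from the snapshot's kappa^2 and
    the configured Q_D, J and refractive index."""
    if kappa2 < 0:
        raise ValueError("kappa^2 must be >= 0")
    r0_6 = (config.forster_prefactor * kappa2 *
            config.refractive_index ** -4 * config.q_d * config.j_overlap)
    return r0_6 ** (1.0 / 6.0)


def fret_efficiency(r0: float, r: float) -> float:
    """Transfer efficiency E = R0^6 / (R0^6 + r^6)."""
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if r0 < 0:
        raise ValueError("R0 must be >= 0")
    return r0 ** 6 / (r0 ** 6 + r ** 6)


def analyze_ensemble(traj: Trajectory, transitions: list[TransitionRecord],
                     selections: SelectionSet,
                     config: PhotophysicsConfig | None = None
                     ) -> list[FRETSnapshotResult]:
    """Per-snapshot FRET analysis over a whole trajectory.

    Output has one entry per frame.  Frames whose acceptor has no
    resonant transition keep their geometry (r) but carry NaN FRET
    fields; frames lacking a donor emission record raise only if nothing
    can be computed — they are reported with NaN throughout and the run
    continues.
    """
    config = config or PhotophysicsConfig()
    selections.validate(traj.n_atoms)
    by_frame: dict[int, dict[str, list[TransitionRecord]]] = {}
    for rec in transitions:
        slot = by_frame.setdefault(rec.frame_index, {"donor": [], "acceptor": []})
        slot[rec.chromophore].append(rec)

    results = []
    for i in range(traj.n_frames):
        r, sep = donor_acceptor_distance(traj.coords[i], selections)
        slot = by_frame.get(i, {"donor": [], "acceptor": []})
        donor_em = [rec for rec in slot["donor"] if rec.kind == "emission"]
        if not donor_em:
            results.append(FRETSnapshotResult(frame_index=i, r=r))
            continue
        donor = donor_em[0]
        k_r = einstein_coefficient(donor.dipole_vector, donor.energy_ev)
        acceptor = select_acceptor_transition(donor, slot["acceptor"],
                                              config.delta_e_cutoff_ev)
        if acceptor is None or r == 0:
            results.append(FRETSnapshotResult(frame_index=i, r=r, k_r=k_r))
            continue
        kappa2, (t_t, t_d, t_a) = orientation_factor(
            donor.dipole_vector, acceptor.dipole_vector, sep)
        r0 = forster_radius(kappa2, config)
        results.append(FRETSnapshotResult(
            frame_index=i, r=r, kappa2=kappa2,
            theta_T=t_t, theta_D=t_d, theta_A=t_a,
            R0=r0, efficiency=fret_efficiency(r0, r),
            k_T_rel=relative_rate(kappa2, r), k_r=k_r,
            selected_acceptor_state=acceptor.state_label))
    return results


def _stats(results: list[FRETSnapshotResult]) -> tuple[dict, dict]:
    """Mean and population SD per summary field over snapshots with a
    qualifying acceptor transition (NaN-fields excluded per quantity)."""
    mean, sd = {}, {}
    for fld in SUMMARY_FIELDS:
        vals = np.array([getattr(res, fld) for res in results], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean[fld] = float(vals.mean())
            sd[fld] = float(vals.std())  # population SD
        else:
            mean[fld] = sd[fld] = float("nan")
    return mean, sd


def summarize_clusters(results: list[FRETSnapshotResult], labels,
                       distance_threshold: float = 20.0
                       ) -> list[ClusterSummary]:
    """Cluster-level FRET table plus pooled rows.

    One row per cluster (count, ensemble fraction, mean +/- population
    SD of r, kappa^2, R0, E, k_T,rel, k_r), a pooled "all" row, and a
    pooled far row over the clusters whose mean r exceeds
    ``distance_threshold`` (the distance regime where the point-dipole
    approximation is valid).  Empty clusters are omitted.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(results):
        raise ValueError("labels must align with results")
    total = len(results)
    ids = sorted(set(labels.tolist()))
    summaries = []
    far_ids = []
    for cid in ids:
        members = [res for res, lab in zip(results, labels) if lab == cid]
        mean, sd = _stats(members)
        summaries.append(ClusterSummary(
            cluster_id=str(cid), n_snapshots=len(members),
            fraction=len(members) / total, mean=mean, sd=sd))
        if np.isfinite(mean["r"]) and mean["r"] > distance_threshold:
            far_ids.append(cid)
    summaries.sort(key=lambda s: -s.n_snapshots)

    mean, sd = _stats(results)
    summaries.append(ClusterSummary(
        cluster_id="all", n_snapshots=total, fraction=1.0, mean=mean, sd=sd))

    # a single far cluster would duplicate its own row; pool only when >1
    if len(far_ids) > 1:
        far_members = [res for res, lab in zip(results, labels)
                       if lab in far_ids]
        mean, sd = _stats(far_members)
        summaries.append(ClusterSummary(
            cluster_id=",".join(str(c) for c in far_ids),
            n_snapshots=len(far_members),
            fraction=len(far_members) / total, mean=mean, sd=sd))
    return summaries
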