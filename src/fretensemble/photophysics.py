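"""Einstein coefficients, ensemble spectral assembly, overlap integral.

Ensemble spectra are built from vertical transitions only: per-record
weights (oscillator strength for absorption, Einstein A coefficient for
emission) are binned on the energy axis, each bin is broadened with a
unit-area Gaussian of configurable FWHM, the Gaussian sums are
accumulated on the energy grid, and the axis is relabeled to wavelength
via lambda = hc/E.  No Franck-Condon structure and no excited-state
relaxation enter, so profiles are narrower than experimental bands.

The default axis relabeling applies no Jacobian (the energy-scale
Gaussian sums are simply plotted against wavelength); a
Jacobian-corrected mode (intensity times dE/dlambda) is available for
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as c
from .ensemble_io import SpectrumProfile, TransitionRecord

__all__ = [
    "SpectrumAssemblySpec",
    "einstein_coefficient",
    "assemble_profile",
    "normalize_emission",
    "overlap_integral",
]


@dataclass(frozen=True)
class SpectrumAssemblySpec:
    """Broadening/binning parameters for ensemble spectra.

    The energy grid coincides with the bin-center lattice (multiples of
    ``bin_width_ev``) extended ``pad_sigmas`` Gaussian widths beyond the
    extreme occupied bins.  ``bin_width_ev <= fwhm_ev / 2`` is enforced
    so each Gaussian is adequately sampled.
    """

    fwhm_ev: float = 0.04
    bin_width_ev: float = 0.01
    energy_range: tuple[float, float] | None = None
    pad_sigmas: float = 6.0

    def __post_init__(self):
        if not self.fwhm_ev > 0:
            raise ValueError("fwhm_ev must be positive")
        if not 0 < self.bin_width_ev <= self.fwhm_ev / 2:
            raise ValueError(
                f"bin_width_ev must be in (0, fwhm/2] = (0, {self.fwhm_ev / 2}]")

    @property
    def sigma_ev(self) -> float:
        return self.fwhm_ev / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def einstein_coefficient(dipole, energy_ev: float) -> float:
    """Spontaneous-emission rate A (s^-1) of a transition.

    A = 16 pi^3 nu^3 |mu|^2 / (3 eps0 h c^3), nu = E/h.  ``dipole`` is a
    3-vector or magnitude in Debye.  This rate is the radiative rate
    constant k_r when applied to the donor S1 -> S0 emission.
    """
    if not energy_ev > 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    mu = np.asarray(dipole, dtype=float)
    mu_si = (np.linalg.norm(mu) if mu.ndim else float(mu)) * c.DEBYE_TO_C_M
    nu = energy_ev * c.EV_TO_JOULE / c.PLANCK_J_S
    return float(16 * math.pi ** 3 * nu ** 3 * mu_si ** 2 /
                 (3 * c.VACUUM_PERMITTIVITY * c.PLANCK_J_S *
                  c.SPEED_OF_LIGHT_M_S ** 3))


def assemble_profile(records: list[TransitionRecord], kind: str,
                     spec: SpectrumAssemblySpec | None = None,
                     jacobian: bool = False) -> SpectrumProfile:
    """Broadened ensemble spectrum from vertical-transition records.

    Absorption weights are oscillator strengths (all S0 -> Si records);
    emission weights are Einstein A coefficients computed from each
    record's transition dipole and energy.  Total weight is conserved:
    the trapezoidal area on the energy axis equals the summed weights.
    """
    spec = spec or SpectrumAssemblySpec()
    if kind not in ("absorption", "emission"):
        raise ValueError("kind must be 'absorption' or 'emission'")
    records = [r for r in records if r.kind == kind]
    if not records:
        warnings.warn(f"no {kind} records; returning empty profile")
        return SpectrumProfile(np.array([]), np.array([]), np.array([]),
                               kind, {"n_transitions": 0, "total_weight": 0.0,
                                      "fwhm_ev": spec.fwhm_ev,
                                      "bin_width_ev": spec.bin_width_ev})
    energies = np.array([r.energy_ev for r in records])
    if kind == "absorption":
        weights = np.array([r.osc_strength for r in records])
    else:
        weights = np.array([einstein_coefficient(r.dipole_vector, r.energy_ev)
                            for r in records])

    h = spec.bin_width_ev
    # bin centers on the lattice m*h
    bin_idx = np.rint(energies / h).astype(int)
    if spec.energy_range is not None:
        lo, hi = spec.energy_range
    else:
        pad = spec.pad_sigmas * spec.sigma_ev
        lo, hi = bin_idx.min() * h - pad, bin_idx.max() * h + pad
    grid_idx = np.arange(math.floor(lo / h), math.ceil(hi / h) + 1)
    energy_grid = grid_idx * h

    occupied, inv = np.unique(bin_idx, return_inverse=True)
    bin_weight = np.zeros(occupied.size)
    np.add.at(bin_weight, inv, weights)

    sig = spec.sigma_ev
    norm = 1.0 / (sig * math.sqrt(2.0 * math.pi))
    # (grid, bins) Gaussian accumulation
    diff = energy_grid[:, None] - occupied[None, :] * h
    intensity = (np.exp(-0.5 * (diff / sig) ** 2) * norm) @ bin_weight

    wavelength = c.HC_EV_NM / energy_grid
    if jacobian:
        # I(lambda) = I(E) * dE/dlambda = I(E) * E^2 / hc
        intensity = intensity * energy_grid ** 2 / c.HC_EV_NM
    return SpectrumProfile(
        wavelength_nm=wavelength, energy_ev=energy_grid, intensity=intensity,
        kind=kind,
        metadata={"n_transitions": len(records),
                  "total_weight": float(weights.sum()),
                  "fwhm_ev": spec.fwhm_ev, "bin_width_ev": spec.bin_width_ev,
                  "jacobian": jacobian})


def normalize_emission(profile: SpectrumProfile) -> SpectrumProfile:
    """Area-normalized donor emission F_D(lambda): unit trapezoidal area
    on the wavelength axis."""
    if profile.intensity.size == 0:
        raise ValueError("cannot normalize an empty profile")
    area = profile.wavelength_axis_area()
    if area <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return SpectrumProfile(
        wavelength_nm=profile.wavelength_nm.copy(),
        energy_ev=profile.energy_ev.copy(),
        intensity=profile.intensity / area,
        kind=profile.kind,
        metadata={**profile.metadata, "normalized": True})


def overlap_integral(f_d, epsilon_a, n_grid: int = 20001) -> float:
    """Spectral overlap J = integral F_D(lambda) eps_A(lambda) lambda^4 dlambda.

    Parameters are either :class:`SpectrumProfile` objects or
    ``(wavelength_nm, values)`` array pairs; F_D must be
    area-normalized, eps_A in M^-1 cm^-1.  Both are linearly interpolated
    onto a common wavelength grid over the overlapping range and
    integrated by the trapezoid rule; J returns in nm^4 M^-1 cm^-1.
    """
    lam_d, val_d = _as_curve(f_d)
    lam_a, val_a = _as_curve(epsilon_a)
    lo = max(lam_d.min(), lam_a.min())
    hi = min(lam_d.max(), lam_a.max())
    if lo >= hi:
        warnings.warn("donor emission and acceptor absorption wavelength "
                      "ranges do not overlap; J = 0")
        return 0.0
    grid = np.linspace(lo, hi, n_grid)
    fd = np.interp(grid, lam_d, val_d)
    ea = np.interp(grid, lam_a, val_a)
    return float(np.trapezoid(fd * ea * grid ** 4, grid))


def _as_curve(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, SpectrumProfile):
        lam, val = obj.wavelength_nm, obj.intensity
    else:
        lam, val = obj
    lam = np.asarray(lam, dtype=float)
    val = np.asarray(val, dtype=float)
    order = np.argsort(lam)
    return lam[order], val[order]
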