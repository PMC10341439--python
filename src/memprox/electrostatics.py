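"""Charge-density profile and slab electrostatic potential along z.

For a slab-periodic system the laterally averaged Poisson equation
reduces to a double integral over the charge density:

    psi(z) = -(1 / (eps0 * eps_r)) * int_0^z dz' int_0^z' rho(z'') dz''

evaluated by cumulative trapezoids with the gauge psi(0) = 0 and the
boundary condition E(0) = 0 at the lower box edge.  rho is in e/Å^3 and
psi is reported in volts.  For electroneutral systems psi is well
defined; otherwise the potential grows quadratically and a warning flag
is attached.  Reported summary quantities (signed extrema, peak
separations) are gauge-shifted so the bulk-water mean is zero when a
bulk window is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .ensemble import AtomSelection, FrameEnsemble

__all__ = [
    "ChargeDensityProfile",
    "PotentialProfile",
    "PotentialSummary",
    "charge_density_profile",
    "potential_from_charge",
    "potential_summary",
]

E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
ANGSTROM = 1e-10  # m


@dataclass
class ChargeDensityProfile:
    """Frame-averaged charge density rho(z) in e/Å^3."""

    bin_width: float
    z_centers: np.ndarray
    rho: np.ndarray
    area: float  # Dx * Dy, Å^2
    n_frames: int = 1

    def total_charge(self) -> float:
        """Integrated charge per frame, e."""
        return float(self.rho.sum() * self.area * self.bin_width)


@dataclass
class PotentialProfile:
    z_centers: np.ndarray
    psi: np.ndarray  # volts
    eps_r: float = 1.0
    nonneutral: bool = False


@dataclass
class PotentialSummary:
    max_positive: float  # V
    max_negative: float  # V (signed)
    positive_peak_separation: float  # Å
    negative_peak_separation: float  # Å


def charge_density_profile(
    ensemble: FrameEnsemble, bin_width: float = 0.5
) -> ChargeDensityProfile:
    """Bin all atomic charges along z, frame-averaged, per slab volume."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not np.all(np.isfinite(ensemble.charges)):
        raise ValueError("missing (non-finite) charge metadata")
    dz = float(ensemble.box[0, 2])
    area = float(ensemble.box[0, 0] * ensemble.box[0, 1])
    n_bins = max(1, int(np.ceil(dz / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    acc = np.zeros(n_bins)
    for f in range(ensemble.n_frames):
        hist, _ = np.histogram(
            ensemble.coords[f, :, 2], bins=edges, weights=ensemble.charges
        )
        acc += hist
    rho = acc / (area * bin_width * ensemble.n_frames)
    return ChargeDensityProfile(
        bin_width=bin_width,
        z_centers=edges[:-1] + 0.5 * bin_width,
        rho=rho,
        area=area,
        n_frames=ensemble.n_frames,
    )


def potential_from_charge(
    cdp: ChargeDensityProfile,
    eps_r: float = 1.0,
    bulk_window: Optional[Tuple[float, float]] = None,
    charge_tol: float = 1e-6,
) -> PotentialProfile:
    """Double-integrate rho(z) to the electrostatic potential psi(z) in volts.

    ``bulk_window`` (z_lo, z_hi in Å), when given, re-zeros the gauge on
    the mean potential over that window; otherwise psi(0) = 0 at the
    lower box edge.
    """
    if eps_r <= 0:
        raise ValueError("eps_r must be positive")
    z_m = cdp.z_centers * ANGSTROM
    rho_si = cdp.rho * E_CHARGE / ANGSTROM**3  # C/m^3
    total = cdp.total_charge()
    nonneutral = abs(total) > charge_tol
    if nonneutral:
        warnings.warn(
            f"total charge {total:.3g} e is not neutral; potential grows quadratically",
            RuntimeWarning,
            stacklevel=2,
        )
    # E(z) with E(0)=0, then psi with psi(0)=0
    e_field = cumulative_trapezoid(rho_si, z_m, initial=0.0) / (EPS0 * eps_r)
    psi = -cumulative_trapezoid(e_field, z_m, initial=0.0)
    if bulk_window is not None:
        lo, hi = bulk_window
        mask = (cdp.z_centers >= lo) & (cdp.z_centers <= hi)
        if not mask.any():
            raise ValueError("bulk_window contains no bins")
        psi = psi - psi[mask].mean()
    return PotentialProfile(
        z_centers=cdp.z_centers.copy(), psi=psi, eps_r=eps_r, nonneutral=nonneutral
    )


def potential_summary(pp: PotentialProfile, center_z: float) -> PotentialSummary:
    """Signed extrema of psi and the separations of the per-side peaks."""
    psi = pp.psi
    z = pp.z_centers
    if np.allclose(psi, psi[0]):
        raise ValueError("constant potential profile has no extrema")
    diffs = np.diff(psi)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise ValueError("monotone potential profile has no interior extrema")
    left = z < center_z
    right = ~left
    if not left.any() or not right.any():
        raise ValueError("center_z outside profile range")
    z_pos_left = float(z[left][int(np.argmax(psi[left]))])
    z_pos_right = float(z[right][int(np.argmax(psi[right]))])
    z_neg_left = float(z[left][int(np.argmin(psi[left]))])
    z_neg_right = float(z[right][int(np.argmin(psi[right]))])
    return PotentialSummary(
        max_positive=float(psi.max()),
        max_negative=float(psi.min()),
        positive_peak_separation=round(z_pos_right - z_pos_left, 2),
        negative_peak_separation=round(z_neg_right - z_neg_left, 2),
    )
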