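"""Photon-interaction physics shared by the projector and the MC engine.

Covers Compton kinematics, Klein-Nishina sampling, energy-dependent linear
attenuation through a per-material table, photopeak energy windows and a
Gaussian detector energy-response model.

The model deliberately keeps only the two interaction channels that matter
for fast scatter estimation at 70-140 keV: incoherent (Compton) scattering
and photoelectric absorption.  Coherent (Rayleigh) scattering, Doppler
broadening and bound-electron corrections are ignored.  Tl-201 emission is
collapsed to a single 72 keV line standing for the Hg X-ray complex; the
weak 167 keV line is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ELECTRON_REST_KEV",
    "FWHM_TO_SIGMA",
    "EnergyWindow",
    "EmissionSpec",
    "MaterialTable",
    "TC99M",
    "TL201",
    "TC_WINDOW",
    "TL_WINDOW",
    "default_material_table",
    "compton_energy",
    "compton_floor",
    "kn_differential",
    "kn_total",
    "sample_klein_nishina",
    "window_acceptance",
    "energy_fwhm",
]

ELECTRON_REST_KEV = 511.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548
DEFAULT_RESOLUTION_FRAC = 0.099  # FWHM/E at 140 keV, typical NaI camera

_E_MIN, _E_MAX = 50.0, 160.0  # tabulated attenuation range, keV


@dataclass(frozen=True)
class EnergyWindow:
    """Photopeak acceptance window, stated as a fractional full width."""

    center_kev: float
    width_frac: float

    def __post_init__(self) -> None:
        if self.center_kev <= 0:
            raise ValueError("window center must be positive")
        if not 0.0 < self.width_frac < 1.0:
            raise ValueError("fractional window width must lie in (0, 1)")

    @property
    def bounds(self) -> tuple[float, float]:
        half = 0.5 * self.center_kev * self.width_frac
        return self.center_kev - half, self.center_kev + half


@dataclass(frozen=True)
class EmissionSpec:
    """Single-line emission model of one isotope."""

    isotope: str
    energy_kev: float

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("emission energy must be positive")


TC99M = EmissionSpec("Tc-99m", 140.0)
TL201 = EmissionSpec("Tl-201", 72.0)  # Hg X-ray complex, single-line model
TC_WINDOW = EnergyWindow(140.0, 0.15)
TL_WINDOW = EnergyWindow(72.0, 0.15)


# ---------------------------------------------------------------------------
# Compton kinematics and Klein-Nishina sampling
# ---------------------------------------------------------------------------

def compton_energy(energy_kev, theta):
    """Energy of a photon after Compton scattering through ``theta``.

    E' = E / (1 + (E / m_e c^2)(1 - cos theta)).
    """
    energy_kev = np.asarray(energy_kev, dtype=np.float64)
    cost = np.cos(theta)
    return energy_kev / (1.0 + (energy_kev / ELECTRON_REST_KEV) * (1.0 - cost))


def compton_floor(energy_kev: float) -> float:
    """Minimum energy retained after a single scatter (backscatter, theta=pi)."""
    return float(compton_energy(energy_kev, np.pi))


def kn_differential(energy_kev, cost):
    """Unnormalised Klein-Nishina differential cross-section d(sigma)/d(Omega).

    Evaluated per unit solid angle at scattering-angle cosine ``cost`` for
    incident energy ``energy_kev``; the constant r_e^2/2 prefactor is
    dropped (it cancels in every normalised use).
    """
    energy_kev = np.asarray(energy_kev, dtype=np.float64)
    cost = np.asarray(cost, dtype=np.float64)
    ratio = 1.0 / (1.0 + (energy_kev / ELECTRON_REST_KEV) * (1.0 - cost))  # E'/E
    sin2 = 1.0 - cost * cost
    return ratio * ratio * (ratio + 1.0 / ratio - sin2)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)


def kn_total(energy_kev):
    """Klein-Nishina cross-section integrated over solid angle.

    Same arbitrary units as :func:`kn_differential`; Gauss-Legendre
    quadrature over cos(theta), exact to machine precision for this smooth
    integrand.
    """
    energy_kev = np.atleast_1d(np.asarray(energy_kev, dtype=np.float64))
    vals = kn_differential(energy_kev[:, None], _GL_NODES[None, :])
    out = 2.0 * np.pi * vals @ _GL_WEIGHTS
    return out[0] if out.size == 1 else out


def sample_klein_nishina(energy_kev, rng, size=None):
    """Sample Compton scattering angles from the Klein-Nishina distribution.

    Rejection sampling against the forward-scatter maximum (the KN
    differential cross-section peaks at theta = 0 for all energies).
    Returns scattering angles in radians; scattered energies follow from
    :func:`compton_energy`.

    ``energy_kev`` may be a scalar with ``size`` set, or an array (one angle
    per entry).
    """
    if size is not None:
        energies = np.full(int(size), float(energy_kev), dtype=np.float64)
    else:
        energies = np.atleast_1d(np.asarray(energy_kev, dtype=np.float64)).copy()
    n = energies.size
    cost = np.empty(n, dtype=np.float64)
    fmax = kn_differential(energies, 1.0)
    pending = np.arange(n)
    while pending.size:
        cand = rng.uniform(-1.0, 1.0, pending.size)
        u = rng.uniform(0.0, 1.0, pending.size)
        f = kn_differential(energies[pending], cand)
        ok = u * fmax[pending] <= f
        cost[pending[ok]] = cand[ok]
        pending = pending[~ok]
    theta = np.arccos(np.clip(cost, -1.0, 1.0))
    if size is None and np.isscalar(energy_kev):
        return float(theta[0])
    return theta


# ---------------------------------------------------------------------------
# Material attenuation table
# ---------------------------------------------------------------------------

class MaterialTable:
    """Per-material linear attenuation coefficients tabulated in energy.

    Stores total, Compton and photoelectric components (1/cm) at reference
    energies; :meth:`mu_at` interpolates log-log between them and is exact
    at the tabulated points.  No extrapolation outside the tabulated range.
    """

    def __init__(self, energies_kev, coefficients):
        """``coefficients``: {material: {"compton": array, "photo": array}}
        or {material: {"total": ..., "compton": ..., "photo": ...}}."""
        self.energies_kev = np.asarray(energies_kev, dtype=np.float64)
        if np.any(np.diff(self.energies_kev) <= 0):
            raise ValueError("tabulated energies must be strictly increasing")
        self._table: dict[str, dict[str, np.ndarray]] = {}
        for mat, comps in coefficients.items():
            compton = np.asarray(comps["compton"], dtype=np.float64)
            photo = np.asarray(comps["photo"], dtype=np.float64)
            total = np.asarray(comps.get("total", compton + photo), dtype=np.float64)
            for name, arr in (("total", total), ("compton", compton), ("photo", photo)):
                if arr.shape != self.energies_kev.shape:
                    raise ValueError(f"{mat}/{name}: wrong number of energies")
                if np.any(arr <= 0):
                    raise ValueError(f"{mat}/{name}: coefficients must be positive")
                if np.any(np.diff(arr) > 0):
                    raise ValueError(f"{mat}/{name}: must be non-increasing in energy")
            if np.any(total + 1e-9 < compton + photo):
                raise ValueError(f"{mat}: total below Compton + photoelectric")
            self._table[mat] = {"total": total, "compton": compton, "photo": photo}

    @property
    def materials(self) -> tuple[str, ...]:
        return tuple(self._table)

    def mu_at(self, material: str, energy_kev, component: str = "total"):
        """Linear attenuation coefficient (1/cm) at ``energy_kev``.

        Log-log interpolation between tabulated energies; raises outside
        the tabulated range.
        """
        if material not in self._table:
            raise KeyError(f"unknown material {material!r}")
        if component not in ("total", "compton", "photo"):
            raise ValueError(f"unknown component {component!r}")
        e = np.asarray(energy_kev, dtype=np.float64)
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside tabulated range [{lo:g}, {hi:g}] keV; "
                "no extrapolation"
            )
        mu = self._table[material][component]
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev), np.log(mu)))
        return float(out) if np.isscalar(energy_kev) else out

    def mu_grid(self, materials, energies_kev, component="total") -> np.ndarray:
        """(n_materials, n_energies) coefficient matrix for fast MC lookup."""
        return np.stack(
            [self.mu_at(m, np.asarray(energies_kev, float), component) for m in materials]
        )


def _kn_shape(energies):
    """KN cross-section relative to its 140 keV value."""
    return np.asarray(kn_total(energies)) / kn_total(140.0)


def default_material_table() -> MaterialTable:
    """Default attenuation table for soft tissue, lung, bone and water.

    The Compton component follows the Klein-Nishina energy dependence
    scaled to standard 140 keV narrow-beam values (soft tissue 0.155,
    lung 0.040, bone 0.25 cm^-1 total); the photoelectric component uses
    the usual ~E^-3 fall-off.  Values are tabulated on a fixed grid so the
    interpolation contract stays exact at the grid points.
    """
    energies = np.array([50.0, 60.0, 72.0, 85.0, 100.0, 120.0, 140.0, 160.0])
    kn = _kn_shape(energies)
    photo = (140.0 / energies) ** 3
    # (compton at 140 keV, photoelectric at 140 keV), 1/cm
    anchors = {
        "soft_tissue": (0.1542, 0.0008),
        "lung": (0.0398, 0.0002),
        "bone": (0.2350, 0.0150),
        "water": (0.1536, 0.0007),
    }
    coeffs = {
        mat: {"compton": c140 * kn, "photo": p140 * photo}
        for mat, (c140, p140) in anchors.items()
    }
    return MaterialTable(energies, coeffs)


# ---------------------------------------------------------------------------
# Detector energy response
# ---------------------------------------------------------------------------

def energy_fwhm(energy_kev, resolution_frac_at_140=DEFAULT_RESOLUTION_FRAC):
    """Absolute detector energy resolution FWHM (keV), scaling as sqrt(E)."""
    return resolution_frac_at_140 * np.sqrt(140.0 * np.asarray(energy_kev, float))


def window_acceptance(energy_kev, window: EnergyWindow,
                      resolution_frac_at_140=DEFAULT_RESOLUTION_FRAC):
    """Probability that a photon of true energy ``energy_kev`` is recorded
    inside ``window`` after Gaussian detector blurring.

    With ``resolution_frac_at_140 == 0`` the response is a delta and the
    result is the window indicator.
    """
    e = np.asarray(energy_kev, dtype=np.float64)
    lo, hi = window.bounds
    if resolution_frac_at_140 <= 0.0:
        out = ((e >= lo) & (e <= hi)).astype(np.float64)
    else:
        sigma = energy_fwhm(e, resolution_frac_at_140) * FWHM_TO_SIGMA
        out = ndtr((hi - e) / sigma) - ndtr((lo - e) / sigma)
    return float(out) if np.isscalar(energy_kev) else out
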