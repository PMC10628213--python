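"""Slab models and specular X-ray reflectivity kernels.

An interface between two semi-infinite media (e.g. buffer and a silicon
substrate), possibly decorated with a stack of homogeneous slabs (lipid
head groups, hydrocarbon chains, an adsorbed protein layer, native silicon
oxide ...), reflects X-rays specularly according to classical optics.  Each
slab is described by a thickness ``d`` (Å), an electron density ``rho``
(e⁻·Å⁻³) and a Gaussian interfacial roughness ``sigma`` (Å) attached to the
interface on its fronting (beam) side.

Two independent formalisms compute the same exact reflectivity of a layered
medium: the Abeles transfer-matrix product and the Parratt recursion.  Both
are implemented here; either can serve as a cross-check of the other.
Interfacial roughness enters through the Névot–Croce damping of each
Fresnel coefficient, ``r -> r · exp(-2 k_i k_{i+1} σ²)``.

Units are fixed: lengths in Å, electron densities in e⁻·Å⁻³, momentum
transfer q in Å⁻¹.  Angles in degrees appear only at conversion boundaries.
Absorption is neglected (real optical profile): at the 22 keV energies used
for high-energy solid/liquid reflectometry the imaginary part of the
refractive index of these materials is ~10⁻³ of the real part.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_E",
    "HC_KEV_ANGSTROM",
    "RHO_SI",
    "RHO_SIO2",
    "RHO_WATER",
    "Medium",
    "Slab",
    "LayerStack",
    "ReflectivityCurve",
    "Instrument",
    "qz_from_angle",
    "electron_density_to_sld",
    "critical_q",
    "fresnel_reflectivity",
    "reflectivity_abeles",
    "reflectivity_parratt",
]

#: Classical electron radius (Thomson scattering length), Å.
R_E = 2.8179403262e-5

#: hc in keV·Å, for wavelength/energy conversion.
HC_KEV_ANGSTROM = 12.3984

#: Electron densities held fixed during refinement (e⁻·Å⁻³):
#: silicon substrate, native silicon oxide, aqueous buffer.
RHO_SI = 0.692
RHO_SIO2 = 0.660
RHO_WATER = 0.335


class StackValidationError(ValueError):
    """Raised when a slab stack or curve violates a structural invariant."""


@dataclass(frozen=True)
class Medium:
    """Semi-infinite medium bounding a slab stack.

    Parameters
    ----------
    name : str
        Text label, e.g. ``"air"``, ``"buffer"``, ``"Si"``.
    electron_density : float
        Electron density in e⁻·Å⁻³; 0 for air, 0.335 for aqueous buffer,
        0.692 for silicon.
    """

    name: str
    electron_density: float

    def __post_init__(self):
        if not math.isfinite(self.electron_density) or self.electron_density < 0:
            raise StackValidationError(
                f"medium {self.name!r}: electron density must be finite and >= 0, "
                f"got {self.electron_density}"
            )


# Common media, ready to use.
AIR = Medium("air", 0.0)
BUFFER = Medium("buffer", RHO_WATER)
SILICON = Medium("Si", RHO_SI)


@dataclass
class Slab:
    """One homogeneous layer of a slab model.

    ``roughness`` is the Gaussian width of the interface on the *fronting*
    (beam) side of this slab.
    """

    thickness: float
    electron_density: float
    roughness: float = 0.0
    name: str = ""

    def validate(self) -> None:
        for attr in ("thickness", "electron_density", "roughness"):
            v = getattr(self, attr)
            if not math.isfinite(v):
                raise StackValidationError(f"slab {self.name!r}: {attr} not finite")
        if self.thickness <= 0:
            raise StackValidationError(
                f"slab {self.name!r}: thickness must be > 0, got {self.thickness}"
            )
        if self.electron_density < 0:
            raise StackValidationError(
                f"slab {self.name!r}: electron density must be >= 0"
            )
        if self.roughness < 0:
            raise StackValidationError(f"slab {self.name!r}: roughness must be >= 0")


@dataclass
class LayerStack:
    """Ordered slab stack between two semi-infinite media.

    Slabs are listed from the fronting medium (beam side) toward the
    backing medium.  An empty slab list describes a bare interface.
    ``backing_roughness`` is the Gaussian width of the last-slab/backing
    (or fronting/backing) interface.
    """

    fronting: Medium
    slabs: list[Slab] = field(default_factory=list)
    backing: Medium = SILICON
    backing_roughness: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for s in self.slabs:
            s.validate()
        if not math.isfinite(self.backing_roughness) or self.backing_roughness < 0:
            raise StackValidationError("backing roughness must be finite and >= 0")
        # Unphysical-smearing guard: a roughness much larger than its
        # neighbouring slabs smears interfaces into each other; warn, do
        # not reject (diffuse layers are sometimes genuinely like this).
        thicknesses = [s.thickness for s in self.slabs]
        sigmas = [s.roughness for s in self.slabs] + [self.backing_roughness]
        for i, sigma in enumerate(sigmas):
            neighbours = thicknesses[max(0, i - 1): i + 1]
            if neighbours and sigma > 2.0 * min(neighbours):
                warnings.warn(
                    f"interface {i}: roughness {sigma:.1f} Å exceeds twice the "
                    f"thinnest adjacent slab ({min(neighbours):.1f} Å); profile "
                    "smearing may be unphysical",
                    stacklevel=2,
                )

    # -- derived arrays used by the optical kernels ---------------------

    def profile_densities(self) -> np.ndarray:
        """Electron density of every layer, fronting first (n_slabs + 2)."""
        return np.array(
            [self.fronting.electron_density]
            + [s.electron_density for s in self.slabs]
            + [self.backing.electron_density]
        )

    def profile_thicknesses(self) -> np.ndarray:
        """Thickness of internal layers only (n_slabs)."""
        return np.array([s.thickness for s in self.slabs])

    def interface_roughnesses(self) -> np.ndarray:
        """Roughness of each interface, fronting-most first (n_slabs + 1)."""
        return np.array([s.roughness for s in self.slabs] + [self.backing_roughness])

    def n_interfaces(self) -> int:
        return len(self.slabs) + 1


@dataclass
class ReflectivityCurve:
    """Measured or simulated reflectivity: R(q), optionally with 1-σ errors."""

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.q.shape != self.R.shape:
            raise StackValidationError("q and R must be 1-D arrays of equal length")
        if self.dR is not None and self.dR.shape != self.q.shape:
            raise StackValidationError("dR must match q in length")
        if np.any(self.q <= 0):
            raise StackValidationError("q values must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise StackValidationError("q must be strictly increasing")
        if np.any(self.R < 0):
            raise StackValidationError("reflectivity must be >= 0")
        if self.dR is not None and np.any(self.dR <= 0):
            raise StackValidationError("dR must be > 0 where present")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class Instrument:
    """Beam description: wavelength (Å) and/or photon energy (keV).

    Defaults correspond to a 22 keV high-energy reflectometry setup
    (λ = 0.56 Å).  If both are supplied they must agree within 1%.
    """

    wavelength: float = 0.56
    energy: float | None = None

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.energy is not None:
            lam_from_e = HC_KEV_ANGSTROM / self.energy
            if abs(lam_from_e - self.wavelength) > 0.01 * self.wavelength:
                raise ValueError(
                    f"wavelength {self.wavelength} Å inconsistent with "
                    f"energy {self.energy} keV (implies {lam_from_e:.4f} Å)"
                )


def qz_from_angle(alpha_deg, instrument: Instrument = Instrument()):
    """Momentum transfer normal to the interface: q_z = 4π·sin(α_i)/λ.

    Parameters
    ----------
    alpha_deg : float or array
        Incident angle(s) in degrees, 0 ≤ α < 90.
    instrument : Instrument
        Supplies the wavelength.
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha < 0) or np.any(alpha >= 90):
        raise ValueError("incident angle must satisfy 0 <= alpha < 90 degrees")
    q = 4.0 * np.pi * np.sin(np.radians(alpha)) / instrument.wavelength
    return q if q.ndim else float(q)


def electron_density_to_sld(rho):
    """Convert electron density (e⁻·Å⁻³) to X-ray SLD (Å⁻²): sld = ρ·r_e."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("electron density must be >= 0")
    sld = rho * R_E
    return sld if sld.ndim else float(sld)


def critical_q(fronting: Medium, backing: Medium) -> float:
    """Total-external-reflection edge q_c = √(16π·Δsld) of a bare interface.

    Returns 0 when the backing is not optically denser than the fronting.
    """
    dsld = electron_density_to_sld(backing.electron_density) - electron_density_to_sld(
        fronting.electron_density
    )
    if dsld <= 0:
        return 0.0
    return math.sqrt(16.0 * math.pi * dsld)


def fresnel_reflectivity(q, fronting: Medium, backing: Medium):
    """Closed-form Fresnel reflectivity of a single sharp interface.

    For q > q_c:  R = ((1 − s)/(1 + s))² with s = √(1 − (q_c/q)²);
    R = 1 below the critical edge (no absorption).
    """
    q = np.asarray(q, dtype=float)
    qc = critical_q(fronting, backing)
    with np.errstate(invalid="ignore"):
        s = np.sqrt(np.clip(1.0 - (qc / q) ** 2, 0.0, None))
    R = ((1.0 - s) / (1.0 + s)) ** 2
    return np.where(q <= qc, 1.0, R)


# ---------------------------------------------------------------------------
# Optical kernels
# ---------------------------------------------------------------------------

_ROUGHNESS_MODELS = ("nevot_croce", "none")


def _kz_layers(stack: LayerStack, q: np.ndarray) -> np.ndarray:
    """Normal wavevector component in every layer, shape (n_layers, n_q).

    k_{z,j} = sqrt(k_{z,0}² − 4π(sld_j − sld_fronting)), complex below the
    layer's critical edge (evanescent wave).
    """
    sld = electron_density_to_sld(stack.profile_densities())
    kz0_sq = (q / 2.0) ** 2
    arg = kz0_sq[None, :] - 4.0 * np.pi * (sld[:, None] - sld[0])
    return np.sqrt(arg.astype(complex))


def _interface_coefficients(
    kz: np.ndarray, sigmas: np.ndarray, roughness_model: str
) -> np.ndarray:
    """Névot–Croce-damped Fresnel coefficient at every interface."""
    if roughness_model not in _ROUGHNESS_MODELS:
        raise ValueError(
            f"unknown roughness model {roughness_model!r}; choose from "
            f"{_ROUGHNESS_MODELS}"
        )
    k_top, k_bot = kz[:-1], kz[1:]
    denom = k_top + k_bot
    # A vanishing denominator only occurs for zero contrast at q=0 (excluded).
    r = (k_top - k_bot) / denom
    if roughness_model == "nevot_croce":
        r = r * np.exp(-2.0 * k_top * k_bot * sigmas[:, None] ** 2)
    return r


def _check_inputs(stack: LayerStack, q) -> np.ndarray:
    stack.validate()
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    return q


def reflectivity_abeles(
    stack: LayerStack, q, roughness_model: str = "nevot_croce"
) -> np.ndarray:
    """Specular reflectivity by the Abeles transfer-matrix method.

    The characteristic matrix of each interface/layer pair is

        C_j = [[exp(iβ_j),      r_j exp(iβ_j) ],
               [r_j exp(−iβ_j), exp(−iβ_j)    ]]

    with β_j = k_{z,j}·d_j the phase accumulated in the layer above
    interface j (β = 0 for the fronting medium) and r_j the (damped)
    Fresnel coefficient of interface j.  The amplitude reflectance is
    M₂₁/M₁₁ of the ordered product.
    """
    q = _check_inputs(stack, q)
    kz = _kz_layers(stack, q)
    r = _interface_coefficients(kz, stack.interface_roughnesses(), roughness_model)
    d = stack.profile_thicknesses()

    n_interfaces = r.shape[0]
    # Running matrix product, element-wise over q.
    m11 = np.ones_like(kz[0])
    m12 = np.zeros_like(kz[0])
    m21 = np.zeros_like(kz[0])
    m22 = np.ones_like(kz[0])
    for j in range(n_interfaces):
        beta = kz[j] * d[j - 1] if j > 0 else np.zeros_like(kz[0])
        e_pos = np.exp(1j * beta)
        e_neg = np.exp(-1j * beta)
        c11, c12 = e_pos, r[j] * e_pos
        c21, c22 = r[j] * e_neg, e_neg
        m11, m12, m21, m22 = (
            m11 * c11 + m12 * c21,
            m11 * c12 + m12 * c22,
            m21 * c11 + m22 * c21,
            m21 * c12 + m22 * c22,
        )
    amp = m21 / m11
    return np.abs(amp) ** 2


def reflectivity_parratt(
    stack: LayerStack, q, roughness_model: str = "nevot_croce"
) -> np.ndarray:
    """Specular reflectivity by the Parratt recursion (independent route).

    Starting from the backing, where no wave returns, the amplitude
    reflectance is propagated upward through

        X_j = (r_j + X_{j+1}·φ_{j+1}) / (1 + r_j·X_{j+1}·φ_{j+1}),
        φ_{j+1} = exp(2i·k_{z,j+1}·d_{j+1}).
    """
    q = _check_inputs(stack, q)
    kz = _kz_layers(stack, q)
    r = _interface_coefficients(kz, stack.interface_roughnesses(), roughness_model)
    d = stack.profile_thicknesses()

    x = r[-1]
    for j in range(r.shape[0] - 2, -1, -1):
        phase = np.exp(2j * kz[j + 1] * d[j])
        xp = x * phase
        x = (r[j] + xp) / (1.0 + r[j] * xp)
    return np.abs(x) ** 2


def _abeles_batch(
    rho: np.ndarray,
    d: np.ndarray,
    sigma: np.ndarray,
    q: np.ndarray,
    nevot_croce: bool = True,
) -> np.ndarray:
    """Abeles reflectivity for a batch of stacks sharing one layer count.

    Low-level kernel used by the fit engine to evaluate a whole optimizer
    population in one vectorized pass.

    Parameters
    ----------
    rho : (S, L) array
        Electron densities of all L layers (fronting first, backing last)
        for S candidate stacks.
    d : (S, L-2) array
        Internal-layer thicknesses.
    sigma : (S, L-1) array
        Interface roughnesses, fronting-most interface first.
    q : (n_q,) array
        Momentum-transfer grid, > 0.

    Returns
    -------
    (S, n_q) array of reflectivities.
    """
    rho = np.atleast_2d(rho)
    d = np.atleast_2d(d)
    sigma = np.atleast_2d(sigma)
    sld = rho * R_E
    kz0_sq = (q / 2.0) ** 2
    # kz: (S, L, nq)
    arg = kz0_sq[None, None, :] - 4.0 * np.pi * (sld - sld[:, :1])[:, :, None]
    kz = np.sqrt(arg.astype(complex))
    k_top, k_bot = kz[:, :-1], kz[:, 1:]
    r = (k_top - k_bot) / (k_top + k_bot)
    if nevot_croce:
        r = r * np.exp(-2.0 * k_top * k_bot * sigma[:, :, None] ** 2)

    m11 = np.ones(kz[:, 0].shape, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for j in range(r.shape[1]):
        if j > 0:
            beta = kz[:, j] * d[:, j - 1, None]
            e_pos = np.exp(1j * beta)
            e_neg = np.exp(-1j * beta)
        else:
            e_pos = np.ones_like(m11)
            e_neg = np.ones_like(m11)
        rj = r[:, j]
        c11, c12 = e_pos, rj * e_pos
        c21, c22 = rj * e_neg, e_neg
        m11, m12, m21, m22 = (
            m11 * c11 + m12 * c21,
            m11 * c12 + m12 * c22,
            m21 * c11 + m22 * c21,
            m21 * c12 + m22 * c22,
        )
    return np.abs(m21 / m11) ** 2


def smear_constant_resolution(
    stack: LayerStack,
    q,
    dq_over_q: float,
    roughness_model: str = "nevot_croce",
    n_points: int = 17,
    kernel=reflectivity_abeles,
) -> np.ndarray:
    """Gaussian resolution smearing with constant relative width dq/q (FWHM).

    Off by default throughout the package (the instrument resolution of
    high-energy reflectometers is rarely the limiting factor and is often
    unreported); exposed for completeness.
    """
    if dq_over_q <= 0:
        raise ValueError("dq_over_q must be > 0")
    q = _check_inputs(stack, q)
    fwhm_to_sigma = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    # Gauss-Hermite style fixed grid in units of sigma, truncated at 3.5 sigma.
    t = np.linspace(-3.5, 3.5, n_points)
    w = np.exp(-0.5 * t**2)
    w /= w.sum()
    smeared = np.zeros_like(q)
    for ti, wi in zip(t, w):
        q_shift = q * (1.0 + ti * dq_over_q * fwhm_to_sigma)
        q_shift = np.clip(q_shift, 1e-6, None)
        smeared += wi * kernel(stack, q_shift, roughness_model)
    return smeared
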