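"""Optical observables: Rayleigh scattering, photon counting, detectability.

Polarizabilities enter as *volumes* in A^3 (Gaussian convention,
alpha_SI / 4 pi eps0) and are converted to m^3 inside the scattering
formulas, where the relative medium permittivity eps_m = n_m^2 is used.
This volume convention is the one that reproduces both the ~1e-17
single-protein scattering fraction and the MW/um^2 resolving intensities
for realistic inputs.  The wavenumber k = 2 pi / lambda uses the vacuum
wavelength.

For a molecule in solution what scattering measures is the *excess*
polarizability: the molecular value minus the polarizability of the solvent
volume the molecule displaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro, c, h

from .errors import DegenerateStatesError, ValidationError

A3_TO_M3 = 1e-30
#: 1 W/m^2 = 1e-12 W/um^2
W_M2_TO_W_UM2 = 1e-12

#: Polarizability volume of one water molecule (A^3), from the
#: Lorentz-Lorenz relation at n = 1.33.
WATER_ALPHA_A3 = 1.45
#: Number density of liquid water (molecules per A^3).
WATER_DENSITY_A3 = 0.0334
#: Typical protein partial specific volume (cm^3 / g).
DEFAULT_PARTIAL_SPECIFIC_VOLUME = 0.73


@dataclass(frozen=True)
class OpticalConfig:
    """Illumination parameters.

    wavelength: vacuum wavelength (m); medium_index: refractive index of the
    surrounding medium; beam_waist: focal-spot width w (m) for the focused
    scattering form; intensity (W/m^2) or power (W) describe the input beam.
    """

    wavelength: float
    medium_index: float = 1.33
    beam_waist: float | None = None
    intensity: float | None = None
    power: float | None = None

    def __post_init__(self):
        if not self.wavelength > 0:
            raise ValidationError("wavelength must be positive")
        if self.medium_index < 1:
            raise ValidationError("medium index must be >= 1")

    @property
    def k(self) -> float:
        """Vacuum wavenumber 2 pi / lambda (m^-1)."""
        return 2.0 * math.pi / self.wavelength

    @property
    def epsilon_m(self) -> float:
        """Relative permittivity of the medium, n_m^2."""
        return self.medium_index ** 2


# ---------------------------------------------------------------------------
# Lorentz-Lorenz
# ---------------------------------------------------------------------------

def lorentz_lorenz_index(alpha_a3: float, density_per_a3: float) -> float:
    """Refractive index from per-particle polarizability volume.

    (n^2 - 1)/(n^2 + 2) = (4 pi / 3) rho alpha, with alpha in A^3 and rho in
    particles per A^3.
    """
    if alpha_a3 < 0 or density_per_a3 < 0:
        raise ValidationError("alpha and density must be non-negative")
    f = (4.0 * math.pi / 3.0) * density_per_a3 * alpha_a3
    if f >= 1.0:
        raise ValidationError(
            f"(4pi/3) rho alpha = {f:.4f} >= 1: beyond Lorentz-Lorenz validity")
    return math.sqrt((1.0 + 2.0 * f) / (1.0 - f))


def lorentz_lorenz_alpha(n: float, density_per_a3: float) -> float:
    """Exact inverse of :func:`lorentz_lorenz_index`."""
    if n < 1:
        raise ValidationError("refractive index must be >= 1")
    if not density_per_a3 > 0:
        raise ValidationError("density must be positive")
    return (n ** 2 - 1.0) / (n ** 2 + 2.0) * 3.0 / (4.0 * math.pi * density_per_a3)


# ---------------------------------------------------------------------------
# Medium model / excess polarizability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumModel:
    """Displaced-solvent polarizability.

    The medium contribution is the polarizability of the solvent volume the
    molecule displaces: alpha_m = V_mol * rho_water * alpha_water.  V_mol can
    be given directly (A^3) or derived from molecular mass (Da) and partial
    specific volume (cm^3/g).
    """

    alpha_m: float  # A^3
    v_mol: float = 0.0  # A^3

    def __post_init__(self):
        if self.alpha_m < 0:
            raise ValidationError("medium polarizability must be >= 0")


def medium_polarizability(mass_da: float | None = None,
                          partial_specific_volume: float = DEFAULT_PARTIAL_SPECIFIC_VOLUME,
                          water_alpha: float = WATER_ALPHA_A3,
                          water_density: float = WATER_DENSITY_A3,
                          v_mol: float | None = None) -> MediumModel:
    """Average polarizability of the displaced solvent (A^3).

    Either pass the displaced volume ``v_mol`` (A^3) directly, or a
    molecular mass in Da with a partial specific volume, from which
    V_mol = mass * v_bar / N_A (converted to A^3).
    """
    if v_mol is None:
        if mass_da is None:
            raise ValidationError("give either mass_da or v_mol")
        if not mass_da > 0:
            raise ValidationError("mass must be positive")
        # g/mol * cm^3/g / (1/mol) = cm^3; 1 cm^3 = 1e24 A^3
        v_mol = mass_da * partial_specific_volume / Avogadro * 1e24
    if v_mol < 0:
        raise ValidationError("displaced volume must be >= 0")
    return MediumModel(alpha_m=v_mol * water_density * water_alpha,
                       v_mol=v_mol)


@dataclass(frozen=True)
class ExcessPolarizability:
    """Molecular polarizability minus the displaced-medium contribution."""

    alpha_ex_avg: float            # A^3
    vector_magnitudes_ex: np.ndarray  # ||alpha_ex,k|| = ||alpha_k|| - alpha_m
    alpha_m: float


def excess_polarizability(result, medium: MediumModel | float = 0.0
                          ) -> ExcessPolarizability:
    """Subtract the displaced-medium polarizability from a molecular result.

    ``result`` is a :class:`~polscat.dipole_model.PolarizabilityResult`.
    Negative excess (molecule less polarizable than the displaced solvent)
    is allowed but flagged with a warning.
    """
    alpha_m = medium.alpha_m if isinstance(medium, MediumModel) else float(medium)
    ex_avg = result.alpha_avg - alpha_m
    ex_vec = np.asarray(result.vector_magnitudes, dtype=float) - alpha_m
    if ex_avg < 0 or np.any(ex_vec < 0):
        warnings.warn("negative excess polarizability: molecule is less "
                      "polarizable than the displaced medium",
                      RuntimeWarning, stacklevel=2)
    return ExcessPolarizability(alpha_ex_avg=float(ex_avg),
                                vector_magnitudes_ex=ex_vec,
                                alpha_m=alpha_m)


# ---------------------------------------------------------------------------
# Scattering and photon counting
# ---------------------------------------------------------------------------

def scattering_fraction(alpha_ex_a3: float, config: OpticalConfig) -> float:
    """Focused-beam scattered/incident power ratio (dimensionless).

    <P_sc>/<P_in> = k^4 alpha^2 / (24 pi^2 eps_m^2 w^2), with alpha the
    excess polarizability volume converted to m^3 and w the beam waist.
    """
    if config.beam_waist is None or not config.beam_waist > 0:
        raise ValidationError("focused form needs a positive beam waist")
    a = alpha_ex_a3 * A3_TO_M3
    return (config.k ** 4 * a ** 2
            / (24.0 * math.pi ** 2 * config.epsilon_m ** 2
               * config.beam_waist ** 2))


def scattering_cross_section(alpha_ex_a3: float, config: OpticalConfig) -> float:
    """sigma/8 (m^2): multiply by intensity (W/m^2) for scattered power.

    Plane-wave dipole form: <P_sc> = k^4 alpha^2 / (48 pi eps_m^2) * I_in.
    """
    a = alpha_ex_a3 * A3_TO_M3
    return config.k ** 4 * a ** 2 / (48.0 * math.pi * config.epsilon_m ** 2)


def scattered_power(alpha_ex_a3: float, config: OpticalConfig) -> float:
    """Mean scattered power (W) from whichever beam description is set.

    Uses the focused form when the config carries a power and waist, the
    plane-wave cross-section form when it carries an intensity.
    """
    if config.power is not None and config.beam_waist is not None:
        return scattering_fraction(alpha_ex_a3, config) * config.power
    if config.intensity is not None:
        return scattering_cross_section(alpha_ex_a3, config) * config.intensity
    raise ValidationError(
        "config needs (power, beam_waist) or intensity to give a power")


def photon_count(p_sc: float, tau: float, wavelength: float) -> float:
    """Mean photon number <n> = tau * P_sc * lambda / (h c)."""
    if p_sc < 0 or tau < 0 or not wavelength > 0:
        raise ValidationError("power/time must be >= 0, wavelength > 0")
    return tau * p_sc * wavelength / (h * c)


def is_resolvable(n_a: float, n_b: float) -> bool:
    """Shot-noise criterion: |<n_a> - <n_b>| > sqrt(<n_a> + <n_b>).

    Poissonian counts: the mean step between the two states must exceed the
    combined standard deviation of the two counts (strict inequality).
    """
    if n_a < 0 or n_b < 0:
        raise ValidationError("photon counts must be >= 0")
    return abs(n_a - n_b) > math.sqrt(n_a + n_b)


# ---------------------------------------------------------------------------
# Minimum resolving intensity
# ---------------------------------------------------------------------------

def _state_weights(alpha_a_a3, alpha_b_a3, tau_a, tau_b):
    if tau_a < 0 or tau_b < 0:
        raise ValidationError("integration times must be >= 0")
    wa = (alpha_a_a3 * A3_TO_M3) ** 2 * tau_a
    wb = (alpha_b_a3 * A3_TO_M3) ** 2 * tau_b
    if wa == wb:
        raise DegenerateStatesError(
            "states indistinguishable (alpha^2 tau equal): "
            "resolving intensity is infinite")
    return wa, wb


def min_intensity(alpha_a_a3: float, alpha_b_a3: float,
                  tau_a: float, tau_b: float, config: OpticalConfig,
                  mode: str = "printed") -> float:
    """Minimum incident intensity (W/m^2) to resolve two states at shot noise.

    mode='printed' (default):
        I_min = 48 c n_m^2 pi h / (k^4 lambda)
                * (a_a^2 t_a + a_b^2 t_b) / |a_a^2 t_a - a_b^2 t_b|^2
        with the polarizability volumes in m^3.
    mode='derived':
        the same quantity obtained self-consistently from the plane-wave
        scattered power, photon counting and the shot-noise criterion; it
        carries eps_m^2 = n_m^4 in the scattered power and therefore differs
        from the printed form by a factor n_m^2.
    """
    wa, wb = _state_weights(alpha_a_a3, alpha_b_a3, tau_a, tau_b)
    nm = config.medium_index
    k4 = config.k ** 4
    ratio = (wa + wb) / abs(wa - wb) ** 2
    if mode == "printed":
        prefactor = 48.0 * c * nm ** 2 * math.pi * h / (k4 * config.wavelength)
    elif mode == "derived":
        prefactor = 48.0 * math.pi * nm ** 4 * h * c / (config.wavelength * k4)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return prefactor * ratio


def min_intensity_w_per_um2(alpha_a_a3, alpha_b_a3, tau_a, tau_b, config,
                            mode: str = "printed") -> float:
    """:func:`min_intensity` expressed in W/um^2."""
    return min_intensity(alpha_a_a3, alpha_b_a3, tau_a, tau_b, config,
                         mode) * W_M2_TO_W_UM2


def photon_count_at_intensity(alpha_a3: float, intensity: float, tau: float,
                              config: OpticalConfig,
                              epsilon_power: int = 2) -> float:
    """Photon count for a state at a given plane-wave intensity.

    ``epsilon_power`` selects how the medium permittivity enters the
    scattered power: 2 is the physical plane-wave form (eps_m^2 = n_m^4);
    1 matches the convention embedded in the printed minimum-intensity
    formula, and is what makes the shot-noise equality exact at I_min in
    'printed' mode.
    """
    a = alpha_a3 * A3_TO_M3
    p_sc = (config.k ** 4 * a ** 2
            / (48.0 * math.pi * config.epsilon_m ** epsilon_power) * intensity)
    return photon_count(p_sc, tau, config.wavelength)


@dataclass(frozen=True)
class DetectabilityResult:
    """Scattered powers, photon counts and resolvability of two states."""

    p_sc_a: float
    p_sc_b: float
    n_a: float
    n_b: float
    resolvable: bool
    i_min: float           # W/m^2
    i_min_w_per_um2: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "p_sc_a_W": self.p_sc_a,
            "p_sc_b_W": self.p_sc_b,
            "n_a_photons": self.n_a,
            "n_b_photons": self.n_b,
            "resolvable": self.resolvable,
            "I_min_W_per_m2": self.i_min,
            "I_min_W_per_um2": self.i_min_w_per_um2,
            "mode": self.mode,
        }


def detectability(alpha_a_a3: float, alpha_b_a3: float,
                  tau_a: float, tau_b: float, config: OpticalConfig,
                  mode: str = "printed") -> DetectabilityResult:
    """Full shot-noise detectability assessment of a conformational change.

    Computes per-state scattered powers and photon counts at the configured
    intensity (if any), whether the change is resolvable there, and the
    minimum resolving intensity.
    """
    i_min = min_intensity(alpha_a_a3, alpha_b_a3, tau_a, tau_b, config, mode)
    intensity = config.intensity if config.intensity is not None else 0.0
    cfg_i = OpticalConfig(wavelength=config.wavelength,
                          medium_index=config.medium_index,
                          beam_waist=config.beam_waist,
                          intensity=intensity)
    p_a = scattering_cross_section(alpha_a_a3, cfg_i) * intensity
    p_b = scattering_cross_section(alpha_b_a3, cfg_i) * intensity
    n_a = photon_count(p_a, tau_a, config.wavelength)
    n_b = photon_count(p_b, tau_b, config.wavelength)
    return DetectabilityResult(
        p_sc_a=p_a, p_sc_b=p_b, n_a=n_a, n_b=n_b,
        resolvable=is_resolvable(n_a, n_b),
        i_min=i_min, i_min_w_per_um2=i_min * W_M2_TO_W_UM2, mode=mode)


def deformation_strain(e_field_magnitude: float, permittivity: float,
                       young_modulus: float) -> float:
    """Electrostrictive strain S = (eps / Y) |E|^2 of a homogeneous sphere.

    ``permittivity`` is the molecular permittivity (F/m), ``young_modulus``
    the molecule's Young modulus (Pa).
    """
    if not young_modulus > 0:
        raise ValidationError("Young modulus must be positive")
    return permittivity / young_modulus * e_field_magnitude ** 2
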