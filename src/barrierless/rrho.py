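"""Quasi-harmonic RRHO entropies for the complex and its fragments.

The molecular partition function is factorized into translational,
rotational, vibrational and electronic parts under the ideal-gas /
rigid-rotor / harmonic-oscillator model and each factor's entropy is
evaluated in closed form (Sackur-Tetrode for translation, classical rotor
formulas, harmonic-oscillator mode sum, R ln(g) for the electronic ground
state).  Vibrational modes below a cutoff (default 100 cm^-1) are raised to
the cutoff before the mode sum, the quasi-harmonic treatment applied by
GoodVibes-style thermochemistry corrections: harmonic frequencies of such
soft modes are unreliable and would otherwise contribute spuriously large
entropies.

The quantity that feeds the entropy sigmoid is the dissociation entropy
amplitude -T*(S_A + S_B - S_AB): the asymptotic value of -T*dS at infinite
fragment separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .scan_io import SpeciesInput

log = logging.getLogger(__name__)

R = constants.R                      # J mol^-1 K^-1
_KB = constants.k                    # J K^-1
_H = constants.h                     # J s
_C_CM = constants.c * 100.0          # cm s^-1
_AMU = constants.atomic_mass         # kg
_A2M = 1e-10                         # m per Å

#: default quasi-harmonic raising cutoff, cm^-1
DEFAULT_RAISING_CUTOFF = 100.0

#: smallest principal moment (amu Å^2) below which a rotor is treated as linear
LINEARITY_TOLERANCE = 1e-3


@dataclass
class ThermoState:
    """RRHO entropy decomposition of one species at fixed (T, P).

    Entropies are in J mol^-1 K^-1; ``minus_T_S`` is -T*s_total in kJ/mol.
    """

    temperature: float
    pressure: float
    s_trans: float
    s_rot: float
    s_vib: float
    s_elec: float
    species_label: str = ""

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib + self.s_elec

    @property
    def minus_T_S(self) -> float:
        return -self.temperature * self.s_total / 1000.0


@dataclass
class EntropyAmplitude:
    """Entropy change of full dissociation AB -> A + B and its -T*dS value.

    ``amplitude`` (kJ/mol) is the asymptote of the sigmoid entropy model; it
    is negative when dissociation gains entropy.
    """

    delta_s_diss: float  # J mol^-1 K^-1
    amplitude: float     # kJ/mol
    temperature: float   # K


def translational_entropy(molar_mass: float, temperature: float,
                          pressure: float) -> float:
    """Sackur-Tetrode translational entropy of an ideal gas.

    Parameters are the molar mass in kg/mol, T in K and P in Pa; the result
    is in J mol^-1 K^-1.
    """
    if molar_mass <= 0 or temperature <= 0 or pressure <= 0:
        raise ValueError("molar mass, temperature and pressure must be positive")
    m = molar_mass / constants.N_A
    q_trans = (2.0 * np.pi * m * _KB * temperature / _H**2) ** 1.5 \
        * _KB * temperature / pressure
    return R * (np.log(q_trans) + 2.5)


def _inertia_moments(element_symbols, coordinates) -> np.ndarray:
    """Principal moments of inertia in amu Å^2, ascending."""
    masses = np.array([_mass_amu(s) for s in element_symbols])
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    coords = coordinates - np.average(coordinates, axis=0, weights=masses)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    ixx = np.sum(masses * (y**2 + z**2))
    iyy = np.sum(masses * (x**2 + z**2))
    izz = np.sum(masses * (x**2 + y**2))
    ixy = -np.sum(masses * x * y)
    ixz = -np.sum(masses * x * z)
    iyz = -np.sum(masses * y * z)
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def _mass_amu(symbol: str) -> float:
    from ._elements import atomic_weight
    return atomic_weight(symbol)


def rotational_entropy(element_symbols, coordinates, symmetry_number: int,
                       temperature: float) -> float:
    """Classical rigid-rotor entropy in J mol^-1 K^-1.

    Single atoms contribute 0.  A species whose smallest principal moment
    falls below the linearity tolerance is treated with the linear-rotor
    formula; otherwise the nonlinear classical formula with the user-supplied
    symmetry number is used.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if symmetry_number < 1:
        raise ValueError("symmetry number must be >= 1")
    if len(element_symbols) < 2:
        return 0.0
    moments = _inertia_moments(element_symbols, coordinates)  # amu Å^2
    if moments[-1] < LINEARITY_TOLERANCE:
        raise ValueError("all atoms coincide: inertia tensor is singular")
    sigma = symmetry_number
    si = moments * _AMU * _A2M**2  # kg m^2
    if moments[0] < LINEARITY_TOLERANCE:
        # linear rotor: the two nonzero moments are (nearly) equal
        i_lin = 0.5 * (si[1] + si[2])
        q_rot = 8.0 * np.pi**2 * i_lin * _KB * temperature / (sigma * _H**2)
        return R * (np.log(q_rot) + 1.0)
    q_rot = (np.sqrt(np.pi) / sigma) \
        * (8.0 * np.pi**2 * _KB * temperature / _H**2) ** 1.5 \
        * np.sqrt(si[0] * si[1] * si[2])
    return R * (np.log(q_rot) + 1.5)


def vibrational_entropy(frequencies, temperature: float,
                        raising_cutoff: float = DEFAULT_RAISING_CUTOFF,
                        discard_imaginary: bool = False) -> float:
    """Quasi-harmonic vibrational entropy in J mol^-1 K^-1.

    Every mode below ``raising_cutoff`` (cm^-1) is replaced by the cutoff
    before the harmonic-oscillator entropy term is applied; the result is the
    sum over modes.  Negative entries denote imaginary modes and raise an
    error unless ``discard_imaginary`` drops them with a warning.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(frequencies, dtype=float)
    if nu.size == 0:
        return 0.0
    if np.any(nu <= 0):
        if not discard_imaginary:
            raise ValueError(
                "imaginary or zero frequency encountered; pass "
                "discard_imaginary=True to drop such modes")
        bad = nu[nu <= 0]
        log.warning("discarding %d imaginary/zero modes: %s", bad.size, bad)
        nu = nu[nu > 0]
        if nu.size == 0:
            return 0.0
    nu = np.maximum(nu, raising_cutoff)
    x = _H * _C_CM * nu / (_KB * temperature)
    terms = x / np.expm1(x) - np.log(-np.expm1(-x))
    return R * float(np.sum(terms))


def electronic_entropy(multiplicity: int) -> float:
    """Ground-state electronic entropy R ln(2S+1) in J mol^-1 K^-1."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return R * np.log(multiplicity)


def species_entropy(species: SpeciesInput, temperature: float = 298.15,
                    pressure: float = 101325.0,
                    raising_cutoff: float = DEFAULT_RAISING_CUTOFF,
                    discard_imaginary: bool = False) -> ThermoState:
    """Full RRHO entropy decomposition of one species."""
    return ThermoState(
        temperature=temperature,
        pressure=pressure,
        s_trans=translational_entropy(species.molar_mass, temperature, pressure),
        s_rot=rotational_entropy(species.element_symbols, species.coordinates,
                                 species.symmetry_number, temperature),
        s_vib=vibrational_entropy(species.frequencies, temperature,
                                  raising_cutoff, discard_imaginary),
        s_elec=electronic_entropy(species.multiplicity),
        species_label=species.label,
    )


def entropy_amplitude(complex_state: ThermoState, fragment_a: ThermoState,
                      fragment_b: ThermoState) -> EntropyAmplitude:
    """Dissociation entropy S_A + S_B - S_AB and its -T*dS amplitude in kJ/mol.

    All three states must share temperature and pressure.  For a typical
    small-molecule dissociation at room temperature the amplitude is of the
    order of tens of kJ/mol and negative (entropy is gained).
    """
    states = (complex_state, fragment_a, fragment_b)
    temps = {s.temperature for s in states}
    pressures = {s.pressure for s in states}
    if len(temps) != 1 or len(pressures) != 1:
        raise ValueError("complex and fragments must share temperature and pressure")
    t = complex_state.temperature
    ds = fragment_a.s_total + fragment_b.s_total - complex_state.s_total
    return EntropyAmplitude(delta_s_diss=ds, amplitude=-t * ds / 1000.0,
                            temperature=t)
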