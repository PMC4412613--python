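"""Activity-corrected equilibrium electrochemistry under the tonoplast sign convention.

Sign convention (Bertl): membrane voltage = cytoplasmic potential minus
vacuolar potential; positive current is cation flux from cytoplasm to
vacuole.  With that convention the Nernst potential of an ion is

    E = (RT / zF) * ln(a_vac / a_cyt)

and the Goldman-Hodgkin-Katz (GHK) voltage equation for a set of permeant
monovalent anions X reads

    E_rev = (RT / F) * ln( sum P_X a_X,cyt / sum P_X a_X,vac ).

Single-ion activity coefficients come from a Debye-Hueckel-family model
selected by ``model``:

``"limiting"`` (default)
    log10 gamma = -A z^2 sqrt(I).  Reproduces the study's printed
    reversal-potential arithmetic essentially exactly (see docs/methods.md).
``"guntelberg"``
    log10 gamma = -A z^2 sqrt(I) / (1 + sqrt(I)).
``"davies"``
    log10 gamma = -A z^2 [ sqrt(I)/(1+sqrt(I)) - 0.3 I ].
``"ideal"``
    gamma = 1 (concentrations used as activities).

A is evaluated at the solution temperature from the dielectric constant of
water.  Divalent ions (Ca2+, Mg2+) enter ionic strength only; they are not
treated as permeant in the GHK sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import (
    ConfigurationError,
    InvalidInputError,
    NoSolutionError,
    UndefinedPotentialError,
)
from .solutions import MOBILITY, SolutionSpec

__all__ = [
    "ReversalResult",
    "GAS_CONSTANT",
    "FARADAY",
    "DEFAULT_ACTIVITY_MODEL",
    "debye_hueckel_a",
    "ionic_strength",
    "activity_coefficient",
    "ion_activity",
    "nernst_potential",
    "ghk_reversal_potential",
    "fit_permeability_ratio",
    "henderson_junction_potential",
]

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212            # C mol^-1

DEFAULT_ACTIVITY_MODEL = "limiting"


@dataclass(frozen=True)
class ReversalResult:
    """Fitted permeability ratio with the reversal potential it reproduces."""

    e_rev_mV: float
    permeability_ratio: float
    reference_ion: str
    test_ion: str = ""

    def __post_init__(self):
        if not math.isfinite(self.e_rev_mV):
            raise InvalidInputError("e_rev must be finite")
        if self.permeability_ratio <= 0:
            raise InvalidInputError("permeability ratio must be > 0")


def _thermal_voltage_mV(temperature_K: float) -> float:
    return 1000.0 * GAS_CONSTANT * temperature_K / FARADAY


def debye_hueckel_a(temperature_K: float) -> float:
    """Debye-Hueckel A coefficient (log10 basis) at the given temperature.

    Uses the standard dielectric-constant polynomial for water; ~0.509 at 22 C.
    """
    t = temperature_K - 273.15
    eps = 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.41e-6 * t**3
    return 1.8246e6 / (eps * temperature_K) ** 1.5


def ionic_strength(solution: SolutionSpec) -> float:
    """Molar ionic strength I = 1/2 sum c_i z_i^2, concentrations in mol/L."""
    total = 0.0
    for s in solution.species:
        if s.concentration_mM < 0:
            raise InvalidInputError(f"negative concentration for {s.name}")
        total += (s.concentration_mM / 1000.0) * s.charge**2
    return 0.5 * total


def activity_coefficient(charge: int, ionic_strength_M: float,
                         temperature_K: float = 295.15,
                         model: str = DEFAULT_ACTIVITY_MODEL) -> float:
    """Single-ion activity coefficient gamma for the given valence."""
    if ionic_strength_M < 0:
        raise InvalidInputError("ionic strength must be >= 0")
    if ionic_strength_M > 0.7:
        warnings.warn(
            f"ionic strength {ionic_strength_M:.3g} M is outside the validity "
            "range of Debye-Hueckel-family activity models",
            stacklevel=2,
        )
    if model == "ideal":
        return 1.0
    a = debye_hueckel_a(temperature_K)
    sqrt_i = math.sqrt(ionic_strength_M)
    if model == "limiting":
        d = sqrt_i
    elif model == "guntelberg":
        d = sqrt_i / (1.0 + sqrt_i)
    elif model == "davies":
        d = sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength_M
    else:
        raise InvalidInputError(f"unknown activity model {model!r}")
    return 10.0 ** (-a * charge**2 * d)


def ion_activity(solution: SolutionSpec, ion: str,
                 model: str = DEFAULT_ACTIVITY_MODEL) -> float:
    """Activity (in mM units) of an ion in a solution: gamma * c."""
    c = solution.concentration_mM(ion)
    charge = next((s.charge for s in solution.species if s.name == ion), None)
    if charge is None or c <= 0:
        raise UndefinedPotentialError(
            f"ion {ion!r} absent or at zero concentration in {solution.label!r}"
        )
    gamma = activity_coefficient(charge, ionic_strength(solution),
                                 solution.temperature_K, model)
    return gamma * c


def nernst_potential(ion: str, cytoplasmic: SolutionSpec, vacuolar: SolutionSpec,
                     model: str = DEFAULT_ACTIVITY_MODEL) -> float:
    """Nernst equilibrium potential in mV, cytoplasmic minus vacuolar.

    E = (RT/zF) ln(a_vac/a_cyt); symmetric activities give 0 mV.
    """
    z = next((s.charge for s in cytoplasmic.species if s.name == ion), None)
    if z is None:
        z = next((s.charge for s in vacuolar.species if s.name == ion), None)
    if z is None or z == 0:
        raise UndefinedPotentialError(f"ion {ion!r} not found in either solution")
    a_cyt = ion_activity(cytoplasmic, ion, model)
    a_vac = ion_activity(vacuolar, ion, model)
    vt = _thermal_voltage_mV(cytoplasmic.temperature_K)
    return vt / z * math.log(a_vac / a_cyt)


def ghk_reversal_potential(permeant_anions, cytoplasmic: SolutionSpec,
                           vacuolar: SolutionSpec,
                           model: str = DEFAULT_ACTIVITY_MODEL) -> float:
    """GHK reversal potential (mV) for monovalent permeant anions.

    Parameters
    ----------
    permeant_anions : iterable of (ion, relative permeability)
        At least one entry; permeabilities > 0.  With a single species this
        reduces exactly to :func:`nernst_potential`.
    """
    permeant = list(permeant_anions)
    if not permeant:
        raise InvalidInputError("at least one permeant species required")
    if all(p == 0 for _, p in permeant):
        raise InvalidInputError("all permeabilities are zero")
    if any(p < 0 for _, p in permeant):
        raise InvalidInputError("permeabilities must be > 0")
    for ion, _ in permeant:
        for sol in (cytoplasmic, vacuolar):
            z = next((s.charge for s in sol.species if s.name == ion), None)
            if z is not None and z != -1:
                raise InvalidInputError(
                    f"GHK sums are restricted to monovalent anions; {ion!r} has z={z}"
                )
    num = 0.0
    den = 0.0
    for ion, perm in permeant:
        try:
            a_cyt = ion_activity(cytoplasmic, ion, model)
        except UndefinedPotentialError:
            a_cyt = 0.0
        try:
            a_vac = ion_activity(vacuolar, ion, model)
        except UndefinedPotentialError:
            a_vac = 0.0
        num += perm * a_cyt
        den += perm * a_vac
    if num <= 0 or den <= 0:
        raise UndefinedPotentialError("permeant anions absent from one side")
    vt = _thermal_voltage_mV(cytoplasmic.temperature_K)
    return vt * math.log(num / den)


def fit_permeability_ratio(measured_e_rev_mV: float, test_ion: str,
                           reference_ion: str, cytoplasmic: SolutionSpec,
                           vacuolar: SolutionSpec,
                           model: str = DEFAULT_ACTIVITY_MODEL,
                           bracket: tuple[float, float] = (1e-4, 1e4)) -> ReversalResult:
    """Invert the two-anion GHK equation for r = P_test / P_reference.

    Finds r such that :func:`ghk_reversal_potential` reproduces the measured
    reversal potential to better than 0.01 mV.
    """
    if not math.isfinite(measured_e_rev_mV):
        raise InvalidInputError("measured reversal potential must be finite")

    def mismatch(log_r: float) -> float:
        r = 10.0 ** log_r
        e = ghk_reversal_potential([(test_ion, r), (reference_ion, 1.0)],
                                   cytoplasmic, vacuolar, model)
        return e - measured_e_rev_mV

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise NoSolutionError(
            f"no permeability ratio in ({bracket[0]:g}, {bracket[1]:g}) reproduces "
            f"{measured_e_rev_mV:g} mV"
        )
    log_r = brentq(mismatch, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    r = 10.0 ** log_r
    assert abs(mismatch(log_r)) < 0.01, "GHK inversion did not reach 0.01 mV"
    return ReversalResult(e_rev_mV=measured_e_rev_mV, permeability_ratio=r,
                          reference_ion=reference_ion, test_ion=test_ion)


def _mobility(species) -> float:
    if species.mobility is not None:
        return species.mobility
    try:
        return MOBILITY[species.name]
    except KeyError:
        raise ConfigurationError(
            f"no mobility configured for species {species.name!r}; set "
            "IonSpecies.mobility or add it to vactrace.solutions.MOBILITY"
        ) from None


def henderson_junction_potential(pipette_filling: SolutionSpec,
                                 bath: SolutionSpec) -> float:
    """Henderson liquid-junction potential in mV, bath minus pipette.

    Antisymmetric by construction: swapping the two solutions flips the sign.
    Raises :class:`ConfigurationError` listing any charged species without a
    mobility.
    """
    names: dict[str, dict] = {}
    missing = []
    for side, sol in (("p", pipette_filling), ("b", bath)):
        for s in sol.species:
            if s.charge == 0:
                continue
            try:
                u = _mobility(s)
            except ConfigurationError:
                missing.append(s.name)
                continue
            entry = names.setdefault(s.name, {"z": s.charge, "u": u, "p": 0.0, "b": 0.0})
            entry[side] += s.concentration_mM / 1000.0
    if missing:
        raise ConfigurationError(
            "no mobility configured for species: " + ", ".join(sorted(set(missing)))
        )
    num = den = sum_p = sum_b = 0.0
    for e in names.values():
        z, u = e["z"], e["u"]
        dc = e["b"] - e["p"]
        num += (abs(z) * u / z) * dc
        den += abs(z) * u * dc
        sum_p += abs(z) * u * e["p"]
        sum_b += abs(z) * u * e["b"]
    if abs(den) < 1e-15 or sum_p <= 0 or sum_b <= 0 or sum_p == sum_b:
        return 0.0
    vt = _thermal_voltage_mV(bath.temperature_K)
    return vt * (num / den) * math.log(sum_p / sum_b)
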