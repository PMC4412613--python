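"""Solution specifications: ion species, recipes, serialization.

Units are fixed package-wide: concentrations in mM, temperature in K,
voltages in mV. A :class:`SolutionSpec` is the unit of solution design and
all electrochemical computations.

The recipe builders below construct the bath/pipette media used throughout
vacuolar patch-clamp work on moss vacuoles: a strong acid (HNO3 or HCl)
neutralised by the bulky, poorly permeant buffer cation BTP
(bis-tris propane), plus CaCl2/MgCl2 and optionally the Ca2+ chelator EGTA.

BTP speciation
--------------
BTP is a diprotic base (literature pKa ~6.8 and ~9.0).  Two conventions are
provided:

``"monovalent"``
    every BTP molecule counted as one +1 charge.  This is the convention
    under which the study's printed reversal-potential arithmetic is
    reproduced essentially exactly, so it is the default for
    electrochemistry recipes.
``"diprotic"``
    Henderson-Hasselbalch speciation into BTP+ and BTP2+ at the solution
    pH.  Chemically more faithful; default for chelator ionic-strength
    computation, where the higher ionic strength it implies is what
    reproduces the printed EGTA designs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import yaml

from .errors import InvalidInputError

__all__ = [
    "IonSpecies",
    "SolutionSpec",
    "MOBILITY",
    "BTP_PKA1",
    "BTP_PKA2",
    "btp_species",
    "btp_acid_solution",
    "egta_buffered_bath",
    "simple_salt_solution",
]

DEFAULT_TEMPERATURE_K = 295.15  # 22 C, the stated growth temperature

# Limiting equivalent conductances at 25 C, S cm^2 per mole of charge.
# Used as relative mobilities in the Henderson junction-potential formula
# (only ratios matter there).  Standard electrochemistry-table values;
# BTP is approximated by the TRIS-H+ value (overridable per species).
MOBILITY = {
    "H": 349.8,
    "K": 73.5,
    "Na": 50.1,
    "Li": 38.7,
    "NH4": 73.6,
    "Ca": 59.5,
    "Mg": 53.1,
    "Cl": 76.35,
    "NO3": 71.46,
    "OH": 198.3,
    "TRIS": 29.5,
    "BTP": 29.5,   # approximated by TRIS-H+
    "BTP2": 29.5,  # per equivalent, same approximation
}

BTP_PKA1 = 6.8
BTP_PKA2 = 9.0


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species in a solution.

    Parameters
    ----------
    name : str
        Ion label ("NO3", "Ca", "BTP", ...).
    charge : int
        Signed valence.  Must be nonzero for any species that enters
        ionic-strength or junction-potential sums.
    concentration_mM : float
        Concentration in mmol/L.
    mobility : float, optional
        Relative ionic mobility for junction potentials; falls back to the
        :data:`MOBILITY` table when omitted.
    """

    name: str
    charge: int
    concentration_mM: float
    mobility: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.concentration_mM) or self.concentration_mM < 0:
            raise InvalidInputError(
                f"species {self.name!r}: concentration must be finite and >= 0, "
                f"got {self.concentration_mM}"
            )
        if int(self.charge) != self.charge:
            raise InvalidInputError(f"species {self.name!r}: charge must be an integer")


@dataclass(frozen=True)
class SolutionSpec:
    """A named solution: list of ion species, pH, temperature."""

    species: tuple[IonSpecies, ...]
    pH: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if not (3.0 <= self.pH <= 10.0):
            raise InvalidInputError(f"pH {self.pH} outside the supported range [3, 10]")
        if not (273.0 <= self.temperature_K <= 310.0):
            raise InvalidInputError(
                f"temperature {self.temperature_K} K outside the supported range [273, 310]"
            )

    # -- convenience -----------------------------------------------------
    def concentration_mM(self, name: str) -> float:
        """Total concentration of all species with the given name."""
        return sum(s.concentration_mM for s in self.species if s.name == name)

    def with_species(self, *extra: IonSpecies) -> "SolutionSpec":
        return replace(self, species=self.species + tuple(extra))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "temperature_K": self.temperature_K,
            "pH": self.pH,
            "species": [
                {
                    "name": s.name,
                    "charge": s.charge,
                    "mM": s.concentration_mM,
                    **({"mobility": s.mobility} if s.mobility is not None else {}),
                }
                for s in self.species
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionSpec":
        species = tuple(
            IonSpecies(
                name=s["name"],
                charge=int(s["charge"]),
                concentration_mM=float(s["mM"]),
                mobility=s.get("mobility"),
            )
            for s in d.get("species", [])
        )
        return cls(
            species=species,
            pH=float(d["pH"]),
            temperature_K=float(d.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            label=d.get("label", ""),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SolutionSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SolutionSpec":
        return cls.from_dict(json.loads(text))


def btp_species(total_mM: float, pH: float, speciation: str = "monovalent",
                pka1: float = BTP_PKA1, pka2: float = BTP_PKA2) -> tuple[IonSpecies, ...]:
    """Charged BTP species for a total BTP concentration at the given pH."""
    if total_mM == 0:
        return ()
    if speciation == "monovalent":
        return (IonSpecies("BTP", +1, total_mM),)
    if speciation == "diprotic":
        # fractions of BTP-H2(2+), BTP-H(+), BTP(0) at this pH
        w2 = 1.0
        w1 = 10.0 ** (pH - pka1)
        w0 = 10.0 ** (2 * pH - pka1 - pka2)
        z = w2 + w1 + w0
        out = []
        if w2 / z > 0:
            out.append(IonSpecies("BTP2", +2, total_mM * w2 / z))
        if w1 / z > 0:
            out.append(IonSpecies("BTP", +1, total_mM * w1 / z))
        return tuple(out)
    raise InvalidInputError(f"unknown BTP speciation {speciation!r}")


def btp_acid_solution(acid_anion: str = "NO3", acid_mM: float = 200.0,
                      btp_mM: float = 160.0, pH: float = 7.0,
                      cacl2_mM: float = 2.0, mgcl2_mM: float = 2.0,
                      temperature_K: float = DEFAULT_TEMPERATURE_K,
                      btp_speciation: str = "monovalent",
                      label: str = "") -> SolutionSpec:
    """BTP-buffered strong-acid medium, e.g. 200 mM HNO3 / 2 CaCl2 / 2 MgCl2.

    CaCl2, MgCl2 and the acid are treated as fully dissociated; the chloride
    pool collects 2 eq per divalent salt.
    """
    for name, v in (("acid_mM", acid_mM), ("btp_mM", btp_mM),
                    ("cacl2_mM", cacl2_mM), ("mgcl2_mM", mgcl2_mM)):
        if v < 0:
            raise InvalidInputError(f"{name} must be >= 0, got {v}")
    species = [IonSpecies(acid_anion, -1, acid_mM)]
    cl = 2.0 * cacl2_mM + 2.0 * mgcl2_mM
    if acid_anion == "Cl":
        species[0] = IonSpecies("Cl", -1, acid_mM + cl)
    elif cl > 0:
        species.append(IonSpecies("Cl", -1, cl))
    if cacl2_mM > 0:
        species.append(IonSpecies("Ca", +2, cacl2_mM))
    if mgcl2_mM > 0:
        species.append(IonSpecies("Mg", +2, mgcl2_mM))
    species.extend(btp_species(btp_mM, pH, btp_speciation))
    if not label:
        label = f"{acid_mM:g} mM H{acid_anion}, {btp_mM:g} mM BTP, pH {pH:g}"
    return SolutionSpec(tuple(species), pH=pH, temperature_K=temperature_K, label=label)


def egta_buffered_bath(cacl2_mM: float = 0.0, mgcl2_mM: float = 2.0,
                       egta_mM: float = 2.0, hno3_mM: float = 200.0,
                       btp_mM: float = 148.0, pH: float = 7.0,
                       temperature_K: float = DEFAULT_TEMPERATURE_K,
                       btp_speciation: str = "diprotic",
                       label: str = "") -> SolutionSpec:
    """EGTA-containing cytoplasmic bath used for free-Ca2+/Mg2+ designs.

    EGTA is entered with charge -2 (its dominant protonation state near
    pH 7) for the ionic-strength estimate; the chelation solver reads the
    total from this species entry.
    """
    for name, v in (("hno3_mM", hno3_mM), ("btp_mM", btp_mM), ("egta_mM", egta_mM),
                    ("cacl2_mM", cacl2_mM), ("mgcl2_mM", mgcl2_mM)):
        if v < 0:
            raise InvalidInputError(f"{name} must be >= 0, got {v}")
    species = [IonSpecies("NO3", -1, hno3_mM)]
    cl = 2.0 * cacl2_mM + 2.0 * mgcl2_mM
    if cl > 0:
        species.append(IonSpecies("Cl", -1, cl))
    if cacl2_mM > 0:
        species.append(IonSpecies("Ca", +2, cacl2_mM))
    if mgcl2_mM > 0:
        species.append(IonSpecies("Mg", +2, mgcl2_mM))
    if egta_mM > 0:
        species.append(IonSpecies("EGTA", -2, egta_mM))
    species.extend(btp_species(btp_mM, pH, btp_speciation))
    if not label:
        label = (f"{hno3_mM:g} HNO3 / {egta_mM:g} EGTA / {cacl2_mM:g} CaCl2 / "
                 f"{mgcl2_mM:g} MgCl2, pH {pH:g}")
    return SolutionSpec(tuple(species), pH=pH, temperature_K=temperature_K, label=label)


def simple_salt_solution(name: str, cation: str, anion: str, mM: float,
                         pH: float = 7.0,
                         temperature_K: float = DEFAULT_TEMPERATURE_K) -> SolutionSpec:
    """Fully dissociated 1:1 salt solution (KCl, NaNO3, ...)."""
    return SolutionSpec(
        (IonSpecies(cation, +1, mM), IonSpecies(anion, -1, mM)),
        pH=pH, temperature_K=temperature_K, label=name,
    )
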