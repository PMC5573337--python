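"""Inorganic aqueous speciation of the test media.

Computes ionic strength, Davies single-ion activity coefficients and the
equilibrium activities of the free ions (Cu2+, Co2+, Mg2+, Ca2+, H+, ...)
and the inorganic complexes (CuOH+, CuCO3(aq), CuHCO3+, CoOH+, CoCO3(aq),
CoHCO3+, plus the MSO4 ion pairs) in a defined nutrient solution.

Model assumptions
-----------------
* pH is fixed (the bioassay media are buffered), so no proton balance is
  solved; {H+} = 10**(-pH) by definition of the pH scale.
* Open CO2 system: dissolved CO2 follows Henry's law at a configurable
  partial pressure (default 10**-3.5 atm), so the carbonate-ligand
  activities are fully determined by pH and pCO2.
* Inorganic ligands only — the media contain no dissolved organic matter,
  so the humic/fulvic chemistry of full speciation codes is not needed.
* Activity corrections via the Davies equation (A = 0.51, b = 0.3, 25 C),
  iterated with the speciation until the ionic strength is stable.

With those assumptions every metal's mass balance is linear in its free-ion
concentration once the free sulfate concentration is known, so the solver
reduces to a one-dimensional root find on sulfate nested in the ionic
strength loop; mass balance then holds to machine precision by
construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConfigError, ConvergenceError, InvalidInputError

__all__ = [
    "SolutionComposition",
    "EquilibriumConstantSet",
    "SpeciationResult",
    "SPECIES_CHARGE",
    "ionic_strength",
    "davies_gamma",
    "speciate",
]

#: charge of every species the solver can produce (free ions and complexes)
SPECIES_CHARGE: dict[str, int] = {
    "H+": 1,
    "OH-": -1,
    "CO2(aq)": 0,
    "HCO3-": -1,
    "CO3-2": -2,
    "K+": 1,
    "Na+": 1,
    "Cl-": -1,
    "Ca2+": 2,
    "Mg2+": 2,
    "Cu2+": 2,
    "Co2+": 2,
    "SO4-2": -2,
    "CuOH+": 1,
    "CuCO3(aq)": 0,
    "CuHCO3+": 1,
    "CuSO4(aq)": 0,
    "CoOH+": 1,
    "CoCO3(aq)": 0,
    "CoHCO3+": 1,
    "CoSO4(aq)": 0,
    "MgSO4(aq)": 0,
    "CaSO4(aq)": 0,
}

_FREE_ION = {"Cu": "Cu2+", "Co": "Co2+", "Mg": "Mg2+", "Ca": "Ca2+"}
_COMPONENTS = ("K", "Na", "Ca", "Mg", "Cu", "Co", "Cl", "SO4")


@dataclass(frozen=True)
class SolutionComposition:
    """Total dissolved composition and pH of one test medium.

    ``totals`` maps component name ({K, Na, Ca, Mg, Cu, Co, Cl, SO4}) to its
    total concentration in mol/L.  pH is treated as externally buffered, so
    the charge balance of the stated totals need not hold.
    """

    totals: Mapping[str, float]
    pH: float
    temperature_C: float = 25.0
    pCO2_atm: float = 10 ** -3.5
    label: str = ""

    def __post_init__(self):
        unknown = set(self.totals) - set(_COMPONENTS)
        if unknown:
            raise ConfigError(f"unknown components in totals: {sorted(unknown)}")
        for name, c in self.totals.items():
            if c < 0 or not math.isfinite(c):
                raise InvalidInputError(f"total {name} must be >= 0, got {c}")
        if not 2.0 <= self.pH <= 12.0:
            raise InvalidInputError(f"pH must lie in [2, 12], got {self.pH}")
        if self.pCO2_atm <= 0:
            raise InvalidInputError("pCO2_atm must be > 0")

    def total(self, component: str) -> float:
        return float(self.totals.get(component, 0.0))


@dataclass(frozen=True)
class EquilibriumConstantSet:
    """Named thermodynamic formation constants (log10, 25 C, I = 0).

    ``complexes`` and ``ion_pairs`` map species name -> dict with keys
    ``metal``, ``ligand``, ``logK``, ``charge``.  The split matters only for
    the ``include_ion_pairs`` switch; both are solved identically.
    """

    carbonate: Mapping[str, float]
    complexes: Mapping[str, Mapping]
    ion_pairs: Mapping[str, Mapping]
    davies_A: float = 0.51
    davies_b: float = 0.3

    @classmethod
    def default(cls) -> "EquilibriumConstantSet":
        """Load the packaged constants table (editable JSON, provenance per
        constant recorded in the file)."""
        with resources.files("blmtu.data").joinpath("equilibrium_constants.json").open() as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "EquilibriumConstantSet":
        carb = {k: v["value"] for k, v in raw["carbonate_system"].items()}
        for block in ("complexes", "ion_pairs"):
            for name, entry in raw.get(block, {}).items():
                if name not in SPECIES_CHARGE:
                    raise ConfigError(f"unknown species in constants: {name!r}")
                if entry["ligand"] not in SPECIES_CHARGE:
                    raise ConfigError(f"unknown ligand for {name!r}: {entry['ligand']!r}")
        return cls(
            carbonate=carb,
            complexes=dict(raw.get("complexes", {})),
            ion_pairs=dict(raw.get("ion_pairs", {})),
            davies_A=raw.get("davies", {}).get("A", 0.51),
            davies_b=raw.get("davies", {}).get("b", 0.3),
        )

    @classmethod
    def from_json(cls, path) -> "EquilibriumConstantSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def logK(self, species: str) -> float:
        if species in self.complexes:
            return float(self.complexes[species]["logK"])
        if species in self.ion_pairs:
            return float(self.ion_pairs[species]["logK"])
        raise ConfigError(f"no formation constant for species {species!r}")


@dataclass
class SpeciationResult:
    """Solved equilibrium state of one solution.

    activities are on the mol/L scale ({X} = gamma_z * [X]); ``fractions``
    are concentration fractions of the parent metal's total (they sum to 1
    over the tracked species of a fully tracked metal).  ``complex_ratios``
    gives, per metal, the activity ratio {IM}/{M2+} for each complex — these
    depend only on pH/pCO2/ionic strength, not on the metal dose, and are
    the lambda terms of the biotic-ligand EC50 model.
    """

    ionic_strength: float
    gamma: dict[int, float]
    activities: dict[str, float]
    concentrations: dict[str, float]
    fractions: dict[str, float]
    complex_ratios: dict[str, dict[str, float]]
    iterations: int
    composition: SolutionComposition = field(repr=False, default=None)

    def free_ion_activity_share(self, metal: str) -> float:
        """Free-ion activity as a proportion of the total metal
        concentration, {M2+}/M_total — the quantity speciation reports as
        'percent free metal activity'. Returns NaN if the metal is absent."""
        tot = self.composition.total(metal) if self.composition else 0.0
        if tot <= 0:
            return float("nan")
        return self.activities[_FREE_ION[metal]] / tot


def ionic_strength(comp: SolutionComposition | None,
                   speciated_concs: Mapping[str, float]) -> float:
    """I = 1/2 * sum(c_i * z_i**2) over all charged species (mol/L).

    ``comp`` is accepted for interface symmetry but the sum runs over the
    explicit species map; unknown species raise ConfigError.
    """
    total = 0.0
    for name, c in speciated_concs.items():
        if name not in SPECIES_CHARGE:
            raise ConfigError(f"unknown species {name!r} in ionic_strength")
        if c < 0:
            raise InvalidInputError(f"negative concentration for {name}: {c}")
        total += c * SPECIES_CHARGE[name] ** 2
    return 0.5 * total


def davies_gamma(I: float, z: int, A: float = 0.51, b: float = 0.3) -> float:
    """Davies single-ion activity coefficient.

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - b I); neutral species and
    zero ionic strength give gamma = 1.  Valid to I ~ 0.5 M.
    """
    if I < 0:
        raise InvalidInputError(f"ionic strength must be >= 0, got {I}")
    if z == 0 or I == 0:
        return 1.0
    s = math.sqrt(I)
    return 10.0 ** (-A * z * z * (s / (1.0 + s) - b * I))


def _fully_dissociated_ionic_strength(comp: SolutionComposition) -> float:
    concs = {
        "K+": comp.total("K"), "Na+": comp.total("Na"), "Ca2+": comp.total("Ca"),
        "Mg2+": comp.total("Mg"), "Cu2+": comp.total("Cu"), "Co2+": comp.total("Co"),
        "Cl-": comp.total("Cl"), "SO4-2": comp.total("SO4"),
        "H+": 10.0 ** -comp.pH,
    }
    return ionic_strength(comp, concs)


def speciate(comp: SolutionComposition,
             constants: EquilibriumConstantSet | None = None,
             *,
             include_ion_pairs: bool = True,
             max_iter: int = 200,
             tol: float = 1e-9) -> SpeciationResult:
    """Solve the fixed-pH, open-CO2 inorganic equilibrium of one medium.

    Iterates the Davies activity corrections with the speciation until the
    relative change in ionic strength is below ``tol`` (default well inside
    the 1e-6 contract).  Per-metal mass balance is closed-form, hence exact.

    Raises ConvergenceError if the ionic-strength loop fails, ConfigError
    for unknown species in a user-supplied constants set.
    """
    K = constants or _DEFAULT_CONSTANTS
    species = dict(K.complexes)
    if include_ion_pairs:
        species.update(K.ion_pairs)

    aH = 10.0 ** -comp.pH
    # ligand activities fixed by pH and pCO2 (activity basis -> gamma-free)
    aCO2 = 10.0 ** K.carbonate["logK_H_CO2"] * comp.pCO2_atm
    aHCO3 = 10.0 ** K.carbonate["logKa1"] * aCO2 / aH
    aCO3 = 10.0 ** K.carbonate["logKa2"] * aHCO3 / aH
    aOH = 10.0 ** K.carbonate["logKw"] / aH
    fixed_ligand_act = {"OH-": aOH, "HCO3-": aHCO3, "CO3-2": aCO3}

    metals = [m for m in ("Cu", "Co", "Mg", "Ca")]
    t_so4 = comp.total("SO4")

    I = _fully_dissociated_ionic_strength(comp)
    last_I = I
    for iteration in range(1, max_iter + 1):
        g = {z: davies_gamma(I, z, K.davies_A, K.davies_b) for z in (0, 1, 2)}

        def metal_side_terms(metal: str, aSO4: float) -> float:
            """sum over complexes of K * {L} * g2 / g_species, i.e. the
            factor s.t. [M_tot] = [M2+] * (1 + terms)."""
            terms = 0.0
            for name, entry in species.items():
                if entry["metal"] != metal:
                    continue
                lig = entry["ligand"]
                aL = aSO4 if lig == "SO4-2" else fixed_ligand_act[lig]
                gz = g[abs(entry["charge"])]
                terms += 10.0 ** entry["logK"] * aL * g[2] / gz
            return terms

        def so4_residual(free_so4_conc: float) -> float:
            aSO4 = g[2] * free_so4_conc
            bound = 0.0
            for m in metals:
                tm = comp.total(m)
                if tm == 0.0:
                    continue
                free_m = tm / (1.0 + metal_side_terms(m, aSO4))
                # sulfate bound in this metal's SO4 species
                for name, entry in species.items():
                    if entry["metal"] == m and entry["ligand"] == "SO4-2":
                        gz = g[abs(entry["charge"])]
                        bound += (10.0 ** entry["logK"] * aSO4 * g[2] / gz) * free_m
            return free_so4_conc + bound - t_so4

        any_so4_pairs = any(e["ligand"] == "SO4-2" for e in species.values())
        if t_so4 > 0 and any_so4_pairs:
            free_so4 = brentq(so4_residual, 0.0, t_so4, xtol=1e-18, rtol=1e-14)
        else:
            free_so4 = t_so4
        aSO4 = g[2] * free_so4

        conc: dict[str, float] = {
            "H+": aH / g[1], "OH-": aOH / g[1],
            "CO2(aq)": aCO2, "HCO3-": aHCO3 / g[1], "CO3-2": aCO3 / g[2],
            "K+": comp.total("K"), "Na+": comp.total("Na"),
            "Cl-": comp.total("Cl"), "SO4-2": free_so4,
        }
        for m in metals:
            tm = comp.total(m)
            free_m = tm / (1.0 + metal_side_terms(m, aSO4)) if tm > 0 else 0.0
            conc[_FREE_ION[m]] = free_m
            for name, entry in species.items():
                if entry["metal"] != m:
                    continue
                lig = entry["ligand"]
                aL = aSO4 if lig == "SO4-2" else fixed_ligand_act[lig]
                gz = g[abs(entry["charge"])]
                conc[name] = 10.0 ** entry["logK"] * aL * g[2] / gz * free_m

        I_new = ionic_strength(comp, conc)
        if I_new > 0 and abs(I_new - I) / max(I_new, 1e-30) < tol:
            I = I_new
            break
        last_I, I = I, I_new
    else:
        raise ConvergenceError(
            "ionic-strength loop did not converge",
            {"I_last": last_I, "I_new": I, "iterations": max_iter},
        )

    g = {z: davies_gamma(I, z, K.davies_A, K.davies_b) for z in (0, 1, 2)}
    activities = {name: conc[name] * g[abs(SPECIES_CHARGE[name])] for name in conc}

    fractions: dict[str, float] = {}
    complex_ratios: dict[str, dict[str, float]] = {}
    for m in metals:
        ratios = {}
        for name, entry in species.items():
            if entry["metal"] != m:
                continue
            lig = entry["ligand"]
            aL = activities["SO4-2"] if lig == "SO4-2" else fixed_ligand_act[lig]
            ratios[name] = 10.0 ** entry["logK"] * aL
        complex_ratios[m] = ratios
        tm = comp.total(m)
        if tm > 0:
            fractions[_FREE_ION[m]] = conc[_FREE_ION[m]] / tm
            for name in ratios:
                fractions[name] = conc[name] / tm

    return SpeciationResult(
        ionic_strength=I,
        gamma=g,
        activities=activities,
        concentrations=conc,
        fractions=fractions,
        complex_ratios=complex_ratios,
        iterations=iteration,
        composition=comp,
    )


_DEFAULT_CONSTANTS = EquilibriumConstantSet.default()


def speciate_media(media, constants=None, **kwargs):
    """Speciate a sequence of SolutionComposition; returns a list of
    SpeciationResult in the same order."""
    return [speciate(m, constants, **kwargs) for m in media]
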