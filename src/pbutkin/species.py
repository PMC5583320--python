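"""Toxin/species identities and the albumin model.

The four model protein-bound uremic toxins (PBUTs) are indole-3-acetic
acid (IAA), indoxyl sulfate (IS), p-cresyl glucuronide (pCG) and
p-cresyl sulfate (pCS); urea is carried as the conventional non-bound
comparator.  Default molecular weights are free-acid values from
standard chemistry references and can be overridden in configuration
(reported clinical concentrations are sometimes for salts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .units import InvalidParameterError, mass_to_molar

#: Default molar masses, g/mol (free acid / free base forms).
DEFAULT_MOLECULAR_WEIGHTS: dict[str, float] = {
    "IAA": 175.18,
    "IS": 213.21,
    "pCG": 284.26,
    "pCS": 188.20,
    "urea": 60.06,
    "phenol_red": 354.38,
    "albumin": 66500.0,
}


@dataclass(frozen=True)
class Species:
    """Identity and pre-dialysis plasma status of one solute.

    Attributes
    ----------
    name : solute identifier (e.g. ``"IS"``).
    molecular_weight : g/mol.
    binding_degree_0 : pre-dialysis bound fraction PT/(PT+T) in plasma,
        in [0, 1).
    c_total_0 : pre-dialysis total (free + bound) plasma concentration,
        mg/L.
    """

    name: str
    molecular_weight: float
    binding_degree_0: float
    c_total_0: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise InvalidParameterError("molecular_weight must be > 0")
        if not 0.0 <= self.binding_degree_0 < 1.0:
            raise InvalidParameterError("binding_degree_0 must be in [0, 1)")
        if self.c_total_0 <= 0:
            raise InvalidParameterError("c_total_0 must be > 0")

    @property
    def c_total_0_molar(self) -> float:
        """Pre-dialysis total plasma concentration in M."""
        return mass_to_molar(self.c_total_0, self.molecular_weight)

    @property
    def free_fraction_0(self) -> float:
        return 1.0 - self.binding_degree_0

    def with_binding_degree(self, bound_fraction: float) -> "Species":
        """Copy with a different initial bound fraction (range studies)."""
        return replace(self, binding_degree_0=bound_fraction)


@dataclass(frozen=True)
class AlbuminModel:
    """Plasma/interstitial albumin pool description.

    ``plasma_mass_fraction`` is the fraction of whole-body albumin mass
    residing in plasma (~40% in hemodialysis patients, the remainder in
    the interstitium).
    """

    plasma_concentration_0: float = 4.0  # g/dL
    molecular_weight: float = DEFAULT_MOLECULAR_WEIGHTS["albumin"]
    plasma_mass_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.plasma_concentration_0 <= 0 or self.molecular_weight <= 0:
            raise InvalidParameterError("albumin concentration and MW must be > 0")
        if not 0.0 < self.plasma_mass_fraction < 1.0:
            raise InvalidParameterError("plasma_mass_fraction must be in (0, 1)")

    @property
    def plasma_molar_0(self) -> float:
        """Pre-dialysis total plasma albumin concentration in M."""
        # g/dL -> g/L -> mol/L
        return self.plasma_concentration_0 * 10.0 / self.molecular_weight

    def interstitial_molar_0(self, v_plasma: float, v_interstitial: float) -> float:
        """Total interstitial albumin concentration (M) implied by the
        mass split, given compartment volumes in L."""
        if v_plasma <= 0 or v_interstitial <= 0:
            raise InvalidParameterError("volumes must be > 0")
        plasma_moles = self.plasma_molar_0 * v_plasma
        total_moles = plasma_moles / self.plasma_mass_fraction
        interstitial_moles = total_moles - plasma_moles
        return interstitial_moles / v_interstitial


def default_species(name: str, binding_degree_0: float, c_total_0: float,
                    molecular_weight: float | None = None) -> Species:
    """Build a :class:`Species` using the default molecular-weight table."""
    mw = molecular_weight if molecular_weight is not None else DEFAULT_MOLECULAR_WEIGHTS[name]
    return Species(name=name, molecular_weight=mw,
                   binding_degree_0=binding_degree_0, c_total_0=c_total_0)
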