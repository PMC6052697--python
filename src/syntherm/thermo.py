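"""Gibbs energy correction chain from tabulated standard values to process conditions.

The chain is: (1) extended Debye-Hueckel correction of each species' formation
Gibbs energy and enthalpy to the medium ionic strength, (2) reaction quotient
term RT ln Q built from partial pressures (atm), solute concentrations (mol/L)
and proton activity 10^(-pH), (3) Gibbs-Helmholtz transfer of the resulting
transformed reaction Gibbs energy to the process temperature.

Conventions: water activity is fixed at 1 and never enters Q; the proton
enters only through 10^(-pH); gases enter as partial pressures.  With the
optional weak-acid speciation, carboxylate concentrations are multiplied by
the dissociated fraction Ka/(Ka + [H+]) of the corresponding acid, with Ka
derived from the bundled ionic-strength-corrected formation energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .library import (
    CompoundRecord,
    Library,
    ReactionSpec,
    emol_transferred,
)

__all__ = [
    "GAS_CONSTANT",
    "REFERENCE_TEMPERATURE",
    "DebyeHuckelParams",
    "ProcessConditions",
    "ThermoResult",
    "correct_formation_gibbs",
    "correct_formation_enthalpy",
    "corrected_dissociation_constant",
    "reaction_standard_state",
    "quotient_term",
    "temperature_adjust",
    "evaluate_drG",
]

#: kJ/(mol K)
GAS_CONSTANT = 8.314e-3
#: K; all standard formation values are tabulated here
REFERENCE_TEMPERATURE = 298.15


@dataclass(frozen=True)
class DebyeHuckelParams:
    """Fixed constants of the extended Debye-Hueckel corrections.

    ``A`` (kg^1/2 mol^-1/2) is the Debye-Hueckel slope in water at 25 C, ``B``
    (L^1/2 mol^-1/2) an empirical constant valid for ionic strengths of
    0.05-0.25 M, and ``enthalpy_coefficient`` the analogous numerator constant
    of the enthalpy correction.
    """

    A: float = 1.1758
    B: float = 1.6
    enthalpy_coefficient: float = 1.4775
    reference_temperature: float = REFERENCE_TEMPERATURE
    gas_constant: float = GAS_CONSTANT


_DH = DebyeHuckelParams()


@dataclass
class ProcessConditions:
    """The environment at which transformed reaction energies are evaluated.

    temperature in K, ionic_strength in mol/kg, partial pressures in atm,
    solute concentrations in mol/L.  ``speciate_weak_acids`` switches on the
    pH-dependent dissociated-fraction correction of carboxylate activities
    (off by default: stated metabolite concentrations are then taken as the
    anion activity directly).
    """

    temperature: float = 310.15
    ionic_strength: float = 0.08
    pH: float = 7.0
    partial_pressures: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    speciate_weak_acids: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        for gas, pressure in self.partial_pressures.items():
            if pressure < 0:
                raise ValueError(f"partial pressure of {gas!r} must be >= 0")
        if not (0.05 <= self.ionic_strength <= 0.25):
            warnings.warn(
                "ionic strength outside 0.05-0.25 M: the Debye-Hueckel B "
                "constant is parameterised for that range",
                stacklevel=2,
            )

    def activity(self, record: CompoundRecord) -> float:
        """Activity of one quotient participant (pressure, concentration or 10^-pH)."""
        if record.phase == "liquid-water":
            return 1.0
        if record.phase == "proton":
            return 10.0 ** (-self.pH)
        if record.phase == "gas":
            try:
                return self.partial_pressures[record.identifier]
            except KeyError:
                raise ValueError(
                    f"no partial pressure supplied for gas {record.identifier!r}"
                ) from None
        try:
            value = self.concentrations[record.identifier]
        except KeyError:
            raise ValueError(
                f"no concentration supplied for solute {record.identifier!r}"
            ) from None
        if value <= 0:
            raise ValueError(
                f"concentration of {record.identifier!r} must be positive to enter Q"
            )
        return value

    def replace(self, **changes) -> "ProcessConditions":
        payload = dict(
            temperature=self.temperature,
            ionic_strength=self.ionic_strength,
            pH=self.pH,
            partial_pressures=dict(self.partial_pressures),
            concentrations=dict(self.concentrations),
            speciate_weak_acids=self.speciate_weak_acids,
        )
        payload.update(changes)
        return ProcessConditions(**payload)


@dataclass(frozen=True)
class ThermoResult:
    """Full correction chain for one reaction at one condition (kJ/reaction)."""

    reaction: str
    drG0_I: float
    drH0_I: float
    rtlnQ: float
    drG_prime_298: float
    drG_prime_T: float
    drG_per_emol: float


def _ionic_factor(ionic_strength: float, params: DebyeHuckelParams) -> float:
    sqrt_i = math.sqrt(ionic_strength)
    return sqrt_i / (1.0 + params.B * sqrt_i)


def correct_formation_gibbs(
    dfG0: float,
    charge: int,
    ionic_strength: float,
    params: DebyeHuckelParams = _DH,
) -> float:
    """Extended Debye-Hueckel correction of a formation Gibbs energy (kJ/mol).

    dfG(I) = dfG(0) - RT A z^2 sqrt(I) / (1 + B sqrt(I)) with RT at 298.15 K.
    Identity for neutral species or zero ionic strength.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    rt = params.gas_constant * params.reference_temperature
    return dfG0 - rt * params.A * charge * charge * _ionic_factor(ionic_strength, params)


def correct_formation_enthalpy(
    dfH0: float,
    charge: int,
    ionic_strength: float,
    params: DebyeHuckelParams = _DH,
) -> float:
    """Ionic-strength correction of a formation enthalpy (kJ/mol), additive with +1.4775 z^2."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    return dfH0 + params.enthalpy_coefficient * charge * charge * _ionic_factor(
        ionic_strength, params
    )


def corrected_dissociation_constant(drG0_I: float) -> float:
    """Ka of an acid dissociation from its (ionic-strength-corrected) reaction Gibbs energy.

    Solves 0 = drG0(I) + RT ln Ka at 298.15 K.
    """
    exponent = -drG0_I / (GAS_CONSTANT * REFERENCE_TEMPERATURE)
    if exponent > 500.0:  # overflow guard
        raise OverflowError("dissociation energy implies an unphysically large Ka")
    return math.exp(exponent)


def reaction_standard_state(
    reaction: ReactionSpec,
    compounds: Mapping[str, CompoundRecord],
    ionic_strength: float,
    params: DebyeHuckelParams = _DH,
) -> tuple[float, float]:
    """Reaction Gibbs energy and enthalpy at the stated ionic strength (kJ/reaction)."""
    drG = 0.0
    drH = 0.0
    for identifier, coeff in reaction.stoichiometry.items():
        record = compounds[identifier]
        drG += coeff * correct_formation_gibbs(
            record.dfG0, record.charge, ionic_strength, params
        )
        if record.dfH0 is None:
            raise ValueError(
                f"no formation enthalpy bundled for {identifier!r}; "
                f"cannot evaluate reaction {reaction.label!r}"
            )
        drH += coeff * correct_formation_enthalpy(
            record.dfH0, record.charge, ionic_strength, params
        )
    return drG, drH


def dissociation_drG0_I(
    anion: str,
    acid: str,
    compounds: Mapping[str, CompoundRecord],
    ionic_strength: float,
    params: DebyeHuckelParams = _DH,
) -> float:
    """Gibbs energy of HA -> A- + H+ at the stated ionic strength (kJ/mol)."""
    a = compounds[anion]
    ha = compounds[acid]
    proton = next(c for c in compounds.values() if c.phase == "proton")
    return (
        correct_formation_gibbs(a.dfG0, a.charge, ionic_strength, params)
        + correct_formation_gibbs(proton.dfG0, proton.charge, ionic_strength, params)
        - correct_formation_gibbs(ha.dfG0, ha.charge, ionic_strength, params)
    )


def _dissociated_fraction(
    identifier: str,
    library_acids: Mapping[str, str],
    compounds: Mapping[str, CompoundRecord],
    conditions: ProcessConditions,
) -> float:
    acid = library_acids.get(identifier)
    if acid is None:
        return 1.0
    ka = corrected_dissociation_constant(
        dissociation_drG0_I(identifier, acid, compounds, conditions.ionic_strength)
    )
    proton = 10.0 ** (-conditions.pH)
    return ka / (ka + proton)


def quotient_term(
    reaction: ReactionSpec,
    conditions: ProcessConditions,
    compounds: Mapping[str, CompoundRecord],
    conjugate_acids: Mapping[str, str] | None = None,
) -> float:
    """RT ln Q in kJ/reaction, with RT at the 298.15 K reference temperature.

    Gases enter as partial pressures in atm, solutes as mol/L, the proton as
    10^(-pH) and water as activity 1.  With ``conditions.speciate_weak_acids``
    the carboxylate activities are scaled by the dissociated fraction of the
    corresponding acid.
    """
    acids = conjugate_acids or {}
    ln_q = 0.0
    for identifier, coeff in reaction.stoichiometry.items():
        record = compounds[identifier]
        if record.phase == "liquid-water":
            continue
        activity = conditions.activity(record)
        if conditions.speciate_weak_acids and record.phase == "aqueous-solute":
            activity *= _dissociated_fraction(identifier, acids, compounds, conditions)
        ln_q += coeff * math.log(activity)
    return GAS_CONSTANT * REFERENCE_TEMPERATURE * ln_q


def temperature_adjust(
    drG_prime_298: float, drH_prime_298: float, temperature: float
) -> float:
    """Gibbs-Helmholtz transfer of a transformed reaction Gibbs energy to T.

    drG'(T) = drG'(298) * T/298.15 + drH'(298) * (298.15 - T)/298.15.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t0 = REFERENCE_TEMPERATURE
    return drG_prime_298 * temperature / t0 + drH_prime_298 * (t0 - temperature) / t0


def evaluate_drG(
    reaction: ReactionSpec,
    conditions: ProcessConditions,
    library: Library,
    quotient_after_gibbs_helmholtz: bool = False,
) -> ThermoResult:
    """Chain ionic-strength, quotient and temperature corrections for one reaction.

    By default the quotient term (evaluated with RT at 298.15 K) is added to
    the standard-state energy before the Gibbs-Helmholtz step, so it is scaled
    by T/298.15 together with it; this is numerically identical to adding
    R*T_process*ln Q afterwards.  Setting ``quotient_after_gibbs_helmholtz``
    instead adds the unscaled 298.15 K quotient term after the temperature
    transfer of the standard-state energy (an alternative literal reading of
    the correction sequence; the difference is (T/298.15 - 1) * RT ln Q).
    """
    drG0_I, drH0_I = reaction_standard_state(
        reaction, library.compounds, conditions.ionic_strength
    )
    rtlnq = quotient_term(
        reaction, conditions, library.compounds, library.conjugate_acids
    )
    drG_prime_298 = drG0_I + rtlnq
    if quotient_after_gibbs_helmholtz:
        drG_prime_T = temperature_adjust(drG0_I, drH0_I, conditions.temperature) + rtlnq
    else:
        drG_prime_T = temperature_adjust(drG_prime_298, drH0_I, conditions.temperature)
    per_emol = drG_prime_T / emol_transferred(reaction, library.compounds)
    return ThermoResult(
        reaction=reaction.label,
        drG0_I=drG0_I,
        drH0_I=drH0_I,
        rtlnQ=rtlnq,
        drG_prime_298=drG_prime_298,
        drG_prime_T=drG_prime_T,
        drG_per_emol=per_emol,
    )
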