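"""Curated compound and reaction data layer.

Holds the chemical species (standard formation Gibbs energies and enthalpies,
charges, elemental composition, degree of reduction) and the net biochemical
reactions of syngas-converting consortia together with their bioenergetic
parameters (ATP yield per turnover and average stoichiometric number chi).

All reactions are validated with exact rational arithmetic for element,
charge and electron balance before they are used anywhere downstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CompoundRecord",
    "ReactionSpec",
    "Library",
    "load_default_library",
    "validate_reaction",
    "degree_of_reduction",
]

PHASES = ("gas", "aqueous-solute", "liquid-water", "proton")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C2H3O2`` into a count mapping."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def degree_of_reduction(formula: Mapping[str, int], charge: int) -> int:
    """Electrons available per mole relative to the CO2/H2O/H+/N2 reference.

    gamma = 4 C + 1 H - 2 O - z.  Examples: H2 -> 2, CO -> 2,
    acetate(-) -> 8, ethanol -> 12, butyrate(-) -> 20; N2 and all inorganic
    carbon species carry 0.
    """
    return (
        4 * formula.get("C", 0)
        + formula.get("H", 0)
        - 2 * formula.get("O", 0)
        - charge
    )


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical species with formation energies and redox bookkeeping.

    ``dfG0`` and ``dfH0`` are standard formation values at 298.15 K and zero
    ionic strength in kJ/mol; ``dfH0`` may be ``None`` for species whose
    enthalpy is not bundled (using it then raises explicitly).
    """

    identifier: str
    formula: dict[str, int]
    charge: int
    phase: str
    dfG0: float
    dfH0: float | None
    source: str

    @property
    def electrons_per_mol(self) -> int:
        return degree_of_reduction(self.formula, self.charge)

    @property
    def carbon_count(self) -> int:
        return self.formula.get("C", 0)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"compound {self.identifier!r}: unknown phase {self.phase!r}"
            )
        if self.phase == "proton" and (self.dfG0 != 0.0 or self.dfH0 != 0.0):
            raise ValueError(
                f"compound {self.identifier!r}: proton must have zero formation values"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """A stoichiometric reaction with its energy-conservation parameters.

    ``stoichiometry`` maps compound identifiers to signed coefficients
    (reactants negative, products positive).  ``atp_yield`` is mol ATP per
    reaction turnover and ``chi`` the average stoichiometric number.
    """

    label: str
    stoichiometry: dict[str, float]
    atp_yield: float
    chi: float
    category: str
    atp_yield_alternatives: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.chi < 1:
            raise ValueError(f"reaction {self.label!r}: chi must be >= 1")

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec(
            label=f"{self.label}_reversed",
            stoichiometry={k: -v for k, v in self.stoichiometry.items()},
            atp_yield=self.atp_yield,
            chi=self.chi,
            category=self.category,
        )


@dataclass(frozen=True)
class Library:
    """The bundled compound table and reaction set plus the acid/anion map."""

    compounds: dict[str, CompoundRecord]
    reactions: dict[str, ReactionSpec]
    conjugate_acids: dict[str, str]

    def reaction(self, label: str) -> ReactionSpec:
        try:
            return self.reactions[label]
        except KeyError:
            raise KeyError(
                f"unknown reaction {label!r}; available: {sorted(self.reactions)}"
            ) from None


def _as_fraction(value: float) -> Fraction:
    return Fraction(str(value))


def validate_reaction(
    reaction: ReactionSpec, compounds: Mapping[str, CompoundRecord]
) -> list[str]:
    """Check element, charge and electron balance with exact arithmetic.

    Returns a list of human-readable violations; an empty list means the
    reaction is balanced.  Unknown compound identifiers raise ``KeyError``.
    """
    for identifier in reaction.stoichiometry:
        if identifier not in compounds:
            raise KeyError(
                f"reaction {reaction.label!r}: unknown compound {identifier!r}"
            )
    violations: list[str] = []
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    electrons = Fraction(0)
    for identifier, coeff in reaction.stoichiometry.items():
        record = compounds[identifier]
        nu = _as_fraction(coeff)
        for element, count in record.formula.items():
            elements[element] = elements.get(element, Fraction(0)) + nu * count
        charge += nu * record.charge
        electrons += nu * record.electrons_per_mol
    for element, total in sorted(elements.items()):
        if total != 0:
            violations.append(
                f"element balance violated for {element}: residual {total}"
            )
    if charge != 0:
        violations.append(f"charge balance violated: residual {charge}")
    if electrons != 0:
        violations.append(f"electron balance violated: residual {electrons}")
    return violations


def _load_compounds(path: Path) -> dict[str, CompoundRecord]:
    compounds: dict[str, CompoundRecord] = {}
    header: list[str] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["identifier", "formula", "charge", "phase", "dfG0", "dfH0", "source"]
            if header != expected:
                raise ValueError(f"{path}: unexpected header {header!r}")
            continue
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: malformed record {line!r}")
        row = dict(zip(header, fields))
        try:
            record = CompoundRecord(
                identifier=row["identifier"],
                formula=parse_formula(row["formula"]),
                charge=int(row["charge"]),
                phase=row["phase"],
                dfG0=float(row["dfG0"]),
                dfH0=float(row["dfH0"]) if row["dfH0"].strip() else None,
                source=row["source"],
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"{path}:{lineno}: bad compound record {row.get('identifier', '?')!r}: {exc}"
            ) from exc
        if record.identifier in compounds:
            raise ValueError(f"{path}:{lineno}: duplicate compound {record.identifier!r}")
        compounds[record.identifier] = record
    if not compounds:
        raise ValueError(f"{path}: no compound records found")
    return compounds


def _load_reactions(path: Path) -> tuple[dict[str, ReactionSpec], dict[str, str]]:
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict) or "reactions" not in payload:
        raise ValueError(f"{path}: expected a mapping with a 'reactions' list")
    reactions: dict[str, ReactionSpec] = {}
    for entry in payload["reactions"]:
        try:
            spec = ReactionSpec(
                label=entry["label"],
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                atp_yield=float(entry["atp_yield"]),
                chi=float(entry["chi"]),
                category=entry["category"],
                atp_yield_alternatives=tuple(
                    float(v) for v in entry.get("atp_yield_alternatives", ())
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: bad reaction record {entry.get('label', '?')!r}: {exc}"
            ) from exc
        reactions[spec.label] = spec
    conjugate = dict(payload.get("conjugate_acids", {}))
    return reactions, conjugate


def load_default_library(
    compounds_path: str | Path | None = None,
    reactions_path: str | Path | None = None,
) -> Library:
    """Load and validate the bundled constants, or user-supplied replacements.

    Every reaction must balance in elements, charge and electrons against the
    compound table; a malformed record fails the load naming the offender.
    """
    data_dir = resources.files("syntherm") / "data"
    cpath = Path(compounds_path) if compounds_path else Path(str(data_dir / "compounds.tsv"))
    rpath = Path(reactions_path) if reactions_path else Path(str(data_dir / "reactions.yaml"))
    compounds = _load_compounds(cpath)
    reactions, conjugate = _load_reactions(rpath)
    for spec in reactions.values():
        violations = validate_reaction(spec, compounds)
        if violations:
            raise ValueError(
                f"{rpath}: reaction {spec.label!r} is unbalanced: {violations}"
            )
    for anion, acid in conjugate.items():
        for name in (anion, acid):
            if name not in compounds:
                raise ValueError(f"{rpath}: conjugate-acid map names unknown compound {name!r}")
    return Library(compounds=compounds, reactions=reactions, conjugate_acids=conjugate)


def emol_transferred(
    reaction: ReactionSpec, compounds: Mapping[str, CompoundRecord]
) -> float:
    """Electron-mol transferred per reaction turnover.

    Computed as the summed degree of reduction of the consumed
    electron-carrying substrates (|coefficient| * electrons_per_mol over
    reactants with gamma > 0), e.g. 8 for 4 H2 + 2 CO2 -> acetate.  Used to
    normalise Gibbs energies per e-mol for cross-reaction comparison; it never
    enters the thermodynamic potential factor itself.
    """
    total = 0.0
    for identifier, coeff in reaction.stoichiometry.items():
        if coeff < 0:
            gamma = compounds[identifier].electrons_per_mol
            if gamma > 0:
                total += -coeff * gamma
    if total <= 0:
        raise ValueError(
            f"reaction {reaction.label!r} consumes no electron-carrying substrate"
        )
    return total


def is_finite_enthalpy(record: CompoundRecord) -> bool:
    return record.dfH0 is not None and math.isfinite(record.dfH0)
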