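"""Compound registry, pseudoisomer data model and reaction parsing.

A metabolite in buffered aqueous solution is modelled as an ensemble of
*pseudoisomers* -- microstates differing only in the number of bound
protons and magnesium ions, each carrying its own chemical standard
formation energy. The registry acts as a local compound cache indexed by
namespaced identifiers ("kegg:C00002" style); bare names live in the
``local:`` namespace and namespaces compare case-insensitively.

Reactions are sparse stoichiometric maps with exact rational
coefficients. By the buffered-proton convention, free H+ never appears
in a reaction's stoichiometry (hydrogen balance is absorbed by the
proton pool); water is kept as an explicit reactant.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import (
    ReactionSyntaxError,
    RegistryConflictError,
    UnknownCompoundError,
    ValidationError,
)

__all__ = [
    "Pseudoisomer",
    "CompoundEnsemble",
    "AqueousConditions",
    "ReactionSpec",
    "BalanceReport",
    "CompoundRegistry",
    "normalize_identifier",
    "register_compound",
    "resolve",
    "parse_reaction",
    "format_reaction",
    "check_balance",
    "parse_formula",
    "species_key",
    "split_species_key",
]


@dataclass(frozen=True)
class Pseudoisomer:
    """One protonation/Mg-binding microstate of a metabolite.

    Parameters
    ----------
    dgf_chemical : float
        Chemical standard Gibbs energy of formation, kJ/mol.
    n_h : int
        Number of hydrogen atoms bound to this microstate.
    n_mg : int
        Number of Mg2+ ions bound.
    charge : int
        Net charge in elementary units.
    """

    dgf_chemical: float
    n_h: int
    n_mg: int = 0
    charge: int = 0

    def __post_init__(self) -> None:
        if self.n_h < 0 or self.n_mg < 0:
            raise ValidationError("pseudoisomer proton and Mg counts must be >= 0")
        if not np.isfinite(self.dgf_chemical):
            raise ValidationError("pseudoisomer formation energy must be finite")


@dataclass(frozen=True)
class CompoundEnsemble:
    """A metabolite: a non-empty set of pseudoisomers plus identifiers.

    ``pseudoisomers[0]`` is the *reference* pseudoisomer: its formula and
    formation energy anchor balance checking and the chemical reaction
    energies the estimator works with.
    """

    primary_id: str
    pseudoisomers: tuple[Pseudoisomer, ...]
    aliases: tuple[str, ...] = ()
    formula: str | None = None
    group_vector: tuple[int, ...] | None = None
    is_proton: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        if not self.pseudoisomers:
            raise ValidationError(
                f"compound {self.primary_id!r} must declare at least one pseudoisomer"
            )
        if self.is_proton and self.is_water:
            raise ValidationError(
                f"compound {self.primary_id!r} cannot be both proton and water"
            )
        states = [(p.n_h, p.n_mg) for p in self.pseudoisomers]
        if len(set(states)) != len(states):
            raise ValidationError(
                f"compound {self.primary_id!r} has duplicate (n_h, n_mg) microstates"
            )
        object.__setattr__(self, "primary_id", normalize_identifier(self.primary_id))
        object.__setattr__(
            self, "aliases", tuple(normalize_identifier(a) for a in self.aliases)
        )
        if self.group_vector is not None:
            object.__setattr__(self, "group_vector", tuple(int(g) for g in self.group_vector))

    @property
    def reference(self) -> Pseudoisomer:
        return self.pseudoisomers[0]

    def all_identifiers(self) -> tuple[str, ...]:
        return (self.primary_id, *self.aliases)


@dataclass(frozen=True)
class AqueousConditions:
    """Buffered aqueous conditions: pH, pMg, ionic strength (M), T (K)."""

    p_h: float = 7.0
    p_mg: float = 3.0
    ionic_strength: float = 0.25
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_h <= 14.0:
            raise ValidationError(f"pH must be in [0, 14], got {self.p_h}")
        if not 0.0 <= self.p_mg <= 14.0:
            raise ValidationError(f"pMg must be in [0, 14], got {self.p_mg}")
        if self.ionic_strength < 0.0:
            raise ValidationError("ionic strength must be >= 0")
        if self.temperature <= 0.0:
            raise ValidationError("temperature must be > 0")

    def replace(self, **kwargs) -> "AqueousConditions":
        fields = dict(
            p_h=self.p_h,
            p_mg=self.p_mg,
            ionic_strength=self.ionic_strength,
            temperature=self.temperature,
        )
        fields.update(kwargs)
        return AqueousConditions(**fields)


_ID_RE = re.compile(r"^([A-Za-z0-9_.\-]+):(\S+)$")


def normalize_identifier(identifier: str) -> str:
    """Canonical identifier form: namespace lowercased, accession verbatim.

    Bare names (no colon) are placed in the ``local:`` namespace.
    """
    identifier = identifier.strip()
    if not identifier:
        raise ValidationError("empty compound identifier")
    m = _ID_RE.match(identifier)
    if m:
        return f"{m.group(1).lower()}:{m.group(2)}"
    if ":" in identifier:
        raise ValidationError(f"malformed identifier {identifier!r}")
    return f"local:{identifier}"


def species_key(identifier: str, compartment: str | None = None) -> str:
    """Stoichiometry key for a (compound, compartment) instance."""
    base = normalize_identifier(identifier)
    return f"{base}[{compartment}]" if compartment else base


_SPECIES_RE = re.compile(r"^(.*?)(?:\[([^\[\]]+)\])?$")


def split_species_key(key: str) -> tuple[str, str | None]:
    """Inverse of :func:`species_key`: (normalized id, compartment or None)."""
    m = _SPECIES_RE.match(key)
    assert m is not None
    return m.group(1), m.group(2)


@dataclass(frozen=True)
class ReactionSpec:
    """Sparse stoichiometric map over species keys.

    Coefficients are exact rationals; negative = consumed, positive =
    produced. For multi-compartment reactions keys carry an
    ``id[compartment]`` suffix and ``compartment_of`` maps each such key
    to its compartment label.
    """

    stoich: Mapping[str, Fraction]
    compartment_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        clean = {k: Fraction(v) for k, v in self.stoich.items() if Fraction(v) != 0}
        object.__setattr__(self, "stoich", clean)
        if self.compartment_of is not None:
            object.__setattr__(self, "compartment_of", dict(self.compartment_of))

    def __iter__(self) -> Iterator[tuple[str, Fraction]]:
        return iter(sorted(self.stoich.items()))

    def reverse(self) -> "ReactionSpec":
        return ReactionSpec(
            {k: -v for k, v in self.stoich.items()}, self.compartment_of
        )

    def __add__(self, other: "ReactionSpec") -> "ReactionSpec":
        stoich = dict(self.stoich)
        for k, v in other.stoich.items():
            stoich[k] = stoich.get(k, Fraction(0)) + v
        comp = dict(self.compartment_of or {})
        comp.update(other.compartment_of or {})
        return ReactionSpec(stoich, comp or None)

    def scale(self, factor) -> "ReactionSpec":
        f = Fraction(factor)
        return ReactionSpec(
            {k: f * v for k, v in self.stoich.items()}, self.compartment_of
        )

    def is_empty(self) -> bool:
        return not self.stoich


@dataclass
class BalanceReport:
    """Per-element/charge bookkeeping for a reaction on reference pseudoisomers.

    Hydrogen is reported separately from the other elements: under the
    buffered-proton convention an H imbalance is absorbed by the proton
    pool and does not count against ``balanced``.
    """

    element_imbalance: dict[str, Fraction] = field(default_factory=dict)
    h_imbalance: Fraction = Fraction(0)
    charge_imbalance: Fraction = Fraction(0)
    warnings: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool | None:
        """True iff all non-H elements balance; None if formulas were missing."""
        if self.warnings:
            return None
        return all(v == 0 for v in self.element_imbalance.values())


class CompoundRegistry:
    """Identifier-indexed local cache of compound ensembles."""

    def __init__(self, group_names: Iterable[str] = ()):
        names = list(group_names)
        if len(names) != len(set(names)):
            raise ValidationError("group names must be unique")
        self.group_names: list[str] = names
        self._by_id: dict[str, CompoundEnsemble] = {}
        self._compounds: list[CompoundEnsemble] = []

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[CompoundEnsemble]:
        return iter(self._compounds)

    def __contains__(self, identifier: str) -> bool:
        try:
            return normalize_identifier(identifier) in self._by_id
        except ValidationError:
            return False

    def register(self, definition: CompoundEnsemble) -> "CompoundRegistry":
        """Add a compound; idempotent for an identical re-registration."""
        if definition.group_vector is not None and self.group_names:
            if len(definition.group_vector) != len(self.group_names):
                raise ValidationError(
                    f"group vector of {definition.primary_id!r} has length "
                    f"{len(definition.group_vector)}, registry has "
                    f"{len(self.group_names)} groups"
                )
        existing = self._by_id.get(definition.primary_id)
        if existing is not None and existing == definition:
            return self  # idempotent
        for ident in definition.all_identifiers():
            bound = self._by_id.get(ident)
            if bound is not None and bound != definition:
                raise RegistryConflictError(
                    f"identifier {ident!r} already bound to {bound.primary_id!r}"
                )
        self._compounds.append(definition)
        for ident in definition.all_identifiers():
            self._by_id[ident] = definition
        return self

    def resolve(self, identifier: str) -> CompoundEnsemble:
        key = normalize_identifier(identifier)
        try:
            return self._by_id[key]
        except KeyError:
            suggestions = difflib.get_close_matches(key, self._by_id, n=3)
            raise UnknownCompoundError(identifier, suggestions) from None

    def resolve_species(self, key: str) -> CompoundEnsemble:
        """Resolve a stoichiometry key, ignoring any compartment suffix."""
        base, _ = split_species_key(key)
        return self.resolve(base)


def register_compound(
    registry: CompoundRegistry, definition: CompoundEnsemble
) -> CompoundRegistry:
    return registry.register(definition)


def resolve(registry: CompoundRegistry, identifier: str) -> CompoundEnsemble:
    return registry.resolve(identifier)


# --- reaction parsing ------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|<->|=>|=")
_COEFF_RE = re.compile(r"^(\d+(?:\.\d+)?|\d+/\d+)$")
_TERM_ID_RE = re.compile(r"^([A-Za-z0-9_.\-]+(?::\S+?)?)(?:\[([A-Za-z0-9_]+)\])?$")


def _parse_coefficient(token: str) -> Fraction:
    if "/" in token:
        num, den = token.split("/")
        return Fraction(int(num), int(den))
    return Fraction(token)


def _parse_side(
    registry: CompoundRegistry,
    side_text: str,
    sign: int,
    offset: int,
    full_text: str,
    stoich: dict[str, Fraction],
    compartments: dict[str, str],
) -> None:
    if not side_text.strip():
        raise ReactionSyntaxError("empty reaction side", full_text, offset)
    for term in side_text.split("+"):
        stripped = term.strip()
        pos = offset + term.index(stripped[0]) if stripped else offset
        if not stripped:
            raise ReactionSyntaxError("empty reactant term", full_text, pos)
        tokens = stripped.split()
        if len(tokens) == 2 and _COEFF_RE.match(tokens[0]):
            coeff, ident_token = _parse_coefficient(tokens[0]), tokens[1]
        elif len(tokens) == 1:
            coeff, ident_token = Fraction(1), tokens[0]
        else:
            raise ReactionSyntaxError(
                f"cannot parse term {stripped!r}", full_text, pos
            )
        m = _TERM_ID_RE.match(ident_token)
        if m is None:
            raise ReactionSyntaxError(
                f"malformed identifier {ident_token!r}", full_text, pos
            )
        ensemble = registry.resolve(m.group(1))
        if ensemble.is_proton:
            continue  # buffered-proton convention: H+ never enters stoichiometry
        key = species_key(ensemble.primary_id, m.group(2))
        stoich[key] = stoich.get(key, Fraction(0)) + sign * coeff
        if m.group(2):
            compartments[key] = m.group(2)
        offset += len(term) + 1


def parse_reaction(registry: CompoundRegistry, text: str) -> ReactionSpec:
    """Parse ``coeff? id (+ coeff? id)* (=|<=>) ...`` into a ReactionSpec.

    Left-side coefficients come out negative, right-side positive; a
    species occurring on both sides (same compartment) nets out, and a
    zero net coefficient is dropped. Protons are dropped entirely.
    """
    m = _ARROW_RE.search(text)
    if m is None:
        raise ReactionSyntaxError("missing '=' or '<=>' arrow", text, len(text))
    stoich: dict[str, Fraction] = {}
    compartments: dict[str, str] = {}
    _parse_side(registry, text[: m.start()], -1, 0, text, stoich, compartments)
    _parse_side(registry, text[m.end():], +1, m.end(), text, stoich, compartments)
    compartments = {k: c for k, c in compartments.items() if stoich.get(k)}
    return ReactionSpec(stoich, compartments or None)


def _format_coeff(coeff: Fraction) -> str:
    if coeff == 1:
        return ""
    if coeff.denominator == 1:
        return f"{coeff.numerator} "
    return f"{coeff} "


def format_reaction(rxn: ReactionSpec) -> str:
    """Canonical string form; ``parse_reaction(format_reaction(r)) == r``."""
    left = [(k, -v) for k, v in sorted(rxn.stoich.items()) if v < 0]
    right = [(k, v) for k, v in sorted(rxn.stoich.items()) if v > 0]

    def side(terms):
        return " + ".join(f"{_format_coeff(c)}{k}" for k, c in terms)

    return f"{side(left)} = {side(right)}"


# --- elemental balance -----------------------------------------------------

_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``C10H12N5O13P3`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN_RE.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


def check_balance(registry: CompoundRegistry, rxn: ReactionSpec) -> BalanceReport:
    """Elemental and charge bookkeeping on reference pseudoisomers.

    Hydrogen imbalance is reported separately (the buffered proton pool
    absorbs it); a missing formula downgrades the check to a warning.
    """
    report = BalanceReport()
    for key, coeff in rxn:
        ensemble = registry.resolve_species(key)
        if ensemble.formula is None:
            report.warnings.append(f"no formula for {ensemble.primary_id}")
            continue
        for element, count in parse_formula(ensemble.formula).items():
            if element == "H":
                report.h_imbalance += coeff * count
            else:
                report.element_imbalance[element] = (
                    report.element_imbalance.get(element, Fraction(0)) + coeff * count
                )
        report.charge_imbalance += coeff * ensemble.reference.charge
    return report
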