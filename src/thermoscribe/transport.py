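"""Multi-compartment reaction energetics.

Species crossing a membrane between compartments with different proton
activity or electric potential pick up an extra Gibbs-energy term

    -N_H * RT ln(10^dpH) - Q * F * dPhi

where N_H is the net number of hydrogen ions moved from the initial to
the final compartment, Q the stoichiometric charge moved, dpH and dPhi
the final-minus-initial pH and potential differences, and F the Faraday
constant. The full transport-reaction dGr'^o additionally transforms
each reactant at its *own* compartment's aqueous conditions.

Orientation convention: the "initial" compartment is the one the
transported species is consumed in; dpH = pH(final) - pH(initial) and
dPhi = Phi(final) - Phi(initial). Reversing the reaction and swapping
the compartments negates every term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .chem_model import (
    AqueousConditions,
    CompoundRegistry,
    ReactionSpec,
    split_species_key,
)
from .component_contribution import CCModel, predict_multi
from .errors import ValidationError
from .legendre import ensemble_transform, pseudoisomer_transform

__all__ = [
    "CompartmentPair",
    "TransportedSpecies",
    "transport_term",
    "multicompartment_dg",
]


@dataclass(frozen=True)
class CompartmentPair:
    """Two compartments joined by a membrane with potential difference dPhi (V)."""

    initial_label: str
    initial_conditions: AqueousConditions
    final_label: str
    final_conditions: AqueousConditions
    delta_phi: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_label == self.final_label:
            raise ValidationError("compartment labels must be distinct")

    def swap(self) -> "CompartmentPair":
        return CompartmentPair(
            self.final_label,
            self.final_conditions,
            self.initial_label,
            self.initial_conditions,
            -self.delta_phi,
        )

    @property
    def delta_p_h(self) -> float:
        return self.final_conditions.p_h - self.initial_conditions.p_h


@dataclass(frozen=True)
class TransportedSpecies:
    """Net protons (N_H) and charge (Q) moved from initial to final compartment."""

    n_h_transported: float
    charge_transported: float


def transport_term(
    ts: TransportedSpecies, pair: CompartmentPair, temperature: float
) -> float:
    """Membrane-crossing energy -N_H RT ln(10^dpH) - Q F dPhi, kJ/mol."""
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    rt = constants.R * temperature
    return (
        -ts.n_h_transported * rt * np.log(10.0) * pair.delta_p_h
        - ts.charge_transported * constants.FARADAY * pair.delta_phi
    )


def _transported_amount(coeff_initial: float, coeff_final: float) -> float:
    """Signed amount moved initial -> final, from the two compartment coefficients."""
    forward = min(max(coeff_final, 0.0), max(-coeff_initial, 0.0))
    backward = min(max(-coeff_final, 0.0), max(coeff_initial, 0.0))
    return forward - backward


def _major_pseudoisomer(ensemble, cond: AqueousConditions):
    """Pseudoisomer with minimal transformed energy at cond (the dominant form)."""
    return min(
        ensemble.pseudoisomers,
        key=lambda p: pseudoisomer_transform(p, cond).dgf_prime,
    )


def multicompartment_dg(
    model: CCModel,
    registry: CompoundRegistry,
    rxn: ReactionSpec,
    pairs: list[CompartmentPair],
    transported: dict[str, TransportedSpecies] | None = None,
) -> tuple[float, float]:
    """dGr'^o of a compartment-tagged reaction: (mean, sd) in kJ/mol.

    mean = chemical component-contribution estimate + each reactant's
    Legendre offset at its own compartment's conditions + the transport
    term for every species crossing a membrane. The sd is that of the
    chemical estimate (transforms are deterministic).

    N_H and Q per transported species default to the major pseudoisomer
    at the source compartment's conditions; ``transported`` overrides
    them per compound id (values are per unit transported).
    """
    if not rxn.compartment_of or set(rxn.compartment_of) != set(rxn.stoich):
        raise ValidationError("every reactant must carry a compartment tag")
    cond_of = {}
    for pair in pairs:
        cond_of[pair.initial_label] = pair.initial_conditions
        cond_of[pair.final_label] = pair.final_conditions
    missing = {c for c in rxn.compartment_of.values() if c not in cond_of}
    if missing:
        raise ValidationError(
            f"no aqueous conditions given for compartments: {sorted(missing)}"
        )

    # chemical estimate over net stoichiometry (same compound across
    # compartments shares one chemical formation energy)
    est = predict_multi(model, registry, [rxn])
    mu = float(est.mu[0])
    sd = float(est.sd[0])

    # per-reactant Legendre offset at its own compartment's conditions
    for key, coeff in rxn:
        ensemble = registry.resolve_species(key)
        if ensemble.is_proton:
            continue
        cond = cond_of[rxn.compartment_of[key]]
        mu += float(coeff) * (
            ensemble_transform(ensemble, cond) - ensemble.reference.dgf_chemical
        )

    # membrane crossings
    for pair in pairs:
        temperature = pair.initial_conditions.temperature
        by_compound: dict[str, dict[str, float]] = {}
        for key, coeff in rxn:
            base, _ = split_species_key(key)
            comp = rxn.compartment_of[key]
            if comp in (pair.initial_label, pair.final_label):
                side = "initial" if comp == pair.initial_label else "final"
                by_compound.setdefault(base, {}).setdefault(side, 0.0)
                by_compound[base][side] += float(coeff)
        for base, sides in by_compound.items():
            if "initial" not in sides or "final" not in sides:
                continue
            amount = _transported_amount(sides["initial"], sides["final"])
            if amount == 0.0:
                continue
            if transported and base in transported:
                per_unit = transported[base]
            else:
                source_cond = (
                    pair.initial_conditions if amount > 0 else pair.final_conditions
                )
                major = _major_pseudoisomer(registry.resolve(base), source_cond)
                per_unit = TransportedSpecies(major.n_h, major.charge)
            moved = TransportedSpecies(
                amount * per_unit.n_h_transported,
                amount * per_unit.charge_transported,
            )
            mu += transport_term(moved, pair, temperature)

    return mu, sd
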