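"""Legendre transforms between chemical and transformed Gibbs energies.

A pseudoisomer's transformed standard formation energy at given pH, pMg
and ionic strength is

    dGf'(j) = dGf(j) + theta_H(j) + theta_Mg(j) + ionic(j)

with the proton term theta_H = -N_H * [dGf(H+) + RT ln 10^-pH]
(= N_H * RT ln10 * pH under the dGf(H+) = 0 convention), the analogous
magnesium term built on dGf(Mg2+) = -455.3 kJ/mol, and an extended
Debye-Hueckel ionic-strength correction in Alberty's form,

    ionic = -alpha(T) * (z^2 - N_H) * sqrt(I) / (1 + B sqrt(I)),

with B = 1.6 M^-1/2 and alpha(T) from :mod:`thermoscribe.constants`.

A metabolite's transformed formation energy is the Boltzmann-weighted
mixture of its pseudoisomers,

    dGf'(ensemble) = -RT ln sum_j exp(-dGf'(j) / RT),

evaluated in log-sum-exp form. The same machinery reverse-transforms
measured apparent reaction energies back to chemical ones for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import constants
from .chem_model import (
    AqueousConditions,
    CompoundEnsemble,
    CompoundRegistry,
    Pseudoisomer,
    ReactionSpec,
)
from .errors import ValidationError

__all__ = [
    "TransformBreakdown",
    "pseudoisomer_transform",
    "ensemble_transform",
    "average_binding",
    "reaction_transform_offset",
    "reaction_dg_prime",
    "reverse_transform",
    "dg_curve",
    "pmg_to_concentration",
]


@dataclass(frozen=True)
class TransformBreakdown:
    """Additive decomposition of one pseudoisomer's Legendre transform (kJ/mol)."""

    dgf_prime: float
    theta_h: float
    theta_mg: float
    ionic_term: float


def _ionic_term(p: Pseudoisomer, cond: AqueousConditions) -> float:
    if cond.ionic_strength == 0.0:
        return 0.0
    sqrt_i = np.sqrt(cond.ionic_strength)
    alpha = constants.debye_hueckel_alpha(cond.temperature)
    return (
        -alpha
        * (p.charge**2 - p.n_h)
        * sqrt_i
        / (1.0 + constants.DEBYE_HUECKEL_B * sqrt_i)
    )


def pseudoisomer_transform(
    p: Pseudoisomer, cond: AqueousConditions
) -> TransformBreakdown:
    """Transform one pseudoisomer's chemical formation energy to dGf' at cond."""
    rt = constants.R * cond.temperature
    ln10 = np.log(10.0)
    theta_h = -p.n_h * (constants.DGF_PROTON + rt * ln10 * (-cond.p_h))
    theta_mg = -p.n_mg * (constants.DGF_MG + rt * ln10 * (-cond.p_mg))
    ionic = _ionic_term(p, cond)
    return TransformBreakdown(
        dgf_prime=p.dgf_chemical + theta_h + theta_mg + ionic,
        theta_h=theta_h,
        theta_mg=theta_mg,
        ionic_term=ionic,
    )


def _transformed_energies(c: CompoundEnsemble, cond: AqueousConditions) -> np.ndarray:
    return np.array(
        [pseudoisomer_transform(p, cond).dgf_prime for p in c.pseudoisomers]
    )


def ensemble_transform(c: CompoundEnsemble, cond: AqueousConditions) -> float:
    """Boltzmann-mixture transformed formation energy of a metabolite, kJ/mol.

    Always <= the smallest pseudoisomer dGf' (mixing can only lower the
    free energy); equal to it for a single-pseudoisomer ensemble.
    """
    rt = constants.R * cond.temperature
    energies = _transformed_energies(c, cond)
    return float(-rt * logsumexp(-energies / rt))


def average_binding(c: CompoundEnsemble, cond: AqueousConditions) -> tuple[float, float]:
    """Boltzmann-weighted mean (<N_H>, <N_Mg>) over the ensemble at cond."""
    rt = constants.R * cond.temperature
    energies = _transformed_energies(c, cond)
    w = np.exp(-(energies - energies.min()) / rt)
    w /= w.sum()
    n_h = np.array([p.n_h for p in c.pseudoisomers])
    n_mg = np.array([p.n_mg for p in c.pseudoisomers])
    return float(w @ n_h), float(w @ n_mg)


def reaction_transform_offset(
    registry: CompoundRegistry, rxn: ReactionSpec, cond: AqueousConditions
) -> float:
    """Additive offset turning a chemical dGr (reference pseudoisomers) into dGr'.

    offset = sum_i nu_i * [dGf'(ensemble_i at cond) - dGf(reference_i)].
    Proton entries never occur in stoichiometry; water is included like
    any other reactant (only concentration terms exclude it, downstream).
    """
    offset = 0.0
    for key, coeff in rxn:
        ensemble = registry.resolve_species(key)
        if ensemble.is_proton:
            continue
        offset += float(coeff) * (
            ensemble_transform(ensemble, cond) - ensemble.reference.dgf_chemical
        )
    return offset


def reaction_dg_prime(
    registry: CompoundRegistry, rxn: ReactionSpec, cond: AqueousConditions
) -> float:
    """dGr'^o directly from registry formation energies (no estimator)."""
    return sum(
        float(coeff) * ensemble_transform(registry.resolve_species(key), cond)
        for key, coeff in rxn
        if not registry.resolve_species(key).is_proton
    )


def reverse_transform(
    dg_prime_obs: float,
    registry: CompoundRegistry,
    rxn: ReactionSpec,
    cond: AqueousConditions,
) -> float:
    """Strip the Legendre offset from a measured dGr'^o, giving chemical dGr^o.

    Inverse of adding :func:`reaction_transform_offset`; used to map
    observed apparent equilibrium constants onto the chemical energy
    scale the estimator is trained on.
    """
    return dg_prime_obs - reaction_transform_offset(registry, rxn, cond)


def dg_curve(
    target,
    variable: str,
    grid: Sequence[float],
    cond: AqueousConditions,
) -> list[tuple[float, float]]:
    """Evaluate dG' along a grid of one condition variable.

    ``target`` is either a :class:`CompoundEnsemble` (curve of dGf') or a
    ``(registry, rxn, baseline_dg_chemical)`` triple (curve of
    baseline + transform offset). ``variable`` is one of ``"p_h"``,
    ``"p_mg"``, ``"ionic_strength"`` (aliases ``"ph"``/``"pmg"`` accepted).
    """
    field = {
        "p_h": "p_h",
        "ph": "p_h",
        "p_mg": "p_mg",
        "pmg": "p_mg",
        "ionic_strength": "ionic_strength",
    }.get(variable.lower())
    if field is None:
        raise ValidationError(f"unknown curve variable {variable!r}")
    if len(grid) == 0:
        raise ValidationError("curve grid must be non-empty")

    def evaluate(c: AqueousConditions) -> float:
        if isinstance(target, CompoundEnsemble):
            return ensemble_transform(target, c)
        registry, rxn, baseline = target
        return baseline + reaction_transform_offset(registry, rxn, c)

    return [(float(v), evaluate(cond.replace(**{field: float(v)}))) for v in grid]


def pmg_to_concentration(p_mg: float) -> float:
    """Free Mg2+ concentration in M for a given pMg (pMg 3 -> 1 mM)."""
    if not np.isfinite(p_mg):
        raise ValidationError("pMg must be finite")
    return float(10.0 ** (-p_mg))
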