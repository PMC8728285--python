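"""Synthetic compound/reaction universes for tests, demos and benchmarks.

Everything here is explicitly synthetic: the generated formation
energies, group energies and pathway energetics are plausible in
magnitude but claim no correspondence to real measured chemistry. The
generators are deterministic under their seed, so a universe can be
reproduced exactly from its provenance record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_model import (
    CompoundEnsemble,
    CompoundRegistry,
    Pseudoisomer,
    ReactionSpec,
    parse_reaction,
)
from .component_contribution import GroupIncidence, TrainingSet
from .errors import ValidationError
from .pathway_mdf import PathwayModel

__all__ = [
    "ToyUniverse",
    "make_toy_universe",
    "make_toy_atp_world",
    "make_toy_pathway",
]


@dataclass
class ToyUniverse:
    """A complete synthetic training universe with known ground truth."""

    registry: CompoundRegistry
    gi: GroupIncidence
    g_true: np.ndarray          # true group energies, kJ/mol
    ts: TrainingSet
    reactions: list[ReactionSpec]
    provenance: dict = field(default_factory=dict)

    @property
    def f_true(self) -> np.ndarray:
        """True compound formation energies G @ g_true, kJ/mol."""
        return self.gi.G @ self.g_true


def _sample_group_incidence(rng, n_compounds: int, n_groups: int) -> np.ndarray:
    g = np.zeros((n_compounds, n_groups), dtype=int)
    for i in range(n_compounds):
        k = int(rng.integers(1, min(4, n_groups) + 1))
        cols = rng.choice(n_groups, size=k, replace=False)
        g[i, cols] = rng.integers(1, 3, size=k)
    # every group must occur somewhere, or it is unidentifiable by design
    for j in np.flatnonzero(~g.any(axis=0)):
        g[rng.integers(n_compounds), j] = 1
    return g


def _sample_stoichiometry(rng, n_compounds: int, n_reactions: int) -> np.ndarray:
    s = np.zeros((n_compounds, n_reactions), dtype=int)
    coeffs = np.array([-2, -1, 1, 2])
    for j in range(n_reactions):
        k_max = min(4, n_compounds)
        k = int(rng.integers(2, k_max + 1)) if k_max >= 2 else 1
        rows = rng.choice(n_compounds, size=k, replace=False)
        vals = rng.choice(coeffs, size=k)
        if k >= 2 and (np.all(vals > 0) or np.all(vals < 0)):
            vals[0] = -vals[0]
        s[rows, j] = vals
    return s


def make_toy_universe(
    n_groups: int = 8,
    n_compounds: int = 24,
    n_reactions: int = 60,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ToyUniverse:
    """Generate a trainable synthetic universe with known group energies.

    Group incidence uses small non-negative counts (1-4 groups per
    compound), true group energies are uniform on [-300, 50] kJ/mol,
    stoichiometries are sparse with coefficients in {-2, -1, 1, 2}, and
    observations are b = S^T G g_true + N(0, noise_sd^2). The sampler
    redraws S (bounded retries) until S^T G has full group rank so all
    group energies are identifiable.
    """
    if not (n_compounds >= n_groups >= 1):
        raise ValidationError("need n_compounds >= n_groups >= 1")
    if n_reactions < 1:
        raise ValidationError("need n_reactions >= 1")
    rng = np.random.default_rng(seed)
    g_mat = _sample_group_incidence(rng, n_compounds, n_groups)
    g_true = rng.uniform(-300.0, 50.0, n_groups)

    target_rank = min(n_groups, n_reactions, np.linalg.matrix_rank(g_mat))
    for _attempt in range(50):
        s_mat = _sample_stoichiometry(rng, n_compounds, n_reactions)
        if np.linalg.matrix_rank(s_mat.T @ g_mat) >= target_rank:
            break
    b = s_mat.T @ (g_mat @ g_true) + rng.normal(0.0, noise_sd, n_reactions)

    group_names = [f"grp{j:02d}" for j in range(n_groups)]
    registry = CompoundRegistry(group_names)
    compound_ids = []
    f_true = g_mat @ g_true
    for i in range(n_compounds):
        ensemble = CompoundEnsemble(
            primary_id=f"toy:c{i:03d}",
            pseudoisomers=(Pseudoisomer(dgf_chemical=float(f_true[i]), n_h=0),),
            group_vector=tuple(int(v) for v in g_mat[i]),
        )
        registry.register(ensemble)
        compound_ids.append(ensemble.primary_id)

    reactions = [
        ReactionSpec(
            {
                compound_ids[i]: int(s_mat[i, j])
                for i in range(n_compounds)
                if s_mat[i, j]
            }
        )
        for j in range(n_reactions)
    ]
    ts = TrainingSet(
        S=s_mat.astype(float), b=b, compound_ids=compound_ids
    )
    gi = GroupIncidence(G=g_mat.astype(float), group_names=group_names)
    return ToyUniverse(
        registry=registry,
        gi=gi,
        g_true=g_true,
        ts=ts,
        reactions=reactions,
        provenance=dict(
            n_groups=n_groups,
            n_compounds=n_compounds,
            n_reactions=n_reactions,
            noise_sd=noise_sd,
            seed=seed,
        ),
    )


# Synthetic nucleotide world: pseudoisomer formation energies with the
# plausible spacing of the ATP/ADP/Pi system (Mg adducts strongly bound,
# protonated forms a few tens of kJ/mol apart), but not real data.
_ATP_WORLD = [
    dict(
        primary_id="local:h",
        aliases=("kegg:C00080",),
        formula="H",
        is_proton=True,
        pseudoisomers=[(0.0, 1, 0, 1)],
    ),
    dict(
        primary_id="local:h2o",
        aliases=("kegg:C00001",),
        formula="H2O",
        is_water=True,
        pseudoisomers=[(-237.19, 2, 0, 0)],
    ),
    dict(
        primary_id="local:atp",
        aliases=("kegg:C00002",),
        formula="C10H12N5O13P3",
        pseudoisomers=[
            (-2768.10, 12, 0, -4),
            (-2811.48, 13, 0, -3),
            (-2838.18, 14, 0, -2),
            (-3258.68, 12, 1, -2),
            (-3287.50, 13, 1, -1),
        ],
    ),
    dict(
        primary_id="local:adp",
        aliases=("kegg:C00008",),
        formula="C10H12N5O10P2",
        pseudoisomers=[
            (-1906.13, 12, 0, -3),
            (-1947.10, 13, 0, -2),
            (-1971.98, 14, 0, -1),
            (-2387.97, 12, 1, -1),
        ],
    ),
    dict(
        primary_id="local:amp",
        aliases=("kegg:C00020",),
        formula="C10H12N5O7P",
        pseudoisomers=[
            (-1034.66, 12, 0, -2),
            (-1078.45, 13, 0, -1),
        ],
    ),
    dict(
        primary_id="local:pi",
        aliases=("kegg:C00009",),
        formula="HO4P",
        pseudoisomers=[
            (-1096.10, 1, 0, -2),
            (-1137.30, 2, 0, -1),
            (-1566.87, 1, 1, 0),
        ],
    ),
]


def make_toy_atp_world(seed: int = 0) -> CompoundRegistry:
    """A small nucleotide-like registry with protonated and Mg-bound states.

    The ATP analog carries Mg-bound pseudoisomers low enough that at the
    physiological pMg of 3 the Mg adduct dominates the ensemble, while
    at high pMg the Mg-free forms do. ``seed`` is accepted for interface
    uniformity; the table is fixed.
    """
    del seed  # deterministic table
    registry = CompoundRegistry()
    for entry in _ATP_WORLD:
        registry.register(
            CompoundEnsemble(
                primary_id=entry["primary_id"],
                aliases=entry.get("aliases", ()),
                formula=entry.get("formula"),
                is_proton=entry.get("is_proton", False),
                is_water=entry.get("is_water", False),
                pseudoisomers=tuple(
                    Pseudoisomer(dgf_chemical=d, n_h=nh, n_mg=nmg, charge=z)
                    for d, nh, nmg, z in entry["pseudoisomers"]
                ),
            )
        )
    return registry


def _chain_registry(names) -> CompoundRegistry:
    registry = CompoundRegistry()
    for i, name in enumerate(names):
        registry.register(
            CompoundEnsemble(
                primary_id=f"local:{name}",
                pseudoisomers=(Pseudoisomer(dgf_chemical=-50.0 * i, n_h=0),),
            )
        )
    return registry


def make_toy_pathway(kind: str = "chain", seed: int = 0) -> PathwayModel:
    """Small pathways with analytically checkable MDF optima.

    ``chain``: 3 reactions A -> B -> C -> D, every compound bounded to
    [1 uM, 10 mM]. The optimum equalizes the driving forces, giving the
    closed form MDF = (-sum(dG'^o) + RT ln(ub/lb)) / n.

    ``with_cofactor``: 3 reactions where the middle step couples to a
    cofactor pair; source, sink and one cofactor are pinned, leaving
    exactly three free metabolites whose optimum sits at their
    concentration bounds (so a coarse grid search finds it exactly).
    """
    rng = np.random.default_rng(seed)
    if kind == "chain":
        names = ["A", "B", "C", "D"]
        registry = _chain_registry(names)
        reactions = [
            parse_reaction(registry, f"{names[i]} = {names[i + 1]}")
            for i in range(3)
        ]
        dg = -10.0 + rng.uniform(-2.0, 2.0, 3)
        return PathwayModel(
            reactions=reactions,
            dg_prime=dg,
            conc_bounds={f"local:{n}": (1e-6, 1e-2) for n in names},
            registry=registry,
        )
    if kind == "with_cofactor":
        names = ["S", "I1", "I2", "P", "X", "Y"]
        registry = _chain_registry(names)
        reactions = [
            parse_reaction(registry, "S = I1"),
            parse_reaction(registry, "I1 + X = I2 + Y"),
            parse_reaction(registry, "I2 = P"),
        ]
        dg2 = -5.0 + rng.uniform(-2.0, 2.0)
        return PathwayModel(
            reactions=reactions,
            dg_prime=np.array([-50.0, dg2, -50.0]),
            conc_bounds={f"local:{n}": (1e-6, 1e-2) for n in ["I1", "I2", "X"]},
            fixed_concentrations={
                "local:S": 1e-3,
                "local:P": 1e-5,
                "local:Y": 1e-4,
            },
            registry=registry,
        )
    raise ValidationError(f"unknown pathway kind {kind!r}")
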