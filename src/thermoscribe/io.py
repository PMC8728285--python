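"""Reading and writing the package's plain-text interchange formats.

* compound table: TSV with columns ``id``, ``aliases`` (pipe-separated),
  ``formula``, ``pseudoisomers`` (JSON list of {dgf, nH, nMg, z}) and
  optional ``is_proton`` / ``is_water`` flags;
* group table: TSV ``compound_id, group_name, count``;
* reaction lists: one reaction string per line, ``#`` comments;
* training table: TSV ``reaction, dg_prime_obs_kj_mol, p_h, p_mg,
  ionic_strength_m, temperature_k, weight`` -- observations are
  reverse-transformed to chemical energies on load;
* pathway files: JSON with reaction strings, fluxes, energies, bounds;
* trained models: a versioned JSON archive of named dense matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_model import (
    AqueousConditions,
    CompoundEnsemble,
    CompoundRegistry,
    Pseudoisomer,
    ReactionSpec,
    format_reaction,
    parse_reaction,
)
from .component_contribution import CCModel, GroupIncidence, TrainingSet
from .errors import ValidationError
from .legendre import reverse_transform
from .pathway_mdf import PathwayModel

__all__ = [
    "write_compound_table",
    "load_registry",
    "read_reaction_file",
    "write_training_table",
    "load_training_table",
    "write_pathway",
    "load_pathway",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def write_compound_table(
    registry: CompoundRegistry, compounds_path, groups_path=None
) -> None:
    rows = []
    group_rows = []
    for c in registry:
        rows.append(
            dict(
                id=c.primary_id,
                aliases="|".join(c.aliases),
                formula=c.formula or "",
                pseudoisomers=json.dumps(
                    [
                        dict(dgf=p.dgf_chemical, nH=p.n_h, nMg=p.n_mg, z=p.charge)
                        for p in c.pseudoisomers
                    ]
                ),
                is_proton=int(c.is_proton),
                is_water=int(c.is_water),
            )
        )
        if c.group_vector is not None:
            # zero counts included so the group-universe ordering round-trips
            for name, count in zip(registry.group_names, c.group_vector):
                group_rows.append(
                    dict(compound_id=c.primary_id, group_name=name, count=count)
                )
    pd.DataFrame(rows).to_csv(compounds_path, sep="\t", index=False)
    if groups_path is not None:
        pd.DataFrame(
            group_rows, columns=["compound_id", "group_name", "count"]
        ).to_csv(groups_path, sep="\t", index=False)


def load_registry(compounds_path, groups_path=None) -> CompoundRegistry:
    """Build a registry from a compound table and optional group table."""
    df = pd.read_csv(compounds_path, sep="\t", dtype=str, keep_default_na=False)
    group_vectors: dict[str, dict[str, int]] = {}
    group_names: list[str] = []
    if groups_path is not None and Path(groups_path).exists():
        gdf = pd.read_csv(groups_path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in gdf.iterrows():
            name = row["group_name"]
            if name not in group_names:
                group_names.append(name)
            group_vectors.setdefault(row["compound_id"], {})[name] = int(row["count"])
    registry = CompoundRegistry(group_names)
    for _, row in df.iterrows():
        pseudoisomers = tuple(
            Pseudoisomer(
                dgf_chemical=float(p["dgf"]),
                n_h=int(p["nH"]),
                n_mg=int(p.get("nMg", 0)),
                charge=int(p.get("z", 0)),
            )
            for p in json.loads(row["pseudoisomers"])
        )
        gv = None
        if row["id"] in group_vectors or (group_names and row["id"] in group_vectors):
            counts = group_vectors.get(row["id"], {})
            gv = tuple(counts.get(name, 0) for name in group_names)
        elif group_names:
            gv = None
        registry.register(
            CompoundEnsemble(
                primary_id=row["id"],
                aliases=tuple(a for a in row.get("aliases", "").split("|") if a),
                formula=row.get("formula") or None,
                pseudoisomers=pseudoisomers,
                group_vector=gv,
                is_proton=bool(int(row.get("is_proton", "0") or 0)),
                is_water=bool(int(row.get("is_water", "0") or 0)),
            )
        )
    return registry


def read_reaction_file(registry: CompoundRegistry, path) -> list[ReactionSpec]:
    reactions = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            reactions.append(parse_reaction(registry, line))
    return reactions


def write_training_table(path, rows) -> None:
    """rows: iterable of (reaction_string, dg_prime_obs, AqueousConditions, weight)."""
    records = [
        dict(
            reaction=rxn,
            dg_prime_obs_kj_mol=dg,
            p_h=cond.p_h,
            p_mg=cond.p_mg,
            ionic_strength_m=cond.ionic_strength,
            temperature_k=cond.temperature,
            weight=weight,
        )
        for rxn, dg, cond, weight in rows
    ]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def load_training_table(
    registry: CompoundRegistry, path
) -> tuple[TrainingSet, list[ReactionSpec]]:
    """Load observations, reverse-transforming each to the chemical scale.

    The stoichiometric matrix spans all non-proton registry compounds in
    registration order.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValidationError("training table is empty")
    compound_ids = [c.primary_id for c in registry if not c.is_proton]
    index = {cid: i for i, cid in enumerate(compound_ids)}
    m = len(df)
    s_mat = np.zeros((len(compound_ids), m))
    b = np.zeros(m)
    weights = np.ones(m)
    reactions = []
    for j, row in df.iterrows():
        rxn = parse_reaction(registry, row["reaction"])
        cond = AqueousConditions(
            p_h=float(row["p_h"]),
            p_mg=float(row["p_mg"]),
            ionic_strength=float(row["ionic_strength_m"]),
            temperature=float(row["temperature_k"]),
        )
        b[j] = reverse_transform(
            float(row["dg_prime_obs_kj_mol"]), registry, rxn, cond
        )
        for key, coeff in rxn:
            base = registry.resolve_species(key).primary_id
            s_mat[index[base], j] += float(coeff)
        if "weight" in df.columns and not pd.isna(row["weight"]):
            weights[j] = float(row["weight"])
        reactions.append(rxn)
    ts = TrainingSet(S=s_mat, b=b, weight=weights, compound_ids=compound_ids)
    return ts, reactions


def group_incidence_for(registry: CompoundRegistry) -> GroupIncidence:
    """Group incidence over non-proton registry compounds (missing vectors -> 0)."""
    n_groups = len(registry.group_names)
    rows = []
    for c in registry:
        if c.is_proton:
            continue
        if c.group_vector is not None:
            rows.append(list(c.group_vector))
        else:
            rows.append([0] * n_groups)
    return GroupIncidence(
        G=np.array(rows, dtype=float), group_names=list(registry.group_names)
    )


def write_pathway(pm: PathwayModel, path) -> None:
    payload = dict(
        reactions=[format_reaction(r) for r in pm.reactions],
        fluxes=list(map(float, pm.fluxes)),
        dg_prime_kj_mol=list(map(float, pm.mean_dg)),
        conc_bounds_m={k: [lb, ub] for k, (lb, ub) in pm.conc_bounds.items()},
        fixed_concentrations_m=dict(pm.fixed_concentrations),
        temperature_k=pm.temperature,
    )
    Path(path).write_text(json.dumps(payload, indent=2))


def load_pathway(registry: CompoundRegistry, path) -> PathwayModel:
    payload = json.loads(Path(path).read_text())
    return PathwayModel(
        reactions=[parse_reaction(registry, r) for r in payload["reactions"]],
        dg_prime=np.array(payload["dg_prime_kj_mol"], dtype=float),
        fluxes=np.array(payload.get("fluxes") or [1.0] * len(payload["reactions"])),
        conc_bounds={
            k: (float(lb), float(ub))
            for k, (lb, ub) in payload.get("conc_bounds_m", {}).items()
        },
        fixed_concentrations={
            k: float(v)
            for k, v in payload.get("fixed_concentrations_m", {}).items()
        },
        temperature=float(payload.get("temperature_k", 298.15)),
        registry=registry,
    )


_MODEL_ARRAYS = [
    "f_cc", "g_gc", "G", "P_R", "P_N", "V_rc", "inv_GSGS", "P_N_gc",
]


def save_model(model: CCModel, path) -> None:
    """Serialize a trained model as a versioned JSON archive of dense matrices."""
    payload = dict(
        format_version=MODEL_FORMAT_VERSION,
        compound_ids=model.compound_ids,
        group_names=model.group_names,
        mse_rc=model.mse_rc,
        mse_gc=model.mse_gc,
        mse_inf=model.mse_inf,
    )
    for name in _MODEL_ARRAYS:
        payload[name] = np.asarray(getattr(model, name)).tolist()
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> CCModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version {version!r}")
    arrays = {name: np.array(payload[name], dtype=float) for name in _MODEL_ARRAYS}
    return CCModel(
        compound_ids=list(payload["compound_ids"]),
        group_names=list(payload["group_names"]),
        mse_rc=float(payload["mse_rc"]),
        mse_gc=float(payload["mse_gc"]),
        mse_inf=float(payload["mse_inf"]),
        **arrays,
    )
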