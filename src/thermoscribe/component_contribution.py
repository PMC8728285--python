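"""Component-contribution estimation of standard reaction Gibbs energies.

The estimator layers two regressions over a training table of chemical
reaction energies b (compounds x measurements stoichiometric matrix S,
compounds x groups incidence matrix G):

* *reactant contribution* -- a direct least-squares fit of formation
  energies on the span of the observed reactions, f_rc = pinv(S^T) b;
* *group contribution* -- a fit of additive group energies on the
  group-collapsed problem, g_gc = pinv(S^T G) b.

The combined formation-energy vector uses the reactant fit where the
data constrain it and falls back to groups on the orthogonal complement:

    f_cc = P_R f_rc + (I - P_R) G g_gc,

with P_R the orthogonal projector onto range(S). Uncertainty is carried
as a full covariance over formation energies assembled from three terms:
the reactant-layer residual spread on range(S), the group-layer spread
on its complement, and an effectively infinite variance (``mse_inf``) on
directions outside both spans. For any set of reactions this yields a
mean vector mu and covariance Sigma = S_new^T Sigma_f S_new together
with a square-root factor Q (Sigma = Q Q^T), so that

    dGr'^o = mu + Q m

with m either a standard multivariate normal variable (sampling) or an
optimization variable constrained to a confidence ball. Because means
and covariances of composed reactions combine linearly, estimates drawn
this way are consistent with the first law of thermodynamics.

Compounds absent from training but carrying a group-incidence vector are
scored through the group layer on the fly; they never alter the trained
projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .chem_model import (
    AqueousConditions,
    CompoundRegistry,
    ReactionSpec,
)
from .errors import EstimationError, ValidationError
from .legendre import reaction_transform_offset

__all__ = [
    "TrainingSet",
    "GroupIncidence",
    "CCModel",
    "EstimateWithUncertainty",
    "train",
    "predict_multi",
    "predict_reaction",
    "standard_dg_prime_multi",
    "sqrt_covariance",
    "sample_dg",
    "confidence_ball_constraint",
]

#: Relative singular-value cutoff shared by every pseudoinverse/projection.
SVD_RCOND = 1e-10

#: Default variance for directions outside both spans, (kJ/mol)^2.
DEFAULT_MSE_INF = 1e10


@dataclass
class TrainingSet:
    """Observed chemical reaction energies: S (compounds x m), b (m,), weights.

    ``compound_ids`` names the rows of S so trained models can score
    reactions given over registry identifiers.
    """

    S: np.ndarray
    b: np.ndarray
    weight: np.ndarray | None = None
    compound_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.S.ndim != 2:
            raise ValidationError("S must be a 2-D compounds x measurements matrix")
        if self.S.shape[1] != self.b.size:
            raise ValidationError(
                f"S has {self.S.shape[1]} measurement columns but b has {self.b.size}"
            )
        if self.b.size == 0:
            raise ValidationError("training set must contain at least one measurement")
        if np.any(~self.S.any(axis=0)):
            raise ValidationError("S contains an all-zero measurement column")
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float).ravel()
            if self.weight.size != self.b.size:
                raise ValidationError("weight length must match b")
            if np.any(self.weight < 0):
                raise ValidationError("weights must be non-negative")
        if self.compound_ids is not None and len(self.compound_ids) != self.S.shape[0]:
            raise ValidationError("compound_ids length must match S rows")


@dataclass
class GroupIncidence:
    """Compound x group incidence counts, rows aligned with TrainingSet."""

    G: np.ndarray
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValidationError("G must be a 2-D compounds x groups matrix")
        if self.group_names and len(self.group_names) != self.G.shape[1]:
            raise ValidationError("group_names length must match G columns")


def _invert_project(a: np.ndarray) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """SVD-based (pinv(A), rank, P_range(A), P_null(A^T)); one factorization."""
    u, s, vt = np.linalg.svd(a, full_matrices=True)
    tol = SVD_RCOND * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    u_r = u[:, :rank]
    inv = vt[:rank].T @ np.diag(1.0 / s[:rank]) @ u_r.T
    p_range = u_r @ u_r.T
    p_null = np.eye(a.shape[0]) - p_range
    return inv, rank, p_range, p_null


@dataclass
class CCModel:
    """Trained component-contribution estimator.

    Stores the fitted formation-energy and group vectors together with
    the projection/pseudoinverse factors needed to assemble the mean and
    full covariance of any new reaction set on the fly.
    """

    compound_ids: list[str]
    group_names: list[str]
    f_cc: np.ndarray       # formation energies over training compounds, kJ/mol
    g_gc: np.ndarray       # group contributions, kJ/mol
    G: np.ndarray          # training group incidence (compounds x groups)
    P_R: np.ndarray        # projector onto range(S)
    P_N: np.ndarray        # projector onto null(S^T) = I - P_R
    V_rc: np.ndarray       # P_R pinv(S S^T) P_R
    inv_GSGS: np.ndarray   # pinv(G^T S S^T G)
    P_N_gc: np.ndarray     # projector onto null((S^T G)^T) in group space
    mse_rc: float
    mse_gc: float
    mse_inf: float = DEFAULT_MSE_INF

    @property
    def n_compounds(self) -> int:
        return int(self.f_cc.size)

    @property
    def n_groups(self) -> int:
        return int(self.g_gc.size)

    def compound_index(self, compound_id: str) -> int | None:
        try:
            return self.compound_ids.index(compound_id)
        except ValueError:
            return None


@dataclass
class EstimateWithUncertainty:
    """Joint estimate for a reaction set: mean, covariance, square-root factor."""

    mu: np.ndarray           # kJ/mol
    sigma: np.ndarray        # (kJ/mol)^2
    sigma_sqrt: np.ndarray   # sigma == sigma_sqrt @ sigma_sqrt.T

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.sigma), 0.0, None))

    @property
    def rank(self) -> int:
        return self.sigma_sqrt.shape[1]


def train(
    ts: TrainingSet, gi: GroupIncidence, mse_inf: float = DEFAULT_MSE_INF
) -> CCModel:
    """Fit the layered reactant/group estimator on a training table.

    Residual mean squared errors use a degrees-of-freedom correction
    ``max(1, m - rank)`` per layer. Optional per-measurement weights
    scale both S columns and b by sqrt(weight) before fitting.
    """
    s_mat, b = ts.S, ts.b
    if gi.G.shape[0] != s_mat.shape[0]:
        raise ValidationError(
            f"G has {gi.G.shape[0]} compound rows, S has {s_mat.shape[0]}"
        )
    if ts.weight is not None:
        sw = np.sqrt(ts.weight)
        s_mat = s_mat * sw[None, :]
        b = b * sw
    m = b.size
    g_mat = gi.G

    inv_st, rank_rc, p_r, p_n = _invert_project(s_mat)
    gs = g_mat.T @ s_mat  # groups x measurements
    inv_gst, rank_gc, _, p_n_gc = _invert_project(gs)

    f_rc = inv_st.T @ b       # pinv(S^T) b
    g_gc = inv_gst.T @ b      # pinv(S^T G) b
    f_cc = p_r @ f_rc + p_n @ (g_mat @ g_gc)

    resid_rc = s_mat.T @ f_rc - b
    resid_gc = gs.T @ g_gc - b
    mse_rc = float(resid_rc @ resid_rc) / max(1, m - rank_rc)
    mse_gc = float(resid_gc @ resid_gc) / max(1, m - rank_gc)

    v_rc = p_r @ (inv_st.T @ inv_st) @ p_r          # = P_R pinv(S S^T) P_R
    inv_gsgs = inv_gst.T @ inv_gst                  # = pinv(G^T S S^T G)

    return CCModel(
        compound_ids=list(ts.compound_ids or []),
        group_names=list(gi.group_names),
        f_cc=f_cc,
        g_gc=g_gc,
        G=g_mat.copy(),
        P_R=p_r,
        P_N=p_n,
        V_rc=v_rc,
        inv_GSGS=inv_gsgs,
        P_N_gc=p_n_gc,
        mse_rc=mse_rc,
        mse_gc=mse_gc,
        mse_inf=mse_inf,
    )


def _reaction_vectors(
    model: CCModel, registry: CompoundRegistry, rxn: ReactionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Split a reaction into (x over training compounds, g over groups).

    Compounds absent from training must carry a group vector; their
    stoichiometry enters through the group side only.
    """
    x = np.zeros(model.n_compounds)
    g = np.zeros(model.n_groups)
    # aggregate by compound so compartment-tagged duplicates sum correctly
    totals: dict[str, float] = {}
    ensembles = {}
    for key, coeff in rxn:
        ensemble = registry.resolve_species(key)
        if ensemble.is_proton:
            continue
        totals[ensemble.primary_id] = totals.get(ensemble.primary_id, 0.0) + float(coeff)
        ensembles[ensemble.primary_id] = ensemble
    for cid, coeff in totals.items():
        if coeff == 0.0:
            continue
        idx = model.compound_index(cid)
        if idx is not None:
            x[idx] += coeff
        elif ensembles[cid].group_vector is not None:
            g += coeff * np.asarray(ensembles[cid].group_vector, dtype=float)
        else:
            raise EstimationError(
                f"compound {cid!r} is neither in the training set nor carries "
                "a group vector; cannot estimate"
            )
    return x, g


def predict_multi(
    model: CCModel, registry: CompoundRegistry, rxns: Sequence[ReactionSpec]
) -> EstimateWithUncertainty:
    """Joint chemical dGr^o estimate (mean + full covariance) for a reaction set."""
    k = len(rxns)
    x_mat = np.zeros((model.n_compounds, k))
    g_mat = np.zeros((model.n_groups, k))
    for j, rxn in enumerate(rxns):
        x_mat[:, j], g_mat[:, j] = _reaction_vectors(model, registry, rxn)

    mu = x_mat.T @ model.f_cc + g_mat.T @ model.g_gc
    # group-side image of each reaction: out-of-range(S) part mapped to groups
    w = model.G.T @ (model.P_N @ x_mat) + g_mat
    sigma = (
        model.mse_rc * (x_mat.T @ model.V_rc @ x_mat)
        + model.mse_gc * (w.T @ model.inv_GSGS @ w)
        + model.mse_inf * (w.T @ model.P_N_gc @ w)
    )
    sigma = 0.5 * (sigma + sigma.T)
    return EstimateWithUncertainty(
        mu=mu, sigma=sigma, sigma_sqrt=sqrt_covariance(sigma)
    )


def predict_reaction(
    model: CCModel, registry: CompoundRegistry, rxn: ReactionSpec
) -> tuple[float, float]:
    """Convenience wrapper: (mean, standard deviation) for one reaction."""
    est = predict_multi(model, registry, [rxn])
    return float(est.mu[0]), float(est.sd[0])


def standard_dg_prime_multi(
    model: CCModel,
    registry: CompoundRegistry,
    rxns: Sequence[ReactionSpec],
    cond: AqueousConditions,
) -> EstimateWithUncertainty:
    """Transformed dGr'^o estimates at cond; the Legendre shift is noiseless.

    Means are shifted by each reaction's transform offset; the covariance
    is that of the chemical estimate (uncertainty attaches to chemical
    energies only).
    """
    est = predict_multi(model, registry, rxns)
    offsets = np.array(
        [reaction_transform_offset(registry, rxn, cond) for rxn in rxns]
    )
    return EstimateWithUncertainty(
        mu=est.mu + offsets, sigma=est.sigma, sigma_sqrt=est.sigma_sqrt
    )


def sqrt_covariance(sigma: np.ndarray, rel_tol: float = SVD_RCOND) -> np.ndarray:
    """Square-root factor Q of a covariance matrix: sigma = Q Q^T.

    Symmetric eigendecomposition; eigenvalues below ``rel_tol`` times the
    largest (and any negative round-off) are clipped to zero, so a
    rank-deficient sigma yields a factor with matching rank. Columns are
    ordered by descending eigenvalue.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValidationError("covariance must be square")
    scale = np.abs(sigma).max() if sigma.size else 0.0
    if scale > 0 and np.abs(sigma - sigma.T).max() > 1e-8 * max(1.0, scale):
        raise ValidationError("covariance must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(0.5 * (sigma + sigma.T))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    cutoff = rel_tol * max(eigvals.max(initial=0.0), 0.0)
    keep = eigvals > cutoff
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def sample_dg(
    est: EstimateWithUncertainty, n: int, seed: int
) -> np.ndarray:
    """Draw n joint samples of dG (n x reactions), via dG = mu + Q m.

    m is standard normal of dimension rank(sigma); identical seeds give
    identical samples.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n, est.sigma_sqrt.shape[1]))
    return est.mu[None, :] + m @ est.sigma_sqrt.T


def confidence_ball_constraint(
    est: EstimateWithUncertainty, confidence: float
) -> float:
    """Radius r so that ||m||_2 <= r covers the requested joint confidence.

    m lives on the rank of sigma, so r is the chi-distribution quantile
    with that many degrees of freedom (rank 1, 0.6827 -> r ~ 1).
    """
    if not 0.0 < confidence < 1.0:
        raise ValidationError("confidence must be in (0, 1)")
    rank = est.rank
    if rank == 0:
        return 0.0
    return float(stats.chi.ppf(confidence, df=rank))
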