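"""Max-min Driving Force (MDF) pathway analysis.

Given a pathway of reactions with standard transformed energies dGr'^o
and per-metabolite concentration bounds, the MDF linear program finds
the concentration vector that maximizes the smallest driving force:

    maximize B
    s.t.  -(dGr'^o_j + RT * sum_i S_ij ln c_i) >= B   for every reaction j
          ln(lb_i) <= ln c_i <= ln(ub_i)

Water and free protons never contribute ln-concentration terms (the
buffered-solution convention); compounds may instead be pinned to a
fixed concentration. A pathway that cannot be made favourable still
solves, yielding a negative MDF. Among alternate optimal concentration
witnesses, a secondary LP picks the one closest (L1 in log space) to the
geometric midpoint of each compound's bounds, so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

from . import constants
from .chem_model import CompoundRegistry, ReactionSpec, split_species_key
from .component_contribution import EstimateWithUncertainty, confidence_ball_constraint
from .errors import PathwayInfeasibleError, ValidationError

__all__ = ["PathwayModel", "MDFResult", "solve_mdf", "driving_force_profile"]

#: Default metabolite concentration bounds, M.
DEFAULT_LB = 1e-6
DEFAULT_UB = 1e-2

_TIE_BREAK_SLACK = 1e-9


@dataclass
class PathwayModel:
    """A stoichiometric pathway with energies, fluxes and concentration bounds.

    ``dg_prime`` is either a per-reaction array of dGr'^o values (kJ/mol)
    or an :class:`EstimateWithUncertainty` for the uncertainty-aware
    mode. ``fluxes`` orient the reactions (only signs matter by
    default). Compounds without explicit bounds get the 1 uM - 10 mM
    defaults; ``fixed_concentrations`` pins compounds instead.
    """

    reactions: list[ReactionSpec]
    dg_prime: object  # np.ndarray-like or EstimateWithUncertainty
    fluxes: np.ndarray | None = None
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_concentrations: dict[str, float] = field(default_factory=dict)
    temperature: float = constants.DEFAULT_TEMPERATURE
    registry: CompoundRegistry | None = None

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValidationError("pathway must contain at least one reaction")
        n = len(self.reactions)
        if self.fluxes is None:
            self.fluxes = np.ones(n)
        else:
            self.fluxes = np.asarray(self.fluxes, dtype=float).ravel()
            if self.fluxes.size != n:
                raise ValidationError("fluxes length must match reactions")
            if np.any(self.fluxes == 0):
                raise ValidationError("fluxes must be non-zero")
        for cid, (lb, ub) in self.conc_bounds.items():
            if not 0.0 < lb <= ub:
                raise ValidationError(
                    f"bounds for {cid!r} must satisfy 0 < lower <= upper"
                )
        for cid, c in self.fixed_concentrations.items():
            if c <= 0:
                raise ValidationError(f"fixed concentration for {cid!r} must be > 0")

    @property
    def mean_dg(self) -> np.ndarray:
        if isinstance(self.dg_prime, EstimateWithUncertainty):
            return np.asarray(self.dg_prime.mu, dtype=float)
        return np.asarray(self.dg_prime, dtype=float).ravel()

    def compound_ids(self) -> list[str]:
        seen: list[str] = []
        for rxn in self.reactions:
            for key, _ in rxn:
                base, _comp = split_species_key(key)
                if base not in seen:
                    seen.append(base)
        return seen

    def _excluded(self, cid: str) -> bool:
        """Water/protons never contribute concentration terms."""
        if self.registry is not None and cid in self.registry:
            ensemble = self.registry.resolve(cid)
            return ensemble.is_proton or ensemble.is_water
        return False

    def bounds_for(self, cid: str) -> tuple[float, float]:
        return self.conc_bounds.get(cid, (DEFAULT_LB, DEFAULT_UB))


@dataclass
class MDFResult:
    """MDF optimum: the max-min driving force and a concentration witness."""

    mdf: float                       # kJ/mol
    concentrations: dict[str, float]  # M, for every non-excluded compound
    driving_forces: np.ndarray        # kJ/mol, -dG' per oriented reaction
    bottleneck_reactions: list[int]   # indices with driving force == mdf


def _assemble(pm: PathwayModel, use_flux_magnitudes: bool):
    """Oriented stoichiometry over free compounds + constant energy terms."""
    rt = constants.R * pm.temperature
    dg = pm.mean_dg
    if dg.size != len(pm.reactions):
        raise ValidationError("dg_prime length must match reactions")
    compounds = pm.compound_ids()
    free = [
        c
        for c in compounds
        if not pm._excluded(c) and c not in pm.fixed_concentrations
    ]
    idx = {c: i for i, c in enumerate(free)}
    n_r, n_c = len(pm.reactions), len(free)
    s_free = np.zeros((n_r, n_c))
    dg_const = np.zeros(n_r)
    for j, rxn in enumerate(pm.reactions):
        sign = np.sign(pm.fluxes[j])
        dg_const[j] = sign * dg[j]
        for key, coeff in rxn:
            base, _comp = split_species_key(key)
            if pm._excluded(base):
                continue
            nu = sign * float(coeff)
            if base in pm.fixed_concentrations:
                dg_const[j] += rt * nu * np.log(pm.fixed_concentrations[base])
            else:
                s_free[j, idx[base]] += nu
    scale = np.abs(pm.fluxes) if use_flux_magnitudes else np.ones(n_r)
    lo = np.array([np.log(pm.bounds_for(c)[0]) for c in free])
    hi = np.array([np.log(pm.bounds_for(c)[1]) for c in free])
    return rt, dg_const, s_free, free, lo, hi, scale


def _tie_break(rt, dg_const, s_free, lo, hi, scale, b_opt):
    """Secondary LP: centred witness at the fixed optimum B."""
    n_c = s_free.shape[1]
    if n_c == 0:
        return np.zeros(0)
    mid = 0.5 * (lo + hi)
    # variables [x (n_c), u (n_c)]; minimize sum u
    c = np.concatenate([np.zeros(n_c), np.ones(n_c)])
    a_rows, b_rows = [], []
    for j in range(s_free.shape[0]):
        row = np.concatenate([rt * s_free[j] / scale[j], np.zeros(n_c)])
        a_rows.append(row)
        b_rows.append(-dg_const[j] / scale[j] - (b_opt - _TIE_BREAK_SLACK))
    eye = np.eye(n_c)
    a_rows.extend(np.hstack([eye, -eye]))       # x - u <= mid
    b_rows.extend(mid)
    a_rows.extend(np.hstack([-eye, -eye]))      # -x - u <= -mid
    b_rows.extend(-mid)
    bounds = [(l, h) for l, h in zip(lo, hi)] + [(0.0, None)] * n_c
    res = linprog(
        c, A_ub=np.array(a_rows), b_ub=np.array(b_rows), bounds=bounds,
        method="highs",
    )
    if not res.success:  # pragma: no cover - slack makes this unreachable
        raise PathwayInfeasibleError(f"tie-break LP failed: {res.message}")
    return res.x[:n_c]


def solve_mdf(
    pm: PathwayModel,
    confidence: float | None = None,
    use_flux_magnitudes: bool = False,
) -> MDFResult:
    """Solve the max-min driving force program.

    ``confidence`` switches on the uncertainty-aware mode (requires
    ``dg_prime`` to be an :class:`EstimateWithUncertainty`): the energy
    vector becomes mu + Q m with the optimizer free to choose m inside
    the chi-ball of the requested joint confidence, which can only
    improve the reported MDF. Off (None) by default.

    ``use_flux_magnitudes`` (experimental) scales each reaction's
    driving-force requirement by 1/|flux|.
    """
    rt, dg_const, s_free, free, lo, hi, scale = _assemble(pm, use_flux_magnitudes)
    n_r, n_c = s_free.shape

    # variables [B, x]; maximize B
    c = np.concatenate([[-1.0], np.zeros(n_c)])
    a_ub = np.hstack([np.ones((n_r, 1)), rt * s_free / scale[:, None]])
    b_ub = -dg_const / scale
    bounds = [(None, None)] + [(l, h) for l, h in zip(lo, hi)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise PathwayInfeasibleError(
            f"MDF linear program failed ({res.message}); check concentration "
            "bounds and reaction energies"
        )
    b_opt = float(res.x[0])
    x = _tie_break(rt, dg_const, s_free, lo, hi, scale, b_opt)

    if confidence is not None:
        if not isinstance(pm.dg_prime, EstimateWithUncertainty):
            raise ValidationError(
                "uncertainty-aware MDF requires dg_prime to carry a covariance"
            )
        b_opt, x = _solve_uncertain(
            pm, rt, dg_const, s_free, lo, hi, scale, confidence, b_opt, x
        )

    forces = -(dg_const + rt * s_free @ x)
    mdf = b_opt
    bottleneck = [
        j for j in range(n_r) if forces[j] / scale[j] <= mdf + 1e-6
    ]
    concentrations = {c_id: float(np.exp(v)) for c_id, v in zip(free, x)}
    concentrations.update(pm.fixed_concentrations)
    return MDFResult(
        mdf=mdf,
        concentrations=concentrations,
        driving_forces=forces,
        bottleneck_reactions=bottleneck,
    )


def _solve_uncertain(pm, rt, dg_const, s_free, lo, hi, scale, confidence, b0, x0):
    """SLSQP refinement with dG = mu + Q m, ||m||_2 inside the chi ball."""
    est: EstimateWithUncertainty = pm.dg_prime
    q = est.sigma_sqrt
    rank = q.shape[1]
    radius = confidence_ball_constraint(est, confidence)
    signs = np.sign(pm.fluxes)
    n_c = s_free.shape[1]

    def unpack(z):
        return z[0], z[1 : 1 + n_c], z[1 + n_c :]

    def neg_b(z):
        return -z[0]

    def force_con(z):
        b, x, m = unpack(z)
        dg_shift = signs * (q @ m)
        return (-(dg_const + dg_shift + rt * s_free @ x)) / scale - b

    def ball_con(z):
        _, _, m = unpack(z)
        return radius**2 - float(m @ m)

    z0 = np.concatenate([[b0], x0, np.zeros(rank)])
    bounds = [(None, None)] + list(zip(lo, hi)) + [(-radius, radius)] * rank
    res = minimize(
        neg_b,
        z0,
        method="SLSQP",
        bounds=bounds,
        constraints=[
            {"type": "ineq", "fun": force_con},
            {"type": "ineq", "fun": ball_con},
        ],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    if not res.success:
        raise PathwayInfeasibleError(
            f"uncertainty-aware MDF optimization failed: {res.message}"
        )
    b, x, _m = unpack(res.x)
    return float(b), x


def driving_force_profile(res: MDFResult, pm: PathwayModel) -> np.ndarray:
    """Cumulative dG' along the pathway at the optimal concentrations.

    Step j equals the oriented dG' of reaction j (= -driving force); the
    final value is the total pathway dG'.
    """
    return np.cumsum(-res.driving_forces)
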