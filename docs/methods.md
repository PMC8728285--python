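# Methods

This note records the models implemented in `thermoscribe`, the
numerical choices behind them, what the synthetic data generators do and
do not emulate, and the known limitations.

## Units and conventions

Energies are kJ/mol, concentrations M, temperature K, membrane
potentials V, and the Faraday constant kC/mol (so Q·F·ΔΦ is directly in
kJ/mol). R = 8.314462×10⁻³ kJ/(mol·K). The Faraday constant is stored
at 96.485 kC/mol; a rounded display value of 96.5 is exposed alongside
it. Default aqueous conditions are pH 7.0, pMg 3.0 (the physiological
intracellular level, i.e. 1 mM free Mg²⁺), ionic strength 0.25 M,
T = 298.15 K.

Two formation-energy conventions anchor the pseudoisomer scale:
Δ_fG°(H⁺) ≡ 0 and Δ_fG°(Mg²⁺) ≡ −455.3 kJ/mol. Free protons never
appear in reaction stoichiometries — hydrogen imbalance is absorbed by
the buffered proton pool, which is why balance checking reports H
separately and judges a reaction balanced on the other elements only.
Water stays an explicit reactant but is excluded from all
concentration-quotient terms (MDF), as is the proton.

Identifiers are `namespace:accession` with the namespace lowercased and
the accession kept verbatim; bare names live in a `local:` namespace.
Stoichiometric coefficients are exact rationals so netting and balance
checks incur no round-off. A compound appearing on both sides of a
reaction *in the same compartment* nets out (catalysts vanish); in
different compartments it does not, which is exactly what a transport
reaction needs.

## Legendre transforms

Per pseudoisomer: Δ_fG′°(j) = Δ_fG°(j) + Θ_H(j) + Θ_Mg(j) + ionic(j),
with Θ_H = −N_H[Δ_fG°(H⁺) + RT ln 10⁻ᵖᴴ] and the analogous Θ_Mg. The
ionic-strength correction is the extended Debye–Hückel form
−α(T)·(z² − N_H)·√I/(1 + B√I) with B = 1.6 M^(−1/2) and α(T) the cubic
fit A₁T − A₂T² + A₃T³ (constants in `constants.py`, after Clarke & Glew
1980 as tabulated by Alberty; α(298.15 K) ≈ 2.915 kJ/mol·M^(−1/2), RT
already folded in). At I = 0 the term is exactly zero.

The metabolite energy is the Boltzmann mixture
−RT ln Σⱼ exp(−Δ_fG′°(j)/RT), evaluated with `scipy.special.logsumexp`
(max-shifted, so 200 kJ/mol spreads cannot overflow). Two useful exact
properties follow and are tested: the mixture lies at or below the
lowest pseudoisomer energy, and ∂Δ_fG′°/∂pH = RT ln10·⟨N_H⟩ with ⟨N_H⟩
the Boltzmann-weighted mean proton count (same for pMg and ⟨N_Mg⟩).

Reverse transformation of an observed apparent reaction energy
subtracts the reaction's transform offset Σᵢ νᵢ[Δ_fG′°(ensembleᵢ) −
Δ_fG°(referenceᵢ)] at the measurement's conditions; forward∘reverse is
the identity by construction. The *reference* pseudoisomer of each
compound is its first-listed microstate; offsets depend only on the
energy spacing within an ensemble, so any consistent anchoring of the
registry energies cancels.

## Component contribution

Training data are a compounds×measurements stoichiometric matrix S and
reverse-transformed chemical reaction energies b; G is the
compounds×groups incidence matrix. With P_R the orthogonal projector
onto range(S) and P_N = I − P_R:

* reactant layer: f_rc = pinv(Sᵀ)·b, residual MSE on its fit;
* group layer: g_gc = pinv(SᵀG)·b, residual MSE on its fit;
* combined: f_cc = P_R·f_rc + P_N·G·g_gc.

The formation-energy covariance is assembled from three terms:
MSE_rc·P_R·pinv(SSᵀ)·P_R on the observed span, MSE_gc carried through
pinv(GᵀSSᵀG) on the group-reachable complement, and MSE_inf
(10¹⁰ (kJ/mol)², configurable) on directions outside both spans. A new
reaction is split into its training-compound part x and a group-side
image w = GᵀP_N·x + g (g collects group vectors of compounds never seen
in training), giving μ = xᵀf_cc + gᵀg_gc and Σ = MSE_rc·xᵀV_rc x′ +
MSE_gc·wᵀpinv(GᵀSSᵀG)w′ + MSE_inf·wᵀP_N(gc)w′. Because μ and Σ are
linear/bilinear in the reaction vectors, composed reactions combine
exactly (first-law consistency) — the headline invariant, tested to
1e-8 kJ/mol.

Numerical choices, centralized:

* every pseudoinverse and projector comes from one SVD per operator
  with relative cutoff 1e-10, so the projections are mutually
  consistent;
* MSE degrees-of-freedom correction divides by max(1, m − rank);
* Σ^(1/2) uses a symmetric eigendecomposition with eigenvalues below
  1e-10 of the largest clipped to zero — a rank-deficient Σ yields a
  factor with matching rank, and reconstruction is tested to 1e-6
  relative max-norm;
* optional per-measurement weights multiply S columns and b by √w, so
  duplicating the entire table leaves the fit unchanged;
* the Legendre offset shifting μ to Δ_rG′° is treated as noiseless:
  uncertainty attaches to chemical energies only, keeping the
  covariance condition-independent;
* group-vector-only compounds are scored through the group layer and
  never alter trained projections.

A caveat: a reaction direction outside range(S) whose group image is
zero (e.g. a compound with an all-zero group vector) evades the
MSE_inf guard; registering such compounds without group information
raises an estimation error instead.

The confidence ball for the optimization use of m has radius equal to
the chi-distribution quantile at rank(Σ) degrees of freedom; sampling
draws m ~ N(0, I_rank) with a seeded `numpy` Generator.

## Transport

The membrane term is −N_H·RT ln(10^ΔpH) − Q·F·ΔΦ per unit transported,
with ΔpH = pH(final) − pH(initial), ΔΦ = Φ(final) − Φ(initial), and
"initial" the compartment where the species is consumed; swapping
compartments and reversing stoichiometry negates everything (tested).
The full multi-compartment Δ_rG′° is the chemical estimate (compounds
collapse across compartments, since chemical formation energies are
compartment-blind) plus each reactant's Legendre offset at *its own*
compartment's conditions plus the transport terms.

N_H and Q per transported compound default to the major (lowest
transformed energy) pseudoisomer at the source compartment — membranes
may transport a specific microstate, so both are overridable per
reaction. The transported amount between a compartment pair is the
signed overlap of consumption on one side and production on the other;
partial overlaps count only the matched part.

## Max–min driving force

Variables are B and ln cᵢ for free compounds; maximize B subject to
−(Δ_rG′°ⱼ + RT Σᵢ S·ln c) ≥ B and box bounds, solved with
`scipy.optimize.linprog` (HiGHS). Reactions are oriented by the sign of
their flux; water/protons/pinned compounds contribute constants.
Default bounds are 1 µM–10 mM. Infeasibility cannot arise from
unfavourable energetics (B is free to go negative); malformed bounds
raise a validation error before the solver runs.

Alternate optimal witnesses are resolved by a secondary LP: with B
fixed at its optimum (minus a 1e-9 slack for strict feasibility),
minimize Σ|ln cᵢ − ln(geometric midpoint of its bounds)|. This makes
results deterministic and centers slack metabolites.

Two extensions are available and off by default: an uncertainty-aware
mode where Δ_rG′° = μ + Qm with ‖m‖₂ inside the confidence ball (a
smooth cone constraint, solved with SLSQP from the mean-problem LP
solution — the optimizer can only raise the MDF), and an experimental
flux-weighted variant that scales each reaction's requirement by
1/|flux|.

## Synthetic data

`make_toy_universe` generates the training conditions used throughout
the tests: 8 groups, 24 compounds, 60 measurements (≥5 measurements per
group), 1 kJ/mol Gaussian observation noise — sizes at which the group
regression is comfortably identified yet everything trains in
milliseconds. Each compound carries 1–4 groups with counts 1–2; true
group energies are uniform on [−300, 50] kJ/mol (the magnitude range of
common biochemical moieties); reactions involve 2–4 compounds with
coefficients in {−2, −1, 1, 2} and are *not* group-conserving — a
group-balanced reaction would carry zero signal under the group model,
so the generator redraws S until SᵀG has full group rank. Compounds are
single neutral pseudoisomers, making transforms trivially the identity;
this deliberately separates estimator tests from transform tests.

`make_toy_atp_world` provides a nucleotide-like registry whose
pseudoisomer energies have realistic *spacing* (protonation steps of
~30–45 kJ/mol, Mg adducts that dominate near pMg 3) but are synthetic
values, not measured data. `make_toy_pathway` builds a 3-step chain
whose MDF has the closed form (−ΣΔG′° + RT ln(ub/lb))/n, and a
cofactor-coupled variant engineered so its optimum sits at
concentration-bound vertices — which is what makes a coarse grid search
an exact independent oracle for it.

What passing on these fixtures does **not** show: accuracy on real
measured equilibrium constants (no real training database ships with
the package), correctness of any particular compound's pKa/Mg-binding
ladder, group decomposition of molecular structures (group vectors are
caller-supplied; automatic decomposition is a pluggable hook), or
behaviour on the degenerate stoichiometries of genome-scale models.

## Limitations

* No temperature dependence beyond the explicit T in RT and α(T): no
  enthalpy/entropy separation.
* No structure handling (InChI/SMILES are accepted as annotations only),
  no pKa prediction, no tautomer or standardization logic.
* The MDF flux-weighted mode is experimental; relative fluxes otherwise
  only orient reactions.
* The CLI holds no persistent database; compound tables are loaded per
  invocation and the trained model archive is the unit of persistence.
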