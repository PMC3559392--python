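# Methods

## Model representation

A model is a sparse species × reaction stoichiometric matrix **S** with
per-reaction bounds (mmol·gDW⁻¹·h⁻¹), an objective vector and a class tag
per reaction: `exchange` (identifier prefix `EX_`/`DM_`), `biomass` (named
explicitly, matched by a biomass/growth name pattern, or identified as the
sole objective carrier), `internal` otherwise. Species identifiers carry a
compartment suffix in either the bracket dialect (`atp[c]`) or the SBML
underscore dialect (`atp_c`, `M_atp_c`); one normalizer handles both, and a
species matching neither maps to itself in lenient mode (strict mode
refuses it). Species differing only in compartment share one base compound,
because a formation energy belongs to the compound, not the compartment.
Both totals "with biomass" and "without biomass" are exposed in the model
summary, since network-wide counts are conventionally quoted without the
growth reaction. Tabular sources keep the coefficient strings exactly as
written so the three-file dialect round-trips byte-identically; SBML files
are read through cobrapy and their stoichiometry is taken verbatim (no
charge or pH rebalancing), which is recorded as a provenance note.

## Energy completion

The reaction–formation relation ΔG_r = Σᵢ sᵢ·ΔGf(i) is linear, so unknown
formation energies are recoverable from known reaction energies. With **P**
the per-species formation vector (zeros at unknowns), **T** the binary
species × unknown-compound transfer matrix and **F** the reaction energies,
the usable equations are the rows of Sᵀ(P + T·X) = F whose F is known and
whose row of SᵀT is nonzero. The reduced system Q·X = b is solved with
SVD-based least squares (LAPACK `gelsd`, relative singular-value cutoff
10⁻¹⁰), which returns the minimum-norm solution when Q is rank deficient.
Rank, singular values and residuals are always reported; compounds with a
significant component (>10⁻⁸) in any null-space direction are flagged
*weakly determined* rather than silently assigned, because their inferred
value is one of infinitely many minimizers.

Back-substitution F₀ = Sᵀ(P + T·X₀) completes every reaction energy.
Values that were known on input are never overwritten; instead the
consistency report partitions reactions into four categories — unknown
energy; known energy touching unknown compounds; known energy touching
none; all known — with max and RMS |F₀ − F| per category. The verdict
threshold is `tol + ‖b − Q·X₀‖₂` with `tol = 10⁻⁶` by default: on clean
data the strict tolerance applies, while a noisy system whose fit is
optimal is still reported consistent relative to its own residual.

Inference runs on the standard scale ΔG°′; the millimolar adjustment is
applied afterwards. This matches the natural pipeline order (complete,
then re-reference) and keeps the linear system in the units of its inputs.

## Millimolar adjustment

ΔG′m = ΔG°′ + R·T·Σ_{i∈PR} nᵢ·ln(cᵢ) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and
T = 298 K. Concentrations default to 10⁻³ mol·L⁻¹ with overrides for
dissolved H₂ (3.4×10⁻⁵) and O₂ (5.5×10⁻⁵); H₂O and H⁺ contribute no term.
Those special compounds are matched by configurable base-identifier lists
(`h2`, `o2`, `h2o`, `h`), since model identifiers are the only reliable
key. The sum runs over species occurrences, so a compound present in two
compartments of one reaction contributes one term per occurrence; for a
transport reaction at default concentrations the two terms cancel, which is
the physically sensible null behaviour. A transmembrane-potential
contribution has no closed form here; it can be supplied as an additive
per-reaction `offset` column in the input table (default 0). Energies are
kcal·mol⁻¹ by default; the unit is a configuration field carried through
all outputs, never assumed.

## Flux balance analysis

Maximize cᵀv subject to S·v = 0 and α ≤ v ≤ β, solved with scipy's HiGHS
backend under fixed options; solver name and the steady-state residual are
recorded in the solution metadata. FBA optima are degenerate in general, so
an optional secondary LP minimizes Σ|v| at the fixed optimum (split
variables, t ≥ |v|), selecting a reproducible representative flux vector —
per-reaction fluxes from different solvers are otherwise not comparable,
only the optimum is. Media are applied as exchange-bound overrides; in
strict-minimal mode unlisted exchange reactions are closed to uptake while
secretion stays open. Internal bounds default to ±1000 when a model does
not specify them.

## Weights, histogram, graph

w = ΔG′m × v per reaction, over the internal (reconstructed) reaction set.
Fluxes and weights with magnitude below 10⁻⁹ snap to exactly zero before
binning: LP solvers emit O(10⁻¹²) noise that would otherwise empty the
dominant zero bin. Histogram convention: negative scopes are half-open
[lo, hi), the zero scope holds |w| ≤ 10⁻⁹, positive scopes are (lo, hi];
the default edges (−200, −100, −50, 0, 40, 100) give eight scopes and every
weight lands in exactly one. Percentages use the weighted-reaction count as
denominator. The exported network is the standard bipartite
species–reaction digraph (reactants point into the reaction node, products
out; coefficients on edges, w on reaction nodes), as GraphML or edge-list
TSV; a reaction-adjacency projection (reactions sharing a metabolite, edge
weight = mean of the two w) is available separately.

## Free-energy balance

G_sys sums ΔG′m·v over internal reactions, G_env over exchange reactions;
biomass is excluded from both. G_phy = −(G_env + G_sys) is explicitly an
estimate by difference. An exchange reaction A ↔ ∅ has no products, so its
ΔG follows from the same stoichiometric relation as any reaction
(−s_A·ΔGf(A), millimolar-adjusted); this convention is written into the
output metadata because it is a choice, not a given. Fractions are
|G_sys|/|G_env| and |G_phy|/|G_env| × 100. The identity
G_env + G_sys + G_phy = 0 holds by construction and is asserted in tests;
linearity in the flux vector is likewise exercised directly.

## Synthetic study conditions

The generator plants a substrate→biomass pathway — an uptake exchange
(bound −10), a transport step, a linear conversion chain and a biomass
drain — guaranteeing a feasible LP with strictly positive optimum, then
adds random sparse reactions (mean ~4 participants, coefficients from
{±1, ±2}, half reversible) and secretion-only exchanges. Formation energies
are drawn uniform on [−200, 50] kcal·mol⁻¹ per compound; every reaction
energy is derived exactly from the stoichiometric relation, so the released
tables are self-consistent by construction. Defaults: 40 compounds, 2
compartments, 60 internal and 8 exchange reactions, 20 % of compounds
masked, noise 0.

Masking removes the formation energies of a random compound subset
(preferring compounds that occur in ≥2 reactions); reactions touching a
masked compound keep their energy with probability 0.8 — those kept rows
are the inference constraints — and at least one constraining reaction per
masked compound is always retained. Gaussian noise, when requested, is
applied to the constraint rows only: it models uncertainty in the estimated
energies that drive the inference, and it leaves reactions that touch no
masked compound exactly self-consistent (their reported discrepancy is a
pure function of the inference, not of simulated measurement error). The
generator reports the rank of the constraint system so tests can
distinguish full-rank recovery from deliberate rank deficiency.

What the generator does *not* emulate: real pathway topology, mass/charge
balance (so stoichiometric amplification loops can carry flux up to the
±1000 caps), realistic flux magnitudes, or the empirical distribution of
group-contribution errors. Passing tests therefore demonstrate correctness
of the linear algebra, the LP, and the bookkeeping under controlled truth —
not biological realism of any particular flux solution.

## Numerical choices

Singular-value cutoff 10⁻¹⁰ (relative) in the least squares; LP feasibility
tolerance 10⁻⁹; zero tolerance 10⁻⁹ for fluxes and weights; consistency
tolerance 10⁻⁶ plus the residual norm. Constant vectors yield an undefined
Pearson correlation (flagged, not raised). Degenerate inputs — no unknown
compounds, empty energy tables, all-zero fluxes — are handled as no-ops
with warnings rather than errors. Problem sizes in the test suite and the
acceptance script (tens of compounds, tens of reactions, 25 random oracle
systems up to 8×6) keep every check well inside interactive runtimes while
still exercising rank-deficient, noisy and multi-compartment regimes.

## Known limitations

Group-contribution estimation itself is out of scope: the package consumes
its outputs. No uncertainty propagation from those estimates; no
thermodynamic constraints inside the LP; no pH/ionic-strength transforms
beyond the millimolar adjustment; the transmembrane-potential term is an
opaque optional offset. Per-reaction flux vectors at degenerate optima are
solver-dependent; only the optimum and aggregate energy sums are promised,
and the parsimonious mode exists precisely to pin a representative.
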