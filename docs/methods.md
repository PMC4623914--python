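# Methods

## Optimization engine

All analyses reduce to linear programs over the steady-state flux cone:
maximize (or minimize) c·v subject to S·v = 0, flux bounds, and coupling
rows v_target − ρ·v_source = 0. Couplings are implemented as extra
homogeneous equality rows rather than bound rewriting so they remain valid
under any objective. LPs are solved with HiGHS (scipy.optimize.linprog)
at primal/dual feasibility tolerances of 1e-10; the API contract asserts
‖S·v‖∞ ≤ 1e-6 and bound satisfaction to 1e-6 on every reported solution.

FBA optima are usually degenerate, so reported flux vectors are
parsimony-resolved (pFBA): the objective is pinned at its optimum (with a
1e-10 slack to absorb solver round-off) and Σ|v| is minimized via variable
splitting v = p − n with the original asymmetric bounds kept as
inequality rows. Headline objective values come from the primary solve
and are degeneracy-free; quoted individual fluxes refer to the
parsimonious optimum.

Flux variability analysis constrains c·v ≥ φ·(optimum) for a fraction φ
(≤ for minimization objectives) and reports per-reaction flux ranges.
Robustness scans sweep one reaction's bound over a strictly monotone grid
(uptake magnitudes by default) and record each objective's optimum and any
reporter fluxes; infeasible grid points are recorded with their status and
the scan continues. Single-gene deletions evaluate each GPR boolean rule
with the gene absent (recursive-descent parser; unknown genes count as
present), close the affected reactions, and report growth relative to wild
type; "essential" means a ratio below 0.01 — a conservative cutoff stated
in the report because no standard value exists.

## Exchange sign convention

Internally, negative exchange flux is uptake. All user-facing entry points
(`set_uptake`, scan grids, scenario constraints) take uptake magnitudes as
positive numbers and convert, matching how uptake rates are quoted in the
fermentation literature.

## SBML I/O

Models are read and written as SBML Level 2 in the COBRA-toolbox dialect:
bounds and objective coefficients as kinetic-law LOCAL parameters
(LOWER_BOUND, UPPER_BOUND, OBJECTIVE_COEFFICIENT), gene rules and
subsystems in reaction notes. Plain L2 files without these annotations are
accepted with default bounds (−1000, 1000) reversible, (0, 1000)
irreversible. Boundary-condition species stay on the metabolite list but
contribute no row to S. The writer emits the same dialect, so
write∘read is the identity on stoichiometry, bounds, gene rules and
objective (generated coefficients are rounded to 9 decimals so the
double→decimal→double trip is exact). Reaction-kind classification is
operational: single-participant reactions (or single non-boundary species)
are exchanges; reactions spanning ≥2 compartments without elemental change
are transports; biomass/maintenance/demand reactions are flagged pseudo;
the rest are enzymatic.

## Biomass with variable neutral-lipid content

`BiomassSpec` fixes a reference composition (signed mmol/gDW at a
reference lipid fraction f_ref), a storage-lipid species, an acyl profile,
and GAM. At lipid fraction f the lipid coefficient delivers f g/gDW
(lipid MW either given directly or assembled as a TAG: glycerol backbone +
3 profile-weighted acyl chains), and every non-lipid component is scaled
by (1−f)/(1−f_ref). This single rule simultaneously "reduces the protein
content" and "keeps the relative amounts of other metabolites constant",
and it preserves the 1 g/gDW mass closure, which is checked to 0.5 % for
every f in [0.004, 0.80]. GAM ATP hydrolysis is per gram of total biomass
and therefore not rescaled.

Maintenance is split: GAM inside the biomass reaction; NGAM enforced as a
coupling v_ATPase = ρ·|v_substrate| with substrate-specific ρ (glucose
5.0, glycerol 2.28 mmol ATP per mmol). A ratio of zero reduces the model
to GAM-only maintenance.

Default acyl profile (C16:0/C16:1/C18:1/C18:2 = 0.15/0.10/0.50/0.25) is a
scaffold-style placeholder; measured phase- and substrate-specific
profiles should be passed in where available.

## Dynamic FBA

Static-optimization dFBA: per step, each uptake bound is min(kinetic cap,
concentration-supported rate over dt); after the solve, biomass updates
exponentially X ← X·e^{μ dt} and each tracked concentration by
v·MW·∫X dt (the integral taken in closed form over the step).
Concentrations are clamped at zero, giving last-step partial uptake.
Default dt = 0.1 h; no Michaelis–Menten term is fitted because the only
kinetic datum used is the maximal specific uptake rate. The scheme is
(at least) first-order in dt; on networks where μ is piecewise constant
in time it is exact away from substrate-exhaustion transitions, so
observed convergence can be faster than first order. Molecular weights
come from metabolite formulas, with glucose 180.16 and glycerol
92.09 g/mol as fallbacks.

## Scenario analyses

**Lipogenesis.** Growth is fixed at zero, substrate uptake pinned to the
measured rate, and lipid (a TAG/fatty-acid demand flux, mmol gDW⁻¹ h⁻¹)
maximized. The measured citrate excretion can enter either as an absolute
exchange rate or per mol substrate (a coupling to uptake); both modes are
supported because published rates appear in both units.

**Fed-batch feed rate.** With citrate export closed and growth arrested,
the minimal uptake sustaining a target lipid flux is found by maximizing
the (negative) substrate exchange flux with the lipid flux bounded below.
`feed_schedule` converts that uptake into a pump rate:
pump [L/min] = uptake·biomass·MW / (1000·feed concentration·60).

**TAG-content scans.** For each lipid fraction the biomass equation is
rebuilt and either growth is maximized at fixed uptake or uptake minimized
at fixed growth; recorded responses are growth/uptake, O₂ uptake, CO₂
output, respiratory quotient, ATP:citrate-lyase flux and total NADPH
production (sum of positive NADPH-producing flux contributions).

**Oxygen thresholds.** From a robustness curve, the threshold is the
largest scanned bound at which the response has dropped below 99 % of its
unconstrained value; the default grid step is 0.25 mmol gDW⁻¹ h⁻¹. The
growth threshold is evaluated in the growth phase (uptake cap 4) and the
lipid threshold under lipogenesis constraints (uptake 0.35), because those
are the states in which each process actually runs; on models of this
class the growth threshold exceeds the lipid threshold, which is the basis
of the reduced-aeration strategy.

**NADPH sources.** NADPH-producing reactions are detected by their net
NADPH coefficient and feasible direction. Restricting to one named source
closes every other producing direction (reversible producers are clipped,
never reversed). Yield comparison re-runs the lipogenesis optimum per
source and reports lipid flux relative to the reference source (PPP).
Source sets are caller-supplied reaction-id sets because identifier
conventions differ between reconstructions; sets must be disjoint.

**Theoretical yields.** Growth is fixed at zero, the maintenance coupling
released, and the ATP-hydrolysis pseudo-reaction left open as a free
dissipation sink, so the number reported is the carbon-stoichiometric
ceiling with energy non-limiting — the conventional meaning of a
theoretical yield, and the denominator used for percent-of-theoretical
comparisons of measured yields (which enter only as inputs).

**Substrate screen.** Every exchange uptake outside the free
mineral-medium set is closed; each candidate substrate is opened in turn
and growth is predicted when μ > 1e-6 h⁻¹ (numerically robust; no
published cutoff exists). Substrates lacking an exchange are reported as
untestable and excluded from the accuracy.

## The synthetic core model

The generator emits a ~23-reaction compartmentalized network with lumped
glycolysis (2 pyruvate + 2 ATP + 2 NADH per glucose), an oxidative-PPP
lump (1 glucose + 12 NADP⁺ → 6 CO₂ + 12 NADPH, equivalent to full
oxidative recycling at 2 NADPH per CO₂), a citrate node (synthesis from
2 pyruvate + 1 NADH; ATP:citrate lyase; OAA decarboxylation back to
pyruvate), fatty-acid synthesis (8 acetyl-CoA + 14 NADPH + 7 ATP per C16),
a TCA lump, P/O-coupled respiration, pyruvate export, an energized citrate
exporter, a glycerol-synthesis valve, and biomass/maintenance/demand
pseudo-reactions. Optional add-ons: glycerol catabolism with
gluconeogenesis, a fructose isomerase, a pathway-less sucrose exchange
(no invertase), the mannitol cycle (whose four reactions sum to the net
transhydrogenation NADH + NADP⁺ + ATP → NAD⁺ + NADPH + ADP + Pᵢ), and an
energy-independent transhydrogenase.

Design choices that matter:

- **Cofactor carriers as pseudo-elements.** ATP/ADP, NAD(H), NADP(H) and
  CoA/acetyl-CoA carry formulas built on carrier symbols (A, R, Q, Z) plus
  real C/H/O for transferred moieties. Elemental balance is validated on
  C, N, P and the carrier elements; H and O bookkeeping is elided in the
  lumped steps, as it is in most published lumped networks.
- **P/O ratio 1.5** (effective ATP per NADH), the conventional value for
  yeast oxidative phosphorylation. This choice sets the energy price of
  NADH and hence the ordering of NADPH sources: an energy-independent
  transhydrogenase is slightly better than the PPP, and the ATP-consuming
  mannitol cycle distinctly worse — the ordering expected for an
  oleaginous network.
- **NGAM 5.0 mmol ATP per mmol glucose**, matching the split-maintenance
  default. It makes ATP genuinely limiting during slow, nitrogen-starved
  lipogenesis, which is what gives maintenance and NADPH-source energetics
  observable consequences.
- **Energized citrate export (2 ATP per citrate)**, a lumped stand-in for
  transport and re-acidification costs. Without an ATP cost, forcing the
  measured citrate overflow would strand surplus ATP and make the scenario
  infeasible in a network this small.
- **Glycerol-synthesis valve** (glucose + 2 ATP + 2 NADH → 2 glycerol), a
  bounded dissipation route playing the overflow role polyol production
  plays in vivo. It never participates in optima but keeps energetically
  over-determined corner cases feasible.
- **Biomass proxies.** One gram of non-lipid biomass is represented by
  11.31 mmol pyruvate plus 4 mmol NADPH and 25 mmol NADH invested
  (reductive biosynthesis of amino acids and nucleotides from keto-acid
  precursors); storage lipid is palmitate (256.42 g/mol). GAM is
  17.05 mmol ATP/gDW.

With the default parameters the lipogenesis optima have closed forms,
derived by hand from the pathway balances and frozen into the test suite:
maximal lipid flux L = (84·U − 87·e)/487 at uptake U and forced citrate
export e; minimal uptake for a lipid target is its inverse (487/84)·L;
sole-source NADPH alternatives give 7U/40 (transhydrogenase) and 7U/47
(mannitol cycle).

The generator is deterministic; a seed only permutes the insertion order
of reactions and metabolites to expose order-dependence bugs. The
manifest's expected optima are computed by exhaustive vertex enumeration,
never typed in by hand: every vertex of {S·v = 0, l ≤ v ≤ u} pins
d = n − rank(S) variables at bounds, and all C(n,d)·2^d pinnings are
solved with batched SVD/pseudo-inverse linear algebra (≈10⁶ cases, a few
seconds, for the default d = 5). The test suite additionally carries a
second, independently written loop-based enumerator used as the oracle
against the HiGHS path on ≥50 reduced model variants (d ≤ 3).

## What the synthetic model does and does not show

Passing tests on the toy demonstrate the correctness of the optimization
machinery (solver-versus-enumeration agreement to 1e-8, steady-state
residuals ≤ 1e-6), the biomass mass-closure and monotonicity properties,
the overflow logic (citrate/pyruvate excretion when downstream capacity or
oxygen is limiting), the NADPH-source energetics ordering, and the
fed-batch inversion. They do not reproduce genome-scale numbers: absolute
growth rates, the oxygen-uptake values of the TAG-content scan, and the
exact NADPH-source percentages depend on the full reconstruction's
stoichiometry. In particular, the direction of the O₂-uptake trend across
lipid fractions depends on quantitative electron retention per gram of
biomass, which a lumped 23-reaction network does not reproduce; on the
toy, O₂ uptake rises mildly with lipid fraction while growth falls,
whereas a full reconstruction shows it falling. Genome-scale validations
(growth on glucose/glycerol, the 0.152 mmol gDW⁻¹ h⁻¹ feed uptake, O₂
endpoints 10→6.5, the 83 % PPP variability bound, and the model statistic
counts) run against the iMK735 supplementary SBML when it is placed at
`data/iMK735.xml`; the file is not redistributed here.

## Numerical choices and problem sizes

Solver tolerances 1e-10, API contract 1e-6, oracle agreement 1e-8.
Robustness grids use step 0.25 over 0–10 mmol gDW⁻¹ h⁻¹; TAG scans use
the fraction range 0.004–0.60 (scans) or 0.004–0.80 (mass-closure
checks); dFBA uses dt = 0.1 h with 20 g/L initial carbon and
0.003 g/L inoculum. The acceptance script runs the entire pipeline on the
synthetic model (23–28 reactions) in well under a minute; the test suite
solves a few thousand small LPs in about a minute.

## Known limitations

- No MILP variants (loopless FBA, MOMA/ROOM) and no quadratic objectives.
- Elemental-balance validation is advisory for models with incomplete
  formulas (true of most published reconstructions).
- The dFBA scheme has no pH, oxygen-transfer or stirring dynamics;
  aeration acts only through the O₂ uptake bound.
- NADPH source sets must be supplied per reconstruction; only the toy's
  sets ship with the package.
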