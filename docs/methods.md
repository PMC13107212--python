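# Methods

`pathkin` analyses first-order chemical kinetics on *reaction path
networks*: graphs whose nodes are equilibrium structures (EQs — local
minima, typically conformers of a handful of chemical species) carrying
Gibbs energies, and whose edges are reaction paths carrying the Gibbs
energy of the transition state (TS, the free-energy maximum along the
path).  From such a network the package predicts product yields,
enantiomer ratios (er), effective free-energy gaps ΔΔG‡, per-state
traffic volumes, and a human-readable coarse-grained mechanism.

All energies are kJ/mol relative to an arbitrary common zero; every
computed quantity depends on energy differences only (asserted by
shift-invariance tests).  Units are Å, K, s throughout.

## Rate model

Each path (a, b) with TS energy g‡ contributes an Eyring
(transition-state-theory) rate in both directions through one shared
effective barrier top

    g_eff = max(g‡, g_a, g_b)
    k[b←a] = (k_B·T/h) · exp(−(g_eff − g_a)/RT)

with CODATA constants and κ = 1 (no transmission coefficient, no
tunnelling, no symmetry numbers; population *ratios* are unaffected by
κ, absolute time scales carry that convention).  Sharing g_eff between
the two directions yields detailed balance by construction; the clamp to
`max(g‡, g_a, g_b)` prevents unphysical super-barrierless rates when a
free-energy TS estimate (a path maximum) dips below an endpoint, a
common artefact of path-based TS estimates.  Parallel paths between the
same pair of EQs are independent channels and their rates add.  The rate
matrix K stores k[j←i] off-diagonal with diagonal −Σ (columns sum to
zero: probability conservation).

## Exact propagation and its numerical limits

The reference solver evaluates p(t) = exp(K·t)·p₀ by dense matrix
exponential (endpoints) or, on a logarithmic time grid, by spectral
decomposition of the detailed-balance symmetrization
S = D^(−1/2) K D^(1/2) (off-diagonals √(k_ij·k_ji)).

Both routes degrade on very stiff matrices, and the package treats their
limits explicitly:

* the spectral route loses reaction channels whose symmetrized coupling
  √(k_fwd·k_rev) falls below the eigensolver's absolute resolution
  ε·‖S‖ — deep product wells do exactly this.  The grid propagator
  therefore validates its endpoint against one direct matrix exponential
  and falls back to stepped exponentials when they disagree by more than
  10⁻⁶;
* the scaling-and-squaring exponential itself becomes unreliable for
  ‖K·t‖ ≳ 10¹⁵.  Beyond that, double precision does not even *define*
  the endpoint: rounding the diagonal leaks probability (validated
  against 60–200-digit arbitrary-precision references, where the float
  matrix visibly loses total mass).  Exact-solver results are therefore
  only meaningful within this trust region; outside it, the contraction
  solver below is the reliable route — removing that stiffness is its
  purpose.

## Rate-constant-matrix contraction (RCMC-style solver)

Realistic networks are stiff: conformer interconversion (barriers
~15 kJ/mol, rates ~10¹⁰ s⁻¹) coexists with product formation over two
days.  The contraction solver removes states whose total escape rate
exceeds `safety · rate_threshold` (defaults: `rate_threshold = 1/t_final`,
`safety = 10¹⁰`), always taking the currently fastest state, with a
deterministic lexicographic tie-break.  Two contraction moves are used,
chosen per state:

* **Steady-state elimination** for *transit* states — states whose
  slaved population share k[i←m]/Σk[·←i] is ≤ 10⁻³ for every feeder m
  (e.g. high-energy intermediates).  The state's inflow is redistributed
  over its neighbours by branching ratios b_j = k[j←i]/Σk[·←i], adding
  effective rates b_j·k[i←m] (the Schur complement of the generator).
  For A ⇌ I → B with metastable I this reproduces the classic
  steady-state rate k_AI·k_IB/(k_IA + k_IB) exactly.  At reporting, the
  eliminated state's population is reconstructed from quasi-steady-state
  balance (inflow/escape), in reverse contraction order.

* **Lumping** for *reservoir* states — fast states that hold real
  population (e.g. low-energy conformers exchanging rapidly).  The state
  is merged with the neighbour receiving its largest outflow into a
  superstate whose internal weights are the equilibrium weights implied
  by the exchange rates (the Boltzmann weights, under detailed balance).
  Superstate outflows are the weight-averaged member rates; inflows add.
  At reporting, superstate masses are back-distributed over members by
  those weights.

The distinction matters: steady-state elimination of a
population-holding state misbooks its mass onto its neighbours — an
error of the order of the slaved share, *not* of exp(−escape·t) — which
is why a share criterion and not a rate criterion selects the move.
The safety factor keeps every state within ten rate decades of the
reporting scale in the retained system, which is then propagated
*exactly* (endpoint through one well-conditioned matrix exponential of
the de-stiffened reduced generator); the contraction only removes the
stiffness the exact propagator cannot absorb.  Against exact references,
endpoint deviations are ≤ 5·10⁻⁴ over 1200 random 5–50-node networks
with barriers of 5–150 kJ/mol inside the exponential's trust region, and
the contraction remains physically correct (mass-conserving, correct
Boltzmann limit) far beyond it.

Every contraction is recorded (state, escape rate, branching ratios,
move kind, accumulated transit population, final superstate
composition) for mechanistic audit.

## Traffic volume

The traffic volume of an EQ is its integrated population throughput,

    V_i = ∫₀^T [ Σ_j k[i←j] p_j + Σ_j k[j←i] p_i ] dt,

influx plus outflow — a measure of kinetic importance independent of
final yield (a catalytic relay can have enormous V and negligible
population).  Integration uses the trapezoid rule on the logarithmic
grid (200 points per decade by default, first point well below the
shortest relaxation time).  Both solvers integrate the same expression
against the *original* rate matrix; on oracle-tractable networks the two
routes agree to ≲ 2%.  Closed forms pin the convention: a single
irreversible step A→B run to completion gives V_A = V_B = 1, a chain
A→I→B gives V_I = 2.  Note that V counts intra-well conformer exchange,
so absolute values on realistic networks are large (10⁶–10¹⁶); they are
reported as log₁₀ per group.

## Selectivity

Yields are read as populations at t_final — products are *not* absorbing
sinks, the network stays fully reversible, so racemization through
reverse steps is representable.  Enantiomer fractions aggregate all
product groups of a given handedness (e.g. differently protonated
product species); er is reported normalized to 100 with two decimals
("98.50:1.50") and the effective gap as ΔΔG‡ = RT·ln(major/minor).  When
no product has formed the er is reported as undefined, never as 50:50.
The conventional Curtin–Hammett baseline — the Boltzmann-weighted
TS-ensemble ratio Σ_S e^(−g/RT) / Σ_R e^(−g/RT) — is provided for
comparison: the kinetic er matches it (to ≲1% on the benchmark) under
fast reactant pre-equilibrium and irreversible product formation, and
departs from it once product reversal competes.

## Synthetic benchmark (study conditions)

The generator builds networks that emulate a conformationally flexible
asymmetric-catalysis reaction with a programmed ground truth:

* six species clusters of 8 conformers each — reactant (base 0 kJ/mol),
  protonated reactant (+25), carbocation-like intermediate (+35), an
  off-path adduct (+20) and S/R product wells (−60); conformer energies
  are base + U(0, 5) kJ/mol (uniform, so programmed extremes stay exact);
* intra-cluster interconversion over barriers 15 kJ/mol above the higher
  endpoint — fast, realizing the pre-equilibrium regime (configurable to
  break it);
* reversible inter-cluster channels: reactant⇌protonated (TS ≈ 60),
  protonated⇌intermediate (≈ 70), intermediate⇌adduct (≈ 75), and the
  two competing product routes of the modelled chemistry — single-step
  ("asynchronous concerted") reactant→product and two-step ("stepwise")
  intermediate→product — each as 3 parallel TSs near 95 kJ/mol with
  U(0, 8) spread;
* gap calibration: after the draws, all S-product-forming TS energies
  are rigidly shifted so that the Boltzmann-ensemble gap equals
  `programmed_ddg` exactly.

Defaults are fixed at the modelled experiment: T = 333.15 K, t_final =
172 800 s (two days).  Product wells at −60 kJ/mol keep reversal
negligible over that window for programmed gaps up to 20 kJ/mol (the
calibration can pull S-forming TSs ~17 kJ/mol down; the reverse barrier
then still exceeds ~135 kJ/mol, i.e. < 10⁻⁴ reversal).  Raising
`product_base_g` toward 0 deliberately re-enables reversal for the
Curtin–Hammett-breakdown tests.  A single integer seed feeds one PRNG;
identical specs generate byte-identical networks.

What the generator does *not* emulate: real conformer-energy
distributions (no quantum-chemistry energies), geometric structure
(synthetic nodes carry no coordinates), network-scale heterogeneity
(tens of thousands of EQs, barriers to 400 kJ/mol), or energy error of
a fitted potential.  Passing tests therefore demonstrate correctness of
the kinetics/selectivity/grouping machinery under controlled truth, not
predictive accuracy for any specific real system.

Small analytic geometries (a 6-atom stereogenic C(H)(F)(Cl)–OH scaffold
and its rotamers, mirror images and bond-broken variants) provide ground
truth for the structural stages.

## Grouping and stereodescriptors

Bonds are perceived by a covalent-radius criterion, d(i,j) <
scale·(r_cov(i)+r_cov(j)), with published single-bond radii and default
scale 1.2 ("bonded" is a modelling choice; the scale is configurable and
group counts on real data should be treated as calibration-sensitive).
Bond patterns are canonicalized by Morgan-style iterative neighbourhood
refinement and hashed, making them invariant under rigid motions, mirror
reflection and permutation of identical atoms.

EQs are grouped by the pair (bond pattern of a user-designated
reaction-site region plus its bonds to the rest, R/S stereodescriptors at
the region's tetra-coordinate centres).  Stereodescriptors use a
simplified priority rule — atomic number, ties broken by sorted
neighbour-shell atomic numbers recursively to depth 3 — with the label
from the signed tetrahedron volume det[v₁−v₄, v₂−v₄, v₃−v₄] (negative =
R under the right-hand convention, viewing the top three priorities from
opposite the lowest).  Centres with |volume| < 0.1 Å³ or exhausted ties
get "none".  This is *not* full CIP: sufficient for stereocenters with
chemically distinct substituents (the intended use), documented as a
limitation for fused or highly symmetric stereochemistry.  Mirror
reflection of every geometry maps the partition onto itself with R and S
exchanged (property-tested).

Group ids G1, G2, … are assigned by ascending minimum Gibbs energy.  The
coarse group network keeps the lowest-G member as each group's
representative and, per group pair, the minimum-energy connecting TS,
flagged when *strictly* below the highlight threshold (default
150.0 kJ/mol).

## Numerical conventions and degenerate inputs

* Self-loop paths are dropped at load with a logged count (they carry no
  first-order kinetic information); duplicate node ids and dangling edge
  endpoints are errors.
* Initial populations default to a Boltzmann distribution over the
  designated reactant conformers (the pre-equilibrated ensemble);
  configurable to any vector.  Populations are validated to sum to 1
  (10⁻⁹) and clipped at −10⁻¹² before reporting.
* CSV round trips preserve energies exactly (`float_precision="round_trip"`);
  rates below 10⁻³⁰⁰ s⁻¹ underflow to zero.
* Barriers are clamped nonnegative; an empty network is an error, an
  edgeless one is valid.
* t_final = 0 returns the initial state; contraction with all escape
  rates below threshold is a no-op equal to the exact solver.

## Design choices made where the design was open

* The contraction scheme (share-criterion hybrid of steady-state
  elimination and Boltzmann-weighted lumping, safety factor 10¹⁰) is the
  package's own; its acceptance surface is equivalence with the exact
  master equation wherever the latter is well-posed.
* The initial condition (Boltzmann over reactant conformers) and the
  treatment of products (reversible, read at t_final) are stated
  defaults, not universal conventions; both are configurable.
* An energy-override table (`kind,id,gibbs_kjmol`) lets users replace
  individual EQ/TS energies to curate a network without editing the
  master tables.
* Test problem sizes (6×8-conformer benchmark, 5–50-node random
  ensembles, 100-network oracle sweeps) were chosen so the whole suite
  runs in seconds while still exercising stiffness ratios of 10¹⁵.

## Known limitations

* Absolute rates assume κ = 1 Eyring kinetics; no RRKM/pressure
  dependence, no variational TST, no tunnelling.
* Dense linear algebra limits the exact solver to a few thousand states;
  the contraction solver's current implementation is dense as well
  (adequate to ~10³ states; the algorithm itself is sparse-friendly).
* Simplified stereo priorities, no full CIP; no automated reaction-site
  detection; bond perception is distance-based only (no bond orders).
* Gibbs energies are inputs; the package computes no thermochemistry.
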