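# Methods

## The model

`cumoflux` simulates and fits the incorporation of ¹³C from
[1,6-¹³C₂]glucose into the multiplet fine structure of brain glutamate and
glutamine, using a two-compartment (neuronal–glial) metabolic network and
the *bonded cumomer* formalism.

A cumomer fraction π_M{i} of pool M is the fraction of M molecules labeled
at least at the carbon set {i}; the set size is the cumomer's order. Bonded
cumomers restrict {i} to chemically adjacent carbons — exactly the
information content of one-bond ¹³C–¹³C scalar couplings — and order ≤ 3
suffices for every observable multiplet of a mid-chain carbon. For each
cumomer of a pool with steady-state concentration P (µmol/g), the balance is

    P · dπ/dt = Σ_inflows V · Π(source-pool cumomer fractions covering the
                mapped positions)  −  (Σ_outflows V) · π

Condensation reactions multiply the cumomer fractions of their substrates
(distinct molecules label independently); sources outside the tracked
network (CO₂ fixed from blood, dilution inflows) contribute a factor equal
to the natural-abundance enrichment (0.011); passage through the symmetric
fumarate/succinate stage averages two orientation-specific atom maps with
weight ½ each.

Observable multiplets are linear images of the bonded cumomers. For a
carbon c with two inequivalent couplings (Glu/Gln C4):

    Q = π{c−1,c,c+1}          D_left  = π{c−1,c} − π{c−1,c,c+1}
    S = π{c} − π{c−1,c} − π{c,c+1} + π{c−1,c,c+1}
    D_right = π{c,c+1} − π{c−1,c,c+1}

and for equal couplings (C3) the doublets merge into D and the triplet T
replaces Q. Patterns always sum to the positional (order-1) enrichment; the
package asserts this as an invariant.

### Assumptions

- Metabolic (not isotopic) steady state: pool sizes and fluxes are constant;
  only label moves.
- The NMR measurement sees concentration-weighted sums over compartments
  (Glu = 90% neuronal + 10% glial; Gln is entirely glial; the splits are
  configurable).
- LDH operates near equilibrium (fixed exchange constant, below).
- No isotope effects on rates; CO₂ refixation only through pyruvate
  carboxylase.

## The canonical network and the 133 state equations

Pools (carbons; default µmol/g): brain glucose (6; 4.0), neuronal and glial
pyruvate (3; 0.1 each), lactate (3; 1.0), CO₂/bicarbonate (1; 12.0), and per
compartment acetyl-CoA (2; 0.1), 2-oxoglutarate (5; 0.2 n / 0.1 g),
glutamate (5; 7.56 n / 0.84 g), oxaloacetate (4; 0.1), aspartate
(4; 1.5 n / 1.0 g), plus glial glutamine (5; 4.3). Plasma glucose is a
driven input with label at C1/C6.

Carbon mappings are textbook TCA biochemistry: glycolysis sends Glc C1 and
C6 to pyruvate C3 (the two triose orientations averaged ½/½); PDH loses Pyr
C1 to CO₂; citrate synthase/IDH map OG C1←OAA C4, C2←OAA C3, C3←OAA C2,
C4←AcCoA C2, C5←AcCoA C1 with OAA C1 lost to CO₂; OGDH loses OG C1, and the
fumarate stage scrambles OAA Ci ← ½ OG C(i+1) + ½ OG C(6−i); pyruvate
carboxylase maps Pyr C1–C3 → OAA C1–C3 and fixes CO₂ onto OAA C4. These
mappings reproduce the classic signatures: PC labels Glu/Gln C2 and dilutes
C3; second-turn label arrives at C2/C3 equally.

Free fluxes (µmol/g/min): vpdh_n, vg, vpc, vx, vnt, vdil, vout. Mass-balance
closures: VTCA_g = vg + vpc, Vsyn = vnt + vpc, Vefflux = vpc, Vin = vout,
CMRglc_ox = (vpdh_n + vg + vpc)/2. Three bookkeeping choices keep every pool
balanced exactly while reproducing the classical labeling equations:

- the glial acetyl-CoA dilution is an unlabeled inflow vdil with a return
  outflow vdil − vpc, so citrate synthase can carry VTCA_g = vg + vpc and
  the AcCoA labeling equation is the familiar
  `P dπ/dt = vg π_pyr − (vg + vdil) π`;
- lactate exchanges with both pyruvate pools at a fixed near-equilibrium
  LDH constant (1.0 µmol/g/min, a network constant, not fitted) and is
  diluted by unlabeled blood lactate at vin = vout;
- CO₂ collects all decarboxylations, feeds pyruvate carboxylase, and is
  washed out at the rate mass balance requires.

Enumerating bonded cumomers of order ≤ 3 over all non-input pools gives
**133 state equations**: 12 for glucose (bonded sets are not tracked across
the aldolase-cleaved C3|C4 bond, which no observable can ever see), 6 per
three-carbon pool (×3), 1 for CO₂, and 3/12/12/9/9 for the 2/5/5/4/4-carbon
pools of each compartment (+12 for glutamine). A state-count argument shows
why the CO₂ pool must be explicit: every pool with ≥ 2 carbons contributes
3n − 3 states, a multiple of 3, so no enumeration without a one-carbon pool
can produce 133. Tracking CO₂ also closes the refixation loop (labeled CO₂
from PDH/IDH/OGDH re-entering via PC), rather than assuming PC fixes only
unlabeled carbon.

The positional (total-enrichment) model is the exact order-1 reduction of
the same system — 61 equations whose right-hand sides are term-for-term
identical to the order-1 components of the full system.

## Verification strategy

A brute-force oracle integrates every isotopomer fraction explicitly (2ⁿ
states per pool; 322 for the canonical network) using explicit joint label
distributions per substrate — no code shared with the compiled cumomer
engine — and aggregates isotopomers into cumomers. The two engines agree to
better than 10⁻⁶ (typically 10⁻⁹) on toy networks and on the full canonical
network; this is the strongest internal check the formalism admits.

## Synthetic data

The generator emulates the study acquisition: a plasma FE input rising
linearly from natural abundance to 0.70 at the end of a 5-min bolus and
constant thereafter (the *enrichment* plateau is what the model consumes;
the exponentially decaying infusate volume is not modeled); sampling at
t = 0 plus 16 blocks of 10.6 min (17 points over ~3 h); and per-curve
Gaussian noise with constant absolute SD equal to a relative SD at steady
state — 5% for totals, 15% for multiplets — mimicking how CRLB-based
uncertainties behave near the inclusion threshold. The observable sets are
17 curves (bonded: totals plus quantifiable multiplets, with C3 S and T
merged because their resonances overlap, and GlnC2 reduced to its singlet),
6 totals (positional), or the 11 multiplets alone.

What the generator does **not** emulate: time-varying CRLBs (real
uncertainties are larger early in the infusion), spectral baseline and
quantification cross-correlations (noise here is independent across curves
and time points), animal-to-animal variability, and line-shape/overlap
artifacts. Passing tests therefore demonstrate correctness of the formalism
and estimator under the stated noise model, not robustness to structured
spectral artifacts.

Reference fluxes for synthetic experiments: vpdh_n = 0.40, vg = 0.10,
vpc = 0.06, vx = 0.45, vnt = 0.10, vdil = 0.30, vout = 0.30 µmol/g/min
(vnt and vdil sit at the middles of the sensitivity grids; CMRglc_ox = 0.28;
vx slightly above vpdh_n, consistent with malate–aspartate shuttle
dominance). vout has no published reference value; 0.30 is a configurable
package choice.

## Estimation

The fit minimizes Σ[(model − data)/sd]² — each residual weighted by 1/sd,
the square root of the inverse variance — over the seven free fluxes with
bounds [0, 5] µmol/g/min, using scipy's trust-region-reflective least
squares (the bounded member of the Levenberg–Marquardt family). Finite
difference steps for the Jacobian are 10⁻³ relative, deliberately far above
the ODE solver's noise floor; optimizer tolerances are 10⁻⁸. On noiseless
data the estimator is an exact fixed point: all seven fluxes return to the
truth within ~10⁻⁵ relative.

Monte-Carlo uncertainty follows the parametric bootstrap: Gaussian noise
with the data's per-point SD is added to the best-fit model curves, each
replicate is refitted from the base estimates, and the replicate spread,
gamma-density summaries and Pearson correlation matrix are reported. Flux
densities are summarized by a maximum-likelihood gamma fit (location fixed
at 0, since fluxes are positive) and its FWHM, located by bisection on the
half-maximum crossings around the mode; the FWHM is defined only for shape
k > 1 (interior mode). More than 10% non-converged replicates is an error.

The sensitivity scan pins one flux to each grid value (defaults: vnt over
{0.07, 0.10, 0.20}, vdil over {0.20, 0.30, 0.60} µmol/g/min), refits the
remaining six, and stores the refit GluC4 and GlnC4 total and multiplet
curves — simulated from the order-3 system even when the positional model is
being fitted, to expose what the positional cost function cannot see.

## Numerical choices

- Integrator: `solve_ivp` LSODA with an analytic Jacobian assembled from the
  compiled bilinear terms; the system is mildly stiff (small intermediate
  pools, fast LDH exchange). RK45 is available via `method=` and agrees to
  < 10⁻⁶; a convergence test halves the tolerance and bounds the change.
- Tolerances: rtol 10⁻⁸ (simulation), 10⁻⁶ (inside the fit loop, where the
  finite-difference step is chosen to dominate it); oracle at 10⁻⁹.
- Initial condition: independent natural-abundance labeling, so an order-k
  state starts at 0.011ᵏ; `natural_abundance=0` starts unlabeled.
- Containment (π_superset ≤ π_subset) is enforced with tolerance 10⁻⁶ at the
  transform stage (10⁻⁴ inside the fit loop, matching the looser integrator
  tolerance); violations beyond tolerance raise rather than silently clip.
- Degenerate inputs: zero-noise datasets carry unit weights (sd = 1) instead
  of the degenerate sd = 0; FE(C3) from C4 multiplets errors when
  S + D34 = 0; constant or non-positive Monte-Carlo samples error rather
  than producing a meaningless gamma fit.

## Problem sizes

The shipped studies use 50 Monte-Carlo replicates per variant (the full
procedure is 500; summaries at 50 are within sampling error of the same
directions), 17 × 17 data points per bonded fit, and the 322-state oracle
on the full network. A bonded fit takes ~1.5 s, a 50-replicate Monte Carlo
~1–2 min on one core.

## Known limitations

- Single tracer protocol (glucose-style driven input; an acetate-style input
  pool can be configured but no dual-infusion protocol is shipped).
- No stiff-solver fallback is needed for physiological fluxes, but extreme
  flux sets (e.g. vx ≫ 1 with tiny intermediate pools) slow LSODA down.
- The bookkeeping outflow vdil − vpc assumes vdil ≥ vpc at the reported
  optimum; integration remains well-posed regardless, but the mass-balance
  report shows a negative dilution return flow if a fit drives vdil below
  vpc.
- Carboxyl carbons (C1/C5) and two-bond couplings are not observables.
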