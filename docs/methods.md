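# Model and methods

`c4sim` is a compartmental kinetic model of C4 photosynthesis in a leaf
with classical Kranz anatomy: mesophyll cells (MC) fix CO2 into C4 acids
and bundle-sheath cells (BSC) decarboxylate them around Rubisco. The
package exists to compare five wirings of that shuttle — the textbook
NADP-malic-enzyme pathway, three mixed pathways that add aspartate
transfer and/or PEP carboxykinase, and a hypothetical pathway that uses
only aspartate and PEPCK — under identical enzyme capacities and energy
budgets.

## State variables and balances

Metabolite pools live in four compartments (MC cytosol, MC chloroplast,
BSC cytosol, BSC chloroplast), with concentrations in µM and fluxes on a
leaf-area basis (µmol m⁻² s⁻¹). Each unclamped pool obeys

    dM/dt = (Σ producing fluxes − Σ consuming fluxes) / V,

where V is the compartment volume per leaf area (defaults 0.02 /0.01
/0.01 /0.01 L m⁻²; they convert areal fluxes to concentration changes and
the reported per-area results are insensitive to the split within a
factor of a few). The mesophyll CO2 pool is clamped to the dissolved
equivalent of the intercellular partial pressure Ci (Henry constant
0.0334 µM µbar⁻¹), and ambient O2 (210 mbar) provides the external O2
boundary. Chloroplast metabolites other than the energy/redox pairs and
the Calvin-cycle intermediates are lumped with the cytosol of their cell;
the BSC chloroplast keeps explicit CO2, O2, PGA, TP and RuBP pools
because the *site* of CO2 release (stroma for NADP-ME, cytosol for
PEPCK) and the locus of PGA reduction are what distinguish the pathways.

## Reactions

Rate laws are irreversible Michaelis–Menten (1–3 substrates, optional
1/(1+I/Ki) inhibition factors), a compact Haldane-consistent reversible
MM, linear mass action for carbonic anhydrase, Fick diffusion for
transport, and the coupled Rubisco carboxylation/oxygenation pair

    vc = Vcmax·C/(C + Kc(1+O/Ko))·RuBP/(RuBP+Km),
    vo = Vomax·O/(O + Ko(1+C/Kc))·RuBP/(RuBP+Km),

with Vomax fixed by the specificity factor (S = 82 on a dissolved-
concentration basis, Kc = 650 µbar, Ko = 450 mbar, Vcmax = 65). Maximum
activities follow the classical maize compendium (PEPC 170, MDH 90, PPDK
90, NADP-ME 90, Rubisco 65, AspAT/AlaAT 400, PEPCK 60, bundle-sheath MDH
60); Km values are mid-range literature numbers recorded with source
notes in `data/default_params.yaml`.

Three regulatory elements are part of the model because the network is
not steady without them:

* **PEPC feedback** by malate/aspartate (Ki 15–30 mM) and its product OAA
  (Ki 5 mM). Without it, a capacity-limited downstream step lets the
  carboxylation products grow without bound.
* **NADP-ME product inhibition** by pyruvate (Ki 15 mM). Without it, dim
  light leaves PPDK unable to return pyruvate and the pool diverges.
* **A Mehler-type NADPH overflow valve** in each chloroplast (Vmax 6,
  consuming O2 — the water–water cycle). Without it the bundle-sheath
  pyridine pool locks fully reduced and the malic-enzyme CO2 source
  dies irreversibly.

The mesophyll pump enzymes (PEPC, PPDK, NADP-MDH) carry a coordinated
light-activation factor J_m/(J_m+K_act) with K_act = 50 µmol e⁻ m⁻² s⁻¹,
standing in for PPDK regulatory protein, PEPC phosphorylation and
thioredoxin activation: in dim light the CO2 pump cannot outrun the
Calvin cycle. NADP-MDH additionally carries a high effective NADPH Km
(300 µM) lumping its activation state; this enzyme's effective ceiling is
what the aspartate route relieves at high light, and it is what makes
the standard pathway saturate earlier than the mixed ones.

The C4 carrier skeleton (PEP/OAA/MAL/ASP/PYR/ALA) is conserved by the
shuttle itself; a reversible PGA↔PEP step (PGA mutase + enolase lump,
Keq 0.1) in the MC cytosol lets the carrier pool grow or shrink from the
Calvin side, as in the plant. PGA reduction (PGA kinase + NADP-GAPDH) is
modeled reversibly (lumped Keq 0.05) so over-reduction self-limits;
bundle-sheath reduction capacity is deliberately small (Vmax 110) because
NADP-ME bundle sheaths are GAPDH-poor — this is why surplus bundle-sheath
LET NADPH is worth little to the shuttle variants and the light-
allocation optimum barely moves with the LET fraction. RuBP regeneration
is a lumped 5 TP + 3 ATP → 3 RuBP step with RuBP product feedback
(stromal phosphate balance). Photorespiration is 2 PGLY → PGA + CO2
(released in the BSC cytosol) at 1 ATP + ½ NADPH; respiration (Rd = 1,
split 0.5/0.5) enters as a boundary CO2 source in each cell, its
substrate being storage carbohydrate outside the modeled pools. Carbon
leaves through a supply-regulated mesophyll sucrose sink and a
bundle-sheath starch sink (squared MM saturations, so they idle when
triose is scarce).

## Energy supply

Electron transport follows the non-rectangular hyperbola
θJ² − (I₂+Jmax)J + I₂Jmax = 0 (θ = 0.7) per cell, with absorbed light
split by the allocation fraction f_MC and the PSII half of the quanta
driving linear flow. Mesophyll chloroplasts run linear transport only;
bundle sheaths split light and capacity by the LET fraction u = v between
a linear chain (NADPH + ATP + O2) and PSI cyclic flow (ATP only, one
quantum per electron). ATP and NADPH synthesis are separate reactions
capped at min(VmaxE, ε·J): ε_ATP = 0.75 per e⁻ (linear), 0.375 per e⁻
(cyclic — equal ATP per photon to the linear chain), ε_NADPH = 0.5 per
e⁻. O2 evolves at J_l/4 in the compartment hosting the linear chain.
Jmax values (220 mesophyll, 340 bundle sheath) were calibrated once so
the variant family saturates near the maize light-response data (best
curve A ≈ 37–38 µmol m⁻² s⁻¹ at PPFD 2000–2500, the standard variant
≈ 33 at its plateau).

Gas leak conductances between the cell types: g_CO2 = 0.15
µmol m⁻² s⁻¹ µM⁻¹ (calibrated once so standard-variant leakiness sits
near the measured mid-light band), with the O2 conductance at 0.15× the
CO2 value. O2 venting from the bundle sheath is therefore strongly
restricted, and with bundle-sheath LET switched on the evolved O2
accumulates appreciably; this photorespiratory penalty on BSC-heavy
light allocations is part of why the allocation optimum stays at 55–65%
mesophyll for every LET fraction.

## Variants

All variants share the catalog; switches set enzyme capacities to zero
(standard: no aminotransferases, no PEPCK, no BSC MDH; the mixed variants
per their names; BSC MDH only where aspartate is decarboxylated through
NADP-ME). The aspartate share of C4-acid transfer is enforced by a single
calibrated scale on the mesophyll AspAT capacity (deterministic bisection
to 25 ± 2% at PPFD 2000, the carbon-label partition value); the
calibrated scales ship in the parameter file. The aspartate/PEPCK-only
variant has no PPDK (PEP itself returns), no PGA/TP traffic anywhere
along its carbon path (the BSC chloroplast envelope exchanges only
gases, starch is the carbon outlet, and the mesophyll keeps no Calvin-
intermediate metabolism), and pyruvate exists purely as the alanine
shuttle's counter-carrier. That closed structure is what makes its LET
dependence exact: without PSII in the bundle sheath there is no NADPH
source anywhere along its carbon path and carboxylation is structurally
zero, at any PEPCK/AspAT capacity.

## Steady states

Runs integrate the stiff ODE system (scipy LSODA, BDF fallback, rtol
1e-8/atol 1e-10) in chunks to t = 2×10⁵ s of model time, stopping when
max |dM/dt| / max(M, 1 µM) < 1e-8 s⁻¹; results carry an explicit
`converged` flag and the residual. The long horizon is needed because
the aspartate pools of the PEPCK-using variants fill on a ~10⁵ s
timescale; wall cost is small because the solver takes large steps on
the smooth tail. The CO2-concentrating steady state coexists with a
throttled low state at high light, so cold starts approach the target
through a light ramp (settle at PPFD 300, then 1000, then the target),
mimicking photosynthetic induction; scans warm-start along their grids.
The default initial state primes the Calvin cycle and carrier pools at
working (millimolar-range) sizes — the Calvin cycle is autocatalytic and
cannot bootstrap from micromolar pools — and the amino-donor moiety
(GLU + 2-OG, conserved per cell) at 8.4 mM. A per-chunk evaluation
budget turns pathological integrations into honestly-flagged unconverged
results instead of hangs.

## What the experiments show (and their problem sizes)

The shipped scans use PPFD step 50 (light response, 5 variants × 51
points), f_MC step 0.05 (allocation, 21 points × 4 LET settings), and
the PEPC scale grid 0.7–1.0. At these sizes the full acceptance
recomputation runs in minutes on one core. Crossovers are reported as
midpoints of the bracketing grid interval, with the interval width
attached; ties in allocation argmax break toward the lower fraction and
are flagged.

## Known limitations

* Kinetic constants not printed in the primary sources are mid-range
  compendium values; absolute pool sizes (e.g., the malate:pyruvate pool
  ratio, here ~2–4× rather than the reported order of magnitude) are
  parameterization-sensitive even where fluxes and orderings are robust.
* Leakiness of the mixed variants runs high (φ up to ~0.5 at low light),
  consistent with the known tendency of single-conductance ODE models to
  overestimate leak because cytosolic/organelle positioning resistance is
  not represented.
* The leakiness response to a 15% PEPC reduction computes to ≈3%
  relative, below the reported ≈7%: in this parameterization the
  substrate-pool and feedback-relief compensations buffer PEPC more
  strongly than in the original model. The direction and the small cost
  in A (<1%) reproduce.
* No NAD-ME/mitochondrial variant, no transient-light dynamics, no
  explicit intracellular diffusion; steady states only.
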