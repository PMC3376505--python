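# Methods

## Scope and model structure

`mitodyn` is a kinetic ODE model of the mitochondrial ATP supply chain of a
neuron: pyruvate oxidation and the TCA cycle in the matrix, a
microstate-resolved respiratory chain, oxidative phosphorylation, adenine
nucleotide exchange, and the electrophysiology of the inner membrane.
Glycolysis is outside the model (cytosolic pyruvate is clamped), as are the
malate/aspartate shuttle, calcium uniporter dynamics, permeability
transition, and any feedback of reactive oxygen species on the respiratory
complexes.  ROS themselves are not simulated; the occupancies of the redox
microstates proposed as superoxide donors (fully reduced flavin, flavin
radical and bound semiquinone of complex I; the p- and n-side semiquinones
of complex III) are reported as proxies for site-specific ROS-producing
propensity.

The state vector holds, in order: 16 matrix metabolite pools (pyruvate, the
CoA esters, the eight cycle acids, NAD(H), adenine nucleotides, phosphate),
the four ubiquinone pools (quinone/quinol at the membrane's n- and p-faces),
the cytochrome c pair, four matrix ions (H+, K+, Na+, Cl-), cytosolic
ATP/ADP, the complex I microstate occupancies (96 lumped or 1536 full), the
48 complex III occupancies, and the membrane potential ΔΨ — 173 states in
the lumped default.  Units are mM, mV and seconds; fluxes are per matrix
volume, and cytosolic concentrations couple through the cytosol/matrix
volume ratio (default 10).

## Respiratory-chain state machines

Complexes I and III are combinatorial state machines: each microstate is an
integer code vector over the complex's redox carriers and quinone binding
sites, and every electron transfer or binding event is a reversible
mass-action transition between microstates, optionally exchanging NADH/NAD,
quinone, cytochrome c or protons with the surrounding pools.

*Complex I.* Carriers: the flavin (three levels — FMN, flavosemiquinone,
FMNH2), the iron–sulfur clusters N3, N1a, N1b, N4, N5, N6a, N6b, N2, and a
bound-semiquinone site, giving 3·2^8·2 = 1536 states.  The lumped variant
replaces the mid-chain clusters N1b…N6b by one two-state effective carrier
(96 states).  The electron path is the linear chain FMN → N3 → … → N2 →
bound SQ → QH2; N1a is an off-path one-electron reservoir exchanging only
with the flavin radical (its physiological wiring is uncertain; the choice
is config-switchable).  One proton is exported per N6b→N2 transfer and per
electron delivered from N2 to the quinone site — four per NADH.  Because
every rule moves electrons in pairs in and out of the machine (NADH
delivers two, ubiquinol removes two) while internal hops conserve count,
electron-count parity is invariant: the state space splits into two
dynamically disconnected sectors, and all occupancy lives in the
even-parity sector of the fully oxidized state.  The stationary
master-equation solver carries one conservation row per sector.

*Complex III.* Carriers: cytochrome c1, the Rieske Fe–S cluster, the p-side
semiquinone pocket, hemes bL and bH, and the n-side semiquinone pocket.
The p-side semiquinone can only exist while the Rieske cluster is reduced
(it is created by the reaction that reduces Fe–S, and holds the cluster
until released), which removes 16 of the 64 code combinations: 48 legal
states.  The q-cycle runs in seven reversible reaction classes: two-step
quinol oxidation at the p-site (first electron to Fe–S with both protons
released to the cytosolic side; second electron to bL with quinone
release), Fe–S → c1 → cytochrome c on the high-potential branch, the
trans-membrane bL → bH transfer, and two-step quinone reduction at the
n-site (two matrix protons).  Two gates reproduce the documented reaction
count of 88: while the p-site semiquinone is bound, neither Fe–S → c1 nor
bL → bH can proceed.  The second gate is a reconstruction — the source
count (48 states, 88 reactions) does not uniquely determine the rule set,
and this gating, consistent with the stated event order (quinone leaves the
p-site before the b-branch moves on), is the minimal choice that lands on
88 exactly.

*Thermodynamic construction.* Backward rate constants derive from
class-level midpoint-potential differences, kb = kf·exp(−ΔEm·F/RT), with
all midpoints quoted at pH 7 and pool concentrations entering as ratios to
common reference concentrations (1 mM; pH 7 for protons).  Any cycle of
transitions therefore closes thermodynamically (Wegscheider criterion,
verified exactly in the tests), and both machines satisfy detailed balance
at zero proton-motive force.  The bound-semiquinone couples sum to twice
the free Q/QH2 midpoint so that binding/release cycles close against the
free pool.

*Membrane-potential coupling.* A transition moving z elementary charges out
of the matrix carries symmetric Butler–Volmer factors exp(α·z·u) forward
and exp(−(1−α)·z·u) backward (u = FΔΨ/RT, α = 0.5), so pumping slows and
its reversal accelerates as the membrane hyperpolarizes.  In complex I the
four pumping steps carry z = 1 each.  In complex III the two charges per
electron pair are distributed over the dielectric: 0.25 on p-side quinol
oxidation, 0.5 on bL → bH, and 0.25 on each n-side reduction step.  A
single fully electrogenic bL → bH step (z = 1) chokes the q-cycle at
physiological potentials — with an 80 mV redox drop against ~140 mV of
electrical work the internal equilibrium jams the b-hemes reduced — whereas
the distributed assignment, which is also closer to the electrogenicity
profile measured for the bc1 complex, leaves the machine responsive.

*Proton bookkeeping.* "Pumped" protons are those appearing on the cytosolic
side: 4 per NADH at complex I, 4 per electron pair at complex III (the two
p-side quinol oxidations), 2 per pair at complex IV — 10 per NADH, 6 per
succinate, 0 for complex II alone, which the assembly-time stoichiometry
audit traces along both substrate paths.  Matrix-side chemistry (scalar
protons of the NAD-linked dehydrogenases, flavin protonation, quinol
formation, the oxidase's chemical protons) is tracked separately and closes
the matrix proton balance exactly at steady state, so total proton re-entry
equals total pumping.

## TCA kinetics

All nine reactions (PDH plus the eight cycle enzymes) use reversible
Michaelis–Menten kinetics with a Haldane-constrained reverse term,

    v = (1 − i) · Vmax · f_Ca · (Π S/Km)(1 − Γ/Keq′) / D,

with apparent equilibrium constants (CO2 and water folded in).  For the
NAD-linked dehydrogenases the denominator carries a single competitive
nucleotide site, (1 + NAD/Km_NAD + NADH/Km_NADH), rather than independent
substrate and product saturation factors.  This is the load-bearing kinetic
choice: at the reference redox poise the site is mostly NADH-occupied, so a
falling NADH level de-represses all four dehydrogenases together and the
cycle can roughly triple its flux as the matrix oxidizes.  With independent
saturation terms the same enzymes respond by only a few percent and the
model cannot reach the observed dynamic range.

Enzyme-specific inhibition is a multiplicative (1 − fraction) on Vmax,
always interpreted against the uninhibited baseline.  Matrix free calcium
is a clamped linear function of ΔΨ standing in for uniporter dynamics, and
activates PDH, IDH and KGDHC through a hyperbolic factor normalized to 1 at
the reference calcium level, so calibration is decoupled from the coupling
constants.

Citrate synthase and malate dehydrogenase operate near equilibrium against
a sub-micromolar oxaloacetate pool, which is why their capacity parameters
are one to two orders of magnitude above the cycle flux (CS is the classic
matrix-content marker for the same reason).  KGDHC carries the smallest
functional ceiling of the eight cycle enzymes — with saturating
α-ketoglutarate and everything else at reference it reaches only ~3× the
reference flux — making it rate-limiting for the cycle, with aconitase far
toward the other extreme (~45×).  Because the model has no anaplerotic
reactions, the eight cycle-acid skeletons form a conserved moiety; the
α-ketoglutarate accumulation that compensates KGDHC inhibition therefore
drains the other intermediates, and the size of this shared carbon pool
(≈1.0 mM) sets how fast NADH falls along the inhibition axis.

## Transport and electrophysiology

Passive ion permeation (H+, K+, Na+, Cl−) follows the
Goldman–Hodgkin–Katz flux equation, continuous at ΔΨ = 0.  The proton leak
additionally carries a non-ohmic amplification exp(−(ΔΨ−ΔΨref)/λ) with
λ = 14 mV, unity at the reference potential: the leak conductance grows
steeply with hyperpolarization and shuts down on depolarization, as
measured for the inner membrane.  This term is what lets the
ATP-synthesis share of proton re-entry climb from 60% to above 90% as the
load approaches capacity.  K+ and Na+ cycling close through electroneutral
1:1 cation/H+ antiporters; chloride has no active pathway and settles at
its Nernst distribution.

The ATP synthase is a reversible sinh-form rate in the scaled driving force
−(ΔG_phos + n_A·F·Δp)/2RT with n_A = 3 protons per ATP; the phosphate
carrier is an electroneutral Pi−/H+ symporter (one further proton per ATP
delivered), and the adenine nucleotide translocase is a saturable
electrogenic ATP4−/ADP3− exchanger whose zero crossing sits at the
thermodynamic ratio exp(−FΔΨ/RT).  All three are poised near equilibrium
at the reference state, which places respiratory control on the supply
side (ADP/Pi availability and the redox chain), in line with the classic
picture.  Complex IV is an irreversible oxidase rate, second order in the
reduced cytochrome c fraction, oxygen-saturable (O2 clamped at 30 µM), with
an exponential ΔΨ attenuation exp(κ·u), κ = 1.95.  κ is the one shape
parameter the capacity calibration adjusts: its physical ceiling is α times
the four charges the oxidase moves per pair (≈2), and near that value the
chain's conductance grows steeply enough on depolarization to roughly
triple its throughput between −140 and −120 mV.

Pyruvate uptake is saturable facilitated diffusion with no net proton cost.
The carrier is physiologically an H+ symporter, but the symported proton is
stoichiometrically returned by the hydration and export of the CO2 produced
by pyruvate oxidation, which the model does not track.  This bookkeeping is
not optional: with a proton debited per pyruvate and no charge
counterpart, the proton and charge balances of any steady state differ by
exactly one charge per cycle turn, and the only steady state of the whole
system is the dead, depolarized one.

Matrix pH is dynamic behind a linear buffering capacity (25 mM per pH
unit); cytosolic pH (7.2), ions, pyruvate, phosphate and oxygen are
clamped.  The membrane potential integrates the signed charge fluxes over
a capacitance of 1.45·10⁻³ mM/mV.

## Calibration: the designed reference state

Calibration is a direct construction, not a fit.  The reference
concentrations, ΔΨ = −140 mV and matrix pH 7.45 are fixed first; the
reference cycle flux v = 0.115 mM/s then determines every pathway flux
through the stoichiometry (4 NADH + 1 FADH2-equivalent + 1 GTP per
pyruvate; 46 protons pumped per turn), the proton re-entry is split
24/16/60% among leak, potassium cycling and ATP synthesis (the sodium
cycle is held at 0.2%, and the split is exact because pyruvate uptake is
proton-neutral), and each capacity parameter is solved so its rate law
carries its designed flux at the designed state.  Every flux is linear in
its own capacity parameter, and a uniform rate scale moves a machine's
stationary throughput linearly without changing its internal occupancy
distribution, so this solve is exact in one pass — the designed state is a
steady state of the parameterized model to machine precision, and it is
dynamically stable.  A second, measured stage bisects the maximal ATP
production capacity and nudges κ (complex IV's potential sensitivity)
until the reference load is 30 ± 3% of capacity; the shipped fixture
converges with the reference at 33% of a 3.03-fold capacity.

"Maximal ATP production capacity" is operationally the largest load
multiplier whose steady state exists, keeps ΔΨ at least as negative as
−80 mV, and actually delivers ≥95% of the nominal demand.  The delivery
clause is needed because the cytosolic load is ATP-saturable: beyond
capacity the system settles into a steady state with a collapsed cytosolic
ATP level rather than losing the steady state, so existence alone does not
mark the limit.  Scan points are flagged as collapsed when the solve fails
or ΔΨ rises above −80 mV.

## Numerics

The full system couples microstate relaxation (10³–10⁵ s⁻¹) to metabolite
and ion dynamics (10⁻²–10² s), which makes brute-force stiff integration to
steady state impractical.  Steady states are instead found by exact
machine elimination: at fixed pools and potential each complex's stationary
occupancy solves a small linear master equation (dense LU with one
refinement step, one conservation row per connected sector), so the fixed
points of the reduced ~29-variable system of pool, ion, nucleotide and
charge balances are exactly the fixed points of the full system.  A damped
Newton iteration runs on this reduced system with one balance row per
conserved moiety replaced by its conservation residual (nine moieties:
NAD(H), CoA esters, the cycle acids, matrix and cytosolic adenine
nucleotides, cytochrome c, both complex occupancies, and total ubiquinone
including machine-bound semiquinones); if Newton stalls, the reduced
quasi-steady-state ODE is relaxed with BDF and Newton retried.  Reported
steady states have scaled residuals below 10⁻⁸ per second relative.  A
caveat on uniqueness: the potassium/charge redistribution mode is orders
of magnitude slower than all other relaxation, so at any practical
tolerance the steady state is pinned only to ~1 mV in ΔΨ and ~1% in fast
observables.

Time-dependent trajectories (used by the conservation and stability tests)
integrate the full system with BDF; conserved moieties drift < 10⁻⁸
relative over 10⁴ s.  The model is deterministic; the only randomness in
the package is the seeded multistart perturbation of steady-state guesses.

Scan grids default to 25 points per axis in the CLI; the test and
acceptance runs use 13–18 point grids, the capacity bisection a 0.01
tolerance on the load multiplier, and the half-NADH bisections a 0.005
tolerance on the inhibition fraction.

## What the model reproduces, and limits

With the shipped fixture the model reproduces, as emergent behavior: the
quasilinear NADH/NAD decline from 0.30 to ~0.10 between normal and
2.5-fold load with ΔΨ confined to [−150, −120] mV; oxygen consumption
doubling while the ATP-synthesis share of the proton gradient rises from
60% to >90%; a total QH2/Q ratio falling from ~1.4 to ~0.5 with the p-side
pool oxidizing fastest; ATP output maintained up to ~60% KGDHC inhibition
through α-ketoglutarate accumulation, with half-reduction of NADH at ~43%
KGDHC but ~93% aconitase inhibition; and, under KGDHC inhibition at fixed
load, falling occupancy of the fully reduced flavin and the p-side
semiquinone with the complex I bound semiquinone nearly unchanged.

Known limitations.  The microscopic rate constants and midpoint potentials
are effective values chosen for thermodynamic consistency and the
reference behavior, not fitted to spectroscopy; absolute site occupancies
should be read as relative trends.  The lumped complex I variant tracks
the full machine to <5% in the forward operating regime but deviates up to
~30% in the reverse regime near the flux-reversal potential (a two-state
carrier cannot represent five clusters' electron capacity); both variants
agree at the calibrated reference because each is flux-matched there.  The
closed cycle-carbon pool means long-term anaplerotic adaptation is absent,
and the collapse beyond capacity manifests as cytosolic ATP depletion at a
still-polarized membrane rather than as electrical collapse; the −80 mV
pathology line is retained as a scan flag but is reached only under strong
enzyme inhibition.  Chloride is decorative.  Cytosolic redox shuttles,
calcium dynamics and ROS-damage feedback are out of scope.
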