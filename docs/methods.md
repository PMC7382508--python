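# Methods

`cgbind` analyses unbiased, reversible ligand-binding trajectories — the
regime where a ligand at millimolar effective concentration finds, leaves
and re-finds its site many times per run — and turns them into binding
thermodynamics, kinetics, poses and pathways.  This note records the
models, conventions and numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Units and constants

Lengths nm, times µs, energies kJ/mol, temperatures K.  Pose RMSDs are
reported in Å.  R = 8.314462×10⁻³ kJ mol⁻¹ K⁻¹, default T = 300 K
(RT = 2.494 kJ/mol).  The standard-state number density is
C⁰ = (1/1.66) nm⁻³ ≙ 1 M; Avogadro's number 6.02214076×10²³ mol⁻¹.  One
coarse-grained water bead represents 4 water molecules; bulk water is
taken at 33.37 molecules nm⁻³ when converting bead counts to volumes.

## Radial PMF and standard-state ΔG

Let r be the minimum-image distance between the centers of geometry
(unweighted — the CG mapping convention) of the pocket and of the ligand.
The estimator is:

1. **Shift.** r ← r + δ with δ = 0.25 nm by default, a proxy for the
   ligand's mean radial extent (a COG-to-COG distance understates
   surface-to-surface proximity for a multi-bead ligand).  δ is a signed
   configuration parameter; synthetic point-ligand benchmarks use δ = 0,
   since a point has no radial extent.  Whether p(r) is normalized before
   or after the shift is immaterial for free-energy *differences*; we
   normalize after.
2. **Histogram.** p(r) on bins of width 0.05 nm, normalized to
   Σ p·Δr = 1 over the binned range.  Empty bins are masked.
3. **PMF.** PMF(r) = −RT ln p(r) + 2RT ln r + C.  The 2RT ln r term
   removes the 4πr² shell Jacobian (the volumetric/entropic correction);
   it is evaluated not at the bin center but at the bin's uniform-density
   rms radius r_eff = √((r_lo² + r_lo r_hi + r_hi²)/3), which makes the
   ideal-gas cancellation exact in every bin (bin centers leave an
   ~RT·ln(1.3) ≈ 0.7 kJ/mol artifact in the innermost bin).  C is chosen
   so the PMF is zero at the single occupied bin nearest r_ref = 4.5 nm
   (bulk); a window-averaged anchor is available by configuration.
4. **Binding constant.** K_bind = ∫₀^{r_c} 4πr² e^(−PMF(r)/RT) dr with
   r_c = 4.0 nm, trapezoid rule on the occupied bins; masked bins count
   as inaccessible (integrand 0).  K_bind is an effective bound volume in
   nm³ and deliberately includes surface association, not just the
   buried-pocket well.
5. **Standard state.** ΔG⁰ = −RT ln(K_bind C⁰).

Statistical errors are the SD of ΔG over bootstrap resampling of whole
replicas (default 1000 resamples); replicas, not frames, are the
independent unit.  `bootstrap_pmf_band` gives the analogous per-bin SD of
the PMF profile, which is the correct yardstick for profile flatness —
per-bin uncertainty at small r is far larger than the ΔG error because
inner shells are visited rarely and in correlated bursts.

**Known bias.** When some replicas never unbind, bulk is under-sampled
relative to the pocket and |ΔG| is underestimated; results carry an
`undersampled_bulk` flag and no correction is applied.

## Events, concentration and k_on

Binding/unbinding events come from a two-threshold hysteresis automaton
on r(t): bound once r < r_on (0.7 nm) is sustained for min_dwell
(0.01 µs), unbound once r > r_off (1.5 nm) is sustained equally.  The gap
suppresses recrossing chatter at the pocket mouth.  The initial state is
read from the first frame relative to r_off; an interval bound at the
start adds no binding count, an interval still bound at the end adds no
unbinding count (so binding totals may exceed unbinding totals, as they
do when long-lived complexes outlast replicas).  Per replica,
|#bind − #unbind| ≤ 1, and events alternate strictly.

Concentration: c = n/(N_A V) reported in mM; one ligand in a (10 nm)³ box
is 1.66 mM.  When only a water-bead count is published, V ≈ 4·n_beads /
33.37 nm³.

k_on = n_bind / (T_unbound · c), with T_unbound = T_total·(1 − f_bound):
association is only possible from the unbound state.  The naive
total-time variant is one flag away.  Units: s⁻¹ µM⁻¹.

## Pose RMSD

The reference ligand is built from a crystal pose by COG mapping
(unweighted centroid of each bead's atoms, hydrogens included).  Per
bound frame: superpose the binding-pocket selection onto the reference by
the optimal proper rotation (Kabsch via SVD; reflections are never
returned), apply the transform to the whole frame, then take the minimum
ligand RMSD over the ligand's symmetry permutation group — for a ligand
with, e.g., threefold ring symmetry, bead orderings related by the group
describe the same chemical pose.  The permutation group is explicit input
(helpers generate cyclic/dihedral groups) and is closed under composition
and inverse at construction.  No re-fit is done on the ligand itself.

The published workflow relaxes the mapped reference by one force-field
minimization step; here that is replaced by an optional bond-geometry
regularization, since the effect is sub-0.1 Å and a force-field engine is
out of scope.  Multi-modal RMSD histograms are summarized by the local
maxima of a Gaussian KDE with absolute bandwidth (default 0.2 Å),
sorted by density, with a configurable prominence threshold; an all-equal
sample returns its single value.

## Density maps

Ligand COG positions (all-bead accumulation by flag) are binned into a
voxel grid (default 0.1 nm spacing) in the reference-aligned frame —
alignment on a backbone-like selection when frames need superposition,
identity for data already in a fixed frame.  Counts are conserved
(Σ counts + clipped = frames).  Enrichment = counts / bulk density, with
bulk estimated as the mean count in a far-field shell (default r > 3 nm
from the binding region, optionally capped to avoid under-covered
corners).  ΔG(x) = −RT ln(enrichment); the conventional isolevels
10/100/1000/10000 correspond to −5.7/−11.5/−17.2/−23.0 kJ/mol at 300 K.
Grids are written as plain-text OpenDX scalar fields (coordinates in Å, z
fastest) readable by standard molecular viewers.

## Pathways

Each binding event is labelled by the named region (loops, helix pairs,
lipid headgroups, synthetic channels) first touched in a look-back window
(default 1 µs) before t_bind; touch = any ligand bead within 0.6 nm
(typical CG first-shell distance) of any region bead, minimum image.
When two regions are first touched on the same frame — a boundary
approach — the closer region at that frame wins; remaining ties break by
name.  A `dominant_contact` rule (most contact frames in the window) is
provided as an alternative, since published pathway counts are
qualitative.  Untouched events are labelled `unclassified` and stay in
the denominator.  Lipid-tagged regions feed a `lipid_first` fraction:
events whose very first contact is a lipid region.

## The synthetic generator

`simulate_ligand_bd` integrates overdamped Langevin dynamics for a point
ligand: x ← x − (D/RT)∇U Δt + √(2DΔt)·𝒩(0,1)³, periodic wrap, with
wrapped and unwrapped coordinates stored (the unwrapped path is needed
for displacement statistics).  Potentials: flat; Gaussian well
U = −ε e^(−r²/2σ²); square well smoothed by a half-cosine ramp of width
0.1 nm so forces stay finite — the ramp adds ~10–15% to K_bind relative
to the sharp well (≈0.3 kJ/mol in ΔG) and `analytic_binding_constant`
integrates the potential actually simulated, so the oracle and the
simulation always refer to the same U(r).

Defaults define the benchmark conditions and are chosen once: a 10 nm
cubic box with one ligand (1.66 mM), 30 µs replicas (1.5×10⁶ steps of
Δt = 2×10⁻⁵ µs, sampled every 25 steps), well depth 20 kJ/mol, width
0.3 nm, D = 10 nm²/µs.  D is an effective coarse-grained diffusivity —
smoothed CG energy landscapes diffuse several-fold faster than atomistic
water — and together with the box yields ~3 binding events per 30 µs
replica, the observed order of magnitude for small aromatic binders at
this concentration.  The integrator refuses parameter sets whose
worst-case per-step displacement (drift bound + 4σ of noise) exceeds a
quarter box edge.  Each replica uses its own generator seeded
seed + replica_index; chunked noise generation uses a fixed chunk size so
trajectories are bit-reproducible regardless of length.  The initial
position is drawn uniformly from the box — exact equilibrium for a flat
potential and a bulk start otherwise; a deterministic far-corner start
was found to leave a relaxation transient that visibly tilts p(r) over a
30 µs replica.

Ground truth: K_bind = ∫ 4πr² e^(−U/RT) dr by adaptive quadrature (sharp
square well also in closed form); equilibrium radii by 1D inverse-CDF
sampling of 4πr²e^(−U/RT) (an independent route the BD distribution is
tested against); pose sets as recorded rotation/translation/permutation/
noise transforms of a reference bead cloud; pathway scenes as azimuthal
wedges tiling the full circle, decorated with marker beads on a Fibonacci
sphere (radius 1 nm, spacing 0.05 nm, contact cutoff 0.15 nm), whose
geometric channel label at the first shell entry in the look-back window
is the classification oracle.

What the synthetic benchmarks show: the estimator chain is unbiased and
correctly normalized for a known radial potential, event bookkeeping is
exact, symmetry RMSD equals the exhaustive minimum, densities recover the
imposed Boltzmann factor, and pathway labels recover approach geometry.
What they do not show: fidelity of any force field, ligand flexibility
and orientational entropy, pocket plasticity, solvent structure, or
membrane partitioning — a point ligand in a static radial well has none
of these.

## Problem sizes used in the shipped checks

The recovery studies run 30 replicas × 30 µs per condition (well depths
10/15/20/25 kJ/mol), 12 replicas for the flat-potential flatness check,
and 8–10 replicas for pathway statistics; these sizes give ~50–90 events
per condition and bootstrap ΔG errors near 0.1 kJ/mol, comfortably inside
the 1 kJ/mol recovery criterion.  The numba-compiled kernel advances
~10⁷ steps per second per core, so a full condition costs seconds.

## Degenerate inputs and edge conventions

Empty selections, empty regions, non-bijective permutations, r_on ≥
r_off, r_c beyond the binned range, an unoccupied anchor bin, K ≤ 0 and
collinear superposition selections are hard errors.  Triclinic boxes are
rejected outright rather than silently wrapped.  A single repeated RMSD
value yields one mode.  Distances at exactly L/2 follow round-half-even
in the minimum-image wrap (measure-zero set).
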