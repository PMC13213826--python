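# Methods

`protorelay` packages the post-catalytic analysis machinery for a
water-mediated amide/imidic-acid tautomerization: detection of
proton-relay water wires around a catalytic asparagine-like fragment,
structural and hydration analytics, coordination-number collective
variables, and an enhanced-sampling engine (OPES plus a machine-learned
committor) exercised on analytic surrogate landscapes.  This note records
the models, the conventions chosen where several were defensible, and what
the synthetic data can and cannot establish.

## Hydrogen bonds and water wires

A hydrogen bond is geometric: donor-acceptor heavy-atom distance
≤ 3.5 Å and donor-hydrogen-acceptor angle (at the hydrogen) ≥ 150°, both
boundaries inclusive.  Participants are restricted to the fragment
heteroatoms (the hydroxyl oxygen OD and imine nitrogen ND) and water
oxygens/hydrogens: in the systems this package targets, no other protein
side chains sit in proton-transfer-competent positions, so including them
would only add noise.

A water wire is a simple directed path OD → w₁ → … → w_k → ND (k ≤ 3) in
the hydrogen-bond digraph whose edges point along the donation direction.
This enforces the alternating donor/acceptor roles of a Grotthuss relay:
each bridging water accepts from its predecessor and donates to its
successor; the first bond is donated by OD through the mobile hydroxyl
proton H*, and ND is the terminal acceptor.  A frame is *catalytically
competent* when at least one wire exists.  Conventions chosen here:

- **Minimal order.** When wires of several orders coexist, the frame is
  labelled by the minimal order (a frame counts as "one-water-mediated"
  only if a one-water wire exists).  Chosen for determinism; the
  alternative (shortest *detected* first) depends on search order.
- **Directionality flag.** Competence can also be evaluated on the
  undirected hydrogen-bond graph ("both heteroatoms engaged"); the
  directional reading is the default because only directionally consistent
  networks can actually shuttle the proton.  The undirected set is always
  a superset (tested).
- Statistics across replica trajectories report mean ± sample SD (n−1) of
  the per-replica competent percentage; the order breakdown pools
  competent frames over replicas.

Correctness is established against exhaustive enumeration: for every test
frame, all ordered water subsets of size ≤ 3 are checked directly with
independent distance/angle arithmetic, and the graph search must reproduce
the exact set.

## Trajectory analytics

RMSD uses Kabsch least-squares superposition (proper rotation only,
det = +1); the residual is recomputed from the aligned coordinates rather
than taken from the solver, which loses ~7 digits to cancellation near an
exact match.  The same atom selection is used for fitting and measurement
unless the caller separates them.  RMSF superposes every frame onto a
reference, then takes the per-atom RMS deviation from the mean fitted
position; superposition absorbs 6 rigid degrees of freedom, which deflates
the expected value by √(1 − 6/3N) — negligible for realistic selections
and accounted for in the tests.

SASA is Shrake-Rupley with a rolling probe of 1.4 Å (a water molecule) and
960 Fibonacci sphere points by default (92 is the accepted floor; 960
gives an isolated-sphere error well under 1%).  Van der Waals radii
(C 1.7, N 1.55, O 1.52, S 1.8, H 1.2, P 1.8 Å) are an explicit parameter —
the backend (biotite) is always called with this table, never its internal
defaults, and with neutral residue names so that its solvent filter cannot
silently drop atoms.

Hydration shells count water *oxygens* within radial cutoffs of the
fragment carbon (1–10 Å in 0.5 Å steps, plus 15 and 20 Å), inclusive at
the boundary, minimum-image when a box is present.

## Collective variables

The coordination number of a proton with a heteroatom uses the rational
switching function s(r) = (1 − (r/r₀)⁶)/(1 − (r/r₀)¹²) with r₀ = 1.1 Å.
The implementation evaluates the algebraically identical form
1/(1 + (r/r₀)⁶), which removes the r = r₀ singularity exactly (s(r₀) = ½)
and keeps all derivatives smooth; analytic gradients are tested against
central finite differences at 1e−6.

The proton-transfer CV is CV = CN_N − CN_O, summed over the transferable
protons — H* plus all water hydrogens of the reactive set (3 for one
bridging water, 5 for two), never the spectator imine proton H_N.  It is
≈ −0.64 in the imidic state, ≈ +0.64 in the amide state, and exactly 0 at
a symmetric proton placement.  The free-energy-surface axes are
CV1 = d(C,N) − d(C,O) (Å; negative in the imidic state) and CV2, the same
coordination-number difference.  An option includes H_N in CV2, which
shifts the amide basin to CV2 ≈ +1.5 (two protons on the nitrogen) while
the imidic basin stays near 0; the default excludes it so CV2 coincides
with the biased CV.

## Surrogate landscapes

The sampling engine is exercised on analytic two-basin surfaces standing
in for the tautomerization free-energy landscape: two Gaussian wells
(width 0.5) at s₁ = ∓1 (imidic at negative s₁, amide at positive), a
Gaussian ridge along s₁ = 0, and a steep x⁸ confinement wall.  The wall is
deliberately close (scales 1.9 and 1.5, height 30 kcal/mol): regions
irrelevant to the two-basin problem are pushed above the bias cap, so a
capped bias cannot park the walker in physically meaningless plateaus.

`make_surrogate(dG, dG_barrier)` calibrates the two well depths by a
numerical root solve so that (i) the saddle energy minus the imidic
minimum equals the requested forward barrier *exactly* (to the optimiser
tolerance, ~1e−6) and (ii) the *quadrature* basin free-energy difference
(−kT log of the Boltzmann basin-population ratio at 300 K) equals the
requested ΔG.  Because calibration uses quadrature rather than a harmonic
approximation, the configured values are exact references for recovery
tests.  The construction certifies exactly two minima on a grid and
rejects infeasible (ΔG, ΔG‡) combinations.

## Enhanced sampling

**Propagator.** Overdamped (Brownian) Langevin dynamics with kT = 0.596
kcal/mol (300 K), friction 1, dt = 0.002 in CV units.  Only equilibrium
statistics matter for free-energy recovery, so the inertial degrees of
freedom of full Langevin are omitted.  Euler-Maruyama discretisation
inflates a harmonic variance by 1/(1 − k·dt/2γ) — ~0.1–0.4% at the
defaults, far below the recovery tolerances.

**OPES.** The bias acts on a scalar CV.  Kernels are deposited every 100
steps (the reference deposition interval of 50 fs at a 0.5 fs time step)
with the iterative-reweighting kernel weight e^{βV}; the kernel bandwidth
follows the adaptive rule σ = σ₀·(N_eff·¾)^(−1/5) every 200 steps, floored
at σ_min = 0.05 so late kernels keep filling at a useful rate.  The
internal estimate uses the explored-volume normalisation
V_int = (1−1/γ)kT ln(P̃/Z + ε) with bias factor γ = βΔE and
ε = e^{−βΔE/(1−1/γ)}; the *applied* bias is V_int shifted to maximum zero
and clipped at −ΔE.  A constant shift changes no forces, and the clip
makes the cap — deposited bias range never exceeding ΔE = 20 kcal/mol —
an exact structural property, asserted at every deposition.  The kernel
weights must come from the *unshifted* estimate: weighting from the
shifted bias would freeze the early transient kernels at full weight and
permanently overestimate the rare basin's probability (this failure mode
is why the two quantities are kept separate).

**Fill/production protocol.** Each run adapts the bias for the first 48%
of steps, then freezes it; only the frozen-bias production segment is
reweighted (w = e^{+βV}), which makes the reweighting exact for an
equilibrated stationary bias instead of approximate for an evolving one.

**FES estimation.** Production samples are histogrammed (80 × 80 over the
CV ranges).  Basins and the saddle are identified on a Gaussian-smoothed
(σ = 1 bin) surface — smoothing suppresses shot-noise minima and phantom
minimax passes, and bins with zero raw counts stay impassable — while
basin *populations* are computed from the weighted samples themselves
(membership by basin label), which is free of binning and empty-bin loss.
ΔG = −kT log(P_amide/P_imidic); ΔG‡ is the minimax-path saddle (Dijkstra
with max-node cost over the 8-connected bin graph) minus the imidic
minimum on the smoothed surface.  The second basin must be separated from
the first by at least 1 kcal/mol of prominence, which rejects shot-noise
"basins".

**Replica protocol.** Landscape recovery starts each run in the *deeper*
basin — the bias then fills bottom-up and reaches the shallow basin
quickly, instead of dropping into the deep well mid-fill and stalling
there — and reports the median over three independent fill+production
replicas (4 × 10⁶ steps each by default, the problem size chosen for the
recovery studies here); the median is robust against the rare replica
whose bias fails to converge within its fill stage.  With this protocol the three reference cases
(ΔG, ΔG‡) ∈ {(0, 5), (−10, 4.3), (−10, 7)} kcal/mol are recovered within
a few tenths of a kcal/mol.

**TS ensemble.** Configurations within ±kT of the saddle are clustered by
a deterministic PAM k-medoids (greedy 1-medoid + maxmin initialisation,
alternating assignment/update) into k = 10 representatives; no installed
package provides k-medoids, so it is implemented here and tested against
brute-force enumeration.

## Committor model

The committor q(x) is a feed-forward network [N, 32, 32, 1] (tanh hidden
layers, sigmoid output) on distance descriptors: for molecular frames, the
relay-chain heteroatom distances plus every transferable proton's distance
to both fragment heteroatoms (N = 9 with one bridging water, 13 with two);
on the surrogate landscapes the CV coordinates are used directly.

The loss is a variational Kolmogorov functional: the weighted mean of
|∇q|² under the sampled measure (weights e^{+βV} reweight biased samples
to the Boltzmann ensemble) plus α·(boundary penalty) anchoring q to 0/1 on
basin-labelled samples, α = 1.  Subject to the boundary conditions, the
minimiser of ∫e^{−βV}|∇q|² is the exact committor, which is why the
trained model can be validated against the closed-form 1D quadrature
committor q(x) = ∫ₐˣe^{βV}/∫ₐᵇe^{βV}.  Training is full-batch Adam
(lr 1e−3 decayed by 0.9999 per epoch) with a fixed seed; a single training
pass suffices, and no iterative CV-refinement loop is implemented.  The
parameter gradient of the |∇q|² term requires differentiating through the
input-gradient computation; this double-backward pass is derived
analytically (forward-mode tangents, then a reverse sweep through tangent
and primal passes) and verified against finite differences at 1e−7.
Models serialise to JSON (architecture, weights, input scaling).

Two objects derive from the trained model:

- **z(x) = logit(q)**, clipped at q ∈ [1e−4, 1−1e−4], used as a smoother
  OPES CV; its input gradient is zero in the clipped (deep-basin) region.
- **The Kolmogorov (TS-focusing) bias** V_K = −λ·ΔE·[4q(1−q)]², λ = 0.3,
  ΔE = 20 kcal/mol: a 6 kcal/mol well at q = ½ that decays quartically —
  below 1% of its TS value already at q = 0.01 — so basin statistics are
  left essentially untouched while the transition region is sampled
  heavily (≥ 5× enrichment of q ∈ [0.4, 0.6] at matched budgets, and
  faster recrossing accumulation when combined with OPES).

## Synthetic data: what it shows and what it does not

Fixtures place an imidic-acid fragment R–C(=NH)OH with exact-geometry
wires: chain donor-acceptor distances of 2.8 Å solved numerically (with
non-adjacent chain atoms ≥ 3.75 Å apart so no shortcut bonds arise),
donated hydrogens placed on the donor→acceptor segment (angle 180°),
distractor waters ≥ 6 Å away, optional Gaussian coordinate noise
(σ = 0.05 Å in the standard conditions, small against the 0.7 Å distance
margin and 30° angle margin).  Every fixture is certified at build time by
the exhaustive-enumeration check, and generation is bit-reproducible per
seed.  Toy trajectories draw competent/incompetent frames as independent
Bernoulli trials at a controlled fraction p.

These generators make the *detection and statistics machinery* fully
testable: recovering p to binomial accuracy shows the detector is unbiased
on frames whose ground truth is known.  They do not emulate solvent
dynamics, conformational ensembles, or correlated frame-to-frame water
motion, so passing tests say nothing about sampling-quality questions in
real trajectories (residence times, wire lifetimes).  Likewise the
surrogate landscapes validate the sampling estimators, not the chemistry:
the reference barriers of the real system come from QM/MM energetics that
an analytic surface does not contain.

## Numerical conventions and edge cases

- Coordinates in Å, energies in kcal/mol, kB = 0.0019872041 kcal/mol/K.
- Orthorhombic boxes only; minimum image applied only when a box exists.
- Hydrogen-to-heavy bonding is name/order based (most recent preceding
  heavy atom in the residue), never distance based, so role assignment is
  deterministic.
- Boundary conventions: shell counting inclusive (≤), hydrogen-bond
  distance inclusive (≤ 3.5 Å), angle inclusive (≥ 150°).
- Sample SD (n−1) wherever an SD is reported; SD of a single replica is
  reported as 0.
- Degenerate inputs raise: collinear RMSD selections, empty proton sets,
  water residues without 1 O + 2 H, infeasible fixture/surrogate specs,
  diverging trajectories (with the step index), TS windows with fewer
  members than clusters.

## Known limitations

- The OPES implementation is 1-D in the CV (a grid-tabulated bias); the
  FES is always reconstructed in 2-D by reweighting.
- Committor training is full-batch and CPU-bound; it is sized for
  descriptor dimensions ≤ ~13, not for deep architectures.
- Basin/saddle extraction assumes exactly two metastable basins on the
  projected surface.
- PDB support covers ATOM/HETATM/MODEL records with first-altloc
  selection; no chain logic, no insertion codes.
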