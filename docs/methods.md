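# Methods

## Representation and topology

A blunt-ended duplex with leading-strand sequence s₁…s_n (5′→3′) is mapped
to three beads per nucleotide — phosphate (P), sugar (S), base (B) — at the
geometric centers of the corresponding moieties.  Base pairs are indexed
i = 1…n along strand 1; strand 2 is antiparallel, its base at index i being
the Watson–Crick complement of s_i.  Sugars and bases exist for all i,
phosphates for i = 2…n on each strand (each strand's 5′-terminal nucleotide
lacks its 5′ phosphate), so N = 2[(n−1) + n + n] = 6n − 2.  On strand 2 the
phosphate P₂,ᵢ links S₂,ᵢ (5′ side) to S₂,ᵢ₋₁ (3′ side).

### Bonded classes

The bonded network consists of 15 classes.  Their bead tuples, written for a
strand-1 step between base pairs i and i+1 (P* denotes the linking phosphate
P₁,ᵢ₊₁; primes mark the Watson–Crick partner):

| kind | class | beads | context |
|---|---|---|---|
| bond | 5′-SP-3′ | Sᵢ–P* | step (16) |
| bond | 5′-PS-3′ | P*–Sᵢ₊₁ | step (16) |
| bond | 5′-BB-3′ | Bᵢ–Bᵢ₊₁ (stacking) | step (16) |
| bond | SB | Sᵢ–Bᵢ | base (4) |
| bond | BB-WC | Bᵢ–B′ᵢ (pairing) | pair (2) |
| angle | 5′-SPS-3′ | Sᵢ–P*–Sᵢ₊₁ | step (16) |
| angle | 5′-PSP-3′ | Pᵢ–Sᵢ–P* | step (16) |
| angle | 5′-PSB-3′ | P*–Sᵢ₊₁–Bᵢ₊₁ | step (16) |
| angle | 5′-BSP-3′ | Bᵢ–Sᵢ–P* | step (16) |
| angle | SBB | Sᵢ–Bᵢ–B′ᵢ | base (4) |
| dihedral | 5′-SPSP-3′ | Sᵢ–P*–Sᵢ₊₁–Pᵢ₊₂ | step (16) |
| dihedral | 5′-PSPS-3′ | Pᵢ–Sᵢ–P*–Sᵢ₊₁ | step (16) |
| dihedral | 5′-SPSB-3′ | Sᵢ–P*–Sᵢ₊₁–Bᵢ₊₁ | step (16) |
| dihedral | 5′-BSPS-3′ | Bᵢ–Sᵢ–P*–Sᵢ₊₁ | step (16) |
| dihedral | 5′-PSBB-3′ | P*–Sᵢ₊₁–Bᵢ₊₁–B′ᵢ₊₁ | step (16) |

12 step classes × 16 + 2 base classes × 4 + 1 pair class × 2 = **202
distinct parameter entries**.  Strand 2 instantiates the mirror-image tuples
with the step context read along its own 5′→3′ direction (the reverse
complement of the strand-1 step), which makes the term multiset invariant
under relabeling the strands; this invariance is property-tested.  Sugar and
base beads of a term never leave one step; the four-body backbone torsions
(SPSP, PSPS) and the PSP angle additionally touch the junction phosphate of
a neighboring linker, which is unavoidable for alternating S/P four-bead
motifs.  A term is instantiated wherever all its beads exist, which
automatically prunes the classes that need a missing terminal phosphate.

### Energy model and units

Internally the package works in molecular-mechanics "real" units (Å,
kcal/mol, fs, g/mol, e₀); analysis converts to nm, pN, pN·nm, pN·nm².
Bonds and angles are harmonic **without** the ½ prefactor (U = kΔ²,
matching the LAMMPS `harmonic` styles the data-file exporter targets), so
the fluctuation relation is k = k_BT/(2 var).  Dihedrals use
U = k[1 + cos(φ − φ₀)] with φ₀ = φ_min − 180°, whose curvature at the
minimum is k, giving k = k_BT/var.  Excluded volume is WCA with per-bead σ
(arithmetic-mean mixing for unlike beads, ε = 1 kcal/mol); electrostatics is
Debye–Hückel between phosphates with reduced charge q = −0.6 e₀,
ε_r = 78.3, cut off at 5 l_D with the energy shifted to zero there
(truncation error < 10⁻³ relative).  Bead pairs sharing any bonded term are
excluded from both nonbonded interactions.  Constants: k_B = 1.38·10⁻²³ J/K,
N_A = 6.022·10²³ mol⁻¹, e₀ = 1.6·10⁻¹⁹ C, ε₀ = 8.859·10⁻¹² F/m; hence
k_BT(300 K) = 4.14 pN·nm and a Coulomb prefactor of 331 kcal·Å/mol.

Forces are exact negative gradients (finite-difference-verified to 10⁻⁵
relative).  One numerical guard: the analytic torsion gradient diverges when
three of the four beads become collinear; the |b×b′|² denominators are
floored at 10⁻⁴·|b|²|b′|², which caps the force in that measure-zero region
and leaves it untouched elsewhere.

## Toy parameter set

The shipped toy table has the full 202-entry class structure with
equilibrium values *measured on an ideal B-DNA-like helix* (rise 3.4 Å,
twist 34.3°/step, phosphate radius 9.4 Å, sugar radius 7.0 Å, base radius
4.5 Å, base phase ±35°, groove phase 154°), so that helix is the bonded
ground state of the toy model.  The geometry was chosen so that no angle
class sits near 0°/180° (margin ≥ 26°), keeping torsion gradients
well-conditioned at 300 K.  Stiffnesses are idealized: bonds 6, SB 8,
angles 12 (kcal/mol/Å² resp. rad²), dihedrals 1.5 kcal/mol, with a
deterministic ±15% context modulation so sequence dependence is nonzero,
and BB-WC pairing constants 2.0 (AT) vs 3.0 (CG) — the 2:3 ratio of the
hydrogen-bond counts.  The stiffest normal mode of the assembled duplex has
ω ≈ 0.054 fs⁻¹ (period ≈ 116 fs), verified stable under the 20 fs
production step.  The toy set is a *stand-in with the same
schema*, not a transcription of the published tables; quantitative elastic
constants of the toy duplex (stretch modulus ≈ 260 pN, crookedness stiffness
≈ 280 pN from the benchmark-pull analysis) are properties of the toy values
and are reported as such by the acceptance script.

The step library used by the molecular builder is cut from the same ideal
helix (all 16 steps share the geometry), which makes the assembled average
structure an exact ideal helix — the oracle used to test the assembly
algorithm.  Assembly is strictly left-to-right: each next step is
Kabsch-superposed onto the four shared beads of the overlapping base pair,
the shared beads are replaced by the mean of the two aligned sets
(averaging is not associative, so the order is part of the definition), and
the result is translated so the first strand-1 sugar is at the origin and
rotated so the principal axis of the base-pair sugar centers lies along +z.

## Dynamics

Langevin dynamics with the BAOAB splitting: half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh (c₁ = e^{−γΔt}, c₂ = √(1−c₁²)·√(k_BT/m)),
half-drift, half-kick.  Defaults: T = 300 K, damping time 20 ps, Δt = 20 fs.
Bead masses split the nucleotide mass by moiety (P 95, S 115, bases 110–150
g/mol); they affect kinetics only, not the configurational ensemble.  Fixed
seeds give bit-identical trajectories (NumPy PCG64).  Nonbonded pairs come
from a KD-tree neighbor list with a 4 Å skin, rebuilt when any bead moves
half a skin, and are contract-tested against a brute-force pair loop.

BAOAB samples the configurational distribution accurately at the production
step, but the *kinetic* temperature measured from full-step velocities
carries an O((ωΔt)²) bias (≈2–3% at Δt = 20 fs for the toy model's stiffest
modes).  Thermostat checks therefore run at Δt = 5 fs with a 0.2 ps damping
time, where the sampled kinetic temperature is 298–300 K across seeds.

Protocols (all forces re-evaluated every step):

* **benchmark pull** — equal and opposite forces ±f/2 on each sugar of base
  pairs 2 and n−1, along the line joining the two sugar centers;
* **stretch–torsion** — all beads of the two bottom base-pair levels
  tethered harmonically (k = 100 kcal/mol/Å², U = kΔ² convention) to their
  start positions; a +z force on the sugar center of the second pair from
  the top with a harmonic x,y restraint on that center; a torque τ about z
  realized as a tangential force couple on **all beads of the two top
  base-pair levels** (bases, sugars and the phosphates present), with the
  multiplier solved each step so ΣF = 0 and Σr×F = τẑ exactly;
* **twist–bend** — same tether, +z force on the free end, no lateral
  restraint (the molecule may bend);
* **quench** — from the average structure, n short runs at the working
  temperature each followed by a 0 K run with the Debye length *held at its
  working-temperature value*; the lowest-energy final conformation is the
  ground-state estimate.

## Observables

All bead-level surrogates of the standard helical parameters use three
derived point sets: base-pair centers Γᵢ = (B₁,ᵢ+B₂,ᵢ)/2, sugar centers
ξᵢ = (S₁,ᵢ+S₂,ᵢ)/2 and sugar separations ζᵢ = S₂,ᵢ−S₁,ᵢ.

* **Helical axis**: axis of the least-squares cylinder through the
  phosphates (residuals dᵢ − r̄, radius eliminated analytically; initialized
  from the principal component, refined by Levenberg–Marquardt; sign toward
  increasing base-pair index).  Appropriate for fragments short enough that
  a global axis is well defined.
* **h-twist**: signed angle between successive ζ projected perpendicular to
  the axis, sign from (ζᵢʳ × ζᵢ₊₁ʳ)·ĥ; **h-rise**: (ξᵢ₊₁−ξᵢ)·ĥ.  On the
  ideal-helix fixture both reproduce the generator inputs to 10⁻⁹.
* **force-axis twist** ψ: the same construction against the fixed lab z
  axis; θ = Σψ is the torsion angle used by the stretch–torsion analysis.
* **crookedness**: β = arccos(|Γ_n−Γ₁| / Σ|Γᵢ₊₁−Γᵢ|) — 0 for a straight
  center line, increasing with spontaneous or thermal bending.
* **grooves**: each strand's phosphates interpolated by centripetal
  Catmull–Rom splines (terminal control points extrapolated by applying the
  terminal step's h-rise/h-twist to the end phosphate).  For base pair i,
  from the arc-length midpoint M₂,ᵢ of the complementary strand the spline
  is walked both ways (step 10⁻³ of a segment, golden-section refinement;
  a walk that immediately increases the distance accepts its start point)
  until the distance to M₁,ᵢ first reaches a local minimum; widths are the
  two minimal distances − 0.58 nm (backbone van der Waals), depths the
  distance of the width-vector midpoints from Γᵢ − 0.35 nm.  The two walk
  directions are mapped to minor/major by handedness (sign of the mean
  h-twist); distances are isometry-invariant, so on a mirror-image frame
  the labels exchange, which is the tested behavior.
* **SBBS dihedral**: the torsion S₁ᵢ–B₁ᵢ–B₂ᵢ–S₂ᵢ, an emergent per-pair
  conformational feature.
* **supercoiling density** σ = Δθ/θ₀ and **helical pitch** =
  n_steps/(Σh-twist/360°), in bp per turn.

Lengths are reported in the unit of the input coordinates except groove
geometry (nm, because its van der Waals offsets are fixed physical
lengths); angles are degrees in outputs, radians internally.

## Elasticity inference

Linear fits use ordinary least squares for the central values and
Monte-Carlo error propagation (default 10⁴ seeded Gaussian resamplings of
the y-values, matching the closed-form weighted-least-squares σ on linear
problems).  The benchmark route neglects the twist–stretch coupling term in
the equipartition relation — a documented systematic, conventional for this
analysis.  The stretch–torsion route inverts A1 = L₀/S̃, A3 = −gL₀/(CS̃),
A4 = (L₀/C)(1+g²/(CS̃)) in closed form: S̃ = L₀/A1, C = L₀/(A4 − A3²/A1),
g = −A3S̃/(A4 − A3²/A1); A4 − A3²/A1 ≤ 0 is rejected as an inconsistent
(unstable-rod) input.  Force fits for stretch–torsion constants default to
the f ≥ 10 pN points to avoid bending contamination; benchmark fits use all
forces.  Crookedness stiffness comes from cos β = cos β₀ (1 + f/k_β).

Persistence lengths: tangents t̂ᵢ = R_{i−5,i+5}/|R_{i−5,i+5}| on sugar
centers (half-window 5; alternative definitions are a parameter), contour
spacing l = mean per-step distance between application points (ensemble
mean).  c_p averages t̂ᵢ·t̂ᵢ₊ₖ over frames and i; c_s is the same on the
minimum-energy structure; c_d = c_p/c_s.  Decay lengths are log-linear fits
with free amplitude (the amplitude absorbs the window-averaging offset),
restricted to separations where both c_p and c_s exceed 0.3 (below that the
sampling noise floor dominates the decay) — the *same* range for all
three, which makes
1/l_p = 1/l_s + 1/l_d an exact identity of the fit.  A non-decaying
correlation reports l = ∞ with a flag.  On discrete worm-like-chain
ensembles with known l_p ∈ {25, 50, 100} nm the estimator is unbiased
within 3% at 10⁴ chains.

## Fixture generators

* **ideal helix** — deterministic double-helical bead placement with exact
  h-rise, h-twist, cylinder radius and groove phase; `mirror=True` gives
  the left-handed reflection.
* **WLC ensemble** — chains whose successive tangents rotate by the fixed
  polar angle arccos(e^{−l/l_p}) with uniform azimuth, so the tangent
  correlation is exactly exponential.
* **rod response** — extension/twist tables from the elastic-rod
  equilibrium with optional Gaussian noise; ground truth stored in the
  table's metadata.

All generators are deterministic given parameters and seed.

## Test and acceptance problem sizes

Simulation-based checks run at desk scale by design: 12–28 bp toy duplexes
for 0.01–0.6 ns, 400 independent harmonic bonds for the Boltzmann χ²
statistics (~10⁵ near-independent samples), 2·10³–10⁴ worm-like chains of
120 segments.  These sizes put statistical tolerances (2–3% for fluctuation
estimators, 2% for the kinetic temperature) at ≥3 standard errors.
Reproducing literature-scale elastic constants and persistence lengths for
real DNA additionally requires the published parameter tables and
hundreds-of-nanosecond replica ensembles, which is outside the scope of the
shipped toy set.

## Known limitations

No melting, nicks, mismatches, overhangs or single-stranded regions — the
bonded topology is fixed.  No explicit ions, ion–ion correlations or
solvation.  No base-fixed reference frames: helical parameters are
bead-level surrogates, not the full rigid-base-pair set.  No writhe; the
supercoiling density assumes negligible bending.  The global cylinder axis
is unsuitable for molecules much longer than a persistence length; the
force-axis twist is provided for tethered geometries.
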