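# duplexcg

A sequence-dependent, three-bead-per-nucleotide coarse-grained model of
double-stranded DNA, with a molecular builder, a Langevin dynamics engine
implementing single-molecule force/torque protocols, and an analysis suite
for helical geometry and elasticity.

## Who this is for

Researchers who want to simulate the mechanical response of duplex DNA —
stretching, twisting, bending, their couplings — at scales where atomistic
simulation is too expensive, and to analyze such simulations with the
standard observables of single-molecule biophysics: helical twist and rise,
groove geometry, crookedness, stretch modulus *S̃*, twist modulus *C*,
twist–stretch coupling *g*, and the static/dynamic decomposition of the
persistence length.

## The model

Each nucleotide is reduced to three beads at the geometric centers of its
phosphate group (P), sugar (S) and base (B); a duplex of *n* base pairs has
*N* = 6*n* − 2 beads (the 5′-terminal nucleotide of each strand has no
phosphate).  The double-stranded architecture is held by a fixed network of
bonded interactions:

* bonds   U(r) = k (r − r₀)²
* angles  U(θ) = k (θ − θ₀)²
* dihedrals U(φ) = k [1 + cos(φ − φ₀)],  φ₀ = φ_min − 180°

Sequence dependence enters through the parameters: classes tagged 5′/3′
(e.g. the stacking bond 5′-BB-3′, the backbone torsion 5′-SPSP-3′) take one
of 16 values according to the dinucleotide step, classes symmetric along the
backbone (SB, SBB) take one of 4 values by base, and the Watson–Crick
pairing bond BB-WC takes one of 2 values by pair — 202 distinct bonded
entries in total.  Beads repel through a WCA (truncated-shifted
Lennard-Jones) potential, and phosphates carry a reduced charge
*q* = −0.6 e₀ interacting through a Debye–Hückel potential whose screening
length is set by temperature and ionic strength (0.79 nm at 300 K, 150 mM).

Because the published force-field tables are distributed separately, the
package ships a *toy* parameter set with the same class structure and
idealized B-DNA values (generated, not transcribed), so that every code path
— building, simulation, analysis — runs self-contained.  Any table in the
documented CSV/JSON schema `(kind, class_label, context, stiffness,
equilibrium)` can be loaded in its place.

Elastic constants are inferred from simulated ensembles through the linear
elastic rod: under force *f* and torque *τ*,

    ΔL = (L₀/S̃) f − (g L₀/(C S̃)) τ
    Δθ = −(g L₀/(C S̃)) f + (L₀/C)(1 + g²/(C S̃)) τ,   S̃ ≡ S − g²/C,

inverted either from force-only data plus the equipartition relation
var(Δθ) = k_B T L₀ / C, or from the three slopes of a stretch–torsion
experiment.  *g* < 0 (extension grows with applied torque, twist grows with
force) means the duplex overwinds when stretched.

## Worked example

Build a 13-bp duplex and write its LAMMPS data file and topology manifest:

```
$ duplexcg build --seq CGCTACTTCGAGG --out demo
built CGCTACTTCGAGG (13 bp, 76 beads) -> demo.data
```

76 beads is 6·13 − 2: three beads per nucleotide on both strands, minus the
two missing terminal phosphates.  Generate a synthetic stretch–torsion data
set from the elastic rod with known constants and invert it:

```
$ duplexcg fixtures --kind rod_response --out rod.csv
$ duplexcg analyze-elastic --data rod.csv --out el.json
{
 "S_eff_pN": 999.9999999999947,
 "C_pN_nm2": 399.99999999999915,
 "g_pN_nm": -100.00000000000021,
 "L0_nm": 13.0,
 ...
}
```

The fixture stored S̃ = 1000 pN, C = 400 pN nm², g = −100 pN nm; the
analysis recovers them to machine precision from the three response slopes
(A1 = 0.013 nm/pN, A3 = 3.25·10⁻³ nm/(pN nm), A4 = 0.0333 rad/(pN nm)).
The negative g means this synthetic duplex overwinds under tension, the
experimentally observed sign for B-DNA.

Run a short Langevin simulation and analyze its persistence length:

```
$ duplexcg simulate --config run.yaml          # protocol: free | pull |
                                               # stretch-torsion | twist-bend | quench
$ duplexcg analyze-persistence --traj run.h5 --seq <sequence> --out pers.json
```

## Scope and limits

The model fixes the duplex topology by construction: no melting, strand
separation, kinks, nicks, mismatches or single-stranded regions.
Electrostatics is implicit-solvent Debye–Hückel with reduced charges — no
explicit ions or ion–ion correlations.  See `docs/methods.md` for the full
model description, parameter conventions and numerical choices.
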