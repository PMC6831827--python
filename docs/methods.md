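# Methods

## The system and the model

The N-terminal region of the motor adaptors JIP3/JIP4 is a constitutive
dimer built from an RH1 (RILP-homology-1) four-helix-bundle domain
followed by the LZI leucine-zipper coiled coil. The package models the
JIP3 expression construct (Gly-Ser-His tag remnant + residues 22–187,
two chains, 169 residues each) as idealized secondary-structure geometry:

- **LZI coiled coil (74–187).** Crick parameterization: each Cα sits on a
  minor helix of radius 2.26 Å wound on a left-handed superhelix of
  radius 4.9 Å and pitch 190 Å, axial rise 1.485 Å/residue; the second
  chain is the first rotated 180° about the superhelical (z) axis. The
  minor-helix phase advances at exactly two turns per heptad *in the
  rotating superhelical frame* (3.5 residues/turn there, ≈3.56 in the
  laboratory frame), which keeps the hydrophobic a/d seam facing the
  partner chain over the full 14 heptads; the phase origin puts heptad
  position *a* at +26° from the inward normal. The helical hinge (74–77)
  and the C-terminal helical continuation (181–187) are part of the same
  coil. Consecutive Cα–Cα distances are 3.8 ± 0.1 Å and inter-chain core
  distances at a/d positions fall in the knobs-into-holes range
  (5.0–7.5 Å).
- **RH1 bundle (26–73).** Four ideal α-helices (rise 1.5 Å/residue, 3.6
  residues/turn, radius 2.3 Å) on the corners of a 10.5 Å square, each
  protomer an antiparallel α1 (26–43)/α2 (50–73) hairpin closed by a
  six-residue coil arc (44–49) whose depth is solved so consecutive
  spacings stay backbone-like; the α2 helix phase is chosen so residue 73
  points inward, where it must meet residue 74 of the coil.
- **Docking.** The bundle+N-terminus block is rotated about z and shifted
  axially so the 73→74 virtual bond is 3.8 Å and the blocks keep ≥2.5 Å
  clearance. Both blocks are two-fold symmetric about z, so the assembly
  is exactly C2-symmetric (chain A/B RMSD < 10⁻¹⁰ Å).

Only Cα centers are built. Backbone N/C/O placement was deliberately
dropped: every downstream consumer (scattering weights, beads,
refinement moves) works per residue, and idealized carbonyl placement
would only add clash-geometry bookkeeping. The resulting model is a
~214 Å rod, ~19 Å across, with a ~43 Å bundle head — consistent with the
published 210 Å × 20 Å description within the idealization error the
acceptance bands allow.

The α1–α2 loop length (6 residues) follows the annotation; a possible
helix kink at Pro57 is *not* modelled — the idealized α2 is straight, and
the question is flagged as open rather than guessed.

## Sequence fixtures

The packaged FASTA is a **synthetic stand-in** for the JIP3/JIP4
N-terminal sequences (the accessions are recorded in the headers). It is
constructed to satisfy every constraint the source study states in text
and tables: lengths 187/182; RH1 [22–73]/[17–68] with exactly 44/52
(84.6%) ungapped identity; all named hydrophobic interface residues at
their stated positions (V24 … L70, Pro57 included); hinge 72-ENQEHE-77;
acidic D48/E49 and E81/E85/E88; no Gly/Pro anywhere in the LZI; heptad
a/d positions ≥96% hydrophobic; and GSH-tagged construct masses of
20.3 kDa (22–187) and 14.8 kDa (71–187) by average-mass summation. A
mouse variant with the single Lys→Arg difference is included. Conclusions
that depend on the *true* residue order at unconstrained positions (e.g.
real surface electrostatics) are outside what these fixtures can support.

## Scattering model

One scattering center per residue at the Cα, weighted by the average
residue mass and modulated by a dummy-sphere form factor of radius
3.26 Å (the mean residue volume ~145 Å³ at 0.83 Da/Å³). The Debye sum is
histogram-accelerated (0.25 Å bins with the weight-averaged distance per
bin, ≤0.1% from the exact double sum, which is retained as the test
oracle). An optional residue-centroid offset (Cα displaced outward from
the local chain axis) is available for cross-section studies but is off
by default: it fattens the apparent cross-section at the cost of
hollowing it, which inflates the Porod volume by ~70% and breaks the mass
estimate, whereas the granular Cα trace — like real atomic detail —
keeps the invariant right.

Known, accepted coarse-grain limitations (all documented by tests):

- the model cross-section is thinner than the real protein's, so the
  dimensionless Kratky peak of the model curve sits later/higher
  (~9.2 qRg, ~5.4) than measured for the real tandem (7.4, 4.1), and
  shape-sensitive P(r) detail is approximate;
- Guinier fits on this strongly elongated particle are biased low by
  3–4% when the window reaches qRg ≈ 1 (the textbook rod bias, which
  also explains why the measured Guinier Rg of the real protein sits
  below its P(r) Rg); recovery to 2% needs windows within qRg ≲ 0.7
  starting from genuinely low q.

**Guinier.** Weighted linear regression of ln I on q²; automatic window
from the lowest measured q extended while qRg ≤ 1.3 (configurable),
iterated to convergence (0.1 Å tolerance, ≤20 iterations).

**Indirect Fourier transform.** P(r) on 101 points in [0, Dmax], p ≥ 0,
p(0)=p(Dmax)=0, minimizing χ² + α‖p″‖² by non-negative least squares; α
from a 13-point logarithmic sweep, choosing the *largest* α whose χ² is
within 10% of the sweep minimum (the smoothest acceptable solution). The
r→0 bins absorb the constant self-term of the granular Debye sum and are
excluded from shape comparisons.

**Porod mass.** Q = ∫₀^{q_m} q²I dq with Guinier extrapolation below the
first measured point, q_m = 0.5 Å⁻¹; V′ = 2π² I₀/Q; mass =
0.83 × 10⁻³ kDa/Å³ × (A + B·V′) with correction coefficients (A, B)
defaulting to identity — at this q_m the truncation error on the rod-like
model curve is within the 10% band, and published empirical coefficients
are instrument/ensemble calibrations not reproducible offline. Truncation
inflates V′ by ~10% for *small* compact particles (R ≈ 20 Å spheres);
the sphere check is therefore stated for protein-scale spheres (R ≥
40 Å).

## Hydrodynamics

One bead per residue at the Cα. Rg uses the 3.8 + 1.1 Å (bead +
hydration) radius and the mass-weighted second moment with the (3/5)a²
per-bead term. For Rh, the classical Kirkwood double sum is provided but
is *not* the predictor: for a slender, densely discretized rod it
underestimates Rh badly (~3.4 nm here; the inverse-distance sum is
dominated by intra-chain near neighbours, and the formula assumes
non-overlapping beads). The predictor is rigid-body friction from the
Rotne–Prager–Yamakawa pairwise mobility tensor (overlap-corrected below
contact): the 3N×3N supermatrix is inverted, bead forces for unit rigid
translations along x, y, z are summed, and the direction-averaged
friction gives 6πηRh. Bead radius 6.1 Å — the published residue-level
(one-bead-per-Cα) hydrodynamic calibration of the Hydropro family —
chosen a priori, not fitted. This yields Rh ≈ 4.2 nm for the model
(measured for the real construct: 4.1 ± 0.3 nm by QELS; predicted by
atomic-shell Hydropro: 4.4 nm).

s and f/f₀ follow analytically with v̄ = 0.73 mL/g (fixed, not computed
from composition) and water at 20 °C (η = 1.002 mPa·s, ρ = 0.9982 g/mL),
giving s ≈ 2.3 S and f/f₀ ≈ 1.9.

## Synthetic SEC-SAXS data

Linear grid of 500 points over q = 0.008–0.5 Å⁻¹ (the SWING-type
geometry; an energy/distance → q conversion is provided, the defaults are
the stated bounds). Noise is Gaussian and uncorrelated with
counting-statistics shape, σ(q) = k√I + 0.01·I, k set so I/σ = 100 at
the first point — representative of well-merged synchrotron SEC-SAXS.
What the generator does *not* emulate: inter-point correlation, beam
smearing, buffer-subtraction artefacts, concentration effects. Passing
tests on these curves therefore validate the mathematics and the
pipeline, not detector physics.

## Refinement and ensembles

A conformer is six joint parameters relative to the start: a hinge bend
vector (the whole RH1 block, both chains, rotates about a pivot at the
top of the flexible window 67–77, the rotation slerp-blended from 1 to 0
across the window so the chain stays connected) and mirrored per-chain
N-terminal and C-terminal bend vectors (which preserve the dimer dyad
exactly; the collective hinge bend, like any real bend of an inter-chain
domain, breaks global C2 by construction). Clash-free conformers require
≥2.5 Å between the rigid blocks.

Refinement is an elitist (top 25%) evolutionary search, population 24 ×
60 generations by default, Gaussian mutation 10°, χ² with the scale
refit at every evaluation, 5 independently seeded runs; ties on χ² break
toward smaller Rg deviation from the start, then run order. Everything is
bit-reproducible given the seed.

**Conformational discriminability — an important negative result.** A
20° hinge bend changes the model's curve by at most 0.4% (relative).
Under the default noise (1% floor) this is invisible: χ² between the
straight model and data simulated from a 20°-bent decoy is ≈0.94, and no
refinement can reduce an already-unity χ² two-fold. This is physics, not
implementation: the bend moves a third of the mass by ~10 Å in a 214 Å
particle. Bends become resolvable at this noise only beyond ~75°; the
recovery demonstrations therefore use a 60° decoy at a quieter noise
setting (σ/I ≈ 0.02–0.3%), where the search recovers the generating
angle to a degree and reduces χ² ~100-fold. The corresponding acceptance
check at the default study conditions is expected to fail and is left
failing rather than weakened.

The ensemble branch generates a pool of hinge-only conformers (default
1000, scaled down from the study-scale 10,000; a flag restores full
scale) and selects multisets of 20 pool members (multiplicity = weight)
by a genetic algorithm (population 30, 20 cycles scaled-down / 100 at
full scale, 5 runs). Even near the noise floor the selection responds to
extended-biased data with a mean-Rg shift above the pool mean,
reproducibly across runs — the directional signature, not the magnitude,
is the supported conclusion.

## Scale choices

Default problem sizes (pool 1000, 5×20 GA cycles, 500-point curves,
population 24 × 60 generations) run the full pipeline in a few minutes on
one CPU; tests use further-reduced settings. All defaults are exposed in
`RefinementSettings`, `FlexibilityMask`, `InstrumentSetup`, `NoiseModel`
and `RunConfig`, and the single pipeline seed fans out to fixed per-stage
offsets so each stage is independently reproducible.
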