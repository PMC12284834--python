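# Methods

## Scope and data model

`coilspect` analyzes coiled-coil bundles of 2–4 α-helices.  All analysis
operates on a minimal chain/residue/atom model keyed by *author* residue
numbering (so residue names like K172 mean the same thing in input files,
crosslink tables and reports).  PDB and mmCIF parsing and PDB writing go
through gemmi; insertion codes and altlocs are rejected rather than
resolved, only the first model of a multi-model file is read, and PDB
output carries coordinates at the format's 3-decimal precision.  These
restrictions keep the residue coordinate system unambiguous; the synthetic
generator never produces the rejected features.

## Synthetic bundles (what the generator emulates, and what not)

The generator builds ideal bundles from the Crick parameterization (see
README for the equations).  Defaults are the canonical heptad coiled coil:
helix radius r₁ = 2.26 Å, rise per residue 1.51 Å, 3.5 residues per turn
in the supercoil frame, left-handed supercoil.  `CrickParams.silk_tetramer()`
fixes the study conditions used throughout the tests: superhelical radius
5.8 Å, pitch 153 Å, 168 residues per chain (24 heptads), orientations
U/D/U/D at azimuths 0/90/180/270°, zero stagger unless requested.

Construction choices:

* **Common supercoil field.**  `phase0` is defined as a chain's azimuthal
  offset in the shared field θ(z) = (ω₀/d·cosα)·z + phase0.  Antiparallel
  (D) chains are built as U chains and rigidly rotated 180° about an axis
  perpendicular to the supercoil axis — which preserves α-helix chirality
  and supercoil handedness — and their build azimuth is pre-compensated so
  the flipped chain lands at its `phase0`.  Axial stagger is applied as a
  screw displacement (translation plus the matching supercoil rotation).
  Without these compensations the four helices do not mesh into a square
  cross-section.
* **Register threading.**  Unless `phase1` is given, each chain's
  minor-helix phase is set so the threaded register's a/d pair straddles
  the inward direction (the a-position residue at minor-helix phase
  205.7°, from ω₁ = 2π/3.5).  This makes register recovery a genuine
  round trip rather than a tautology: the fitter scores all seven cyclic
  offsets against the measured Crick phases.
* **Pseudo-atoms.**  A CB is placed 1.53 Å from each CA along the outward
  radial from the local helix axis — purely radial, without the small
  tetrahedral tilt of real side chains.  Lys/Arg/Asp/Glu additionally get
  a single charged-group atom (NZ/NH1/OD1/OE1) at 5.0/5.5/2.5/3.2 Å along
  the same direction.  This suffices for packing topology and distance
  anchoring but does not emulate rotamers; consequences below.
* **Default sequences** are seeded "silk-like" draws: alanine-dominated
  pools at a/d/e/g, charged/polar pools at b/c/f.  This reproduces the
  composition signature (a/d/e/g most alanine-rich and hydrophobic) but
  not the real proteins' sequences.
* **Noise** is isotropic per-atom Gaussian displacement with a seeded
  generator; crosslink tables are sampled without replacement from the
  true/violating pair pools at an exact decoy fraction; melts follow the
  two-state model with linear baselines (defaults: folded −28000 + 40·T,
  unfolded −6000 + 10·T mean-residue-ellipticity units, 30–80 °C at 1 °C,
  matching a 222 nm melt protocol); CD spectra are sums of Gaussian bands
  at 209/222 nm (negative) and 192 nm (positive) whose 222-band depth is
  solved exactly for the requested 222/209 ratio.  The CD bands are
  phenomenological — only ratios and additivity are meaningful, never
  absolute band shapes.

Passing tests on these synthetics demonstrates correctness of the
measurement machinery on ideal and mildly noisy geometry.  They do not
demonstrate robustness to real structural irregularity: bent or locally
frayed coiled coils, heterogeneous registers with stutters/stammers,
missing atoms, or real side-chain packing.

## Geometry fitting

Local helix axes use sliding window-of-7 CA centroids (TWISTER-style):
exact on-axis for 3.5 residues/turn, robust to noise, at the cost of three
unsampled residues per chain end.  The bundle axis is the first principal
direction of all axis points, signed so chain 1 runs N→C positive.

* **Radius.**  The mean perpendicular distance of window-7 centroids
  underestimates R₀ by the chord-averaging factor
  sin(7ω₀/2)/(7·sin(ω₀/2)) — about 0.75% at the silk dimensions and 1.4%
  at the tightest supercoils in the tested parameter range.  The fitter
  measures ω₀ from its own azimuth regression and divides the bias out,
  making radius recovery essentially exact on ideal builds.
* **Pitch and handedness** come from the per-chain unwrapped azimuth
  versus axial coordinate regression: P = 2π/|slope|, averaged over
  chains weighted by point count; slope < 0 in a right-handed frame means
  a left-handed supercoil.  |slope| below 2π/2000 Å⁻¹ (pitch > 2000 Å) is
  reported as "none".  Fits spanning under two supercoil turns are
  flagged low-confidence (the 24-heptad silk rod itself spans ~1.5 turns;
  the flag is informational, not an error).
* **Conventions.**  "Clockwise" arrangement is judged looking from the
  positive axis end; U/D labels are relative to the chain-1-signed axis.
  Two consequences are intentional: if chain 1 of a bundle runs "down" in
  some external frame, all labels flip as a block; and mirroring a
  structure flips the measured handedness while preserving the U/D
  pattern relative to chain 1.
* **Register.**  Crick phase is the signed angle, in the plane normal to
  the local tangent, between the inward direction (axis point → supercoil
  axis) and the CA offset.  The register is the cyclic a–g labeling, out
  of the seven possible offsets, that maximizes mean cos(phase) over its
  a/d residues (ties to the smallest offset), extended periodically over
  the whole chain including the window-truncated ends — so a 168-residue
  chain threaded from *a* counts 24 complete heptads.  Register is
  assigned per chain; cross-chain consistency is observable in the output
  but not enforced.  The rod extent and heptad count are reported
  independently; no relation between them is asserted.

## Packing

Side-chain centers are means of non-backbone heavy atoms (a lone CB
counts; glycines are skipped).  A knob is a residue with ≥4 side-chain
centers of one other chain within 7 Å of its own center; the four nearest
form the hole.  This is a deliberate simplification of SOCKET's four-atom
packing criterion; complementarity typing (parallel/perpendicular knobs)
is out of scope.  On ideal alanine-like builds at the silk radius,
adjacent helix axes sit only ~8.2 Å apart, so core-adjacent e/g centers
also qualify as knobs alongside a/d; b/c/f never do.  The alternating-
layer report therefore considers core (a/d) knobs: contacts are grouped
into layers wherever the axial gap exceeds 2.5 Å (chosen between the
within-layer spread of merged a- or d-layers and the ~4.4 Å a↔d layer
spacing), and strict a/d alternation is reported.

Salt bridges pair Lys NZ and Arg NH1/NH2/NE against Asp OD1/OD2 and
Glu OE1/OE2 at a minimum charged-heavy-atom distance of 4.0 Å (common
literature convention).  Histidine is excluded from the basic set.
Intra-chain bridges are computed but separable by scope.  Position classes
join the two register letters, basic first ("c-c", "g-c", "b-b", …).

## Crosslink restraints

Records are CSV rows (chain_a,res_a,chain_b,res_b[,count]); duplicates of
the same unordered residue pair merge with summed observation counts.
Distance anchors: NZ–NZ when both residues are lysines with NZ present,
otherwise CA–CA; a link to a chain's first residue anchors at its backbone
N when present.  Published crosslink validations rarely state their anchor
atoms, so results at this rule may differ marginally from any particular
study's mapping.  Satisfaction is a strict `distance < cutoff`
(default 30 Å, the accepted reach of BS3-class linkers); the surface flag
requires both registers in {b, c, e, f, g}.  Unresolvable residues produce
per-record error entries without aborting the run.

## CD and melts

The 222/209 ratio uses linear interpolation to exactly 222 and 209 nm and
requires both ellipticities negative; the coiled-coil call is ratio > 0.9.
(Some reports quote the second minimum at 220 nm; 222/209 is fixed here,
in line with the common 222/208–209 convention.)  Mixture simulation
weights mean residue ellipticity by molar fraction — the equal-
concentration assumption of mixing equal mg/mL stocks of similar-size
proteins — with a mass-weighting toggle that converts through molar
masses.

Melt fitting is multi-start nonlinear least squares (Tm initialized every
5 °C across the measured range, width started at 3 °C, baselines from the
first/last fifth of the curve; bounds keep Tm inside the measured range
and width in [0.05, 60] °C).  A fit whose transition amplitude at Tm is
below twice the residual standard deviation reports "no transition"
(Tm = NaN).  Cooperativity is an operational definition: R² ≥ 0.98 and
fitted width < 15 °C.  A superposition of two well-separated two-state
transitions fails the R² criterion and is correctly called
non-cooperative.

## Assembly

The strong-binding limit is used because the observed complexation is
essentially complete on gels and SEC and no binding constants are
available; `assemble` exposes a per-step dissociation-constant hook that
deliberately raises until an equilibrium model is parameterized.  SEC
profiles are sums of Gaussian peaks with areas proportional to amount ×
subunit count (toggleable); the default calibration carries only the
species with measured elution volumes (tetramer 8.71, F2·F4 dimer 9.75,
F1 10.12, F2 10.34, F3 11.22, F4 11.31 mL on a Superdex200 10/300) — the
trimer has no measured volume, so predicting a trimer-containing mix
requires a user-supplied entry.  Higher-order aggregates outside the
four-state pathway are not modeled.

## Problem sizes and determinism

Tests and the acceptance script run on 168-residue 4-chain bundles
(the full 24-heptad rod), 50-draw random-parameter round trips over
R₀ ∈ [4, 9] Å, pitch ∈ [100, 250] Å, n_res ∈ [35, 175], 51-point melt
curves with three seeds per midpoint, and 1000-draw mass-balance sweeps —
seconds each on one CPU.  Every stochastic step takes an explicit seed;
reruns of the pipeline with the same config are byte-identical.

## Known limitations

* Purely radial CB/charged-atom placement: no rotamers, no tetrahedral
  tilt; KIH and salt-bridge results on synthetics reflect topology, not
  atomic packing energetics.
* No global Crick-parameter refinement (SamCC-style), no bent/fragmented
  coiled-coil segmentation, no sequence-based coiled-coil prediction.
* Single-register assignment per chain: heptad stutters/stammers within a
  chain are not segmented.
* The equilibrium assembly model is a stub; only the infinite-affinity
  limit is implemented.
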