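# Methods

## Model

`bwsme` implements a block-resolved Wako–Saitô–Muñoz–Eaton (WSME) model:
an Ising-like, native-centric description of protein folding in which every
folding unit is either natively folded or disordered, and only interactions
present in the native structure contribute. Blocks of up to `block_size`
consecutive residues (default 4) form the units; block boundaries never
cross a secondary-structure element, so short trailing blocks occur at
element ends rather than merged across them.

The ensemble comprises all block configurations with at most two folded
islands. Two-island configurations enter twice: once with the islands
non-interacting (DSA), and once with their native inter-island contacts
active (DSAw/L). In the DSAw/L case the residues of the intervening loop
are also conformationally fixed and pay their full per-residue entropy,
while their own native contacts remain off; the stability of such states is
therefore a genuine balance between the inter-island stabilization gained
and the loop entropy spent. (Without the loop-entropy cost DSAw/L would
strictly dominate DSA whenever any inter-island contact exists and the
distinction would be vacuous.) The fully unfolded configuration is the
reference state with ΔG = 0 and weight 1; it is counted explicitly, so the
ensemble size is `1 + C(Nb+1,2) + 2·C(Nb+1,4)`.

### Energy function

For a microstate, a residue pair is *active* when both residues lie in
folded islands and — for DSA states — in the same island. The microstate
free energy is ΔG = ΔG_stab − T·ΔS_conf with three stabilizing terms summed
over active pairs:

| term | form | parameter (default) |
|---|---|---|
| van der Waals | `n_ij · ξ` | ξ calibrated; −48.9 J mol⁻¹ per contact as the uncalibrated default |
| solvation | `n_ij · ΔC_p^cont · [(T−T_ref) − T ln(T/T_ref)]` | ΔC_p^cont = −0.36 J mol⁻¹ K⁻¹ per contact, T_ref = 385 K |
| electrostatics | `N_A q_i q_j e² exp(−κ r_ij) / (4π ε₀ ε r_ij)` | ε = 4, ionic strength 0.1 M, no distance cutoff |

and per-residue entropies ΔS: −10 J mol⁻¹ K⁻¹ per fixed residue, an extra
−6.1 J mol⁻¹ K⁻¹ for residues labelled coil, and 0 total for proline.
`n_ij` counts heavy-atom pairs within 5 Å between residues i and j
(|i−j| = 1 included, intra-residue excluded). Contacts are **atom-pair
counts**, not a residue-level binary: both ξ and ΔC_p^cont are defined per
native contact and should scale with packing density. The Debye screening
length κ(T) is computed from the ionic strength, the dielectric constant
and T; the same low dielectric applies everywhere (a single-ε stand-in for
the membrane environment — no dielectric gradients). The electrostatic
activation rule mirrors the van der Waals rule, which keeps DSA and DSAw/L
distinguishable under one convention.

T_ref for the solvation term and the Henderson–Hasselbalch pKa table are
package choices exposed as parameters; charge assignment defaults to fixed
integer charges at pH 7 (Asp/Glu −1, Lys/Arg +1, His 0, termini ±1) with a
fractional `henderson` mode available. Charge sites sit at the charged-group
centroid with Cβ/Cα fallback. Disulfides are not modelled (chains are
treated as reduced).

### Observables

Partial partition functions over the number of structured blocks give the
1D free-energy profile; binning over N-/C-half block counts gives the 2D
landscape (default split: the block containing the residue midpoint;
configurable to a TM3/TM4-style boundary). Residue folding probabilities,
logit stabilities, element stabilities (average probability **before** the
logit), conditional N/C-half probabilities at a chosen reaction-coordinate
fraction (nearest integer bin; nearest non-empty bin if needed), and the
ΔG₊/ΔG₋/ΔG_c coupling matrices all derive from the weighted ensemble.
Residues sharing a block are perfectly correlated by construction and their
couplings are reported as missing rather than infinite. Z-scoring of mean
couplings is per protein; f_c is the fraction with Z > 1.

Intermediate counting on a 1D profile: strict local minima are found, the
lowest- and highest-RC basins are labelled unfolded/folded and excluded,
and any interior minimum whose smaller separating barrier is below
`threshold·RT` (default 1 RT) is merged into the deeper adjacent basin —
smallest barrier first, ties to the shallower minimum — until all survivors
pass. The count is invariant to additive shifts of the profile.

### Calibration

ξ is the single adjustable scale. `calibrate_xi` brackets and bisects ξ in
[−200, −1] J mol⁻¹ until the heat-capacity peak — computed from ln Z by
centered finite differences on a 1 K grid and localized with 3-point
parabolic refinement — sits within 0.5 K of the 333 K target (the mean
melting temperature of mesophilic proteins). When the curve is bimodal the
trough between the two most prominent peaks is placed at the target
instead. For active/inactive structure pairs, `calibrate_isostable_pair`
calibrates the inactive structure to the Tm target and then solves
ξ_active so that the folded–unfolded free-energy difference at 310 K
matches the inactive value within 0.1 kJ mol⁻¹; the folded/unfolded split
is taken at the highest interior barrier of the 1D profile, and profiles
that are barrierless at a trial ξ are classified by their dominant basin so
the bisection remains well posed. Identical inputs recover identical ξ.

### Alanine scanning

A mutation is modelled as side-chain truncation past Cβ on the wild-type
coordinates: the contact map is recomputed with the site's atoms beyond Cβ
removed and the site's side-chain charge dropped; terminal charges,
entropies and every parameter stay at wild-type values. This is a
deterministic approximation to rebuilding the mutant side chain with a
modelling tool — it can only remove contacts, never gain the few a rebuilt
methyl might make. Only ΔG₊ is differenced (it reports on states harboring
coupled residues in the native ensemble); ⟨ΔΔG₊⟩ is the row mean over the
partner dimension, missing entries skipped. The wild-type matrix is
computed once: scanning m sites costs exactly m + 1 ensemble evaluations.
Default sites exclude alanine, glycine and proline. Note that responses far
from a mutated site are damped but not zero even for contact-disconnected
regions: the at-most-two-islands constraint correlates folding along the
chain topologically.

## Numerical implementation

State enumeration is index-based: single islands come from the upper
triangle of an Nb×Nb grid and two-island configurations from the bijection
with 4-subsets of {0..Nb}. Per-state free energies factorize into
temperature-independent features — active contact count, fixed entropy, and
0/1 activity flags for each block pair carrying charges — evaluated once
through 2D prefix sums of block-level matrices; a temperature grid is then
a small matrix product per state chunk, with a streaming log-sum-exp
keeping memory at O(states) scalars. Block-level folded and jointly-folded
probabilities are accumulated directly (never by subtraction), so even
probabilities near 10⁻¹⁶ retain full relative accuracy; this is what makes
10⁻¹⁰-level agreement with the brute-force oracle possible for the coupling
matrices. Zero sub-ensemble sums are floored at 10⁻³⁰⁰ with a warning.
Probabilities below 10⁻¹² are clipped before logit transforms, also with a
warning.

The heat capacity C_p = 2RT·(dlnZ/dT) + RT²·(d²lnZ/dT²) is an exact
identity for H = RT²·dlnZ/dT; with the solvation term active, C_p of a
predominantly folded ensemble is negative relative to the unfolded baseline
(⟨n⟩·ΔC_p^cont < 0) — that is the meaning of a negative folding ΔC_p, not a
numerical artifact. With ΔC_p^cont = 0 the model C_p reduces to the
nonnegative variance form, which the tests exploit.

## Synthetic fixtures

`bwsme.fixtures` generates everything the tests and the acceptance script
consume:

* ideal α-helices and extended chains built by internal-coordinate (NeRF)
  chain growth with textbook bond geometry (φ/ψ = −57/−47 for helix);
* helix bundles: ideal helices placed antiparallel on a circle of
  `packing_radius`, joined by circular-arc loops with 3.8 Å Cα spacing,
  written as standard PDB text, byte-identical per spec and seed, with a
  steric-clash guard (< 2 Å between residues ≥ 2 apart is an error). The
  default 7×25-residue bundle with 5-residue loops (205 residues, 61
  blocks, ~1.1 M states) is the package's stand-in for a
  seven-transmembrane fold. One lysine and one aspartate are always present
  so the electrostatics path is exercised;
* compact random toy chains (self-avoiding biased walks) with crude
  synthetic side-chain atoms, used for oracle cross-checks and non-null
  alanine scans;
* `brute_force_partition`: an independent oracle that enumerates all binary
  folded/unfolded strings with ≤ 2 islands in straight-line Python,
  duplicating two-island strings as DSA/DSAw/L, and recomputes every
  observable (Z, per-state energies, probabilities, coupling sums,
  profiles) sharing no code with the vectorized engine.

What the fixtures do **not** emulate: real side-chain packing density (the
bundles carry backbone + Cβ only, so calibrated |ξ| is ~3× larger than for
a fully packed structure), loop geometry realism, sequence diversity, and
membrane anisotropy. Passing tests therefore demonstrate the correctness of
the statistical mechanics and the pipeline, not agreement with any
particular experimental system; applying the package to real structures
requires only a complete single-chain PDB file.

## Problem sizes and tolerances

The test suite and acceptance script run the full 205-residue bundle
(~1.1 M states) for calibration and coupling, 24–44-residue bundles for
observable checks, and ≤ 12-residue toys (block size 1) for the brute-force
comparisons, which are held to 10⁻¹⁰ relative agreement. Calibration
tolerance is 0.5 K on the C_p peak; iso-stability tolerance 0.1 kJ mol⁻¹.
A full calibration of the 205-residue bundle takes about a minute on one
CPU.

## Known limitations

* Single uniform dielectric; no membrane/water gradient, no lipids.
* Native-centric: no non-native interactions, no kinetics or rates.
* Side-chain truncation underestimates mutations that would gain contacts.
* Residues within one block are perfectly correlated; couplings at
  sub-block resolution are not defined.
* The two-peak trough rule for calibration uses scipy peak prominences;
  pathological multi-peak C_p curves may need an explicit temperature grid.
* Missing loops/residues must be modelled upstream; chains with numbering
  gaps are rejected rather than repaired.
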