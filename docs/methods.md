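# Methods

## Microenvironments

A microenvironment is every atom with distance < 10 Å (strict inequality,
configurable) from the focal residue's α-carbon, excluding the focal
residue's own atoms, re-centred on that α-carbon.  One neighborhood is
extracted per residue that has an α-carbon and a standard 1-letter label;
residues without a Cα are skipped with a warning.  Neighbour atoms may come
from any residue, including hetero groups, as long as their element is one of
{C, N, O, S, H}; atoms with other elements are kept in the structure but
flagged and excluded from the element channels.  Waters are removed at parse
time, only the first model is read, and alternate locations are resolved to
the highest occupancy.

Channels: five element channels (weight 1 per atom), a charge channel
(weight = per-atom partial charge) and a SASA channel (weight = per-atom
solvent-accessible surface area, Å²).  SASA is Shrake–Rupley with a 1.4 Å
probe and a fixed quadrature of 256 points per atom (biotite's
implementation; the element-generic radius set when hydrogens are present,
the heavy-atom ProtOr set otherwise).  Charges come from a bundled template
keyed by (residue name, atom name): a formal-charge model that distributes
each charged side-chain group's unit charge evenly over its equivalent
terminal atoms (Asp/Glu carboxylate oxygens −0.5 each, Lys NZ +1, Arg
NH1/NH2 +0.5 each, His neutral); all other atoms are 0 and the table is
user-overridable.  This is deliberately the simplest defensible choice — the
channel contract (a signed scalar per atom) is what the encoder needs, and
any finer-grained partial-charge set can be swapped in as a CSV.

Gaussian coordinate noise (a training augmentation) perturbs each atom once,
identically across channels, with per-component SD σ; points pushed beyond
the extraction radius are retained, because the noise models coordinate
uncertainty rather than a re-query of the structure.  Noise is deterministic
given its seed.

## Holographic encoding

The channel density is a sum of delta functions, so its projection onto the
3D Zernike basis reduces to a sum over atoms:

    Z^c_{nlm} = sum_i v_i^c R_nl(|r_i| / r_max) S_lm(theta_i, phi_i).

Conventions, fixed throughout:

- **Real** orthonormal spherical harmonics S_lm (Condon–Shortley phase
  absorbed; m > 0 cosine-type, m < 0 sine-type), ordered m = −l … +l, degrees
  ascending.  All activations everywhere are real.
- Radial Zernike polynomials R_nl(r) = sqrt(2n+3) r^l P_k^{(0, l+1/2)}(2r²−1)
  with k = (n−l)/2, zero unless n ≥ l and n − l even; orthonormal under
  r² dr on [0, 1].  Any other normalisation convention differs by a constant
  per (n, l) that the network's first linear layer absorbs.
- The 10 Å ball is mapped to the unit ball by r → r/r_max.  A point beyond
  r_max is an error; the caller decides whether to clip or rescale.
- Default truncation l_max = 6, n_max = 10, chosen for desk-scale cost;
  both are configurable, and the learning experiments below use l_max = 4,
  n_max = 6 for speed.

Rotations act on each degree-l block by the real Wigner matrix D^l(R),
computed numerically from the defining relation S(Rx) = D S(x) on a fixed
Fibonacci-sphere sample by least squares — the relation is exact, so the
matrices are accurate to machine precision and orthogonality is guaranteed
up to rounding.  `reconstruct` evaluates the band-limited density on
arbitrary points for validation (a single encoded point reconstructs to a
peak at its true location, with resolution set by the truncation).

## Clebsch–Gordan coupling in the real basis

Complex-basis coefficients <l1 m1 l2 m2 | l3 m3> are evaluated with the Racah
closed form in exact rational arithmetic (one final square root), cached, and
validated in the tests against sympy and against numerically integrated
triple products of spherical harmonics (the Gaunt relation).  The equivariant
bilinear map for *real* tensors is the complex CG tensor conjugated with the
complex-to-real change of basis; the result is purely real when l1+l2+l3 is
even and purely imaginary when odd, in which case it is multiplied by −i —
still an intertwiner because the real Wigner matrices are real.  Couplings
are truncated to l3 ≤ l_max of the network.

## Network

A layer applies, in order: linearity (per-degree channel mixing to
`hidden_channels` rows), the CG nonlinearity, a second linearity compressing
the product channels back to `hidden_channels`, and spherical batch norm.
The compression after the nonlinearity keeps the fully-connected mode's
combinatorial growth (all degree and channel pairs) bounded; in simply
connected mode only a row's product with itself (same degree, same channel)
is taken.  Batch norm divides each (l, channel) row by the batch mean of its
Euclidean row norm in training (updating a running mean, momentum 0.1,
epsilon 10⁻⁶) and by the running mean at inference; the divisor is treated as
a constant during backpropagation.  The l = 0 channels of every layer are
concatenated and fed to a ReLU feed-forward head ending in 20 logits
(pseudoenergies); probabilities are their softmax.  Amino-acid order is fixed
alphabetically by 1-letter code (ACDEFGHIKLMNPQRSTVWY) and embedded in every
model file.  Ties in argmax resolve to the alphabetically first amino acid.

Initialisation is scaled Gaussian per l-block (variance 1/fan-in; He for the
head).  Training is Adam (default lr 10⁻³), softmax cross-entropy,
mini-batches of 32, fully deterministic given the seed; a non-finite loss
aborts with a diagnostic.  When a validation set is supplied, the
best-validation-accuracy checkpoint is returned.  Forward and backward passes
are hand-written numpy (explicit vector–Jacobian products per operation) and
are verified against central finite differences in the test suite.

Because only invariants reach the head, predicted profiles are exactly
rotation invariant — not approximately so — which the tests assert both per
operation and end to end.

## Synthetic data

The generators define the study conditions; every stage is testable offline.

- **Geometric classes**: each class is a fixed template of points on
  concentric shells with class-specific radii (12@3.0 Å; 12@6.5 Å;
  6@3.0+6@8.0 Å; further classes at 4.75 and 2.0/8.0 Å), with a shared,
  deterministic channel assignment; a sample is a Haar-random rotation of the
  template plus isotropic Gaussian jitter (default SD 0.25 Å).  Classes are
  therefore distinguished *only* by rotation-invariant geometry — mean shell
  radius already separates them perfectly at zero jitter — so any classifier
  beating chance must be rotation-robust, and the learning smoke test doubles
  as a correctness filter on the symmetry machinery.  The learning experiment
  uses 3 classes × 100 samples, l_max 4 / n_max 6 encoding, a 2-layer
  fully-connected network with 8 hidden channels, and 200 epochs.
- **Ideal peptide chains**: built by natural-extension (NeRF) placement with
  ideal internal coordinates (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231,
  Cα–Cβ 1.521 Å; angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°), ω
  fixed at 180°, and prescribed per-residue (φ, ψ) that re-measure to the
  requested values to ~10⁻¹³ degrees.  Atoms per residue: N, Cα, C, O, Cβ
  (no Cβ for glycine).
- **Protein G stand-in** (labelled synthetic): the 56-residue B1-domain
  sequence built with per-segment (φ, ψ) from its known secondary structure
  (four β-strands, one α-helix, loops elsewhere).  It has correct local
  geometry and a realistic site count but *not* the native tertiary fold or
  side chains beyond Cβ; it is the substrate for the backbone-shear bound,
  which is a local-geometry property.

What passing tests on these fixtures do **not** show: classification
accuracy on real PDB neighborhoods, or mutation-score correlations with
experimental stability data — both require corpus-scale training that is out
of scope.  What they do show: the encoding, symmetry machinery, training
loop, perturbation geometry and score definitions are each correct.

## Shear perturbation

`apply_shear` rotates the C-terminal side of the chain rigidly about the
N_i–Cα_i axis (+δ on φ_i: residue i's atoms except N and its hydrogens, plus
all later residues) and about the Cα_{i−1}–C_{i−1} axis (−δ on ψ_{i−1}:
residues ≥ i plus the carbonyl oxygen of residue i−1).  The N-terminal side
staying fixed is a convention (lever choice); the two targeted dihedrals are
re-measured after the move and must match to 10⁻⁶ degrees, while every bond
length and angle is preserved exactly because only rigid subsets move.
Coordinates are kept in float64 throughout (the underlying AtomArray's
float32 view is synchronised on export) so that ±δ round trips restore
coordinates to better than 10⁻⁸ Å.

Distortion = RMS of (D'_ab − D_ab) over atom pairs whose *wild-type*
distance is below the 10 Å cutoff (heavy atoms by default, hydrogens by
flag; intra-residue pairs included), multiplied by sign(Δψ) = −sign(δ).
Because the compensating (+δ, −δ) pair moves each distal segment rigidly,
the internal geometry of residues far from the hinge is untouched — their
absolute positions do shift (the distal segment swings as a lever), but
their environments do not, which is the sense in which the perturbation is
local and the reason the sub-10 Å pair distortion stays below 0.4 Å at the
20° cap.  `shear_scan` tabulates (site, δ) → (signed RMS, ΔE) and continues
past per-site failures; with no model it produces a geometry-only scan.

## Scoring conventions

Natural logarithm throughout.  Δlog P > 0 means the mutation is favourable
(destabilising mutations negative) — stated explicitly because sign
conventions for ΔΔG vary between communities.  Paired-structure scoring
resolves the mutant site by chain + author numbering (+ insertion code);
mismatched wild-type identity at the site is a hard error, never a silent
re-alignment.  In wt-only mode the 19 mutant scores at a site reproduce raw
pseudoenergy differences exactly (softmax normalisation cancels), so
rankings are identical.  Profile overlap is undefined for a constant profile
and raises.  Confusion-matrix rows with no samples are NaN and reported.
Ensembling averages log probabilities (not probabilities) across models over
a consistent site set, then recomputes scores from the mean.

## Numerical choices and degenerate inputs

- Atoms at the exact origin of a neighborhood encode with θ = 0 (only m = 0
  harmonics contribute), no division by zero.
- Empty neighborhoods encode to all-zero coefficients and are valid inputs.
- Batch-norm divisors are floored by epsilon 10⁻⁶; an untrained model with a
  zeroed head outputs exactly uniform probabilities.
- The boundary convention for "within 10 Å" is a strict `<`; the distortion
  pair cutoff is evaluated on wild-type distances.
- Quadrature oracles in the tests use Gauss–Legendre in cos θ × uniform
  azimuth (exact for band-limited integrands) and 120-point Gauss–Legendre
  radially.

## Known limitations

- The architecture (layer order linearity → CG product → compression →
  batch norm; batch-norm statistic; initialisation) follows this package's
  own documented choices where the published description leaves details
  open; exact parity with any other implementation's coefficients or
  weights is not claimed.
- The charge template is a formal-charge model, not a force-field
  partial-charge set; hydrogens are used when present but never placed.
- No fast (FFT-style) transforms; encoding cost is linear in atoms × basis
  size, fine for desk scale.
- Training at PDB-corpus scale, external-dataset benchmarks (stability
  ΔΔG correlations, DMS AUCs) and structure relaxation are out of scope.
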