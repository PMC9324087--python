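# Methods

`stackmrf` reconstructs quantitative T1/T2 maps from through-plane
accelerated stack-of-stars MR-fingerprinting (MRF) acquisitions, and ships
a digital phantom and acquisition simulator so the entire pipeline can be
exercised and validated without scanner data.  This note describes the
signal model, the sampling and reconstruction algorithms, the numerical
conventions, and the choices made where the design was genuinely open.

## Signal model

The sequence is an inversion-prepared, gradient-spoiled FISP train: T
excitation pulses with varying flip angles at fixed TR, preceded by an
adiabatic inversion, with a long recovery delay between repetitions of the
train.  Signals are simulated with the extended-phase-graph (EPG)
formalism: configuration states F(+k), conj(F(-k)), Z(k) over dephasing
order k, mixed by the standard RF rotation matrix, relaxed per interval,
and shifted by one order per TR by the unbalanced spoiler.  Within each TR
the order is pulse → relaxation to TE → echo readout (the k = 0
transverse state) → relaxation over TR − TE → gradient shift.  With T
pulses at most T + 1 orders are populated, so the state buffer of T + 1
orders is exact for one train.  The recovery delay is free relaxation (no
gradients); transverse states decay by exp(−delay/T2) and are not forced
to zero.  Repetition history matters because recovery is incomplete: the
simulator cycles (inversion → train → delay) `n_repetitions_to_steady_cycle`
times (default 3, at which point consecutive cycles differ by < 1e−6
relative) and returns the last repetition.

The inversion is instantaneous, Mz → −efficiency · Mz (default efficiency
1.0).  Efficiency 0 is interpreted as "no inversion pulse" rather than the
literal map (which would describe saturation, not an absent pulse).

Defaults where an acquisition protocol leaves freedom: TR 12 ms, TE =
TR/2 (FISP convention), 3 s recovery delay, and a shipped 512-point
flip-angle train of four half-sine lobes with peaks (60, 30, 45, 25)
degrees — `alpha[n] = A[lobe]·sin(pi·(n mod L)/L)`, L = T/4.  Any
user-supplied pattern is accepted; all shipped tests use the default
generator (at 256 points for desk-scale runs).

## Dictionary and temporal subspace

The dictionary simulates one fingerprint per (T1, T2) pair on a log-spaced
grid — T1 ∈ [10, 3000] ms and T2 ∈ [5, 1500] ms, 60 points each, keeping
pairs with T2 ≤ T1 (≈2200 entries) — bracketing both the NiCl2 plate of
the NIST/ISMRM system phantom and in vivo tissue.  Rows are L2-normalized;
pre-normalization norms are retained so matching can recover the proton
density scale.  B1+ is deliberately not a dictionary dimension.

The temporal subspace is the span of the leading right singular vectors of
the dictionary.  The basis columns are the rows of Vh from the SVD,
transposed *without* conjugation: time signals x then satisfy x ≈ Φa with
a = Φᴴx.  (Conjugating, as is tempting, silently changes the span for
complex signals; FISP fingerprints are real up to a global phase, which
can mask the error.)  At the default rank K = 5 the relative represented
energy leaves a ~3% residual; this residual is a genuine property of the
wide (T1, T2) range and matters for voxelwise exactness (see
Limitations).

## Sampling

Stack-of-stars: one radial spoke per MRF frame, Cartesian partition
encoding along kz.  The spoke angle advances by the 7th tiny golden angle
π/(φ+6) ≈ 23.628°; with it, no two of the first 512 spokes coincide
modulo π.  Readout samples lie at radii (j − n/2)/n cycles/pixel,
j = 0..n−1 (origin included for even n); the default readout length is 2N
(two-fold radial oversampling).

Through-plane acceleration R samples, at frame t, the kz comb
{(t + origin) mod R + mR}.  After a per-frame unitary inverse DFT along
the sampled comb, each of the Nz/R "slice groups" g superposes the R true
slices z = g + r·Nz/R.  Writing o(t) = kz-comb offset of frame t, the
decoded group-g data are

    d_g(t) = (1/√R) · e^{−2πi·o(t)·g/Nz} · Σ_r e^{−2πi·o(t)·r/R} ρ_{g+rNz/R}(t)

where ρ_z(t) is the spoke of slice z at frame t.  The replicate factor
e^{−2πi·o(t)·r/R} is the controlled-aliasing (CAIPIRINHA) phase — for
R = 2 the shifted replicate alternates +1/−1 frame to frame.  The common
factor e^{−2πi·o(t)·g/Nz} depends on the frame and group but not the
replicate; `hybrid_decode` removes it, so every downstream operator sees
exactly the T × R phase matrix exp(−2πi·o(t)·r/R).  The 1/√R scale is kept
in the forward model so that simulation → decode → model is an exact
round trip under unitary DFT conventions (verified to machine precision in
the tests).

## Forward model and operators

Per slice group the model is y = S Θ F B C x: coil weighting C, expansion
of K coefficient images to T frames by the temporal basis B, per-frame
radial NUFFT F, CAIPIRINHA phases Θ, replicate summation S (with the 1/√R
scale).  The basis weights are folded into a per-sample weight table so an
application costs K oversampled FFTs plus one sparse interpolation product
over all T spokes — the frame dimension never materializes.

The NUFFT is Kaiser–Bessel gridding: oversampling 2, kernel width 8 with
the Beatty shape parameter, apodization from the kernel's continuous
Fourier transform (computed by quadrature), and a precomputed sparse
interpolation matrix.  Scaling is unitary (1/N), so the operator matches
the normalized dense DFT with no extra constants; measured accuracy
against a dense oracle is ~1e−7, far inside the package's 1e−5 operator
contract, and the adjoint is the exact conjugate transpose.  Width 8 was
chosen over narrower kernels because it met the accuracy contract with a
wide margin at no measurable speed cost at these matrix sizes.

No density compensation enters the forward model; the inverse problem is
solved as least squares.  A block-circulant preconditioner built from the
exact Toeplitz spectrum of the normal operator is available
(`SliceGroupSystem.make_preconditioner`) but is off by default: on the
ρ-shifted ADMM system plain CG already converges in ~15 iterations, and on
the unshifted normal equations preconditioning injects near-null-space
components that plain Krylov iterations implicitly suppress.

Coil sensitivities: simulated mode uses the generator's ground-truth maps
(the prescribed bypass); for measured data a simplified calibration
low-pass filters per-coil images and divides by the root sum of squares,
yielding smooth unit-SOS maps correct up to the object's per-pixel phase.

## Solvers

*Unaccelerated (R = 1).*  20 iterations (default) of CG on the normal
equations from zero initialization — the linear reference reconstruction.

*Accelerated (R > 1).*  ADMM on data fidelity plus a locally-low-rank
(LLR) penalty: the K coefficient images are tiled into non-overlapping
8×8 patches; each patch, stacked over the R replicate slices of the group,
is cast as a (64·R) × K matrix whose nuclear norm is penalized (the joint
casting couples the aliased slices; per-replicate casting is available by
flag).  The x-update runs 5 warm-started CG steps on (EᴴE + ρI)x = Eᴴy +
ρ(z − u); the z-update is exact singular-value soft-thresholding with
threshold λ/ρ; u is the scaled dual.  Defaults: 8 outer × 5 inner
iterations, λ = 1e−4, ρ = 1e−2.

Before solving, data are normalized so max|Eᴴy| = 1 (per slice group) and
the solution is scaled back; λ and ρ are interpreted on that scale, which
is what makes a dimensionless λ = 1e−4 transferable between data sets.
The patch tiling is fixed at the image origin (an exact prox); optional
per-iteration tile cycling exists but is off by default.

## Post-processing

*Non-local means.*  Applied slice-wise to each accelerated-path
coefficient image: 3×3 patches, 32×32 search window (offsets
±search/2), weights exp(−d²/h²) on the mean squared complex patch
difference — one weight set from the joint real/imaginary distance.
Weights are normalized to sum to 1, so constants are fixed points and the
stationary mean is preserved.  The default bandwidth is h = 1.5·σ̂ with σ̂
from the median absolute deviation of the image's Laplacian residual
(noise gain 6, normal-consistency constant 1.4826).

*Dictionary matching.*  Per voxel, exhaustive maximum |dot product| over
the grid.  Subspace-reconstructed coefficients are matched in the
K-dimensional compressed domain against the projected dictionary Φᴴd,
with the projected atoms re-normalized to unit length *in the compressed
domain*.  This matters: matching against unnormalized projections
systematically favors entries with more in-subspace energy, and only 58%
of projected dictionary signals self-matched before normalization (100%
after, as Cauchy–Schwarz guarantees).  M0 is the complex dot product
divided by the matched atom's norms; the match score |dot|/‖signal‖ lies
in [0, 1] and voxels below 0.1 are flagged invalid rather than assigned.
Time-domain matching (against the full rows) is available when
coefficients are not subspace-compressed.

*Slice cropping.*  With oversampling fraction f, the acquired Nz
partitions cover (1 + f) slabs; the central Nz/(1 + f) slices are kept
(40 → 32 at 25%), symmetric by construction.

## Synthetic data generator

The phantom is a set of spheres (center, radius, T1, T2, M0) in an empty
volume, emulating the contrast-sphere plate of the NIST/ISMRM system
phantom.  Rasterization is a center-of-voxel test with the z distance
scaled by the voxel aspect ratio.  The default layout places 10 spheres on
a ring, with (T1, T2) from (100, 20) to (2500, 800) ms snapped onto the
dictionary grid, at desk scale 64 × 64 × 8 (scalable to the full
128 × 128 × 40 protocol).

Coil maps are 3-D Gaussian lobes centered outside the FOV at equispaced
azimuthal *and staggered z* positions (two rings along the slab), with a
mild linear phase, unit-SOS normalized.  The through-plane variation is
essential, not cosmetic: coil maps constant in z provide no slice
encoding, and the accelerated inverse problem then becomes nearly
singular — an early version of the generator had exactly this flaw, and
its converged R = 2 solutions were 20% from the truth with badly inflated
long T2.  Real multi-channel arrays are localized along z just as they are
in-plane.

Acquisition simulation evaluates each voxel's *exact* fingerprint (never
grid-snapped), so dictionary-grid discretization error and encoding error
remain separable.  The per-frame temporal combination runs through the
same fused gridding machinery using the phantom's tissue fingerprints as
the basis — exactly linear, so prospective undersampling and retrospective
decimation of a full simulation agree sample-for-sample at zero noise.
Noise is additive complex Gaussian in k-space; the replication experiment
sets the per-component sd to rms(|y|)/(30·√2), i.e. sample SNR ≈ 30.

What the generator does *not* emulate: B0 inhomogeneity, slice-profile and
B1+ effects, gradient delays, motion, anatomical structure, and the true
SNR regime of a 0.35 T scanner.  Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not scanner-level
accuracy.

## The replication experiment

`run_replication_experiment` simulates the default phantom once per
acceleration (R = 1 and prospective R = 2) with independent noise draws,
reconstructs R = 1 with the linear 20-iteration CG and R = 2 with
8 × 5 ADMM-LLR plus NLM, matches both, and compares per-sphere interior
means (one-voxel erosion of each sphere): mean absolute percent error and
Pearson correlation of the 10 per-sphere means for T1 and T2, plus SD
ratios.  Desk-scale problem sizes (64 × 64 × 8, T = 256, 4 coils,
~2200-entry dictionary) keep the full experiment under ~2 minutes of CPU;
`scripts/acceptance.py` re-runs it from scratch for any seed.

## Limitations

- **Voxelwise exactness is not achievable at K = 5.**  Adjacent atoms of
  the 60 × 60 log grid (≈10% steps) subtend only ~0.5–0.9° in signal
  space — in the full time domain as much as in the compressed domain —
  so exact per-voxel recovery requires total reconstruction error below
  ~1%.  The K = 5 subspace leaves ~3% of fingerprint energy
  unrepresented, which biases the least-squares solution by about that
  margin, and the single-spoke-per-frame radial system needs >10³ CG
  iterations to converge below it.  Noiseless on-grid simulations
  therefore reproduce the generator's (T1, T2) exactly on only a minority
  of voxels (measured ~17% at the default 20 iterations, plateauing near
  ~52% at full convergence), while *per-sphere means* — the quantity the
  method is used for — agree between R = 1 and R = 2 to ~0.5% (T1) and
  ~2% (T2) with correlations above 0.999.  Voxel estimates scatter over
  neighboring grid atoms; their averages are accurate.
- The λ = 1e−4 regularization weight is only meaningful relative to the
  data normalization convention described above.
- ADMM's equivalence to plain CG at λ = 0 and its objective-descent
  properties are convergence statements; at very small iteration budgets
  the warm-started restarts trail an equal-effort uninterrupted CG.
- The sampled-comb decode assumes a uniform kz comb per frame; irregular
  through-plane sampling is rejected, not approximated.
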