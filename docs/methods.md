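# Methods

## Scope and data model

`fretensemble` operates downstream of whatever produces conformations
and excited states. Its inputs are (1) a trajectory — per-snapshot
coordinates over a shared atom table, read from multi-model PDB or
multi-frame XYZ — with named atom selections for the donor ring, the
acceptor ring and the backbone fit atoms, and (2) a per-snapshot table
of vertical electronic transitions (energy in eV, oscillator strength,
transition-dipole vector in Debye). Internal units are Å, eV, Debye and
s⁻¹; every conversion constant (CODATA 2018) lives in
`fretensemble.constants`.

## Per-snapshot FRET quantities

The donor–acceptor distance r is the Euclidean distance between the
unweighted geometric centers of the donor and acceptor ring selections;
the same center-to-center vector defines the separation axis used in
the orientation factor. κ² = (cos Θ_T − 3 cos Θ_D cos Θ_A)² is computed
from the donor S1 emission dipole and the dipole of the *selected*
acceptor absorption; it is invariant to dipole magnitude and sign and
clipped to [0, 4] against floating-point overshoot at the collinear
limit.

Acceptor-transition selection emulates the resonance condition in the
absence of an explicit spectral-overlap density: among a frame's
acceptor absorptions, candidates must lie strictly below the donor
emission energy (strict inequality makes the degenerate-resonance
boundary deterministic) and within `delta_e_cutoff_ev` of it; the
largest oscillator strength wins, ties going to the lowest energy.
Frames with no qualifying transition stay in the output with NaN FRET
fields and are excluded from averages. The default window of 0.75 eV is
a package choice: it comfortably admits a Q-like band ~0.5 eV below the
donor emission while rejecting Soret-like bands above it; it is
configurable because the appropriate width depends on the systematic
error of the upstream excited-state method.

R₀⁶ = C κ² n⁻⁴ Q_D J with C selectable between the two printed
conventions of the same constant, 8.79·10⁻⁵ (`eq4`, default) and
0.211⁶ ≈ 8.825·10⁻⁵ (`eq3`); they differ by 0.066% in R₀ and both are
exposed because published values are quoted in either form. Defaults
Q_D = 0.099 and J = 1.044·10¹⁵ nm⁴ M⁻¹ cm⁻¹ are the experimental values
for a carboxyfluorescein donor / pyropheophorbide-a acceptor pair on
DNA 21-mers; n defaults to 1.333 (aqueous buffer) and is configurable
since summary tables in the literature rarely state it. k_T,rel = κ²/r⁶
is reported in raw Å⁻⁶ units with no absolute prefactor — the package
deliberately makes no absolute-rate claim.

k_r is the Einstein spontaneous-emission coefficient
A = 16π³ν³|μ|²/(3ε₀hc³) of the donor S1→S0 transition, evaluated per
snapshot in SI from the Debye dipole. Reference point: |μ| = 1 D at
500 nm gives A = 2.509·10⁶ s⁻¹.

## Spectral assembly

Weights (oscillator strengths for absorption over all S0→Si records;
Einstein coefficients for emission) are binned on the energy axis
(default bin 0.01 eV, centers on the multiples-of-bin-width lattice),
each occupied bin is spread as a **unit-area** Gaussian (default FWHM
0.04 eV) centered at the bin center, the Gaussian sums are accumulated
on an energy grid that extends six Gaussian widths past the extreme
bins, and the axis is relabeled to wavelength via λ = hc/E with no
Jacobian re-weighting (a Jacobian-corrected mode exists behind a flag
for comparison). Unit-area rather than unit-height Gaussians were
chosen because they make weight conservation exact and assertable: the
trapezoidal energy-axis area equals the summed weights (tests enforce
1%, observed ≪ 0.1%). `bin_width ≤ FWHM/2` is enforced so the grid
resolves each Gaussian. No Franck–Condon structure or excited-state
relaxation is modeled, so emission profiles are intrinsically narrower
than experimental bands.

The overlap integral J = ∫F_D(λ) ε_A(λ) λ⁴ dλ takes an area-normalized
donor emission (trapezoid rule on the wavelength axis) and an acceptor
extinction curve in M⁻¹ cm⁻¹, interpolates both linearly onto a common
20001-point grid over the overlapping range, and integrates by the
trapezoid rule; disjoint ranges give J = 0 with a warning.

## Structure analyses

Superposition is Kabsch's SVD solution with the determinant correction,
so reflections are never returned; fewer than three points or collinear
points raise a degeneracy error. The fit protocol everywhere is
fit-once-to-one-reference: each frame is fitted on the fit selection
(backbone), metrics are evaluated on the eval selection in that common
frame without refitting. RMSD is mass-unweighted. RMSF is the RMS
deviation from the time-averaged position after per-frame fitting (so
rigid whole-body motion cancels exactly); residue-level values average
the residue's atoms; a single-frame trajectory returns zeros with a
warning. Ring planes use the smallest-variance principal axis as
normal; stacking series re-sign normals for frame-to-frame continuity
and fold inter-normal angles to [0°, 90°]. Hydrogen bonds use
heavy-atom D–A distance ≤ 3.5 Å and D–H···A angle ≥ 135°, a base pair
counting as frayed in a frame when none of its triples is formed, with
a paired-occupancy threshold of 0.5 — conventional criteria, exposed in
`HBondCriteria`, not claims about any particular published analysis.
Stacking defaults (centroid distance ≤ 4.5 Å, normals within 30°) are
likewise conventional and configurable.

## Clustering

Pairwise RMSD over the chromophore-ring atoms is computed in the common
single-reference frame, which reduces to Euclidean distance between
flattened coordinate vectors divided by √m — O(n²) in cheap vector
arithmetic. A per-pair optimal-superposition mode exists behind a flag
for the (much slower) alternative protocol. Clustering is
unweighted-average-linkage (UPGMA) agglomeration via
`scipy.cluster.hierarchy`, cut at a cluster count k (default 10,
matching the conventional cluster-table size) or a height cutoff;
merge heights are verified in the tests against an exhaustive
hand-written UPGMA oracle. At exactly tied merge distances the merge
order is scipy's deterministic one rather than an index-lexicographic
rule; identical inputs always give identical outputs, and merge heights
are unaffected wherever distances are distinct. Labels are re-ordered
by descending cluster size (ties by the smallest member frame index);
representatives are medoids (minimum summed within-cluster distance,
ties to the lowest frame index).

Cluster summaries report population (divide-by-N) standard deviations —
the ensembles summarized are complete populations of their clusters,
not samples. The pooled far row unions clusters whose per-cluster mean
r exceeds `distance_threshold` (default 20 Å, the conventional validity
limit of the point-dipole approximation); it is emitted only when it
pools more than one cluster, since otherwise it would duplicate a
cluster row.

## Synthetic ensembles

The generator reproduces the *statistical* structure of a dye–DNA
conjugate ensemble, not its chemistry. Chromophores are rigid planar
hexagons (circumradius 1.39 Å) so centroid, normal and long axis are
exact; the duplex is a static two-strand ladder (3.4 Å rise) that
serves as the backbone fit selection; linkers are jittered pseudo-atom
chains. Donor–acceptor distances are drawn from a weighted Gaussian
mixture, defaulting to 10 ± 1 Å at 90% plus 30 ± 3 Å at 10% — a
dominant close-contact population with a minor solvent-separated one.
The acceptor placement direction is jittered within a 15° cone of a
fixed axis, a tethered-dye constraint that also keeps the distance
modes separable in RMSD space; dipole/ring orientations are
independently controlled (isotropic by default, cone- or
fixed-orientation options). Uniform orientations are sampled as
normalized Gaussian triples (no polar-angle bias) — the isotropic
⟨κ²⟩ = 2/3 null is exact for this sampler — and random rotations as
normalized quaternions.

Synthetic transitions place one donor S1 emission (default 2.4 eV,
|μ| = 4 D) and two acceptor bands per frame: Soret-like (3.0 eV,
f = 1.0) and Q-like (1.9 eV, f = 0.1), i.e. a Q band 0.5 eV below the
donor emission, matching the experimentally observed donor-emission/
Q-band gap for this dye pair. Band energies are Gaussian (σ = 0.05 eV);
dipoles lie in the ring plane (long axis for even bands, in-plane
perpendicular for odd, mimicking orthogonal band polarizations), with
acceptor magnitudes derived from f and the sampled energy. The toy
duplex generator builds collinear D–H···A pseudo-triples at 2.9 Å
heavy-atom separation and opens named base pairs in a stated fraction
of frames by a 20 Å strand displacement.

All generators are pure functions of (params, seed): one
`numpy.random.Generator` per call, no global state, bit-identical
reruns.

What passing tests on these ensembles do **not** show: real linkers
correlate distance with orientation, real chromophores are neither
rigid nor planar, real duplexes breathe, and real vertical-transition
energies carry method-dependent systematic shifts. The synthetic
ensembles validate the estimator pipeline (geometry → κ², R₀, E →
clusters → summaries), not any chemical prediction.

## Problem sizes and numerical choices

Default problem sizes were chosen as the smallest that make the
statistical assertions sharp: 10⁶ orientation pairs for the isotropic
null (3·SE ≈ 0.002), 1000 frames for two-mode recovery (mode-fraction
SE ≈ 1%), quadrature oracles on grids 40–100× finer than the assembly
grid. Degenerate inputs fail loudly (collinear fits, zero dipoles,
r = 0) or warn and continue (empty record lists, single-frame RMSF,
detached hydrogens, frames without a resonant acceptor). The κ²
formula's collinear limit is clamped at 4.0; angle cosines are clipped
to [−1, 1] before arccos.

## Known limitations

No absolute FRET rates, no Dexter/contact quenching, no
transition-density or linear-response couplings for the r ≲ 20 Å
regime where the point-dipole approximation fails (close-contact
cluster rows should be read as point-dipole extrapolations), no
time-resolved kinetics, no vibronic band shapes, and no dispersion or
solvatochromic shift corrections in the spectra.
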