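# fretensemble

Ensemble FRET photophysics of dye-labeled DNA conjugates.

Flexible linkers let a donor dye (e.g. a fluorescein reporter) and an
acceptor chromophore (e.g. a pyropheophorbide-a photosensitizer)
attached to an oligonucleotide sample many relative geometries: a
dominant close-contact π-stacked population plus minor solvent-separated
ones. Because Förster transfer depends steeply on both the
donor–acceptor distance and the mutual dipole orientation, single-value
FRET estimates (and the ubiquitous κ² = 2/3 assumption) can be badly
wrong for such tethered systems. `fretensemble` analyzes the problem at
the ensemble level: given per-snapshot chromophore geometries and
per-snapshot vertical electronic transitions, it computes per-snapshot
FRET quantities, broadened steady-state spectra, conformational
clusters, and cluster-resolved summary tables. A synthetic-data module
generates statistically controlled stand-in ensembles so the whole
pipeline runs and is testable without molecular-dynamics or
excited-state engines.

## The model

Per snapshot, with donor emission dipole **μ**_D, selected acceptor
absorption dipole **μ**_A and separation unit vector **R̂**:

- orientation factor κ² = (cos Θ_T − 3 cos Θ_D cos Θ_A)² ∈ [0, 4],
  where Θ_T is the inter-dipole angle and Θ_D, Θ_A the angles of each
  dipole to the donor–acceptor line; isotropic average 2/3
- relative transfer rate k_T,rel = κ² / r⁶ (no absolute prefactor)
- Förster radius R₀⁶ = 8.79·10⁻⁵ κ² n⁻⁴ Q_D J (R₀ in Å for J in
  nm⁴ M⁻¹ cm⁻¹; the equivalent 0.211·[...]^(1/6) convention is
  selectable)
- efficiency E = R₀⁶ / (R₀⁶ + r⁶), so E = ½ exactly at r = R₀
- donor radiative rate k_r = Einstein coefficient
  A = 16π³ν³|μ|²/(3ε₀hc³) of the S1→S0 emission

The acceptor transition entering κ² is re-selected each snapshot: the
most intense acceptor absorption at longer wavelength than the donor
emission and within a configurable energy-difference window (default
ΔE ≤ 0.75 eV). Defaults Q_D = 0.099 and J = 1.044·10¹⁵ nm⁴ M⁻¹ cm⁻¹
describe a carboxyfluorescein/pyropheophorbide-a pair on DNA 21-mers.

Ensemble spectra are sums of unit-area Gaussians (FWHM 0.04 eV on the
energy scale) over binned per-snapshot weights — oscillator strengths
for absorption, Einstein coefficients for emission — plotted against
wavelength. Snapshots are clustered by chromophore-ring RMSD (after a
single backbone superposition) with average-linkage (UPGMA)
hierarchical clustering; summaries report count, fraction and
mean ± SD of r, κ², R₀, E, k_T,rel, k_r per cluster, for the whole
ensemble, and pooled over the "far" clusters (mean r above 20 Å, where
the point-dipole approximation holds).

## Worked example

```python
import fretensemble as fe

params = fe.ConjugateModelParams(n_frames=1000, seed=42)   # 10±1 Å (90%) + 30±3 Å (10%)
traj, sel, truth = fe.gen_conjugate_trajectory(params)
records = fe.gen_transitions(traj, sel, fe.SpectralModelParams(seed=43))

cfg = fe.PhotophysicsConfig()                              # Q_D=0.099, J=1.044e15, n=1.333
results = fe.analyze_ensemble(traj, records, sel, cfg)

dm = fe.pairwise_rmsd_matrix(traj, 0, sel.backbone_fit,
                             sel.donor_ring + sel.acceptor_ring)
assignment = fe.average_linkage(dm, k=2)
for s in fe.summarize_clusters(results, assignment.labels):
    print(s.cluster_id, s.n_snapshots, round(s.fraction, 2),
          f"r={s.mean['r']:.2f}", f"k2={s.mean['kappa2']:.2f}",
          f"R0={s.mean['R0']:.2f}", f"E={s.mean['efficiency']:.2f}")
```

prints

```
0 902 0.9 r=9.93 k2=0.68 R0=31.37 E=0.98
1 98 0.1 r=29.64 k2=0.59 R0=30.15 E=0.53
all 1000 1.0 r=11.86 k2=0.67 R0=31.25 E=0.93
```

The clustering recovers the two generated populations (902/98 vs the
90/10 mixture); the close-contact cluster transfers almost quantitatively
(E ≈ 0.98 at ~10 Å) while the solvent-separated one sits near its
Förster radius (E ≈ 0.53 at ~30 Å), and both cluster-mean κ² values are
near the isotropic 2/3 because the synthetic dipole orientations are
unrestricted.

The same pipeline is available from the shell:

```sh
fretensemble pipeline --out-dir run --seed 42 --n-frames 1000 -k 2
```

which writes frames (`frames.pdb`), transitions (`transitions.csv`),
spectra, per-frame FRET results, cluster labels, the summary table and
a JSON run manifest.

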