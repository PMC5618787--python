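# Methods

## Scope and conventions

The package analyzes pre-computed conformational ensembles; it does not
run dynamics. Inputs are assumed pre-oriented with the membrane normal
along +z (the OPM convention), whole and centered — distances are plain
Euclidean with no periodic-boundary handling. All internal lengths are
nanometres (PDB files are Å and converted at the I/O boundary); tilts and
dihedrals are degrees. Residue numbers are taken verbatim from the file
(author numbering), never renumbered, so catalytic residues keep their
literature identities (Asp257/Asp385). Alternate locations other than
'A'/blank are dropped with a warning; multi-model PDB is the portable
trajectory dialect, with XTC/DCD available through the optional mdtraj
backend behind the same `Trajectory` contract.

## Order parameters

**Helix axis and tilt.** A helix axis is the dominant principal direction
of the centered Cα coordinates (best-fit line); `fit_rmsd` (RMS
perpendicular distance) exposes fit quality. This is the simplest
estimator consistent with tilt-angle semantics; local quaternion methods
were deliberately not used. Tilt is arccos |d · n̂| ∈ [0°, 90°], so the
axis sign convention (z-component ≥ 0, ties broken toward +x then +y) can
never change a tilt. A finite *discrete* helix has a small correlation
between its axial and in-plane coordinates, so the best-fit line of an
ideal helix wobbles around the true axis by an amount that depends on the
residue count modulo the 3.6-residue period (measured: 0.4°–18° for 7–30
residues). Two consequences were designed around:

- the synthetic generator shears this correlation out of its helices
  (an affine correction ≤ 0.02 nm per bead), making the fitted axis equal
  the nominal axis to machine precision — so configured tilts are exact
  ground truth, not approximations;
- the curvature profile defaults to 9-residue windows (2.5 turns), where
  the wobble of a straight ideal helix stays below ~1.5°, and windows are
  contiguous (step = window) so a sharp bend between two windows is
  reported at its full angle rather than smeared across overlapping fits.

**Distances and dihedral.** Pair distances support single-atom and
unweighted-centroid (center-of-geometry) modes; the ECD anchors of the
rotation dihedral may be centroids of residue ranges. The dihedral is the
standard atan2 construction with the IUPAC sign convention (clockwise
positive looking along the central bond) and range (−180°, 180°]. The
third dihedral anchor is nominally a center of mass; with Cα/bead-only
models mass weighting degenerates to the geometric centroid used here.

## Synthetic benchmark

The generator emulates, at benchmark scale, the geometry the analysis
measures on the real complex: a 9-helix bundle (Cα beads, ideal α-helix
geometry: 0.15 nm rise, 0.23 nm radius, 100°/residue) on a 1.4 nm circle,
two catalytic "CG" beads mid-membrane, a rod-plus-lobe extracellular
domain, and single anchor beads for the major axis. Two hidden states
switch by a first-order Markov chain; each frame is the rigid state
geometry plus i.i.d. isotropic Gaussian displacement of every atom
(`noise_sigma_nm` per coordinate). There are no within-state kinetics, no
lipids, no solvent, and no physical forces — passing tests demonstrates
estimator correctness on geometry with known truth, not realism of
dynamics.

Default state parameters mirror the scales reported for the complex:
inactive state 1 with dd_Asp 1.0 nm, ECD up (5.2 nm) and rotated right
(+30°), TM6/TM7 tilts 25°/20°; active state 2 with dd_Asp 0.45 nm (below
the 0.5 nm hydrogen-bond-competent criterion), ECD down (4.3 nm) and
rotated left (−50°, the reported preferred lobe orientation), TM6/TM7
tilts 12°/8°; all other helices 10°. The default transition matrix
(p₁₂ = 0.03, p₂₁ = 0.07) gives a stationary active-state occupancy of
0.30, the benchmark condition; noise defaults to σ = 0.05 nm and runs to
10,000 frames. Ground truth is exact by construction: catalytic beads are
placed exactly dd apart, the lobe centroid exactly `ecd_height` above the
bundle's center of geometry, the fourth dihedral anchor by closed-form
inversion of the dihedral, and tilts exactly nominal thanks to the shear
correction above. Randomness uses a single named generator
(`numpy.random.Generator` / PCG64) seeded from the config and recorded in
output metadata.

## Classification and the noise-spillover bias

Classification is instantaneous per-frame geometry with fixed, documented
boundary behavior: dd_Asp exactly at the threshold → state 1; dd_PS-NCT
between 4.5 and 5.0 nm → intermediate; dih_NCT = 0 → right; major-axis
values exactly at an edge → intermediate. No temporal smoothing is
applied by default (an optional odd-window majority filter exists).

One quantitative caveat is intrinsic to the 0.5 nm criterion: the active
state's 0.45 nm geometry lies only 0.05 nm below the threshold, while the
distance between two beads carrying i.i.d. per-coordinate noise σ
fluctuates with standard deviation ≈ σ√2 (0.071 nm at the default
σ = 0.05 nm). Roughly 30% of true active frames therefore measure above
0.5 nm and are labelled inactive, so thresholded occupancy systematically
underestimates the hidden-state occupancy (≈ 0.21 recovered vs 0.30
true at benchmark conditions). This mirrors the behavior described for
the real ensembles, where the active conformer fluctuates up to 0.75 nm;
the test suite verifies the recovered occupancy against an independent
Monte-Carlo prediction of this spillover, and verifies sub-0.05 recovery
at noise levels where the margin allows it (σ ≤ 0.02 nm). Users needing
unbiased occupancies should treat the threshold count as a lower bound or
fit the dd_Asp distribution directly.

For the compact/intermediate/extended split no numeric edges are
established in the literature, so both modes are provided: fixed edges,
or `"auto"` — a seeded 3-component 1-D Gaussian mixture
(quantile-initialized means at the 1/6, 3/6, 5/6 quantiles, ≥ 100 samples
required) whose labels come from posterior crossovers; on
non-convergence or collapsed components it falls back to quantile
terciles with a warning.

## Ensemble statistics

Superposition is the Kabsch least-squares rigid fit (proper rotation,
det = +1); near-collinear fit sets (second singular value < 1e-10 of the
first) are rejected. RMSF fits every frame to the first frame and
measures RMS deviation from the time-averaged position; "normalized"
divides by the maximum (range (0, 1]), the convention of color-coded
flexibility figures — min-max normalization was considered and rejected
to keep zero meaningful. PCA operates on superposed Cartesian coordinates
(reference frame configurable, first frame by default) via SVD of the
centered frame matrix; eigenvalues and variance fractions are reported
over all nontrivial modes while eigenvectors/projections keep the leading
10 by default. Porcupine output is the mean structure plus the scaled
eigenvector reshaped per atom.

GROMOS clustering takes the frame with the most neighbors within the RMSD
cutoff as a centroid, removes it with its neighbors, and repeats;
ties break toward the lowest frame index, making results
bit-reproducible. The pairwise superposed RMSD matrix is O(F²) Kabsch
fits, so the pipeline subsamples to ≤ 150 frames by stride before
clustering (configurable).

Hydrogen bonds are geometric: present iff d(D, A) ≤ 0.30 nm and the
D–H–A angle ≥ 150°. The angle is defined at the hydrogen; for topologies
without hydrogens (bead models, heavy-atom cryo-EM coordinates) a
distance-only mode is used with an explicit warning rather than inventing
a surrogate angle. Occupancy is the fraction of frames within a chosen
window in which the bond is present.

Density maps render each atom as a normalized isotropic Gaussian with
σ = 0.225 × resolution (the molmap-style convention), on a voxel grid
centered on the data midpoint and padded by 4σ; the integrated map equals
the total weight to well within 1% at the default 0.8 nm resolution /
0.1 nm voxel. Maps export to CCP4/MRC through gemmi.

## Pipeline determinism and problem sizes

The pipeline writes CSV at full double precision; identical config + seed
give byte-identical numeric outputs, and the manifest records package and
numpy versions, the seed, a config hash and a checksum per artifact. The
bundled benchmark sizes — 10,000 frames for occupancy/tilt recovery,
5,000 frames for the PCA variance-split fixture, ≤ 30-frame instances for
exhaustive clustering cross-checks, 2,000 frames for the worked example —
were chosen so each property is measured well inside its sampling error
while the whole suite stays interactive on a laptop.

## Known limitations

- The synthetic ECD is rigid within a state; PCA on synthetic data
  therefore concentrates variance in few modes, unlike the broad spectra
  of real ensembles.
- Helix-axis estimation assumes mostly-straight helices; strongly curved
  helices should be examined with `curvature_profile`, not a single tilt.
- The heavy-atom hydrogen-bond mode is distance-only and thus permissive.
- Selections are chain + author-residue based; insertion codes are not
  modeled, and maps for real depositions must be verified per entry
  (`gsecens validate`).
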