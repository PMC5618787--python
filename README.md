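# gsecens

Conformational-ensemble analysis for γ-secretase-style membrane-protease
trajectories.

γ-Secretase is a four-subunit intramembrane aspartyl protease (presenilin 1,
nicastrin, PEN-2, APH-1A) whose cleavage of the amyloid precursor protein
fragment APP-C99 produces the Aβ peptides implicated in Alzheimer's disease.
Its functional cycle is commonly characterized through a small set of
geometric order parameters measured frame-by-frame along molecular-dynamics
trajectories:

- **dd_Asp** — distance (nm) between the side-chain γ-carbons of the
  catalytic aspartates (PS1 Asp257 on TM6, Asp385 on TM7). A value below
  0.5 nm permits the aspartate–water hydrogen-bond network of the active
  protease; frames are classified *state 2* (active) iff dd_Asp < 0.5 nm,
  else *state 1* (inactive).
- **T_TM** — tilt angle (degrees) of each PS1 transmembrane-helix axis
  relative to the membrane normal, T = arccos |d · n̂|, with the axis d
  estimated as the dominant principal direction of the helix Cα
  coordinates.
- **dd_PS-NCT** — distance between the centers of geometry of PS1 and of
  the nicastrin (NCT) extracellular large lobe: the ECD is "up" above
  5.0 nm and "down" below 4.5 nm.
- **dih_NCT** — signed four-point dihedral quantifying left/right rotation
  of the NCT lobe (negative = leftward; the preferred orientation sits
  near −50°).
- **axis_length** — the complex's major-axis length separating its
  compact / intermediate / extended global forms.

Around these order parameters the package provides the standard ensemble
machinery: least-squares superposition and per-residue RMSF, Cartesian
coordinate PCA with porcupine vector fields, GROMOS iterative-centroid RMSD
clustering, geometric hydrogen-bond occupancy (3.0 Å / 150° criterion), and
Gaussian density-map rendering — plus a synthetic two-state trajectory
generator with *exact* ground truth, so every stage of the pipeline is
testable without downloading trajectories.

Intended users: computational structural biologists analyzing membrane
protein MD output (multi-model PDB natively; XTC/DCD via the optional
mdtraj backend), and method developers who need a fully controlled
benchmark with known per-frame state labels.

## Worked example

Run the full pipeline on the bundled synthetic benchmark (2,000 frames of
a 9-helix bundle with hidden two-state switching, 0.05 nm positional
noise, seed 1):

```sh
gsecens run --config examples/pipeline_synthetic.yaml
```

which writes `ops.csv`, `rmsf.csv`, `pca_*.csv`, `clusters.csv`,
`labels.csv`, `summary.csv`, `truth.csv` and a checksummed `manifest.txt`
into `gsecens_out/`. The summary from that exact run:

```
family,label,occupancy,transitions
ps1_state,1,0.80049999999999999,236
ps1_state,2,0.19950000000000001,236
nct_vertical,down,0.27550000000000002,72
nct_vertical,up,0.72450000000000003,72
nct_rotation,left,0.27550000000000002,72
nct_rotation,right,0.72450000000000003,72
global_form,compact,0.27550000000000002,72
```

Reading it: the hidden active-state occupancy in this run is 0.2755
(`truth.csv`), and every ECD-based family (vertical position, rotation,
global form) recovers it exactly because those order parameters are far
from their thresholds. The dd_Asp thresholding recovers 0.1995 — lower
than the truth because the active-state geometry (0.45 nm) sits only
0.05 nm below the 0.5 nm criterion, so positional noise pushes a
predictable fraction of active frames across it (see
`docs/methods.md`). GROMOS clustering at a 0.2 nm cutoff finds exactly
2 clusters matching the hidden states, and PCA assigns 79% of the total
variance to the leading component (the ECD up/down translation that
dominates the inter-state motion).

The same stages run on real data by swapping the input block of the
config for a trajectory file plus a topology map; an editable map for the
deposited complex is in `examples/topology_map_5fn2.yaml`, and
`gsecens validate <structure> <map>` reports which selections resolve.

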