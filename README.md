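# flexmotif

Detection of **high-fluctuation 3D motifs** in molecular-dynamics (MD)
trajectories of proteins, using per-residue **sphere-neighborhood RMSD**
between consecutive frames.

Classical flexibility measures such as RMSF describe how far each atom
strays from its *mean* position over a whole trajectory. flexmotif
instead asks a local, time-resolved question: *which spatial
neighborhoods deform the most between one frame and the next?* For
every residue a sphere of radius *d* (2–8 Å) is built around its Cα on
a target frame (by default the first); the atom membership of that
sphere is frozen there and tracked through the trajectory. For each
consecutive frame pair *t → t+1* the RMSD of the sphere's atoms is
computed, giving an *R × (F−1)* score matrix (*R* residues, *F*
frames). The cells with the top *p%* scores — out of a candidate pool
of exactly *R × (F−1)* — are the high-fluctuation motifs, which are
reported, ranked, and painted into the B-factor column of a per-frame
PDB file so any molecular viewer can color them.

Two RMSD variants are provided for the frame-to-frame comparison:

- **raw** — RMSD of the paired atoms as given:
  `sqrt(mean_i ||a_i − b_i||²)`. Global rigid-body drift of the whole
  molecule contributes to every score.
- **superposed** (default) — minimum RMSD after an optimal rigid-body
  fit of the sphere (Kabsch algorithm: centroid alignment + SVD
  rotation with reflection correction), so only internal deformation
  of the neighborhood is scored.

The package also validates and cleans input structures (non-protein
chains, ligands, ions and waters are discarded; amino acids with
missing heavy-atom coordinates are rejected; everything is logged),
reads/writes trajectories as multi-model PDB, computes a per-residue
Cα RMSF baseline for comparison, and ships a deterministic synthetic
trajectory generator used throughout the test suite.

## Worked example

Generate a 30-residue synthetic trajectory (5 frames) in which
residues 12–14 receive 1.5 Å Gaussian perturbations each frame, then
analyze it:

```sh
flexmotif synth --residues 30 --frames 5 --window 12 14 --sigma 1.5 \
    --seed 42 --out demo
flexmotif analyze demo/synthetic_trajectory.pdb --radius 5 --percent 2 \
    --out demo/results
```

The analysis selects `ceil(2% × 30×4) = 3` motifs. `motifs.tsv`:

```
rank	residue	transition	score_A	sphere_members
1	A:11	frame 3->4	2.6270	A:10,A:11,A:12,A:13
2	A:11	frame 4->5	2.5128	A:10,A:11,A:12,A:13
3	A:12	frame 3->4	2.3926	A:8,A:11,A:12
```

Every top-ranked sphere overlaps the perturbed 12–14 window: the
residue-11 sphere scores highest because it contains residues 12 and
13, whose atoms move ~σ√6 ≈ 3.7 Å between frames while the rest of the
chain is static. `scores.csv` holds the full 30 × 4 RMSD matrix
(columns labelled by the later frame of each pair):

```
residue,2,3,4,5
A:1::ALA,0.0000,0.0000,0.0000,0.0000
...
```

`annotated_trajectory.pdb` carries B-factor 99.99 on motif atoms in
the affected frames (frame 1 shows the union of all motifs as an
overview), and `selections.txt` gives ready-made viewer selections:

```
frame 1	chain A and resi 8+10-13
frame 4	chain A and resi 8+10-13
frame 5	chain A and resi 10-13
```

`rmsf.tsv` contains the per-residue Cα RMSF baseline for the same
trajectory — note how it blurs the signal over the whole window and
over time, where the sphere scores pinpoint individual transitions.

The same pipeline is available as a library:

```python
from flexmotif import (SphereParams, build_spheres, read_trajectory,
                       score_transitions, select_high_fluctuation)

with open("trajectory.pdb") as fh:
    traj = read_trajectory(fh)
spheres = build_spheres(traj, SphereParams(radius_d=5.0))
matrix = score_transitions(traj, spheres, rmsd_mode="superposed")
motifs = select_high_fluctuation(matrix, p=2.0)
```

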