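# Methods

## The fluctuation score

Given a protein MD trajectory with frames `X_1 … X_F` (all sharing one
atom topology), the method proceeds in three phases.

**1. Sphere construction (target frame).** For each residue *i*, a
spatial neighborhood is fixed on one target frame (default: frame 1).
In the default `residue_ca` mode, residue *j* belongs to sphere *i*
iff the Euclidean Cα–Cα distance on the target frame is ≤ *d*; all
heavy atoms of member residues are included. In the alternative
`atom_any` mode an individual atom belongs iff its own distance to
Cα(*i*) is ≤ *d*. Both readings of "atoms within distance *d*" are
defensible — one selects whole residues through their reference atom,
the other selects atoms directly — so both are implemented and the
mode is an explicit parameter rather than a hidden assumption.
Membership is computed once and never updated, so the score tracks the
*same* group of atoms through time. Spheres may span chains; a sphere
always contains its own center residue.

**2. Frame-to-frame RMSD.** For every consecutive frame pair
*(t, t+1)* and every sphere, the RMSD of the sphere's member atoms is
computed between the two frames, producing an `R × (F−1)` matrix of
scores in Å. The candidate pool for motif selection is therefore
exactly `R × (F−1)` cells. Two modes:

- `raw`: `sqrt(mean_i ||a_i − b_i||²)` with no fit. Faithful to a
  literal frame-difference reading, but global rigid-body drift —
  ubiquitous in un-fitted MD output — enters every score.
- `superposed` (default): the minimum RMSD over all proper rotations
  and translations of one sphere onto the other, via the Kabsch
  algorithm (centroid alignment, SVD of the 3×3 covariance,
  determinant-sign correction so reflections are excluded). The
  rotation is applied explicitly and the RMSD taken on the rotated
  coordinates; this keeps near-zero scores at machine precision,
  whereas the `E₀ − 2Σσ` shortcut loses accuracy like √(ε·E₀) and can
  turn an exact zero into ~10⁻⁶ Å.

`superposed` is the default because without it rigid drift dominates
the ranking; `raw` remains available for trajectories already globally
fitted. Superposed ≤ raw always holds, and both scale linearly with the
coordinates.

**3. Top-p% selection.** The `ceil(p/100 · R·(F−1))` highest-scoring
cells are selected and ranked. Ceiling rounding guarantees a non-empty
result for any p > 0. Ties are broken deterministically: higher score,
then earlier transition, then lower residue index — a total order, so
repeated runs are byte-identical. Scores are attributed to the later
frame of each pair in all reports (a transition is labelled by the
frame in which the motion has happened), and printed with 4 decimals,
beyond the 10⁻³ Å precision of PDB coordinates.

## Parameters

| parameter | default | range | meaning |
|---|---|---|---|
| `radius_d` | 4.0 Å | [2, 8] | sphere cutoff; ~4 Å captures a residue plus its contact shell, 8 Å approaches a full secondary-structure element |
| `percentage_p` | 5 % | (0, 100] | fraction of the R×(F−1) pool reported as motifs |
| `target_frame` | 1 (1-based) | any frame | frame on which membership is fixed |
| `rmsd_mode` | superposed | raw / superposed | see above |
| `membership_mode` | residue_ca | residue_ca / atom_any | sphere granularity |
| `include_hydrogens` | false | — | hydrogens as sphere members; off by default so scores are comparable between MD setups with and without explicit-H output |

The radius bounds are enforced strictly (2.0 and 8.0 accepted, 1.9 and
8.1 rejected). The defaults for *d* and *p* are this package's own
choices: a mid-range radius and a small motif fraction suited to
highlighting a handful of flexible regions.

## Structure validation

Input PDB files are cleaned before analysis: HETATM entities are
removed and counted (waters kept as their own category, separate from
ligands and monoatomic ions); chains containing no standard amino-acid
ATOM residue are removed whole; alternate-location groups collapse to
the highest-occupancy conformer (ties to first occurrence); residues
missing any heavy atom of their standard chemical composition —
including the Cα — are rejected (hydrogens are never required);
non-standard residue names (e.g. MSE) are treated as non-protein, with
an anomaly note, rather than chemically repaired. Multi-model inputs
used as a single structure contribute model 1, with a note. Every
removal, rejection and anomaly lands in the validation log; validation
never modifies a coordinate. The parser recovers per line: a record
with unparseable coordinates is skipped and logged instead of aborting
the file.

Trajectories are read as multi-model PDB. Only model 1 is validated;
later models must match its cleaned topology exactly by (residue id,
atom name). Atoms that validation removed from model 1 (e.g. waters)
are ignored in later frames too, but a missing topology atom or a new
protein atom in frame *k* is a hard error — per-frame re-validation
would let atom topology drift silently. Frames are 0-based internally
and 1-based in every user-facing report.

## Synthetic data

The generator builds poly-alanine chains (N, CA, C, O, CB per residue;
alanine is the smallest standard residue with a side-chain atom, so
missing-atom validation stays exercised) in two geometries: an ideal
helix (1.5 Å rise, 100° turn per residue) and an extended chain
(3.5 Å Cα spacing). A trajectory applies, per frame, an optional
rigid motion (rotation about the base centroid plus translation,
composed cumulatively) and adds independent Gaussian noise of standard
deviation σ to all atoms of a chosen residue window, redrawn each
frame. Because the noise is independent across frames (not a random
walk), the frame-to-frame displacement of a perturbed atom has
expectation `E[‖Δ‖²] = 6σ²`, which the tests verify by Monte-Carlo.
Coordinates are rounded to the PDB's 3 decimals at generation so
write/read round-trips are exact. Everything is a pure function of
(spec, seed).

What the generator does **not** emulate: physically realistic
dynamics, correlated motions, solvent, periodic boundaries, or
chemistry beyond poly-alanine. Passing tests on this data demonstrates
that the scoring machinery recovers localized, uncorrelated motion on
a rigid background; it does not by itself establish sensitivity on
real force-field trajectories, where flexibility is correlated along
the chain and drift is partially removed by post-processing.

## Numerical choices

- Sphere search uses a KD-tree; correctness is defined by (and tested
  against) the exhaustive all-pairs distance scan, with the closed
  ball (≤) as the boundary rule.
- Scores below 10⁻¹² Å are clamped to exactly 0 so "identical frames
  score zero" holds as an identity, not an approximation.
- Kabsch for degenerate inputs: a single atom or collinear sets fall
  back gracefully (the SVD still yields a valid rotation; a single
  point scores 0 after centroid alignment).
- Selection arithmetic is pure integer/ceiling logic; no floating
  comparison decides the selected count.

## Problem sizes

The test suite runs on chains of 1–93 residues and 2–11 frames; the
reproduction script's main run uses 93 residues × 51 frames
(4650-candidate pool), sized to exercise the full pipeline — PDB
round-trip included — in a few seconds on one core. Larger
trajectories scale linearly in R·F for scoring.

## Known limitations

- Only multi-model PDB input; binary formats (XTC/TRR/DCD) need prior
  conversion.
- No mass weighting; all atoms contribute equally to the RMSD.
- No periodic-image handling: trajectories should be whole-molecule
  (unwrapped) before export.
- "Percentage of motifs" is interpreted over residue×transition cells,
  following the pool-size definition `R × (F−1)`; a per-residue
  interpretation would be a different statistic.
- Non-consecutive frame-pair comparison and time-windowed RMSF (tRMSF)
  are out of scope.
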