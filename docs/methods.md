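# Methods

`decoybench` measures what a protein structural model of known, graded
accuracy is still good for.  Given a native (experimental) single-chain
structure and a set of decoy models of the same sequence, it scores each
decoy (GDT-TS, RMSD) and asks three practical questions: does the model
preserve the exposed/buried classification of residues, the largest
surface cavity, and the internal geometry of catalytic sites?  A seeded
generator produces the native-like fixtures and the decoy sets, so the
whole pipeline runs from nothing but a random seed.

## Model quality scores

**RMSD** uses the closed-form Kabsch solution (SVD of the 3×3
cross-covariance, determinant sign fixed so reflections are excluded).
Tests verify optimality against a numerical minimiser over rotation
vectors and against large ensembles of random rigid placements.

**GDT-TS** is the average over cutoffs 1, 2, 4, 8 Å of the maximal
fraction of corresponding Cα atoms that one rigid superposition can bring
within the cutoff, ×100.  Correspondence is fixed by residue identity
(chain, number, insertion code): the decoys scored here are models of the
same sequence, so no alignment search is needed.  Residues missing from
the model are excluded from the common count; fractions are over common
residues.

The maximal fraction is found by seed-and-refine search: superpositions
seeded on contiguous Cα windows (lengths 3, 5, 7 at stride 2, plus the
full trace), each refined by alternating *select pairs within the cutoff /
re-fit on the selection* for at most 10 rounds, keeping the best fraction
(ties broken by lower fit RMSD).  For traces of ≤ 10 common residues the
seed set switches to every subset of size ≥ 3, which makes the search
*provably* exhaustive: every reported fraction is realised by a
least-squares fit on some subset, and every subset fit is visited.  The
acceptance suite exploits this to pin the heuristic against an
independent brute-force oracle on adversarial 8-residue traces.  This is
a faithful implementation of the standard GDT-TS definition, not a
bit-compatible reproduction of any particular scoring program.

## Solvent accessibility

Per-atom SASA is computed with the Shrake–Rupley method on a
deterministic golden-spiral point lattice (default 960 points, probe
1.4 Å; doubling the lattice changes totals by < 1 %).  Van der Waals
radii: C 1.70, N 1.55, O 1.52, S 1.80 Å, with a 1.70 Å fallback plus a
warning for unknown elements.  Residue SASA is normalised by the Miller
et al. (1987) per-residue maxima and classified with strict inequalities:
above 70 % exposed, below 30 % buried, otherwise intermediate.  Relative
values above 100 % (chain termini, sparse synthetic residues) are kept
and classify as exposed.  The implementation is verified against the
analytic isolated-sphere and two-sphere cap formulas and, per residue,
against biotite's independent implementation (within 3 %).  A DSSP-based
accessibility engine would give slightly different absolute areas; only
the relative classes matter for the benchmarks here.

## Cavity detection

A LIGSITE-style grid method (default 1.0 Å spacing, 4.0 Å padding).
Grid points inside any solvent-expanded atom sphere are *occupied*; empty
points 6-connected to the box boundary are *bulk solvent*; the remaining
empty points are enclosed voids and are always accepted; bulk-connected
empty points are additionally accepted as pocket points when occupied
points flank them on both sides along ≥ 5 of 7 scan axes (x, y, z, four
body diagonals).  Accepted points are clustered at 26-connectivity
(asymmetry intended: conservative solvent, permissive grouping), clusters
under 3 points are dropped, and cavities are ranked by volume
(count × spacing³), ties going to the cluster nearer the protein
centroid.  A residue belongs to a cavity if any of its atoms lies within
vdW + probe + spacing of a cavity point; cavity depth is the mean
distance from cavity points to the nearest bulk point.  Volumes converge
on a Monte-Carlo rejection-sampling oracle applied to the same occupancy
rule (within 25 % at 1.0 Å, 15 % at 0.5 Å on the shell fixture).  No
numeric compatibility with any published cavity program is claimed.

## The three benchmarks

* **Exposure recovery** — reference set: native residues of the requested
  class (exposed or buried); recovered: those with the same class in the
  model.  Native residues absent from the model count against recovery
  (they cannot be classified there).  Success means a fraction ≥ 0.75,
  inclusive at the boundary.
* **Cavity recovery** — reference: residues lining the native's largest
  cavity; recovered: those also lining the model's largest cavity.  A
  model without cavities scores 0; a native without cavities makes the
  benchmark not assessable.
* **Catalytic-site geometry** — for each unordered pair of site residues
  with Cα in both structures, the absolute difference of native and model
  Cα–Cα distances, averaged per site.  Ordered permutations would count
  each symmetric difference twice and leave the mean unchanged, so pairs
  are used.  Internal distances make the metric superposition-free and
  rigid-motion invariant.  Sites need ≥ 2 usable residues.

Per-decoy rows are aggregated in GDT-TS decade bins [0,10) … [90,100]
(top bin closed): percentage of successful models per bin for the
recovery benchmarks, mean and maximum of per-site means for the site
benchmark.  Decade bins are a reporting choice, not forced by the
benchmark definitions.

## Synthetic fixtures and decoy generation

The generator replaces a homology-search + comparative-modelling stage so
the pipeline is self-contained.

* **Helix fixture** — ideal α-helix (rise 1.5 Å, twist 100°/residue, Cα
  radius 2.3 Å) with N, CA, C, O, CB pseudo-atoms at plausible offsets;
  the consecutive Cα distance comes out at the canonical 3.8 Å virtual
  bond.  Used as the elongated test body for scoring and ladder checks.
* **Pocket fixture** — pseudo-residues (4 carbon atoms each, the first
  named CA) tiling concentric spheres from `void_radius + 3.1 Å` out to
  `shell_radius`, ~2.2 Å point spacing on the inner layers (solvent-tight
  at 1 Å grid) and ~3.5 Å on the surface layer so its residues keep an
  exposed outer face.  One fixture therefore offers all three benchmark
  substrates: an exposed surface, a buried middle layer, and a single
  enclosed cavity of known nominal volume.

* **Perturbation** — each residue's atoms are displaced rigidly by a sum
  of `n_modes` sinusoids over the residue index with wavelengths ≥
  `correlation_length`, random directions and phases, scaled so the RMS
  per-residue displacement equals `amplitude`; optional independent
  per-segment translations (`segment_jitter`).  The field's shape depends
  only on the seed, amplitude is a pure scale — so an amplitude search
  traverses one deformation family.
* **Ladders** — per target GDT-TS bin and replicate, amplitude is
  bisected over [0, 30] Å until the decoy's *verified* GDT-TS (always
  recomputed with the scoring module) lands in the bin; after 40
  iterations the nearest result within bin ± 2 GDT units is accepted,
  otherwise the replicate is reported missing, never fabricated.
  Sub-seeds derive from (root seed, bin index, replicate) via numpy seed
  sequences, making generation bit-reproducible.  Ladder decoys default
  to 3 modes with correlation length 25 residues: coherent, segment-scale
  error — an intact core with smoothly displaced regions — which is how
  template-based models actually fail; with such fields the benchmarks
  degrade gradually and monotonically across bins, whereas short-range
  fields scramble surface texture almost immediately below the top bin.

What the generator does **not** emulate: real side chains and their
packing, secondary-structure content beyond the single helix, sequence
heterogeneity, physically relaxed models (no energy minimisation or
side-chain repacking), template-dependent coverage gaps.  Passing
benchmarks on these fixtures demonstrates the correctness and the
qualitative behaviour of the metrics, not the quantitative recovery rates
expected on real comparative models.

## Dataset filters and annotations

Experimental chains are admitted with resolution ≤ 2 Å, R-factor ≤ 0.3,
20–10000 residues, and rejection of Cα-only chains.  Chains lacking a
resolution or R-factor record (all synthetic fixtures) pass those rules
as not assessable.  Catalytic sites are read from a local CSA-like TSV
(`site_id chain seq_num icode res_name`); single-residue sites are parsed
but flagged ineligible for distance analysis.  Decoy metadata carries the
homology-search statistics (probability, E-value, score, coverage — with
the conventional admission defaults of ≥ 80 % coverage and E ≤ 0.1) plus
GDT-TS/RMSD, and sorts stably with better-first semantics per key.  The
protrusion index follows the CX method (10 Å sphere, 20.1 ų mean atom
volume); the burial companion is reported as 1/(1+CX) ∈ (0,1), a
convention of this package.

## Numerical and degenerate-input policy

* Strict thresholds everywhere they are worded strictly ("above 70 %",
  "at least 75 %"): classification uses strict inequalities, success uses ≥.
* Ties: GDT selections with equal fractions keep the lower-RMSD fit;
  equal-volume cavities rank by centroid proximity to the protein
  centroid; decoy sorting is stable with missing keys last.
* Altloc resolution keeps the highest-occupancy conformer, first-in-file
  on ties; hydrogens and HETATM records are dropped on read (modified
  residues appearing as HETATM are therefore ignored — a documented
  limitation).
* Empty reference sets make a recovery result "not assessable" rather
  than 0 or 1; one failing decoy is recorded in its row and does not
  abort a benchmark run.
* PDB coordinates outside the fixed-width field range refuse to
  serialise; parsing errors name the offending line.

## Problem sizes

Default test and acceptance runs use 20–60-residue helices, 40–100-residue
shell fixtures, ladders of ≤ 9 decoys, 960-point SASA lattices, 1.0 Å
(occasionally 0.5 Å) cavity grids and 2×10⁵-sample Monte-Carlo volume
oracles.  These sizes give stable statistics for every check while the
full suite stays fast; all of them scale up through public parameters.
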