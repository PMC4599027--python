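# Methods

This document records the models implemented by `alignpocket`, every
parameter default with its rationale, what the synthetic generators do and
do not emulate, and the numerical choices that matter for reproducibility.

## 1. Alignment handling (`alignpocket.msa`)

**Model.** An `Alignment` is an immutable rectangular block of aligned
sequences over the 20 standard amino acids, the ambiguity codes X/B/Z/U/O,
and `-` for gaps. `.` (insert-state gap) is normalised to `-` and sequences
are upper-cased on read. FASTA and Stockholm are read with Biopython's
`AlignIO`; the Stockholm **writer** is implemented in-package because
Biopython's writer silently drops custom `#=GC` per-column annotation
lines, which we must round-trip.

**Masking and filtering.**

- `mask_query_insertions` removes columns where the query has a gap
  (reason `query_gap`); scores are only meaningful at query positions.
- `column_gap_fraction` counts `-` over all rows.
- `conservation_score` returns an integer 0–10. If the alignment carries
  an explicit per-column conservation annotation (any `#=GC` tag whose
  name contains `cons`, excluding `SS_cons`), its digits are used.
  Otherwise the score is `floor(10 × p)` where `p` is the modal
  standard-residue proportion among non-gap entries.
- `filter_columns(max_gap=0.30, min_cons=8)` keeps a column iff
  `gap_fraction < 0.30` **and** `conservation > 8`. Both inequalities are
  strict: a column at exactly 30 % gaps or score exactly 8 is removed.
  The returned `ColumnMask` records kept indices and a per-column removal
  reason, and `ColumnMask.compose` maps coordinates through successive
  maskings.

## 2. Exceptionality score (`alignpocket.exceptionality`)

**Categories.** aliphatic {A,V,L,I,M,C}, aromatic {F,W,Y,H}, polar
{S,T,N,Q}, positive {K,R}, negative {D,E}, special {G,P}. Histidine is
treated as aromatic. Ambiguity codes and gaps contribute to no category.

**Column profile.** For column *l*, proportions `P_c` are computed over
the **homolog** rows only — the query is excluded by default so its own
residue cannot dilute the signal it is being compared against. The
denominator is the number of homolog residues that fall in some category
(gaps and ambiguity codes excluded).

**Masking.** A column is masked (entropy defined as 0, no score) when its
gap fraction exceeds 0.5 or no homolog residue is scoreable; the latter
case emits a warning because it usually signals a degenerate input.

**Score.**

```
s(l) = − Σ_c P_c ln P_c          (sum over non-empty categories)
S(l) = (P_max − P_i) / s(l)
```

`P_max` is the modal category proportion and `P_i` the proportion of the
query residue's category (0 if the query residue is a gap/ambiguity code).
Natural log is used; because a base change multiplies every finite score
by the same positive constant, rankings are base-invariant. Statuses:

- `finite` — numerator > 0, entropy > 0;
- `zero` — numerator exactly 0 (query agrees with the majority);
- `infinite` — perfectly conserved column (entropy 0) that disagrees with
  the query; these outrank every finite score;
- `masked` — excluded from ranking.

`rank_exceptional(profile, k)` sorts infinite first, then score
descending, then position ascending, and never returns masked columns.

**Reference value.** With 23 homologs split 20 aliphatic / 3 aromatic and
an aromatic query: `P_max = 20/23`, `P_i = 3/23`, `s ≈ 0.387213`,
`S ≈ 1.908850`. This closed form is used as an oracle throughout the
tests.

## 3. Family screen (`alignpocket.family`)

An `EvalueTable` holds a families × proteins matrix of E-values (strictly
positive; `NaN` marks searches with no reported hit) plus a family→model
(Pfam accession) map. TSV input uses header `family<TAB>model<TAB><protein …>`;
missing cells may be empty, `-`, en/em dashes, `na`/`NA`/`NaN` or `.`.

- `significant_hits(table, alpha=0.05)` — a hit is significant when
  `E ≤ alpha` (inclusive boundary).
- `separation_magnitude(best, second) = round(log10(second / best))`.
- `assign_family(table, protein)` picks the smallest E-value (stable sort,
  so ties break by table order and are reported in `tied_families`); the
  call is `assigned` only when that best hit is significant.

The bundled panel (`alignpocket.datasets`) is the published 7-family ×
4-protein ligase screen with 8 missing cells. For DpRNL the best hit is
PF09414 at 4.9 × 10⁻¹², the runner-up PF01068 at 3.3 × 10⁻⁵, giving a
separation magnitude of 7.

## 4. Pocket geometry (`alignpocket.geometry`)

**Structures and trajectories.** Single- and multi-model PDB files are
read with Biopython's `PDBParser`; coordinates are promoted to float64.
All frames must contain the same atom count. Atom selections use
`resid:atom_name` strings.

**Superposition.** `kabsch_superpose` computes the optimal rotation via
SVD of the covariance matrix, flipping the sign of the last singular
vector when needed so the rotation is proper (det +1). It requires ≥ 3
points and a covariance matrix of rank ≥ 2. `rmsd_series` superposes each
frame onto the first (default selection: Cα atoms). `rmsf` uses the
standard two-pass scheme: superpose all frames onto frame 0, compute the
mean structure, re-superpose onto the mean, then take per-atom RMS
deviation from the mean.

**Hydrogen bonds.** Criteria (defaults): donor–acceptor heavy-atom (N/O)
distance ≤ 3.0 Å and deviation of the D–H…A angle from linearity ≤ 30°.
Hydrogens are assigned to the nearest heavy atom within 1.2 Å; a
structure without hydrogens yields no bonds and a warning.
`hbond_occupancy` reports the percentage of frames in which the given
donor/acceptor pair forms a bond through *any* of the donor's hydrogens.

**π-stacking.** Each ring's least-squares plane is found by SVD of the
centred ring atoms; the normal is canonicalised (positive z, then y, then
x component) so signs are deterministic. A frame is stacked when centroid
distance ≤ 5.0 Å and the acute inter-plane angle ≤ 30°; the verdict is
`stacked` iff the stacked fraction is ≥ 0.5.

**Flat-bottom restraint.** `RestraintSpec(r_i_nm, k=1000 kJ·mol⁻¹·nm⁻²,
half_width_nm=0.30, linear_offset_nm=1.0)` defines `r₀ = r_i`,
`r₁ = r_i + half_width`, `r₂ = r₁ + linear_offset` (all nm):

```
U(r) = k/2 (r₀ − r)²                         r < r₀
     = 0                                     r₀ ≤ r ≤ r₁
     = k/2 (r − r₁)²                         r₁ < r ≤ r₂
     = k/2 (r₂ − r₁)² + k (r₂ − r₁)(r − r₂)  r > r₂
```

The linear tail's slope `k(r₂ − r₁)` matches the quadratic's derivative
at `r₂`, so `U` is C¹ everywhere. `restraint_violation_fraction` converts
trajectory distances from Å to nm and counts frames with `r` outside
`[r₀, r₁]`.

## 5. Synthetic generators (`alignpocket.synthetic`)

All generators are driven by `numpy.random.default_rng(seed)` and are
byte-deterministic for a given recipe. Category definitions are restated
locally (not imported from `exceptionality`) so the generator cannot
inherit a bug from the module it is meant to test.

**`gen_alignment(AlignmentRecipe)`** — defaults 23 homologs × 60 columns,
matching the study conditions. Background columns draw one category per
column and fill it with in-category residues; `noise=0.10` substitutes a
bounded number of rows (capped at n/4) with residues from other
categories; `gap_prob=0.05` introduces per-column gaps (capped at
(n−1)/2 so no column can trip the 50 % mask). Planted deviants place
`n_minority` homologs in the query's category and the rest in the
majority category, with no noise or gaps at that column, so the expected
score has the closed form of §2. Query gaps (off by default) are never
placed on planted positions. Returns the alignment plus a truth table
(position, expected score, status, planted flag).

**`gen_evalue_table`** — plants a winner per protein: winner E-value
log-uniform below `alpha/10^m`, runner-up = winner × 10^m × U[0.8, 1.2]
(so `round(log10)` recovers `m` exactly), remaining families uniform in
(max(0.06, runner-up), 1] or missing with probability 0.25. Note the
runner-up may itself be significant when `m` is small; only families
beyond the top two are guaranteed non-significant.

**`gen_trajectory(TrajectoryRecipe)`** — emits multi-model PDB text (no
binary fixtures) with 19 atoms in four well-separated groups: an N–H/O
hydrogen-bond system at the origin, two six-membered rings at (0, 50, 0),
a restrained atom pair at (50, 0, 0) and a probe pair at (0, 0, 50).
Defaults encode the study conditions: 50 frames; hydrogen bond present in
43/50 frames (86 %), broken frames violating either the distance or the
angle criterion (`hbond_off_mode`); rings stacked at 3.5 Å / 5°
(`deviant_trajectory_recipe` gives 5.79 Å / 52°, outside both
thresholds); restraint `r_i = 0.45 nm` with 9/50 frames (18 %) placed
outside the flat bottom; probe distances Gaussian with mean 7.7 Å and
SD 0.5 Å. Ground truth records the schedule percentages and the probe
statistics recomputed after rounding coordinates to the PDB's three
decimals, so recovery checks can be exact. Recipes that would place
distinct atoms closer than 0.8 Å (the N–H pair excepted) are rejected.

**What the generators do not emulate:** real sequence evolution
(phylogenetic correlation between rows, indel structure), HMM search
score distributions, solvent, thermal ensembles, or forces — trajectories
are scheduled geometric configurations, not dynamics. They exist to
provide exact ground truth, not realism.

## 6. Numerical choices

- Natural log for entropy; base invariance of rankings is tested by
  rescaling scores by ln 2.
- Kabsch via `numpy.linalg.svd` with explicit determinant correction.
- Population (not sample) standard deviation in `distance_stats`.
- Å→nm conversion factor 0.1 applied at the restraint boundary only;
  geometry is otherwise in Å.
- Acceptance checks of C¹ continuity use second-order one-sided finite
  differences, which are exact for the piecewise-polynomial restraint, so
  the tolerance (10⁻⁶ relative) tests the implementation, not the
  stencil's truncation error.
- Ranking base-invariance is asserted on sorted score sequences rather
  than argsort indices, so 1-ulp floating-point ties cannot produce
  spurious failures.

## 7. Limitations

- Conservation scoring without explicit annotation is a simple modal
  proportion, not a substitution-matrix-weighted measure.
- The exceptionality score treats columns independently; covarying pairs
  of positions are invisible to it.
- H-bond detection requires explicit hydrogens and classifies donors and
  acceptors purely by element (N/O), ignoring chemistry (e.g. amide N
  with no lone pair can still be scored as an acceptor).
- Ring planarity is assumed; strongly puckered rings get a best-fit
  plane without warning.
- The family screen consumes E-value tables; it does not run HMM searches
  itself.
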