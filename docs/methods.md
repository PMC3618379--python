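# Methods

This note records the models, conventions, parameter defaults and open
design choices behind `nmrval`, and what the synthetic test conditions do
and do not demonstrate about real archive data.

## Ensemble model and atom addressing

An ensemble is an ordered list of conformers with identical topology;
atoms are addressed by `(chain id, author residue number, atom name)`.
Insertion codes are rejected rather than folded in — keys stay
total-ordered and the author numbering is preserved verbatim.  Alternate
locations other than blank/'A' are dropped on reading (NMR entries rarely
carry altlocs); hydrogens are kept because they carry RDC vectors and
shift assignments.  Mismatched atom sets between models are a hard error:
every downstream quantity assumes a common key set.

## Dihedral order parameter

For residue dihedral type *i* with values γ_{ij} over N conformers,

    s_i = (mean_j cos γ_ij)² + (mean_j sin γ_ij)²,
    S² = (1/M) Σ_i s_i

over the M angle types defined for the residue (φ/ψ for proteins, α–ζ for
nucleotides).  Two forms of this statistic exist in the literature —
averaging per-angle order parameters, or pooling all M·N angles into one
resultant — and they differ whenever different angle types have different
spreads.  The per-angle average is implemented because it matches the
index structure of the defining sum (i over angle types, j over
conformers) and keeps each s_i an interpretable circular R̄² in [0, 1].
Angle types with any undefined value (terminal residues, missing atoms,
collinear geometry) are excluded from M; a residue with no complete angle
type gets a null S².  A single-conformer ensemble returns 1.0 with a
warning, since dispersion is unmeasurable.

S² is computed from internal coordinates, so it is invariant under global
rotation and blind to rigid-body motion: a hinge swing leaves S² ≈ 1 on
both sides of the hinge.  That is why clustering on pairwise Kabsch RMSD
is reported alongside it.

## Superposition, clustering, representative

Kabsch superposition uses the SVD of the covariance of centered
coordinates with the standard determinant-sign correction, guaranteeing a
proper rotation (det = +1); fewer than three points or a collinear set is
an error.  The pairwise model RMSD matrix (backbone atoms N, CA, C, O for
proteins; P, O5', C5', C4', C3', O3' for nucleic acids) feeds
average-linkage agglomerative clustering cut at a configurable RMSD
(default 2.0 Å, a sensible scale for typical solution ensembles).  Each
cluster's representative is its medoid — minimal summed RMSD to cluster
members — and the ensemble representative is the medoid of the largest
cluster; all ties break toward the lower model id so results are
deterministic.  The representative model anchors everything downstream
that needs a single conformer (secondary structure, accessibility, RDC
convention detection).

## Restraint violations

Sequence-separation classes: 0 → intra, 1–2 → short, 3–4 → medium,
≥ 5 → long.  An ambiguous restraint takes the maximum separation over its
member pairs and any inter-chain pair makes it long-range — the
conservative reading for "how much does this restraint pin down the
fold".  Ambiguous members are combined with r⁻⁶ sum averaging,
d_eff = (Σ d⁻⁶)^(−1/6), which is bounded above by the closest member and
monotone under adding members.  Bounds are closed: d_eff exactly at a
limit is satisfied.  Dihedral arcs run counter-clockwise from lower to
upper (wrap permitted), and the violation magnitude is the shortest
angular distance to the nearer endpoint, which is zero exactly on the
allowed arc and bounded by 180°.  Long-range counts credit both endpoint
residues of a long-range restraint, once per restraint per residue; the
alternative (once per member pair) over-weights methyl ambiguity and was
rejected.

## RDC tensor fitting

Observed couplings are first mapped to the N–HN scale with
(γ_N γ_H / r_NH³)/(γ_A γ_B / r_AB³); γ signs are retained (γ_15N < 0), so
normalized C–H couplings flip sign, as in the usual convention.  Defaults:
r_NH = 1.02 Å, r_CH = 1.09 Å, r_NC' = 1.329 Å, γ in 10⁶ rad s⁻¹ T⁻¹ —
all editable through the configuration; they are conventions, not
results.  Per model and medium the design matrix rows
(x²−z², y²−z², 2xy, 2xz, 2yz) against unknowns (Sxx, Syy, Sxy, Sxz, Syz)
with Szz = −Sxx−Syy are solved by SVD pseudo-inverse (rcond 1e-10); at
least five couplings are required, and a design condition number above
1e6 (e.g. near-parallel bond vectors) flags the fit as degenerate rather
than failing.  Eigenvalues are ordered |λ₁| ≤ |λ₂| ≤ |λ₃|; Da = λ₃/2 and
R = 2(λ₁−λ₂)/(3λ₃) ∈ [0, 2/3].  Q defaults to the original
rms(obs−calc)/rms(obs) normalization; the Da√(4+3R²) variant is available
as `q_value_da_normalized`.  Internuclear vectors come from each model's
coordinates with no librational correction.  Unit-convention detection
fits each medium both raw and pre-scaled and keeps the lower Q; with a
single RDC type the two are indistinguishable (the scale is absorbed by
the tensor) and raw is returned by convention, with both Q values
reported either way.

## Chemical-shift validation

The re-referencing offset per nucleus class is the median of
(observed − expected mean) over all class members with a reference entry.
A curated, correctly-referenced protein shift corpus is the ideal anchor
for this step; here the offset is instead computed robustly against
whatever reference table is supplied — a deliberate design choice that
makes the table pluggable.  Classes with fewer than 10 matched atoms
(configurable) keep offset 0 with a warning.  Z-scores use reference
entries conditioned on (residue type, atom, secondary structure,
accessibility bin) with at least 10 underlying observations
(configurable); |z| > 3 is an outlier (strictly greater — z = 3.0 exactly
is not flagged).

Secondary structure is assigned from the representative model's φ/ψ:
H for φ ∈ (−100, −30) and ψ ∈ (−80, −5); E for φ ∈ (−180, −45) and
ψ ∈ (90, 180] ∪ (−180, −150); else C, with termini C.  Relative
accessibility is per-residue Shrake–Rupley ASA (probe 1.4 Å, 256
quasi-uniform sphere points per atom, heavy atoms only — hydrogens
neither occlude nor contribute area) divided by the residue's theoretical
Gly-X-Gly maximum; below 0.20 is "buried".  Two burial bins and three SS
classes are deliberately coarse: they stay stable with small reference
tables.  Aromatic ring currents are not modeled; residues with any atom
within 5 Å of a PHE/TYR/TRP/HIS ring centroid are marked so outliers
there can be discounted.  The color ramp is piecewise linear in |z|:
green (0,255,0) up to 2, yellow (255,255,0) at 3.5, red (255,0,0) from 5,
continuous and hue-monotone in between.

## ROG roll-up

Per residue, triggers fire on restraint violations that exceed a
threshold in at least half the models (so a single flickering conformer
cannot dominate) and on shift Z-scores.  Defaults: red for > 0.5 Å /
> 20° persistent violations or |z| > 5; orange for > 0.3 Å / > 10° or
3 < |z| ≤ 5; green otherwise.  The aggregation is monotone — worsening
any single piece of evidence never moves a residue toward green — and the
thresholds used are embedded in the report so scores are self-describing.
These thresholds are this package's own defaults; they are deliberately
simple and configurable rather than a reproduction of any external
scoring scheme.

## Report

One JSON document with sections entry / ensemble / residues /
distance_constraints / dihedral_constraints / rdc / shifts / rog; absent
data types yield empty sections, never missing keys.  Serialization is
deterministic (sorted keys, NaN/inf mapped to null, UTF-8), so identical
inputs give byte-identical files; per-model violation detail is behind a
flag to bound file size.  A JSON Schema document ships in
`src/nmrval/data/report_schema.json`; `validate_report` performs the
structural checks in-package.

## Synthetic study conditions

The generator builds poly-alanine backbones from ideal helix internal
coordinates (φ = −57°, ψ = −47°, standard bond lengths/angles, NeRF
extension), optionally with one PHE whose ring exercises the aromatic
paths.  Default conditions: 20 residues, 10 models, 0.05 Å per-coordinate
Gaussian jitter (0.02 Å in the violation preset, so planted magnitudes
dominate the jitter; zero in the RDC preset, where recovery is checked to
numerical precision).  The two-conformation preset hinges the C-terminal
half by 90° about an axis perpendicular to the chain direction in half of
20 models — a rigid-body split far larger than the 2 Å clustering cut.
Planted features are exact by construction: a distance bound tightened
1.0 Å below truth, a ψ arc shifted 20° off truth, a Saupe tensor with
Da = 10 Hz and R = 0.3 in a seeded random orientation, per-class shift
offsets (1.7 ppm on aliphatic carbons), and shift outliers at +6 sd.
Shift noise is drawn at 1 sd per atom (the realistic condition for
recall/false-positive measurements); offset-recovery precision is
measured on the noise-free draw, where the median estimator is exact.
All randomness flows through one seeded generator per step, seeds are
recorded in file headers, and identical specs produce byte-identical
files.

What these conditions do not show: real ensembles have side chains,
loops, non-ideal geometry, correlated (not isotropic) coordinate
uncertainty, genuinely ambiguous NOE networks, sparse and biased shift
coverage, and reference tables estimated from heterogeneous corpora.
Passing here demonstrates the correctness of the computations and
bookkeeping under controlled truth, not archive-scale performance.

## Numerical choices and degenerate inputs

* Torsions via atan2 of normal-vector products; collinear geometry
  (cross-product norm² < 1e-10) is undefined, recorded as null with a
  warning, never an exception mid-pipeline.
* Kabsch requires two non-negligible singular values (relative 1e-9);
  reflections corrected by sign flip of the smallest singular vector.
* Angles are degrees in (−180, 180] at every interface; radians only
  inside computations.
* Effective distance rejects non-positive inputs; violation magnitudes
  are exactly zero on the feasible set.
* Reports carry null (not NaN) wherever a quantity is undefined:
  single-type Q comparisons, Pearson under zero variance, S² with no
  complete angle type, Z-scores without adequate reference.

## Known limitations

* Protein-only generator; the nucleic dihedral definitions are exercised
  on hand-built coordinates in the tests, not by the generator.
* No NMR-STAR/NEF input; the TSV dialects and PDB/mmCIF are the contract.
* No restraint-energy or information-content analysis, no shift
  prediction, no tensor prediction from molecular shape, no per-domain
  rigid-body detection — cluster membership is reported instead.
* Solvent accessibility ignores hydrogens and uses a single radius per
  element; relative accessibilities are capped at 1.
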