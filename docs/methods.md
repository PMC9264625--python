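# Methods

This note records the model underlying `facesym`, the defaults that matter,
what the synthetic generator does and does not emulate, and the choices made
where the design was genuinely open. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is quoted from
external data.

## The measurement model

Facial asymmetry is treated as deviation of a surface from its own mirror
image. All coordinates are millimetres; the 1 mm classification threshold
makes the unit semantic, so no unit metadata is read from files. Left/right
always means the subject's anatomical side.

**Mirror plane (P1).** Four midline landmarks (Tr, N, Sn, Li) over-determine
a plane; we use the total-least-squares fit (smallest principal direction of
the centred points), oriented right → left. Collinear midline landmarks are
a hard error: the plane would be unconstrained.

**Reflection and registration.** The whole mesh is reflected through P1 and
rigidly registered back onto the original. Reflecting the whole surface and
registering it is equivalent, for distance mapping, to mirroring each half
onto the opposite half, and avoids defining a cut boundary. Registration is
point-to-surface ICP: exact nearest point on the fixed surface for every
moving vertex, closed-form Kabsch/SVD rigid update, no scaling (a scale step
would absorb genuine asymmetry). The landmark-fitted reflection already
provides coarse alignment, so ICP starts at the identity. The RMS
point-to-surface distance is non-increasing by construction; iteration stops
when it improves by less than `tol` (default 1e-6 mm) or at `max_iter`
(default 100, warning + best transform on expiry). The plain closest-point
update converges linearly: on the synthetic face a 5°/2 mm perturbation
needs ≈ 270 iterations to converge fully (to ~2e-4 mm max vertex error);
after 100 it still carries ~0.1 mm. Recovery demonstrations therefore run
with `max_iter=400`; routine mirror-matching does not need micrometre
convergence because the threshold is 1 mm.

**Distance map.** Unsigned exact point-to-triangle distances (vectorised
closest-point-on-triangle with a KD-tree over triangle centroids pruning to
a provably sufficient candidate set), weighted by barycentric vertex areas
(one third of incident face areas). Area weighting makes percentages robust
to tessellation density; a vertex-count variant is available
(`weighted=False`).

**Degree of symmetry.** A vertex is symmetric iff its distance is *strictly
below* the threshold (default exactly 1.0 mm); the degree is the symmetric
area percentage. Whether the original protocol counted points or area is
unknowable; area weighting is the default because it is
tessellation-robust, and the whole-face degree is then exactly the
area-weighted combination of the regional degrees (a conservation law the
tests assert).

## Region partition

Planes P2–P7 derive from the landmarks: P2 is the TLS plane through the four
eye commissures (normal toward Tr = superior); P3/P4/P5 are its parallels
through Sn, Ch_L and Li; P6/P7 pass through En and Ch on each side,
constrained perpendicular to P2 and oriented away from the midline. Vertex
labels follow a fixed decision tree on the signed plane coordinates —
medial: forehead above P2, nose above P3, lip above P5, chin below; lateral:
forehead above P2, cheek above P4, lateral mandible below. Ties (a vertex
exactly on a plane) go to the inferior/lateral region; exactly on a vertical
plane counts as medial. This bounding table is the largest interpretive
choice in the package and is override-able (`assign_regions(...,
rule_fn=...)`).

**A geometric caveat.** "Through En and Ch, perpendicular to P2" defines a
sensible parasagittal wall only when Ch lies (nearly) vertically below En —
the facial-fifths canon that motivated these landmarks. If the En→Ch
segment has a lateral offset comparable to its depth offset, the constrained
plane degenerates toward a coronal wall and the medial/lateral split
collapses. The synthetic faces place Ch exactly below En (±16 mm at
reference scale); landmark files from other sources should respect the same
canon or supply a custom rule.

## Synthetic faces

The generator produces a height field z = f(x, y) over an elliptical domain:
an ellipsoidal dome (depth 45 mm over a 140 × 180 mm outline) plus
mirror-symmetric Gaussian features — two brows (3 mm), nose ridge (5 mm),
nose tip (9 mm), two lip rolls (3 mm), chin boss (5 mm) — sampled on a
49-per-axis grid (≈ 1 800 vertices, ~3 mm edges; odd count puts a vertex
column on the midline). f(−x, y) = f(x, y) exactly, so the base face is
perfectly symmetric and every landmark is analytic (midline landmarks at
x = 0; En/Ex/Ch at the feature ends). Amplitudes sit at adult-face
magnitudes; the defaults were fixed once, before any acceptance
measurement.

**Asymmetry injection** displaces vertices on one side of P1 along their
normals by δ·exp(−‖v−c‖²/2σ²), with c snapped to the on-side region vertex
nearest the region centroid so the peak displacement equals δ exactly. The
per-vertex displacement field is returned as ground truth. Because the
mirrored shell deviates both at the displaced vertices *and* at their mirror
images, ground-truth audits use the symmetrised field max(d(v), d(mirror v));
with that accounting the measured chin degree matches the predicted
sub-threshold area fraction essentially exactly (well inside the 3-point
audit tolerance).

**Cohorts** allocate exactly round(n·fraction) symmetric subjects; symmetric
subjects receive a sub-threshold injection (δ ∈ [0, 0.8] mm), asymmetric
ones one or two supra-threshold injections (δ ∈ [1.5, 5] mm, σ ∈ [8, 15]
mm) in lower-face regions (lip, chin, cheek, lateral mandible), with ±5 %
variation of face proportions. **Raters** are i.i.d.: each rating equals
the truth with probability p (default panels: 10 raters, p = 0.9).

What this world does *not* emulate: scanner noise and holes, texture,
expression, hair/ear confounds, landmark placement error, correlated rater
behaviour. A green test therefore establishes the geometry, the scoring
rule and the statistics — not robustness to real acquisition artefacts.
Notably, sub-threshold synthetic subjects score ≈ 100 % (real symmetric
faces average far lower), so cohort-level effect sizes here are larger than
clinical ones; only orderings and calibration properties carry over.

## Statistics layer

* **Consensus**: majority label where agreement ≥ 0.7 (with 10 raters, at
  least 7 must agree), otherwise excluded — the 70 % reading of the 7/10
  rule; the fraction is configurable.
* **Fleiss' κ** (two categories) summarises panel reliability; if every
  rating falls in one category, chance agreement is 1 and κ is reported as
  1.0 with a warning.
* **t-tests**: pooled variance is the headline (matching the named SPSS
  procedure), Welch available; a summary-statistics entry point reproduces
  significance calls from printed mean ± SD ± n. Zero variance in both
  groups degenerates to t = 0, p = 1 (equal means) by convention.
* **ROC**: symmetric is the positive class and a higher degree predicts it.
  AUC is the tie-half-credited trapezoidal area (≡ normalised Mann–Whitney
  U). Cut-offs scan SPSS-style midpoints between consecutive distinct
  scores; the Youden index J = sens + spec − 1 picks the cut-off, ties
  breaking toward the higher value.
* **Predictive values** from sens/spec and class sizes; **Pearson r** with
  the t-based two-sided p. In cohort runs the correlation pairs each
  retained subject's asymmetric-vote fraction with its whole-face degree,
  so a negative r reproduces the published sign convention.

## Numerical choices and degenerate inputs

* Degenerate (zero-area) faces are dropped at mesh construction; empty
  meshes, out-of-range indices and non-triangular faces are hard errors.
* Cropping keeps any triangle not entirely on the discarded side — no
  re-meshing; edge effects are small because scoring is area-weighted.
* Point-to-triangle distance is exact (Voronoi-region projection); the
  KD-tree pruning bound is `best-so-far + max triangle circumradius`, so
  the candidate set provably contains the optimum.
* Rigid transforms re-orthonormalise on composition to stop rotation drift.
* Regions with zero total weight report NaN degrees with a warning;
  single-subject groups report SD = 0 flagged with n = 1.
* All generators take integer seeds and are bit-reproducible; the pipeline
  embeds a config hash in its logs and bundles.

## Known limitations

* Rigid-only registration: a globally bent (e.g. scoliotic) face inflates
  distances everywhere rather than isolating the local deviation.
* The region rule table is a reconstruction from the plane definitions;
  other plausible boundaries (e.g. cheek/lateral-mandible split) would move
  regional — not whole-face — degrees.
* ICP has no outlier trimming; it is adequate here because shell and
  original are the same surface up to the injected deformity.
* The synthetic world's effect sizes are optimistic (see above); cohort
  statistics validate machinery and orderings, not clinical magnitudes.
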