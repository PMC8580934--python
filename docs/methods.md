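# Methods

## Scope and data model

`segrel` analyses the reliability of manual 3-D lesion segmentations in a
two-operator, two-session design. The unit of analysis is the *femur*: all
lesions segmented by one operator in one session are merged into a single
voxel set before any comparison, because operators frequently disagree on
lesion count (one large vs two small lesions) and the merged Dice is
invariant to that disagreement. Masks of one femur must share one voxel
grid — operators annotate the same CT scan, so no resampling or
registration is provided, and every metric is an exact voxel-set
operation. Masks are exchanged as NIfTI-1 volumes (any nonzero stored
label is in-set; spacing comes from the header in mm); the cohort is
described by a CSV manifest. Femurs missing any of their four
(operator, session) masks are excluded from paired analyses rather than
imputed, since every summary requires all four comparisons.

## Metrics

For masks *A*, *B* with voxel counts |A|, |B| and intersection |A ∩ B|:

- Dice coefficient DC = 2|A ∩ B| / (|A| + |B|), computed on counts so the
  (anisotropic) voxel volume cancels exactly.
- Non-overlapping segmentation volume |A| + |B| − 2|A ∩ B|, converted to
  cm³ with the voxel volume; algebraically (|A| + |B|)(1 − DC) as a volume.
- Mean pair volume (|A| + |B|)/2 in cm³, the size coordinate for the
  lesion-size stratification. For inter-operator rows this averages the
  two operators within a session; for intra-operator rows one operator's
  two sessions.

A pair with exactly one empty mask scores DC = 0 (the formula's value); a
pair of two *empty* masks is excluded with a logged reason rather than
scored 1 — a cohort artefact, and a silent 1.0 would inflate reliability.
Connected components (for lesion-count diagnostics only) use
26-connectivity; Dice never depends on this choice because lesions are
merged per femur.

## Summaries and inference

Group summaries are sample mean and sample SD (n − 1); an n = 1 cell
reports its SD as absent, and empty cells are absent rather than zero.
Because lesion types partition the cohort, the n-weighted mean of per-type
mean DCs equals the overall mean DC exactly; this identity is tested.

Thresholds follow the strict conventions of the field: DC > 0.7 is *good*
agreement (a value exactly 0.7 is not good), and the size strata are mean
pair volume > 60 cm³ vs the rest (exactly 60 cm³ falls in the small
stratum). Both thresholds are configurable.

Dice differences across the three lesion types are tested per comparison
set with the Kruskal–Wallis rank test (tie-corrected H, chi-square
approximation with k − 1 df, via `scipy.stats.kruskal`). Group sizes around
19/17/18 are comfortably within the approximation's range. The two
inter-operator sessions are flagged as the primary tests. The degenerate
all-tied input, where the tie correction divides by zero, is defined as
H = 0, p = 1 with a warning. The test suite cross-checks H against an
independent first-principles rank computation and verifies the test's
type-I error at α = 0.05 by null simulation.

Reports are written as CSVs plus a JSON carrying all numbers at full
precision and a 2-decimal presentation copy; rounding happens only at
report time.

## Synthetic cohorts

No public segmentation masks exist for this study design, and no ground
truth exists even conceptually — only operators' delineations. The
generator therefore produces a *hidden reference* lesion per femur purely
as a testing device (recorded in the truth table, never consumed by the
analysis) and derives the four observed masks from it.

**Study conditions (defaults).** 54 femurs (19 osteolytic, 17
osteoblastic, 18 mixed), 2 operators × 2 sessions, a 96 × 96 × 160 grid at
0.98 × 0.98 × 3.0 mm (CT-like anisotropy within the 0.86–1.27 mm in-plane,
2.5–3 mm slice range typical of such scans). Lesion volumes are log-normal
per type, moment-matched to means/SDs of 14.48 ± 13.83 cm³ (osteolytic),
33.35 ± 32.42 cm³ (osteoblastic) and 41.2 ± 27.47 cm³ (mixed); a normal
distribution would generate negative volumes since the SDs are of the
order of the means. Draws above 140 cm³ are redrawn so lesions fit the
grid.

**Reference lesion.** A randomly oriented ellipsoid with log-uniform axis
ratios in [0.5, 2], surface-roughened by a smoothed Gaussian field; the
level-set threshold is bisected until the voxelised volume is within 5% of
the draw, and the largest connected component is kept (roughness is halved
and the fit retried in the rare case this breaks the volume tolerance).

**Boundary perturbation.** Operator disagreement is modelled as coherent
boundary disagreement, not i.i.d. voxel noise: a candidate mask at noise
amplitude *a* (mm) is the level set of *signed distance + a · G*, where
*G* is a unit-variance Gaussian random field with ≈ 5 mm correlation
length. The level set is thresholded at the quantile that preserves the
(jittered) base voxel count, so perturbations neither balloon nor shrink
the lesion and the configured volume distributions survive arbitrarily
chained perturbations; a mean-one log-normal count jitter (SD 0.10,
clipped to the range compatible with the pair's Dice target, since a
volume ratio f caps Dice at 2f/(1+f)) keeps paired volumes realistically
unequal. The amplitude is bisected until the pair's measured Dice is
within ±0.03 of its target (±0.05 below 0.3) — a compromise between
runtime and calibration tightness.

**Pairing design.** The four measured pairs per femur are inter@1,
inter@2, intra@I, intra@II. Three are calibrated directly by the bisection
above: operator II's session 1 is a mild perturbation of the reference
(anchor, Dice 0.93), session 2 is perturbed from it to the intra-II
target, and each operator-I session is perturbed from the corresponding
operator-II mask to that session's inter target. The fourth pair
(intra-operator I) emerges from operator I's two perturbations sharing a
common systematic deviation field with weight 0.85 (one operator's
consistent reading of an ambiguous boundary): raising that weight raises
operator I's self-agreement toward the intra-II level, lowering it pushes
it toward the inter level. Calibrating the measured pairs directly — rather
than perturbing all four masks independently from the reference — is what
lets the realized inter-operator mean Dice track the configured target to
well within sampling error, which the calibration tests require.

Per-femur Dice targets are drawn as
*base = clip(target + slope · log₁₀(V / 20 cm³) + N(0, 0.15), 0.20, 0.96)*
with small per-pair jitter (SD 0.03); 20 cm³ is the cohort's n-weighted
geometric-mean volume, so the size effect is centred and does not shift
the overall mean. The defaults — inter target 0.55 → 0.52-ish realized
mean, intra-II boost +0.19, size slope 0.35/decade — reproduce the
qualitative structure typical of such studies (intra II > intra I ≈ inter;
large lesions more reproducible than small), not any specific cohort's
exact numbers. With probability 0.15 one of a femur's four masks is split
in two by carving a thin in-plane gap (lesion-count disagreement); the gap
is part of the calibrated candidate, so pair targets still hold (capped at
0.90 for the carved pair), and a gap on the anchor itself is carved after
calibration since the anchor-vs-reference pair is never measured.

**What the generator does not emulate.** CT intensities and HU-dependent
appearance; anatomically shaped (cortex-bounded) lesions; operator-specific
systematic biases in volume (operators differ only stochastically);
spatially varying slice spacing. Passing tests therefore demonstrate that
the *pipeline* computes agreement statistics correctly and that the
generator is statistically calibrated — not that any particular clinical
cohort's values are reproduced.

## Numerical choices and degenerate inputs

- Grids are compared with exact shape equality and 1e-6 mm spacing
  tolerance (NIfTI headers store spacing as float32).
- Quantile thresholding breaks ties in the distance map by flat voxel
  index, making every candidate mask an exact-count, deterministic
  function of the RNG stream.
- Bisections run at most 36 iterations with early exit at half tolerance;
  unattainable Dice targets raise an error carrying the best achieved
  value.
- All generation is a pure function of the config (including seed);
  identical seeds give byte-identical manifests and truth tables.
- Problem sizes in the test suite: unit tests run 6-femur cohorts on
  48 × 48 × 40 grids; the calibration checks run the full 54-femur default
  conditions over 20 seeds, the statistical scale at which a 3·SE
  equivalence band is meaningful.

## Known limitations

- The Kruskal–Wallis p-value uses the chi-square approximation; no exact
  permutation option is exposed (group sizes here make the difference
  negligible).
- No boundary-distance metrics (Hausdorff, average surface distance) —
  volume-based overlap is the chosen outcome, precisely because operators
  may disagree on lesion count.
- Table-style volume aggregation conventions differ between published
  reports; this package consistently uses the mean of the two paired
  masks' volumes and does not attempt to reproduce per-operator volume
  tables that mix sessions differently.
- Very low Dice targets (< 0.20) are not generated: at the cohort's lesion
  sizes they would require degenerate masks rather than plausible
  boundary disagreement.
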