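# Methods

This note documents the models and procedures implemented in
`bodymap`, the defaults they ship with, and what the synthetic cohorts
do and do not demonstrate about real drawing data.

## Drawing representation

A drawing session consists of four body views (front, back, left,
right). Each view is a row-major integer raster (origin top-left,
0-based indices) whose values are VAS levels 0–10; 0 means "not
drawn". The default canvas is 1280 × 800 pixels per view — the
acquisition tablet's screen in portrait orientation; the resolution is
a convention of this package, configurable everywhere. Sub-unit VAS
values from slider widgets are rounded half-up at ingestion, so all
stored intensities are integer levels.

Ink is only meaningful inside the body-outline interior. Out-of-outline
ink is treated as a validation error rather than silently clipped: the
acquisition app prevents it at the source, so its presence indicates a
corrupted or foreign file, and the analysis functions additionally
apply outline restriction defensively. Validation is report-based
(`validate_drawing` returns the complete list of violations) so that a
single malformed symptom does not mask other problems.

PNG serialization uses a single 8-bit gray channel with
level = round(255·VAS/10); decoding snaps to the nearest VAS level,
making the round trip lossless. Drawings exported by apps that encode
intensity as color saturation can be ingested via an HSV-saturation
decoder with a configurable transfer curve (linear by default — the
true curve is device-specific and must be calibrated). NIfTI export
wraps a raster as a single-slice volume with an identity affine and
nominal 1 mm spacing; the format is a carrier for neuroimaging cluster
tools, not a spatial claim.

## Reproducibility metrics

Multiple symptoms of one drawing are merged by per-pixel maximum VAS
before metric extraction. All overlap and cluster metrics operate on
the binarized merged map; the default binarization threshold is 0
("any ink counts"), exposed for sensitivity analyses.

Per view, the pipeline reports symptom extent (count of drawn interior
pixels), cluster count, intersection, union and Jaccard index of the
two sessions. Cluster counting uses 8-connectivity by default — the
2-D analogue of the 26-connectivity convention of common neuroimaging
cluster tools — with 4-connectivity as an option; the choice is
consequential (diagonally touching blobs merge under 8- but not
4-connectivity) and is surfaced in the CLI.

View exclusion: a view is excluded from a pair's analysis only when it
is blank in *both* sessions. A view drawn in exactly one session stays
in and contributes Jaccard 0, deliberately penalizing forgotten views;
the stricter blank-in-either rule is available as a switch because the
reporting convention differs between studies. Whole-drawing extent and
cluster totals sum over included views; the whole-drawing Jaccard
pools pixels across included views into a single ratio (per-view
values and their max/mean are also reported, since both granularities
appear in the literature). An undefined Jaccard (empty union)
propagates as missing — never as 0 or 1 — and is dropped from cohort
means.

## Agreement statistics

**ICC(3,1).** Two-way mixed model, single measure, consistency form:
with MSR and MSE the between-subject and residual mean squares of the
subjects × sessions ANOVA, ICC = (MSR − MSE)/(MSR + (k−1)·MSE). The
confidence interval maps the F-quantile bounds
FL = F/F(1−α/2; n−1, (n−1)(k−1)) and FU = F·F(1−α/2; (n−1)(k−1), n−1)
of F = MSR/MSE through (F−1)/(F+k−1). A constant matrix raises (ICC
undefined); a matrix with MSE = 0 returns ICC 1 with a degenerate CI.
Being a consistency coefficient, the estimate is invariant to a
constant shift of one session's column. The implementation is
cross-checked in the tests against an explicit-loop ANOVA oracle
(≤ 1e−10) and against pingouin's `intraclass_corr`.

**Bland–Altman.** Differences test − retest (absolute, or as percent
of the pair mean) against pair means; limits of agreement use the
conventional literal 1.96 multiplier on the sample SD (ddof = 1), not
a t-quantile. Percent mode is undefined when a pair mean is zero and
raises rather than guessing.

**Summary t tests.** Usability questionnaires are usually published as
per-item (n, mean, SD); the two-sample t test is therefore computed
from summary statistics. The default variant is the pooled-variance
Student test (the unqualified "t test" of the usability literature),
with Welch–Satterthwaite available; for the shipped comparison table
both variants round to the same reported p values. P values are
formatted journal-style (two decimals, three when p < .01, no leading
zero). Chi-square on contingency tables is Pearson's without Yates
continuity correction — the uncorrected statistic is what reproduces
published demographic comparisons of this kind.

**Sample-size planning.** The expected full width of the ICC CI at n
subjects and k sessions, planning value ρ, is
w(n) = 2·z·(1−ρ)(1+(k−1)ρ)·√(2/(k(k−1)n)); the planner returns the
smallest n ≥ 2 with w(n) ≤ the target width, guarded against float
rounding at the boundary. At ρ = 0.95, k = 2, α = .05 and width 0.1
this gives n = 15.

## Usability instruments

SUS: 10 items scored 1–5; odd items contribute (score − 1), even items
(5 − score); the sum × 2.5 gives 0–100 in steps of 2.5. Attrakdiff 2:
28 bipolar items on −3..3 averaged into four 7-item subscales
(pragmatic quality, hedonic quality identity/stimulation,
attractiveness); instrument variants order and orient items
differently, so the item → (subscale, polarity) mapping ships as an
editable JSON data file whose default is consecutive 7-item blocks
with positive polarity. ISONORM 9241/10: 35 items on −3..3 in 7
categories × 5 consecutive items, averaged per category. Missing items
are handled by per-item n in the comparison tables, never by
imputation.

## Synthetic cohort model

The generator produces test-retest pairs with known ground truth.

*Outlines* are deterministic schematic silhouettes (head, torso,
limbs from ellipse/rectangle primitives), one connected component
occupying 20–60% of the canvas, front/back two-limbed and the side
views a narrower profile.

*Test drawings.* Per view, the number of drawn clusters follows a
negative binomial with mean 4.8 and SD 6.0 — matching the over-
dispersed per-view cluster counts observed in pain-clinic populations
(per-view means roughly 4–6 with SDs exceeding the means); when the
configured variance does not exceed the mean the sampler falls back to
Poisson. Each cluster is a union of 1–3 filled disks with one VAS
level; the main disk's radius is lognormal (median 18 px on the
full-resolution canvas, σ = 0.5), satellite disks are constrained to
overlap the main disk so that a drawn cluster is one connected blob.
Cluster centers are sampled uniformly from the outline interior, and
distinct clusters may merge by overlap — as in real drawings, so the
drawn-cluster count is an upper bound on the connected-component
count. Clusters are partitioned among 1–3 symptoms whose textual
specifications are sampled from the shipped vocabularies.

*Retest perturbation.* Each test cluster is independently dropped with
probability 0.15 ("forgot a symptom"), otherwise translated by an
isotropic Gaussian offset (σ = 10 px) and grown/shrunk by a signed
Gaussian radius increment (σ = 2 px); per view, Binomial(n_clusters,
0.15) new clusters appear ("remembered a new one"), balancing dropout
in expectation. All retest ink is clipped to the outline. The
zero-perturbation setting reproduces the test drawing pixel for pixel.

These perturbation defaults are a deliberate calibration: they place
default cohorts in the regime clinical test-retest drawing studies
report — mean whole-drawing Jaccard near 0.45 (moderate overlap) with
extent ICC above 0.9 — so that the pipeline is exercised under
realistic signal-to-noise. Across master seeds the 25-patient default
cohort's mean Jaccard varies roughly between 0.42 and 0.48 and its
extent ICC between 0.90 and 0.99.

*Reproducibility.* One master seed; patient *i* uses the substream
`SeedSequence(seed, spawn_key=(i,))`, so cohorts are bit-reproducible
and enlarging a cohort never changes earlier patients.

*What this does not model.* No anatomy (dermatomes, innervation,
organ projections), no gender-specific outline geometry, no
intensity-gradient drawing styles, no correlation between symptom
specification and location, no doctor-vs-patient concordance, and no
learning or recall effects between sessions beyond independent
dropout/addition. Passing tests therefore demonstrate the correctness
of the measurement pipeline and the statistical machinery under
controlled conditions — not clinical validity of any particular
reliability figure.

## Numerical and testing choices

Problem sizes in the test suite are chosen for tight feedback: most
simulation tests run on a 160 × 100 canvas with proportionally scaled
blob radii, while the default-parameter regime check runs one full
25-patient cohort at 1280 × 800. Monte-Carlo checks are seeded and use
3-standard-error bands (count recovery) or the tolerance stated with
each test (ICC recovery bias < 0.02; CI coverage 95% ± 3% over 500
replicates). Geometry operations are verified against exhaustive
pixel-enumeration and BFS flood-fill oracles. Degenerate inputs raise
informative errors rather than returning conventional values:
constant ICC matrices, empty unions (missing Jaccard), zero-mean pairs
in percent Bland–Altman, and sub-64-pixel canvases.

## Known limitations

* The Attrakdiff default mapping is structural (blocks of 7, positive
  polarity); scoring a specific published administration requires the
  matching item order/polarity file.
* The saturation decoder's linear transfer curve is a placeholder for
  device calibration.
* Per-view ICCs on small cohorts can be non-estimable (fewer than two
  patients with the view included, or zero variance); they are
  reported as missing rather than interpolated.
* The ICC CI uses the standard F-bound interval, which is slightly
  conservative for very small n; no exact or bootstrap interval is
  provided.
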