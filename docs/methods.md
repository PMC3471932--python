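# Methods

This note documents the statistical procedures, the generative model behind
the synthetic plates, the numerical conventions, and the design choices made
where the underlying protocol left the design open.

## 1. Well statistics

### Signed two-sample KS distance

For a treated well with empirical CDF F_s (right-continuous, F(x) =
#{v ≤ x}/n) and the pooled in-plate negative-control CDF F_r, the statistic
is D = F_r(x*) − F_s(x*) at the breakpoint x* maximising |F_r − F_s| over
the union of both supports. It is exact (no asymptotic approximation) and
carries no p-value: it is used as a normalised effect size, not a test.
Conventions:

* **Sign.** D > 0 iff the sample is shifted toward higher values (its CDF
  lies below the reference). Toxicant-induced TMRM loss is therefore
  negative; the rare TMRM *increase* phenotype is positive.
* **Ties.** If several breakpoints attain the maximal |ΔCDF|, the smallest
  x wins, and the sign is read there. This makes the statistic fully
  deterministic.
* **Pooling.** The reference pools *all* negative-control cells of the same
  plate (wells are the unit of replication; fields are not treated
  separately). Plates without negative-control cells are rejected outright.
* **Exclusions.** Wells with fewer than 50 cells (default) are flagged and
  excluded from fingerprints with a recorded reason rather than silently
  dropped. The threshold is configurable; 50 cells bound the KS sampling
  noise at roughly 0.19 in the worst case (95th percentile ~0.12), well
  inside one activity-cutoff unit.

Properties asserted by the test suite: antisymmetry, identity, invariance
under strictly increasing transforms, monotonicity under stochastic
dominance shifts, and exact agreement with a brute-force breakpoint scan
and with the classical two-sample KS magnitude.

### TO-PRO-3 gate and viability

TO-PRO-3 mean intensity is bimodal: an intact-membrane (live) mode near
10^2.5 a.u. and a permeable (dead) mode near 10^4 a.u. The gate is found on
the plate-pooled log10 intensities: histogram with 0.05-decade bins,
Gaussian smoothing (σ = 2 bins), two most prominent peaks (prominence ≥ 10%
of the maximum, separation ≥ 0.5 decades), gate at the centre of the
density minimum between them. When bimodality is absent — an all-live
plate, or fewer than 100 cells — the default gate 10^3.25 ≈ 1778 a.u. is
used, and the method ("valley", "default", "fixed") is recorded in every
output. Viability is the fraction of cells at or below the gate, reported
both as a fraction and rescaled to 2f − 1 ∈ [−1, +1] so that it shares the
KS range inside fingerprints.

Replacing a by-eye gating step with the valley rule is a deliberate
determinism choice; the recorded `gate_method` makes the substitution
auditable.

### Z′ plate quality

Every control well contributes |D| of the TMRM peripheral integral against
the pooled negative control; Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| uses the
means and sample standard deviations (ddof = 1) of the positive- and
negative-control |KS| samples. Z′ here is a *robustness* readout — the
pipeline treats only its reproducibility, not its absolute value, as the
QC criterion, and reports per-parameter control CVs alongside.

## 2. SCRIT fingerprints

A fingerprint concatenates well statistics over an ordered component index:
parameter-major, condition (glu+ then glu−), dose ascending. KS parameters
enter as signed D; viability enters rescaled. The index is serialised with
the vector (TSV columns `param|condition|dose`), so any distance computed
downstream is reproducible from the file alone.

* Wells sharing (compound, replicate, condition, dose) — e.g. the two
  replicate dose rows within one plate — are averaged into one component;
  separate plate runs are separate biological replicates and yield separate
  vectors ("replicates are analysed independently").
* A vector with any missing dose×condition cell is excluded with the
  missing components listed; assembly is invariant to row order.
* Doses are matched after rounding to 6 decimals to absorb float noise in
  serialised dose series.
* No per-parameter standardisation is applied beyond KS normalisation and
  viability rescaling: both already live on [−1, 1], and rescaling
  z-scores would let noise-only parameters inflate distances. A config
  hook is the natural place to add it if other descriptors are mixed in.

**Primary screen calls.** The single-dose 7-parameter × 2-condition vector
(14 components) is called *active* when any |KS| ≥ 0.2, or when the live
fraction differs from the in-plate negative-control live fraction by ≥ 20
percentage points (= 0.4 on the rescaled scale). The viability baseline is
the control mean rather than the ideal 1.0 because even untreated wells sit
near 0.97 live. Inactive compounds are designated group IV.

**Replicate consistency.** All pairwise Pearson distances among one
compound's replicate vectors; any pair > 0.2 flags the whole compound as an
outlier and removes it (the distances are reported). A single replicate
passes with a warning.

## 3. Classification

* **Pearson distance** 1 − r ∈ [0, 2]. A vector with component variance
  below 10⁻⁶ has no defined correlation; the distance is set to 1 with a
  warning. This matters for near-constant inactive-compound fingerprints;
  in practice the shared viability offset keeps even group-IV vectors
  non-degenerate.
* **Hierarchical clustering**: average linkage by default (the linkage was
  an open choice; single/complete/ward are selectable), on the condensed
  distance matrix. The flat partition cuts at the smallest height yielding
  ≥ k clusters (default k = 5, matching the number of mechanistic groups);
  the cut is exposed in the configuration because the original choice was
  visual.
* **Classical (Torgerson) MDS**: eigendecomposition of the double-centred
  squared-distance matrix — deterministic, unlike stress-majorisation with
  random starts. Axes are ordered by eigenvalue; each axis' sign is fixed
  by making its largest-magnitude coordinate positive. If fewer positive
  eigenvalues than requested dimensions exist, the embedding shrinks with a
  warning.
* **Group assignment**: each flat cluster's medoid (minimum summed
  within-cluster Pearson distance; single-member clusters are their own
  medoid) is compared against reference fingerprints — by default the
  noise-free expected vectors of the five archetypes (§4). The cluster
  takes the nearest reference's label unless that distance exceeds the
  ceiling (default 0.8), in which case it is labelled `other` for manual
  review. Compound-level labels are the majority over the compound's
  replicate items.

The primary screen uses Euclidean distances (responses at one dose are
compared in absolute terms); the secondary screen uses Pearson distances
(dose-response *shapes* are compared).

## 4. Synthetic plates

The generator stands in for the wet-lab screen so every stage is testable.
Per cell, channels are sampled as:

| channel | model | untreated median | cell σ (ln) |
|---|---|---|---|
| TMRM peripheral integral | log-normal | 5×10⁴ a.u. | 0.50 |
| TMRM max pixel | log-normal | 8×10³ a.u. | 0.45 |
| Hoechst integral | log-normal | 4×10⁶ a.u. | 0.35 |
| Hoechst mean | log-normal | 6×10³ a.u. | 0.30 |
| nuclear area | log-normal, clipped to [20, 250] µm² | 110 µm² | 0.18 |
| nuclear circularity | logit-normal | ≈ 0.82 (logit centre 1.5) | 0.50 (logit) |
| TO-PRO-3 mean | 2-component log-normal mixture | live 10^2.5 / dead 10^4 a.u. | 0.25·ln10 |

Intensities are log-normal because fluorescence is positive and
right-skewed; TO-PRO-3 is an explicit live/dead mixture whose medians
bracket the 10^3.25 gate. Compound action multiplies each channel median by
1 − e(d), with e a Hill curve (EC50 in µM, slope default 1.5); negative
maximal effects encode intensity *increases* (the inverse-TMRM phenotype).
Circularity responds on the logit scale (shift −3·e), so toxicant-treated
nuclei become rounder while shrinking and brightening — the condensation
phenotype. The dead fraction follows its own Hill curve per condition.

Two well-level noise sources are deliberately separated:

* `well_sigma` = 0.045 (ln): per-channel staining/illumination factor
  applied to every well, the source of untreated-well KS spread;
  morphology channels use `morph_well_sigma` = 0.015 since geometry does
  not inherit staining variability (an intensity-sized well effect on the
  tight area distribution would swamp its KS).
* `effect_sigma` = 0.065 (ln): one response-strength factor per well
  scaling all of that well's dose effects and its excess dead fraction —
  treated wells vary biologically in how hard they respond; untreated
  wells are untouched.

These defaults were calibrated *jointly* so the simulated 48/48 control
plate yields Z′ ≈ 0.6–0.7 (the documented operating window of the assay)
while untreated wells stay far below the 20% activity cutoff. They were
then frozen; all reported behaviours (archetype recovery, replicate
reproducibility, activity calls) are measured at these settings.

**Archetypes.** I: TMRM/viability/condensation response present in glu+ and
strongly amplified (lower EC50, larger effects) in glu−. II: identical
strong response in both media. III: exactly flat in glu+, sharp (Hill 2)
late response in glu−. IV: flat everywhere. V: potent TMRM collapse in both
media with nearly no condensation; the dead fraction saturates at 0.5 in
glu+ (half of uncoupler-treated cells stay membrane-intact) and 0.95 in
glu−. An `inverse_tmrm` archetype (TMRM doubling with viability loss)
models the calcium-channel-blocker phenotype. Positive-control wells use
archetype V at 75 µM; negative controls use archetype IV at dose 0.

**Benchmark set.** `benchmark_models()` builds 3 compounds per archetype.
Within an archetype, potency varies by about one 1:3 dilution step either
way (EC50 × 0.4 / 1 / 2.5). Group-I compounds additionally differ in their
glucose-medium response — strengths 0.35 / 0.55 / 0.12 at EC50 0.6 / 3 / 5
µM, the third being rotenone-like, nearly silent in glucose — because that
heterogeneity is what the nutrient-sensitisation design exists to absorb:
with both conditions in the fingerprint the three still co-cluster (shared
early-saturating glu− signature), while glu+-only truncation scatters them,
reproducing the loss of the direct-toxin cluster when the differential is
discarded.

**Determinism.** Per-well streams derive from
`SeedSequence([master_seed, crc32(plate_id), crc32(well_id)])`, so a fixed
master seed gives byte-identical tables and editing one well never touches
another.

**What the generator does not emulate** — and hence what passing tests do
not show about real screens: spatial plate effects (edge evaporation, row
drift), channel–channel correlation within a cell (dead cells keep their
sampled TMRM), cell-cycle structure, compound autofluorescence and dye
interference (only an exclusion flag is modelled), incomplete dose
solubility, and inter-plate batch effects beyond the per-well factors.

### Field-image rendering

`render_well_image` paints a feature table into one synthetic field
(1000×737 px at 0.5 µm/px): a Hoechst disk per nucleus, TO-PRO-3 co-located
with the nucleus, TMRM in the perinuclear annulus, plus dim Gaussian
background far below the segmentation threshold. The painted disk radius is
pre-compensated for the outward bias of the smooth-then-threshold step
(≈ 2.5 − 5·t/v px for paint value v and threshold t), so the segmentation
round trip recovers each cell's area, Hoechst integral (over the expanded
measurement region), ring-integrated TMRM and TO-PRO-3 mean within 10%
(typically < 6%), and the cell count exactly for non-overlapping layouts.
Because the per-cell mean and max-pixel columns are sampled independently
of the integrals in the feature table, no single image can realise all
columns at once; in rendered mode `hoechst_mean` and `tmrm_max_pixel` are
derived from the painted geometry instead of matched. Cells are placed by
rejection sampling with non-overlapping measurement rings; unplaceable
cells are dropped with a warning and counted.

## 5. Segmentation

Mirrors the cytometer protocol on the Hoechst channel: 5×5 uniform low-pass
→ fixed threshold 2500 a.u. → connected components → watershed split →
area filter 20–250 µm². The watershed is seeded from maxima of the
Euclidean distance transform of the thresholded mask (minimum seed
separation 5 px ≈ the minimum-area radius), then run on the negative
distance: synthetic nuclei are flat-topped, so geometric seeding is the
deterministic choice that splits touching pairs at their waist and never
oversegments a single disk; the original instrument's seeding rule is not
specified beyond "watershed". Labels are renumbered in centroid scan order
for determinism.

Feature extraction: primary contours expanded by 4 px
(`skimage.segmentation.expand_labels`, nearest-label geodesic, so
overlapping expansions never double-count); the peripheral ring is the
14-px band beyond the expanded contour, excluding it, with contested
pixels again going to the nearest nucleus. Hoechst integral/mean and
TO-PRO-3 mean are measured on the expanded region; TMRM integral and max
pixel on the ring (the max-pixel region was not specified; it follows its
pairing with the peripheral integral and is configurable); area and
circularity on the primary region. Circularity is 4πA/P² with the Crofton
perimeter, clipped to 1 (discretisation can push a digital disk slightly
above 1). Pixels are treated as square 0.5 µm by default; the true
0.5×0.48 µm rectangle is available via `pixel_um`. Cells whose ring is cut
by the field border are flagged in a `ring_clipped` QC column.

## 6. Problem sizes and tolerances

The test suite and the examples in this note run at deliberately moderate
scale — 200–500 cells per well, the 5×3×4-replicate benchmark (~1.5M
simulated cells, a few seconds) — chosen so that sampling error is small
relative to every asserted margin; the signed-KS oracle check uses 1000
random pairs at n ≤ 50 where the brute-force scan is cheap and exact.
Stochastic assertions (Z′ band, archetype recovery ARI ≥ 0.9, replicate
distances < 0.2, activity-call error rates) hold across the seeds exercised
in the suite and were additionally spot-checked on neighbouring seeds
during development.

## 7. Known limitations

* The generator's effect sizes are qualitative archetypes, not fits to any
  compound; absolute KS magnitudes should not be read as predictions for a
  given chemical.
* Signed KS compares a well against a *pooled* control; systematic
  intra-plate gradients would bias all wells coherently and are neither
  simulated nor corrected.
* Group assignment needs reference fingerprints; for real data the
  references should be in-screen anchors (e.g. FCCP wells) rather than the
  synthetic archetype expectations used by default.
* The closed-form expected-KS oracle ignores the area clipping at the
  filter bounds (negligible at the default spread, exact elsewhere).
* Image rendering targets geometric fidelity of the measurement regions,
  not optical realism (no PSF, no photobleaching, no debris).
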