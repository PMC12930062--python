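# Methods

## Scope and data model

`synaptopy` quantifies excitatory-synapse markers in dual-channel confocal
z-stacks and scores complex sensory learning task (CSLT) session logs. All
image data live in a `VoxelGrid`: a non-negative float array indexed
`(z, y, x)`, 0-based, with voxel edge lengths `(dz, dy, dx)` in µm and
half-open physical extents `[0, n·d)`. A voxel index *i* maps to physical
coordinate *i·d*. The default calibration follows the targeted confocal
acquisition — 0.30 µm z-steps over 30 planes and 60.13 × 60.13 nm pixels at
1024 × 1024 — treated as configuration, with the pixel size taken as
authoritative for physical conversions. Intensities stay in native units
(photon counts, camera ADU) until normalization.

## Puncta detection

Each channel is processed independently:

1. **Percentile normalization** maps intensities to [0, 1] between the
   `p_low` = 0.1 and `p_high` = 99.9 percentiles of the whole stack
   (clipped; a degenerate range maps to 0). Per-stack normalization makes
   the downstream thresholds unit-free and cancels affine gain/offset
   differences between samples exactly; whether a cohort-wide normalization
   would be preferable is a protocol question the package leaves to the
   caller (the percentiles are parameters).
2. **White top-hat**, per z-slice, with a disk of radius 8 px (~0.5 µm):
   removes background structure larger than a punctum, including smooth
   gradients, while passing sub-diffraction spots.
3. **Adaptive Wiener denoising**, per slice, 3 × 3 window:
   `out = m + max(s² − ν, 0)/s² · (in − m)` with local mean `m`, local
   variance `s²`, and noise power ν estimated as the mean local variance
   when not supplied. Slices are edge-replicated before filtering so local
   statistics see no artificial zero border; a noiseless constant region is
   preserved exactly.
4. **Blob response**: per slice, Gaussian smoothing at scale σ followed by
   the discrete 5-point Laplacian, negated and scale-normalized
   (`−σ²∇²`), maximized over σ ∈ {1.5, 2, 3} px. These scales bracket
   puncta of roughly 0.2–0.6 µm diameter at 60 nm pixels. The discrete
   Laplacian stencil sums to exactly zero, so flat input yields exactly
   zero response (a truncated analytic LoG kernel leaves a small DC bias).
5. **Candidate mask** at `response_threshold` = 0.06 (normalized-intensity
   units), then a 3 × 3 **median filter** on the binary mask to remove
   speckle.
6. **Component linking**: 8-connected components per slice become 2D
   footprints; a component extends the punctum whose previous-slice
   footprint it overlaps by ≥ 1 px. Conflicts resolve to the larger pixel
   overlap, then the lower punctum id, and each punctum gains at most one
   footprint per slice, so z-runs stay contiguous with one footprint per
   plane — the representation volumetric colocalization needs.
7. **Quality filter**: keep puncta with 30–1500 voxels and mean normalized
   intensity ≥ 0.05. The bounds were chosen on generator output at the
   reference condition (signal-to-noise ratio 5): spurious noise components
   are small, so a permissive mask threshold combined with a size floor
   separates cleanly; a 0.3 µm punctum spanning 3–5 slices occupies ~60–150
   voxels.

Punctum measurements: intensity-weighted centroid (µm, on the normalized
intensities), voxel count, volume = voxels · dz·dy·dx, mean normalized
intensity, and peak blob response. Mean intensity is measured on the
normalized (not raw, not background-subtracted) values, and this choice is
recorded in the output metadata via the stored parameters.

Detection is deterministic, and invariant to affine intensity transforms of
the input by construction of step 1.

## Colocalization

The overlap volume of a pre/post pair is
`Σ_z |A_pre(z) ∩ A_post(z)| · (dx·dy·dz)` over slices where both have
footprints; it is zero when z-ranges or in-plane footprints are disjoint.
All positive-overlap pairs (default minimum: 1 voxel, configurable) are
matched **one-to-one, greedily by descending overlap volume** (ties broken
by ascending pre id then post id). One-to-one matching keeps "number of
colocalized puncta" well defined and ≤ min(n_pre, n_post); greedy matching
can in principle fall below the maximum-cardinality matching, and the test
suite bounds it against a brute-force oracle on small instances. Counts,
total/per-pair overlap volumes, and per-channel mean punctum intensities
are emitted per image.

## Aggregation and ROUT outlier screening

Per mouse × ROI (medial/ventral orbital cortex), each metric is averaged
over the available images — nominally 2 hemispheres × 2 sections; missing
replicates simply reduce the divisor, and incomplete metadata flags the
image as one of the available replicates.

Group value lists are screened per group × ROI cell with the ROUT
procedure reduced to the univariate case: the "robust regression" is the
constant model (median, K = 1 parameter); residual scale is
RSDR = P₆₈.₂₇(|r|) · n/(n − K); residuals ranked by decreasing magnitude
get two-tailed t p-values (|r|/RSDR, df = n − K) and the rank-i value —
together with all larger residuals — is flagged when
p_i < α_i = (Q/100)·(n − i + 1)/n, with Q = 1% by default. Identical
values are never flagged. This follows the published description of the
method; proprietary small-sample corrections in commercial implementations
are not reproduced, so exact agreement with them is not claimed. Measured
behaviour at Q = 1%, n = 12: ~0.7–0.8% of clean normal values flagged,
and a planted 8σ outlier caught in effectively every replicate (the
acceptance script recomputes both). Group summaries report mean, SEM
(ddof = 1), and n after removal.

## CSLT scheduling and scoring

A daily session is 4 unscored free trials (each distractor-pairing × side
combination once, shuffled) followed by up to 30 closed trials with exactly
15 left- and 15 right-rewarded, no more than `max_run` = 3 consecutive
same-side trials, generated by seeded constrained sampling (weighted by
remaining side counts, full restart on dead ends; deterministic per seed).

The learning criterion is read as: the earliest closed trial *t* such that
some window of 8–10 consecutive closed trials ending at *t*, wholly within
one session, contains ≥ 8 correct choices. Windows never span sessions,
matching the rule that the consecutive-correct count resets at a new day's
session; omissions (no choice within 120 s) are non-correct and count as
errors. The alternative reading — a strict run of 8 consecutive correct
choices — is available via `strict_run=True`; the window reading is the
default because "8 correct in 8–10 consecutive trials" describes windows,
not runs, and criterion detection is verified against an exhaustive window
enumeration on all short sequences. Stage scores: total closed trials up to
and including the criterion trial summed across sessions, total errors
(incorrect + omission) among them, and the median latency over those trials
(omissions excluded — they carry no latency). Free trials never enter
scores, so the free-trial omission-as-incorrect rule has no downstream
effect.

## Synthetic ground truth

**Stacks** (`gen_stack`): puncta are separable profiles — isotropic
in-plane Gaussian (σ ~ U(1.5, 2.5) px) and triangular z-profile over 3–5
slices — on a background of 20 counts plus a 10-count linear ramp, with
Poisson shot noise and Gaussian read noise (SD 2). SNR is defined as peak
amplitude over the background noise SD √(base + gradient/2 + read²);
amplitudes are jittered ±20% around `snr × noise SD`, default SNR 5.
`⌊f·min(n_pre, n_post)⌋` post puncta are planted within 1.5 px (in-plane,
same z) of a pre punctum; **all other centers keep ≥ 12 px in-plane
separation**, so a cross-channel overlap exists iff the pair was planted —
without this exclusion the planted fraction *f* would not be a well-defined
ground truth, since ~15% of "non-colocalized" puncta would overlap by
chance at the reference density. The default frame is a 256 × 256 × 15 crop
of the full acquisition geometry so studies run in seconds; the full
1024 × 1024 × 30 frame is available (`StackGeometry.full_frame()`).

The generator does not emulate: a realistic 3D point-spread function
(puncta are separable, not Airy), spectral bleed-through between channels,
tissue autofluorescence texture, or spatially varying labeling efficiency.
Recovery results on it therefore demonstrate the pipeline's correctness and
calibration on its stated object model, not performance on tissue.

**Behavior** (`gen_behavior`): per closed trial *t* (cumulative across
sessions) the choice is correct with probability
p_t = p_∞ − (p_∞ − p₀)·e^(−t/τ) (defaults p₀ = 0.5 chance start,
p_∞ = 0.95, τ = 10 trials — a learner that typically passes within one
session); omissions are drawn independently (default 1%, reflecting their
reported rarity); latencies are log-normal (median 12 s, log-SD 0.5,
capped at the 120 s limit). Sessions follow the 4-free + 30-closed
structure with next-day continuation, up to 5 days.

## Problem sizes and numerical choices

Reference studies use the 256 × 256 × 15 frame with 150 puncta/channel
(≈ 0.5 puncta/µm² per channel, at the upper end of plausible synaptic
densities) — one stack in ~2 s — and 5-seed averages for recovery numbers;
the ROUT studies use 1,000 replicates of n = 12 (a typical group size);
the behavioral study 100 simulated mice. The bundled demo cohort
(2 groups × 8 mice × 2 ROIs × 4 images) mirrors a full experiment's data
volume. Centroid-to-truth matching uses greedy nearest one-to-one pairing
with a 3-voxel radius. Volumes are computed as `count × (dz·dy·dx)`
throughout so bookkeeping identities hold to machine precision. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
reruns are bit-identical, including the pipeline's CSV outputs.

## Known limitations

- Detection is 2D-per-slice with z-linking, not full 3D filtering; the
  0.30 µm z-step undersamples axially, and heavily elongated axial
  structures may fragment.
- Greedy matching is not guaranteed maximum-cardinality (bounded against
  the exact oracle in tests; differences are rare at realistic densities).
- The ROUT univariate reduction approximates unpublished commercial
  internals; flag sets near the decision boundary may differ from them.
- Default detection parameters were calibrated on the synthetic object
  model; real tissue will need parameter review (all are exposed on
  `DetectionParams`).
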