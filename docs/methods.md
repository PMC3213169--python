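# Methods

This note documents the models and numerical choices behind `stripeflow`:
what the synthetic-data generator emulates, how the analysis pipeline makes
its measurements, which parameters matter, and what a green test does and
does not establish.

## 1. The generative expression model (`synth`)

### Resolved pattern

Expression along the anteroposterior axis (x, in % egg length) at
developmental time t is a baseline plus seven asymmetric-Gaussian stripes
and one broad anterior "shoulder":

    I(x, t) = b + Σₛ Aₛ(t) · exp(−(x − μₛ)² / 2σₛ(x)²)
                + S(t) · exp(−(x − (μ₂ − 3.5))² / 2·2.5²)

with σₛ(x) the anterior or posterior width depending on side.  Defaults:
μ = (31, 40, 47.5, 55, 62.5, 70, 77.5) % EL, all widths 1.8 % EL, baseline
b = 0.05.  These mirror the canonical seven-stripe geometry (stripe 2 near
40% EL, the 1–2 interstripe wider than the rest); none of them is a
published measurement — the published evidence for stripe amplitudes and
widths is figure-only, so these are free parameters chosen once to be
realistic and are documented as such.

Amplitude trajectories Aₛ(t) are piecewise linear at 3-min knots.  The
genotype presets encode the qualitative maturation contracts:

| preset  | A₂/A₁ over 30–48 min | shoulder S(t) | positional SD σ_pos(t) |
|---------|----------------------|---------------|------------------------|
| WT      | 0.55 → 1.00 (rises)  | 0.22 → 0.03 (anterior border represses) | 1.5 → 1.2 % EL |
| MSE     | 0.72 → 0.50 (falls)  | 0.03 flat (symmetric borders) | 1.2 → 2.2 % EL (grows) |
| INV_MSE | ≈ 0.75 flat          | 0.22 → 0.16 (incomplete repression) | 1.5 flat |

The shoulder raises the 1–2 interstripe floor and thereby sets the
anterior/posterior border-height asymmetry (relative repression); its decay
in WT reproduces the progressive repression of the anterior border, its
persistence in INV_MSE the visibly derepressed border, and its absence in
MSE near-symmetric borders.

### Stripe emergence

Early in cycle 14 the pattern is a broad domain, not discrete stripes.
Each interstripe valley k–(k+1) has a window [μₖ+0.8, μₖ₊₁+0.6] that is
replaced by a straight descending chord (its endpoints on the resolved
curve) and cross-fades to the resolved shape over 2 min after a
per-embryo onset time.  Before the onset the window is monotone — no local
minimum exists, and the enclosed peak is a shoulder, not a maximum; the
minimum and the stripe peak are born as a pair as the blend passes the
detectability threshold.  Onsets for the 1–2 and 2–3 valleys are drawn per
embryo (Normal, per-preset means/SDs), so the incipient-stripe time and the
border order (which valley resolves first) are exact model properties.
Preset onset means give initiation mostly before 30 min, an
anterior:posterior first-border bias of roughly 2:3 for WT, 2:1 for MSE,
and a stronger posterior bias for INV_MSE; valleys 3–4 … 6–7 follow the
2–3 onset with fixed lags (the posterior pattern matures later).

### Embryo-level variability and noise

* Positional jitter: one standard-normal draw z per embryo shifts the whole
  pattern rigidly by z·σ_pos(t); a time-dependent σ_pos makes the
  across-embryo positional SD grow (MSE) or shrink (WT) while each embryo
  remains internally consistent.
* Amplitude variability: a per-embryo multiplier on A₂
  (Normal, CV 0.15, floored at 0.2) models embryo-to-embryo differences in
  stripe-2 strength that survive within-embryo normalization.  With the
  ≈0.5 difference in final relative activation between WT-like and
  MSE-like presets this puts the group separation near three phenotype
  SDs at the final timepoint.
* Nucleus noise: iid Gaussian (σ_n = 0.05 of the normalized scale) added
  per nucleus, clipped at zero.  Spline residuals at the extrema then come
  out at ~5% of the stripe-1 peak — the same order as the ~10% mean
  spline error reported for this class of live-imaging data.
* Temperature: the 29C presets compress developmental time by the ratio of
  cellularization landmark times, 38.2 min (25C) / 30.6 min (29C) ≈ 1.25,
  and report over 30–39 absolute minutes; the MSE-29C preset initiates
  earlier (in absolute time) and loses its anterior-first bias.

### Image scenes

512×512, 16-bit frames every 3 min, anterior left, dorsal up.  A scene is
an ellipsoidal embryo (semi-axes 230×115 px) with: a cortical monolayer of
nuclei (radius 4 px, 110 by default, equal arc spacing on the centerline,
infeasible packings rejected), cortical cytoplasm at 0.5 of nuclear
intensity filling the band, smooth interior yolk autofluorescence, a
bright 2.5 px vitelline ring just outside the cortex, per-pixel Gaussian
noise and 16-bit quantization.  Reporter nuclei carry the 1-D model value
at the nucleus's AP position (plus nucleus noise).  Scheduled membrane
artifacts draw a ~2.4 px dark line through a nucleus perpendicular to the
radial direction, splitting it into a yolk-facing and an outside-facing
half; the line dims the nuclear channel only — reporter disks are left
intact so fused-label means stay comparable to truth (a documented
simplification).  The seed fully determines the output.

What the generator does **not** emulate: optics (PSF, z-sectioning),
photobleaching, gastrulation movement, tracking across frames, and any 2-D
(AP×DV) expression structure.  Green pipeline tests therefore establish
correctness of the measurement machinery on a stated world, not
performance on real movies.

## 2. Segmentation (`segment`)

Cortical mask: gray-scale top-hat (disk radius 2× nucleus radius) removes
the broad yolk glow; Otsu thresholding keeps the bright small-scale
structures; binary erosion (radius 2) followed by morphological
reconstruction deletes the thin vitelline ring (which erodes away
completely) while regrowing everything else; a closing (1.5× radius)
solidifies the band.  Watershed: markers are the h-maxima of the
Gaussian-smoothed frame (σ = 0.4× nucleus radius) inside the band, with
prominence threshold 4% of the band's dynamic range; the watershed floods
the negated smoothed image over the whole band, so basins partition the
cortical mask and genuinely border the yolk cavity and/or the exterior.
Two numerical choices deviate from first guesses and matter: smoothing at
σ = radius/2 erases the intensity dip across membrane-split half-nuclei
(no oversegmentation ever occurs, making the fusion rule vacuous), and
absolute-threshold markers either drop dim split fragments or fire on
cytoplasm noise — hence 0.4× and prominence-based markers.

Fusion: merge every adjacent pair whose shared watershed line is ≥ 2 px
(measured as the larger one-sided count of 8-neighbor boundary pixels; a
single diagonal contact scores 1) and whose members lie on opposite faces
of the band (one touches only the yolk cavity, the other only the
exterior, by 4-connected adjacency to the complement components).  Merging
is union-find followed by recomputation, iterated to a fixpoint; a merged
nucleus touches both faces and cannot re-qualify, so the procedure is
idempotent and a coarsening of the input partition.

Quantification: each basin's *core* (basin ∩ the bright nuclear foreground
from a second Otsu restricted to band pixels) is the nucleus mask; means
and unweighted centroids are computed over the core, which keeps the
dimmer cortical cytoplasm out of the per-nucleus mean.  Pixel indexing is
0-based row-major.

## 3. Profiles and features (`quantify`)

Times are registered to the completion of the 13th nuclear division
(±0.5 min, carried as metadata).  Edge profiles project one side's nuclei
(ventral by default — the more mature pattern) onto the AP axis given the
pole coordinates; duplicate AP positions within 0.1% EL are averaged;
profiles with fewer than 30 nuclei are flagged.

The smoothing spline minimizes p·SSR + (1−p)·∫f″², implemented via the
penalized formulation SSR + λ∫f″² with λ = (1−p)/p (identical minimizer;
p = 1 → λ = 0 natural interpolating spline, p = 0 → closed-form
least-squares line).  Both limits are verified to 1e-8.  The p = 0.5
default is convention-dependent (different tools scale the roughness term
differently); x is in % EL and y on the [0, 1] normalized intensity scale
by contract, which fixes the units the trade-off operates in.

Extrema are the exact polynomial roots of f′ (endpoints excluded,
tangencies dropped, alternation enforced); border positions are the unique
Brent-solved crossings of f with the mean of adjacent extremal values
(uniqueness follows from strict monotonicity between extrema and is
asserted on a dense grid in tests).  Adjacent extremal pairs shallower
than a prominence threshold (0.06 on the normalized scale in the phenotype
pipeline) are treated as noise: at σ_n = 0.05 the spline at λ = 1 carries
residual wiggles of up to ~0.05 prominence, while genuine young borders
start near 0.1.  This threshold trades early-detection latency (≤ 1 frame)
against false minima.

Stripe identity: at the most mature timepoint, maxima above 25% of the
tallest peak are numbered anterior→posterior; because the pattern is
quasi-periodic, a gap between consecutive anchored peaks close to a
multiple of the median interstripe distance skips the intervening ids, so
an undetectably weak stripe stays missing rather than silently renumbering
its neighbors.  Identities propagate to other timepoints by
nearest-position matching with a 3% EL gate.  The flanking interstripe
minima are tracked the same way, so a border can be present before the
stripe's own peak resolves.

## 4. Phenotypes and statistics (`phenotype`)

Relative activation and repression are computed per embryo and timepoint;
a missing feature drops that cell, never the embryo (sample sizes are
bookkept per timepoint).  Border-height ratios above 10 (configurable),
including infinities from a zero posterior height, are flagged for
exclusion from time-series plots but retained in all statistical testing.
Incipient-stripe time is the earliest timepoint at which both flanking
minima are present and persist, tolerating at most one missing later
timepoint; border order compares the first stable detections of the two
minima with the same persistence rule and returns unresolved on same-frame
detection.  Positional variation is the n−1 sample SD over embryos.

The rank-sum test is two-sided throughout.  For min(n) ≤ 8 the exact null
distribution of the rank sum is computed by a subset-sum recursion over
midranks (mathematically identical to enumerating all C(N, n₁)
assignments, ties handled by midranks); otherwise the normal approximation
with tie correction is used.  Chi-squared tests are Pearson with
df = classes − 1 and no continuity correction.  The binomial SD of a
rescue percentage is 100·√(p̂(1−p̂)/n) with p̂ = observed/expected capped
to [0, 1] and n the expected count — the capping makes the SD zero at
≥100% rescue, a deliberate consequence of the formula.  Temperature
comparisons support absolute time and scaled time
(t × 38.2/30.6) as declared modes.

## 5. Constructs (`constructs`)

Coordinates are 1-based inclusive.  The bundled reference annotation is a
synthetic placeholder: it carries every printed length (798 bp span,
26/18 bp conserved border blocks, 33 + 211 = 244 bp deletions, 480 bp
classic element + 29 bp extension = 509 bp minimal element) but invented
endpoints and a fixed-seed random sequence, because the real sequence and
exact fragment endpoints are not derivable from the printed arithmetic
(798 − 244 = 554 ≠ 509; the relation between the deletions and the
minimal-element endpoints requires the original supplementary sequence).
Real sequence work should load a user FASTA and interval table.  Sites
straddling a deletion edge are an error, not a truncation — the published
deletions were designed around intact sites.  Inversion is an in-place
reverse complement with end-for-end site remapping and strand flips;
overlap with the protected border blocks is an error.

## 6. Known limitations

* The spline estimator carries a deterministic attenuation bias of ~1%
  (relative) on peak ratios, because the stripe-2 neighborhood has higher
  spatial-frequency content than stripe 1's; it is inherent to smoothing
  at p = 0.5 and affects real-data estimates equally.
* The 1-D profile generator and the image renderer share the same model
  but different nucleus densities are possible; the default 1% EL profile
  spacing corresponds to a denser sampling than one midsagittal edge of
  the default scene provides.
* Mendelian machinery models sexes as labels on counts (all assayed loci
  autosomal) and supports no X-linkage.
* The "1/9 hemizygotes in the standard assay" sometimes quoted for this
  cross design corresponds, under straightforward Mendelian arithmetic
  with both balancer homozygote classes lethal, to the homozygous-rescue
  class (1/9) — the hemizygous class is 2/9.  The package computes and
  reports the arithmetic; it does not assert the quoted figure.
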