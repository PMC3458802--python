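# Methods

This note records the models, defaults and numerical choices behind
`softagar`, and what the synthetic-data validation does and does not show.

## Assay model

A chip holds up to 50 wells (3 mm diameter in the physical assay); each
siRNA condition occupies a block of replicate wells (default 5), including
a pooled negative-control block (no-siRNA + non-targeting). Each well is
seeded with 500-700 cells suspended in soft agar and imaged as a short
brightfield z-stack at day 2 and on later days. Analysis treats day 2 as
the baseline for every metric, because day-2 images contain clumped and
overlapping cells whose effect cancels under differencing.

Growth is modelled per object: a seeded cell either founds a colony (with
condition probability `colony_forming_fraction`) or stays at single-cell
area. A colony's area follows `A_i(t) = A_i(2) · exp(k_i (t − 2))` with
per-colony rates `k_i` lognormal around the condition rate `k` (CV
`rate_cv`, default 0.2) scaled by a per-well lognormal factor (CV
`well_cv`, default 0.05) that creates replicate scatter. The doubling time
is `t_d = ln 2 / k`. Optional per-object death is available
(`death_rate_per_day`, default 0 - published protocols do not quantify
colony loss, so it is off unless a user wants it).

## Synthetic well rendering

* **Raster.** Default 600×600 px frame with a 560 px circular well; the
  real 3 mm well at a 4× objective would be ~1900 px, so the default is a
  ~1/3-scale raster chosen to keep simulations fast. `pixel_size_um`
  (default 5.36 µm/px at that scale) is carried through so areas can be
  reported in µm². The frame outside the well is rendered as a darker rim,
  which forces the analysis to honour the footprint restriction.
* **Objects.** Dark disks (intensity `cell_level` = 80) on a bright noisy
  background (200 ± 5, 8-bit), radius from the true area. Colony founders
  appear at day 2 as clusters of `founder_cell_multiple` (default 4) cell
  areas - the day-2 clumping that motivates baseline differencing. Disk
  centres are uniform in the well; merging at late days is emergent disk
  overlap, not an explicit event, reproducing why late colony counts are
  excluded.
* **Focus.** Each object is sharp in exactly one uniformly assigned slice.
  In other slices it appears Gaussian-blurred with σ proportional to slice
  distance (2 px per slice) *and* amplitude-attenuated (×0.35 per slice
  step). The attenuation is deliberate: with blur alone, defocused copies
  put dark halos around every object in the minimum projection, dilating
  segmented particles and breaking the rendering round trip; attenuated
  copies stay above any sensible threshold, so the projection recovers
  exactly the sharp footprints while every object is still "present" in
  all slices. This is a rendering model, not physical optics (out of
  scope), and is the package's own resolution of the focal model.
* **Fluorescence.** A labeled fraction of cells draws per-cell intensity
  from N(150, 17), the rest from the non-targeting-like N(100, 10)
  (arbitrary units, chosen overlapping enough that the mean + 2 SD rule is
  non-trivial); disks are drawn at those intensities on a near-zero
  background so brightfield particles serve as measurement masks.
* **Determinism.** Every (well, stream, day) owns a `SeedSequence`-derived
  generator; identical configs give byte-identical screens regardless of
  the order in which stacks are rendered.

## Segmentation choices

* Threshold: Otsu on within-footprint intensities (parameter-free and
  standard; "per-image" rather than global, flagged for sensitivity
  analysis). For integer images the implementation maximises between-class
  variance over integer thresholds exactly, with foreground = values ≤
  threshold (cells are dark). A fixed threshold is available via config.
* A guard rejects weakly bimodal splits (class-mean separation ≤ 3 pooled
  within-class SDs): a featureless noise image yields an empty mask rather
  than hallucinated foreground, since any split of a normal sample
  separates its halves by only ~1.6σ.
* Connectivity: 8-connected, so diagonal cell contacts do not split
  particles. Debris: components < 4 px are dropped (configurable).
* Particle areas are raster pixel counts. For disks at generic sub-pixel
  centres the count is unbiased with a boundary jitter of order the
  perimeter, hence the ±15% round-trip tolerance for small objects; ratio
  metrics (percent of control) are insensitive to this.

## Statistics choices

* Normalisation is within-chip: each well ÷ mean of that chip's pooled
  negative controls × 100. Doubling time is normalised the same way.
* "Appropriate t-tests" are Welch, two-sided, on per-well normalised
  values vs the pooled control wells, uncorrected by default (raw p < 0.05
  is the assay's own criterion); Benjamini-Hochberg is available via
  `p_adjust="bh"`. The 2 SD hit band uses the SD of per-well control
  values, not the SEM.
* Z′ uses per-well normalised size-change values of the positive vs
  negative control wells within one screen.
* The colony-threshold scope defaults to per-chip pooling of day-2
  particles (stabler SD); per-well scope is available.
* Plating efficiency uses the first post-baseline imaging day (the
  earliest day on which formed colonies clear the size threshold but have
  not yet merged); the colony-change metric uses the fit day when it
  precedes the day-14 exclusion.
* Missing wells/time points propagate as missing values with warnings;
  wells that shrink are `no_fit` and drop out of doubling-time summaries
  (their count is reported).

## Validation experiments (scripts/acceptance.py)

Each experiment fixes generator parameters whose analytically expected
metric is known, then requires the full image pipeline to recover it.
Problem sizes are desk-scale on purpose; the expected values are
scale-free ratios.

* **Doubling-time ratio** - 5 + 5 wells, 600 cells each, forming fraction
  0.39, rates 0.2310 vs 0.0873 /day (t_d ratio 2.65), days 2→8. Run on the
  default raster. The 4-cell founder clusters matter here: the total-area
  fit includes the constant area of non-forming singles, and with
  single-cell founders that dilution would push the measured ratio ~25%
  above the per-colony truth; with clustered founders the expected
  pipeline value is ~2.8, within the assay's reported ±38-point band.
* **Size-change percent of control** - all cells forming, colony areas ×6.0
  vs ×2.8 over days 2→7 (and ×5.0 vs ×2.8 over days 2→10), expected 36%
  (resp. 45%). 100 cells/well with single-cell founders keep day-7/10
  occupancy ≈ 4%, so emergent merging shifts the measured ratio by at most
  a point or two.
* **Colony-number percent of control** - forming probabilities 0.39 vs
  0.16 at equal k = 0.3/day, days 2→7, expected 41%. Run on a 1150 px
  (half-scale) well: at 1/3 scale, 234 colonies/well overlap so heavily by
  day 7 that the count ratio is biased - the very artifact that motivates
  the late-day exclusion rule.
* **Replicate correlation** - per-siRNA effects with SD 20 plus per-screen
  noise SD 10 give E[r] = 400/(400+100) = 0.8; averaged over 200 pairs of
  40-siRNA screens.
* **Transfection efficiency** - labeled fraction 0.82 with the default
  intensity mixture; expected percent above the non-targeting mean + 2 SD
  threshold is 0.82·Φ̄((thr−150)/17) + 0.18·Φ̄((thr−100)/10) ≈ 79%.

## What the synthetic validation does not show

The simulator draws circular, internally uniform colonies with Gaussian
noise and a clean two-level intensity model. Real brightfield wells have
uneven illumination, meniscus and rim artifacts, irregular colony
morphology, z-dependent contrast reversal and debris with cell-like sizes.
Passing recovery therefore demonstrates that the measurement chain and
statistics are correct and unbiased under the assay's own model
assumptions - not that Otsu-on-minimum-projection is robust to arbitrary
real-world imaging pathology. The per-image threshold choice and the
debris cutoff are the first knobs to revisit on real data.
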