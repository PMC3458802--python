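# softagar

Quantification and screen statistics for chip-based soft-agar siRNA
colony-formation screens.

Anchorage-independent (3D, soft-agar) growth is the classic functional
readout for transformed cells: tumour cells divide while suspended in agar,
normal epithelial cells do not. Chip-format screens exploit this by
immobilising a different siRNA under each well of a 50-well slide, seeding
500-700 agar-embedded cells per well, and imaging each well as a short
brightfield z-stack on a fixed schedule (day 2 baseline, then e.g. day 7/8
and day 14/15). `softagar` is for people who run or study such screens: it
implements the complete image-to-hit-list analysis, and - because raw image
stacks from published screens are generally not deposited - a ground-truthed
synthetic screen simulator with which every stage of the analysis can be
validated end to end.

## What it computes

Per well and time point, the z-stack is collapsed by **minimum-intensity
projection** (dark, in-focus cells from all focal planes survive the
per-pixel minimum), thresholded inside the circular well footprint (Otsu by
default; cells are darker than the agar background), and measured as
8-connected particles. From the particle tables:

* **Colony rule** — a particle is a colony when its area exceeds the day-2
  mean particle size plus two standard deviations,
  `A > mean₂ + 2·SD₂`.
* **Size and colony change** — change in average particle size and
  `(colonies_d − colonies₂) / cells₂`, both differenced against day 2 to
  cancel the cell clumps present at seeding. Colony counts on/after day 14
  are excluded: colonies merge and the counts become unreliable.
* **Doubling time** — the rate constant `k` solves `x = x₀ e^{kt}` for the
  total cell-covered area between day 2 (`x₀`) and the fit day, and
  `t_d = ln 2 / k`. Wells whose area did not increase are flagged `no_fit`.
* **Plating efficiency** — colonies at the first post-baseline day divided
  by the day-2 cell count.
* **Screen statistics** — every metric is expressed as percent of the
  pooled negative controls (no-siRNA + non-targeting) of its own chip and
  summarised per siRNA as mean ± SEM over replicate wells; hits are siRNAs
  beyond two SDs of the control wells with a significant Welch t-test
  (after a one-way ANOVA). Assay quality is the screening window
  `Z′ = 1 − 3(SD₊ + SD₋)/R` with `R = |mean₊ − mean₋|`; reproducibility is
  the Pearson r between per-siRNA means of replicate screens; transfection
  efficiency is the fraction of cells whose fluorescence exceeds the
  non-targeting mean + 2 SD.

## Worked example

Simulate a 25-well chip (5 conditions × 5 replicate wells, imaged at days 2
and 7) in which `ESR1` and `PIK3CA` knockdowns slow colony growth
(k = 0.06 and 0.05 per day against the control 0.231), then run the full
pipeline:

```sh
softagar simulate -c sim.yaml -o screen
softagar run-all -i screen -m screen/plate_map.csv -o out --fit-day 7 --well-diameter-px 380
```

`out/report.json` then contains (abridged):

```
delta_mean_size_pct                       doubling_time_pct
  ESR1    mean=12.4  sem=1.0  hit=True      ESR1    mean=455.4  sem=14.4  hit=True
  PIK3CA  mean=10.2  sem=0.7  hit=True      PIK3CA  mean=530.9  sem=21.8  hit=True
  GAPDH   mean=90.7  sem=8.0  hit=False     GAPDH   mean=105.0  sem=4.3   hit=False
  hits: ['ESR1', 'PIK3CA']                  hits: ['ESR1', 'PIK3CA']
z_prime: {SD+ 2.1, SD- 22.2, R 87.6, Z' 0.165}
colony threshold (chip1): mean 28.1 px², SD 20.8 px² -> 69.6 px²
```

Reading: the two slow-growth conditions change average cell size at only
~10-12% of the control change, their doubling times are prolonged to ~5×
control, and both are called as suppressor hits on both metrics; the
housekeeping-like `GAPDH` condition stays at control level. The positive-
vs negative-control separation gives a modest screening window (Z′ ≈ 0.17
here; 1 is a perfect assay, values ≤ 0 mean overlapping controls).

The same steps are available as library calls (`simulate_screen`,
`segment_stack`, `fit_growth`, `normalize_to_controls`, `hit_call`, ...) and
as separate `simulate` / `quantify` / `analyze` subcommands that compose to
exactly the `run-all` result.

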