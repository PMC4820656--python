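# nkscreen

Single-cell cytotoxicity screening of natural killer (NK) cells in
microwell arrays: image analysis, killing statistics, and a fully
ground-truthed synthetic assay generator.

## The problem

A silicon–glass microchip with 32,400 square microwells (~50 µm wide,
300 µm deep, arranged as 20 × 20 subunits of 9 × 9 wells) confines small
groups of cells — a few tumour target cells (e.g. K562) and zero or more
NK cells per well — for the duration of a 12-hour assay. The chip is
screened repeatedly on a fluorescence microscope (one 10× field per
subunit, 400 images per screen) in four channels:

| channel | content |
|---|---|
| transmitted light | well walls/floors — used to locate the well grid |
| calcein orange | NK cells |
| calcein green | target cells; lost on death |
| DDAO | targets; weak while alive, **bright and persistent after death** |

Counting NK cells and live/dead targets per well at each screen turns
images into per-NK-cell killing statistics: what fraction of NK cells
kills at all, how kills distribute per cell, and how much of the total
killing is done by rare "serial killers" (cells with ≥ 3 kills).

`nkscreen` implements the complete computation:

- **layout / grid** — chip geometry; template-matched well localization in
  the transmitted channel with subpixel refinement.
- **detect** — circular-Hough detection of round target cells on the union
  evidence of green and DDAO (so dead, calcein-negative targets are still
  found); connected-component counting of irregular NK cells; a per-well
  *figure of goodness* in [0, 1] penalizing crowding, merged objects,
  unidentified bright signal and overlaps, with `manual_review` flags.
- **viability** — live/dead classification from the log-ratio
  `d = log((green+ε)/(DDAO+ε))`, thresholded manually or automatically by
  maximizing a balanced live–dead pairwise-distance objective per screen.
- **analysis** — screen alignment, the study's well-selection criteria
  (`fig2`: single NK + ≥1 live target; `fig3`: single NK + ≥3 live
  targets; `fig4`: ≥5 live targets at the target-only prescreen plus a
  single NK; `spontaneous`: NK-free wells), and kill scoring from
  live-count decreases between screens.
- **stats** — cytotoxic fractions (with Wilson intervals), kill-count
  distributions, killing shares, the Yates continuity-corrected χ² test
  with star annotation, and a spontaneous-death-corrected kill
  distribution (see `docs/methods.md`).
- **synthetic** — a generator that emulates the assay end to end (Poisson
  seeding, preset kill distributions, spontaneous death, photobleaching,
  late-screen debris, imaging noise) with exact per-cell ground truth.

## Worked example

Simulate one field of the serial-killing assay and run every stage:

```bash
nkscreen run --preset serial_assay --subunits 1 1 --seed 9 --outdir demo/
```

```
simulate: 4 tiles, 81 wells -> demo
detect-wells: 324 well ROIs -> demo/wells.csv
detect-cells: 2004 cells in 324 well-screens
classify: thresholds per screen written to demo/cells.csv
analyze: 15 scored wells under criterion fig4
report: pooled cytotoxic fraction 0.733 -> demo
```

The run directory then contains the four-channel TIFF tiles, the ground
truth (`truth_cells.csv`, `truth_kills.csv`), per-stage CSVs (`wells.csv`,
`cells.csv`, `well_counts.csv`, `timecourse.csv`, `kills.csv`,
`selection_*.csv`) and the summaries: `summary.csv` (cytotoxic fraction
with Wilson 95% interval), `distribution.csv` (observed and
spontaneous-corrected kill-count frequencies), `shares.csv` (fraction of
all kills committed by NK cells with ≥ k kills) and `run_report.json`.
At this tiny scale only 15 wells pass the ≥5-target single-NK selection,
so the fractions carry wide intervals; the statistics stabilize over many
simulated fields.

The same pipeline is callable as a library:

```python
import numpy as np
from nkscreen import ChipLayout, preset_config, simulate_assay, analyze_screen

layout = ChipLayout(subunit_rows=2, subunit_cols=2)
config, dist = preset_config("resting")
sim = simulate_assay(layout, config, dist, rng=np.random.default_rng(0))
timecourse = analyze_screen(sim)   # aligned per-well counts across screens
```

## Limitations

The synthetic generator is the package's test bed, not a physical
simulator: cells are static disks/blobs in 2D, bleaching is exponential,
and kill times are uniform. Donor-to-donor variability and absolute
experiment sizes are outside desk scale and are represented only as
preset calibration anchors. See `docs/methods.md` for the model,
parameter defaults and design decisions.
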