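# nuctension

Quantification pipeline for nuclear-envelope tension imaging and its
downstream readouts. The package covers five analysis stages plus a
synthetic-data generator that provides known ground truth for every stage:

- **`nuctension.synthetic`** — simulators for three-channel FRET image sets
  (annular nuclear-envelope signal with configurable true transfer
  efficiency and bleed-through fractions under Poisson + Gaussian noise),
  two-Gaussian axial staining profiles, colonies with position-dependent
  marker positivity, paired genomic peak sets with controlled
  shared/unique structure, and qPCR Ct tables with known fold changes.
- **`nuctension.fret`** — nucleus segmentation, 3-px nuclear-envelope band
  masks (dilate-by-1 / erode-by-width−1), bleed-through calibration from
  single-fluorophore control fields, per-pixel
  `NFRET = (I_F − BT_d·I_D − BT_a·I_A) / sqrt(I_D·I_A)` on
  background-subtracted intensities, per-nucleus band means, and
  control-median normalization (control median = 1).
- **`nuctension.lamin`** — axial profile extraction from z-stacks, nonlinear
  least-squares fit of baseline + two Gaussians, basal/apical
  area-under-curve ratio, and fixed-width (default 0.05) ratio histograms
  per group.
- **`nuctension.colony`** — periphery/interior classification of colony
  cells (background 8-adjacency on label masks, convex-hull proximity on
  centroid tables) and marker-positivity summaries under both
  normalizations (% of all cells in the field; % of positive cells per
  compartment).
- **`nuctension.regions`** — BED peak-set loading (0-based half-open,
  within-set merge), midpoint region membership, maintained/gained/lost
  accounting with ≥1 bp overlap, novel-peak percentages, and
  equal-width flanking windows.
- **`nuctension.stats`** — Livak 2^(−ΔΔCt) fold changes, step-down Šidák
  ("Holm–Šidák") multiple-comparison adjustment, pooled/Welch t-tests and
  one-way ANOVA.

## CLI

Every stage is exposed under a single `nuctension` entry point:

```bash
# synthetic inputs (ground truth written alongside)
nuctension simulate fret    --config fret.yaml --seed 1 --out sim/
nuctension simulate profile --seed 1 --out sim/
nuctension simulate colony  --seed 1 --out sim/
nuctension simulate peaks   --seed 1 --out sim/
nuctension simulate ct      --config ct.yaml --seed 1 --out sim/

# FRET: calibrate bleed-through from single-fluorophore fields, then quantify
nuctension fret calibrate --donor-only 'sim/donor/*.tif' \
                          --acceptor-only 'sim/acceptor/*.tif' --out bt.json
nuctension fret quantify  --images 'sim/sensor/*.tif' --bt bt.json \
                          --control 'sim/control/*.tif' --out nfret.csv

# lamin profiles and ratio histograms
nuctension lamin fit  --profiles 'profiles/*.csv' --out fits.csv
nuctension lamin hist --ratios fits.csv --bin-width 0.05 --out hist.csv

# colony scoring
nuctension colony score --labels colony.tif --cells cells.csv --out score.csv

# peak-set comparison over a region and its flanks
nuctension atac compare --a wt.bed --b dko.bed \
                        --region chr3:90000000-93000000:EDC --flanks 2 --out cmp.csv

# qPCR fold changes and p-value adjustment
nuctension stats ddct --table ct.csv --housekeeping Gapdh \
                      --reference "WT low-Ca" --out fold.csv
nuctension stats adjust --pvalues 0.01,0.04 --method holm-sidak
```

## File formats

All inputs and outputs are standard text or TIFF: multi-page 16-bit TIFF
for image sets (donor, acceptor, FRET page order) with JSON sidecars, CSV
for profiles/Ct/attribute tables, 3-column BED (0-based half-open) for
peak sets, YAML for simulator configs.
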