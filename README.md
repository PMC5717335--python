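# kinquant

Quantitative-immunofluorescence kinetochore intensity analysis and label-free
bait-interactome (volcano) statistics, with a ground-truthed synthetic-data
generator so every stage is verifiable without external data.

## What it does

**Imaging flow** — for each multi-channel 3D stack (DAPI, an ACA centromere
reference channel, and one or more measurement channels):

1. a cuboid region of interest is cropped around the Otsu-thresholded DAPI
   foreground;
2. kinetochores are segmented in 3D on the ACA channel (Otsu threshold,
   connected components, 70-voxel minimum object size);
3. each mask is expanded in-plane by 4 px (0.32 µm at 0.08 µm pitch) to cover
   the outer kinetochore, and a 2-px background annulus with a 1-px gap is
   built around it (neighbouring objects excluded);
4. per region and channel, the mean annulus background is subtracted from
   every in-mask voxel and the result summed (negative values retained);
5. per-cell summaries feed normality-routed group statistics: Shapiro-Wilk →
   unpaired Student's t-test or Mann-Whitney for two groups, Kruskal-Wallis +
   Dunn's post hoc for three or more, with the `* / ** / ***` significance
   tiers at 0.05 / 0.01 / 0.001.

**Proteomics flow** — tab-separated protein-group intensity tables
(`intensity.<group>.<replicate>` columns, 4 bait vs 4 control replicates) are
filtered by valid-value counts, log2-transformed, and tested per protein with
an unpaired Student's t-test; the volcano output carries log2 fold change,
p-value, −log10 p, a significance flag at p < 0.05, and optional static
annotation-set flags (e.g. a kinetochore protein list).

**Synthetic data** — `kinquant.simulate` renders sister-pair spots as
voxel-integrated anisotropic 3D Gaussians inside a nuclear ellipsoid
(0.2 µm z-spacing, 0.08 µm xy pitch by default) with Poisson + read noise,
and generates log-normal LFQ tables with planted enrichment and explicit
missing values. Everything is bit-reproducible from a seed.

## CLI

All stages are driven by one YAML config (see `kinquant.config` for the
schema; unknown keys are rejected):

```bash
kinquant simulate -c config.yaml   # synthetic stacks + ground truth + manifest
kinquant quantify -c config.yaml   # per-kinetochore and per-cell CSVs
kinquant compare  -c config.yaml   # group statistics report
kinquant volcano  -c config.yaml   # interactome volcano CSV
```

Minimal example config:

```yaml
seed: 11
output_dir: out
simulate:
  n_cells_per_group: 10
  depleted_fraction: 0.65
  image:
    grid_dims: [16, 72, 72]
    n_pairs: 3
    sigma_xy_um: 0.15
    sigma_z_um: 0.40
    amplitude_mean: {ACA: 5.0e4, target: 5.0e4}
    nuclear_semiaxes_um: [1.1, 2.2, 2.2]
quantify:
  manifest: out/manifest.csv
  channels: [target]
```

Exit codes: 0 success, 2 config error, 3 data error. Every run writes a JSON
provenance record (config hash, seed, library versions, per-stage counts).

## Layout

```
src/kinquant/
  simulate.py      synthetic stacks + LFQ tables with ground truth
  io.py            TIFF stack and CSV results-table I/O
  segmentation.py  ROI, Otsu, components, mask expansion, annuli
  quantify.py      corrected sums, line profiles, per-cell summaries
  stats.py         routed two-group tests, Kruskal-Wallis + Dunn, stars
  interactome.py   LFQ filtering, volcano, annotation joins
  config.py, cli.py
tests/             unit, property and acceptance suites (+ _oracles.py)
```
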