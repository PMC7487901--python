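# rhoquant

Quantitative measurement pipelines for Rho-GTPase cell-biology assays:

* **fret_ratio** — ratiometric FRET biosensor quantification: acceptor-channel
  cell masking, background correction, per-pixel FRET/donor ratio image, and
  fold change versus control cells.
* **puncta_detect** — focal-adhesion / invadopodia scoring: CLAHE contrast
  enhancement, scale-normalized Laplacian-of-Gaussian blob detection with
  robust (median + k·MAD) thresholding, per-punctum areas (component or
  Gaussian-fit), per-cell counts, and line intensity profiles.
* **matrix_degradation** — fluorescent-gelatin degradation index per cell:
  cell trace, equal-area background ROI, index D = background mean / cell
  mean (D > 1 means degradation).
* **motility** — wound-healing widths at 11 lines and closure rate (μm/hr);
  single-cell track statistics (total path, net displacement, speed μm/min)
  and greedy nearest-neighbour track linking.
* **aux_quant** — DNA-content cell-cycle gating (2n / >2n&<4n / 4n),
  Annexin/PI quadrant classification, gel densitometry fold change, sphere
  morphometry, tissue mean fluorescence intensity.
* **scene_sim** — synthetic scene generators for all of the above (FRET image
  triplets, gelatin scenes, puncta fields, wound series, persistent-random-
  walk tracks, cytometry events, gel lanes), each returning an exact
  ground-truth record; fully deterministic per seed.
* **img_io** — TIFF raster and CSV track-table I/O (lossless integer
  round trips; intensities are never rescaled on read).
* **cli_pipeline** — YAML-configured end-to-end runs and the `rhoquant` CLI.

## CLI

```bash
rhoquant demo --seed 42 --out fixtures/        # synthetic fixtures + truth.yaml
rhoquant run config.yaml                       # config-driven pipeline
rhoquant fret --donor d.tif --fret f.tif --acceptor y.tif --out ratio.tif
rhoquant puncta --image tks4.tif --mask cell.tif --sigma 2 --out puncta.csv
rhoquant degrade --matrix alexa.tif --cells gfp.tif --out degradation.csv
rhoquant wound --t0 m0.tif --t1 m1.tif --hours 48 --out wound.csv
rhoquant motility --tracks tracks.csv --interval-min 1 --out speeds.csv
rhoquant cytometry --events events.csv --mode cellcycle --out fractions.csv
rhoquant densitometry --bands bands.csv --control lane0 --out folds.csv
```

A pipeline config is a YAML mapping with `experiment`, `seed`, `outdir` and a
`stages` block (any of `fret`, `matrix`, `puncta`, `wound`, `motility`,
`cellcycle`, `annexin`, `densitometry`); unknown keys are rejected.  The same
config + seed always reproduces bit-identical outputs.

## Conventions

* Rasters are (row, col) indexed; physical x = col·pixel size, y = row·pixel
  size.  Pixel size defaults to 1 μm/px with a warning when unspecified.
* Masks are binary with 1 = inside the cell.
* Track tables are CSV with columns `track_id,frame,x,y` (μm), plus a frame
  interval in minutes.
* All detection/gating defaults (CLAHE tile 64 px / clip 0.01, LoG σ = 2 px
  for invadopodia and {2, 4, 8} px for adhesions, k_MAD = 5, cell-cycle gate
  half-width 2.5·CV) are declared conventions and configurable.
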