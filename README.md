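# dryshift

Semi-supervised SAR–optical land-cover mapping toolkit: paired synthetic
scene simulation, multi-resolution dual-encoder fusion segmentation, k-means
ensemble pseudo-labeling, ensemble post-classification change detection, and
Getis-Ord Gi* hotspot analysis.

The pipeline mirrors a tropical-dry-forest monitoring workflow: a fine
(5 m, 4-band optical + NDVI/GNDVI) and a coarse (10 m, 4-band SAR
backscatter) raster are chunked into co-indexed 576/288-pixel patches,
normalized with training-set statistics, split into tile-grouped
train/val/test sets (59.5/10.5/30 %), and classified by a dual-stem
encoder-decoder network trained on a mix of labeled and k-means-ensemble
pseudo-labeled patches with a soft Jaccard loss (AdamW, one-cycle schedule,
early stopping). Per-epoch class maps from a five-model ensemble are
differenced pixel-wise, change is declared by 3-of-5 majority vote, areas
are booked in hectares with percent changes and truncated error margins, and
change clusters are scored with the Gi* statistic.

Everything runs on synthetic paired scenes with known labels and injected
class transitions, so no external imagery is required. The network is
implemented directly on NumPy (manual backpropagation), making the package
dependency-light and fully deterministic under seeds.

## Layout

| module | contents |
| --- | --- |
| `dryshift.synthetic_scene` | label-field simulation, optical/SAR rendering with gamma speckle, change injection, multi-date series |
| `dryshift.raster_prep` | temporal median composites, NDVI/GNDVI, min-max normalization, chunking, tile-grouped splits, resampling |
| `dryshift.ynet_model` | dual-encoder fusion network + single-stream baseline, soft Jaccard loss, AdamW, one-cycle schedule |
| `dryshift.pseudolabel` | 10-feature pixel stack, three k-means variants, cluster-to-class mapping, majority-vote pseudo-labels |
| `dryshift.train_eval` | SSL dataset assembly, training loop, full-scene prediction, OA/IoU/F1/confusion metrics |
| `dryshift.change_analysis` | pixel-wise map differencing, k-of-n change vote, hectare/percent/error-margin ledger |
| `dryshift.hotspot_stats` | change-count aggregation, Gi* z-scores, significance classes, GeoJSON export |

## CLI

```bash
dryshift simulate --seed 3 --out scenes/ --epochs 2
dryshift prep --optical scenes/optical_0.tif --sar scenes/sar_0.tif \
              --chunk 32 --split --seed 0 --out prep/
dryshift pseudolabel --optical scenes/optical_0.tif --sar scenes/sar_0.tif \
              --labels scenes/labels_0.tif --k 6 --seed 1 --out pseudo.tif
dryshift train --optical scenes/optical_0.tif --sar scenes/sar_0.tif \
              --labels scenes/labels_0.tif --arch ynet --out model.npz
dryshift predict --checkpoint model.npz --optical scenes/optical_1.tif \
              --sar scenes/sar_1.tif --out map_1.tif
dryshift evaluate --predicted map_1.tif --truth scenes/labels_1.tif
dryshift change --masks m1.txt --masks m2.txt --masks m3.txt \
              --masks m4.txt --masks m5.txt --threshold 3 --out voted.txt
dryshift hotspot --mask voted.txt --cell-size 8 --out hotspots.geojson
```

Rasters are plain TIFFs with an `.aux.json` sidecar carrying the
geotransform, CRS, band names and nodata value.

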