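# landprior

Grid-based spatial conservation prioritization and protected-area gap
analysis, built around a greedy additive-benefit cell-removal ranking.

The package covers the full desk-scale pipeline:

1. **`landprior.synthetic_landscape`** — virtual landscapes: categorical land
   cover with a natural/human split, Gaussian-kernel species suitability
   surfaces with presence sampling, a two-valued cost layer (10 for natural,
   1 for human cover), region-grown protected-area (PA) masks, and IUCN
   category → weight mapping (LC→1 … CR→5).
2. **`landprior.range_mapping`** — binarization of continuous suitability at
   the 10th percentile of training presences, Spearman-correlation
   collinearity pruning (|ρ| ≥ 0.7), spatial block cross-validation folds,
   rank-based AUC and TSS.
3. **`landprior.prioritizer`** — iterative cell ranking by
   `δi = (1/ci)·Σj wj·[V(qj) − V(qj−i)] + β·Δ(BL/A)` with `V(q)=q^z`
   (z=0.25 by default), boundary-length penalty (β=0.1), edge-restricted
   removal, 50-cell removal batches, and forced top-ranking of PA cells.
   A from-scratch `greedy_oracle` validates the fast path on small grids.
4. **`landprior.representativeness`** — per-species range coverage and the
   range-size-dependent well-represented criterion (100% required below
   1,000 km², 10% above 25,000 km², linear interpolation between).
5. **`landprior.scenario`** — top-fraction protection scenarios (e.g. 9% and
   30% land targets) and expansion summaries (percent relative increase and
   fold ratios).
6. **`landprior.io_cli`** — ESRI ASCII grid / GeoTIFF raster I/O, YAML run
   configuration, the umbrella pipeline with a checksummed manifest, and the
   CLI.

## CLI

```sh
landprior simulate  --rows 60 --cols 60 --n-species 12 --pa-fraction 0.05 \
                    --seed 1 --out-dir sim/
landprior binarize  --suitability-dir sim/ --occurrences sim/occurrences.csv \
                    --species-csv sim/species.csv --out-dir ranges/
landprior prioritize --ranges-dir ranges/ --species-csv sim/species.csv \
                    --cost sim/cost.asc --pa sim/pa.asc --out-dir prio/
landprior gapcheck  --ranges-dir ranges/ --species-csv sim/species.csv \
                    --mask sim/pa.asc --out gap.csv
landprior report    --rank prio/rank.asc --pa sim/pa.asc --ranges-dir ranges/ \
                    --species-csv sim/species.csv --targets 0.09,0.30 \
                    --out-dir report/
landprior run       --config config.yaml --seed 42 --out-dir run/   # umbrella
```

`landprior run` writes a `manifest.json` recording the configuration, the
declared numeric conventions (percentile method, benefit exponent,
interpolation mode, neighborhood, grid indexing) and a SHA-256 checksum for
every output; reruns with the same configuration are bit-identical.

## Conventions

- Grids are 0-based, row-major, origin top-left; `NODATA_value -9999` in
  ASCII grids marks invalid cells.
- Percentiles use linear interpolation between order statistics, with the
  binarization threshold capped so at most the stated fraction of training
  presences is strictly omitted.
- Boundary length counts exposed cell sides (4-neighborhood); the lattice
  border and NoData cells count as exposed.
- Range-size boundaries 1,000/25,000 km² are classed `intermediate` and take
  the continuous endpoint requirement values (100%/10%).
- All randomness flows from explicit integer seeds; there is no global
  random state.
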