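# straitgen

Analysis pipeline for cryptic-species phylogeography on archipelagos:

* **genetic landscapes** — mitochondrial p-distances, neighbour-joining
  identification trees with bootstrap, site-level distance averaging,
  Delaunay triangulation, competing distance-decay regressions selected by
  R², edge-midpoint residuals and inverse-distance-weighted interpolation;
* **haplotype networks** — ambiguity-free haplotype collapsing and a
  parsimony-limited minimum spanning network (default connection limit of
  11 mutational steps for a 658-bp barcode fragment);
* **over-sea dispersal inference** — minimum crossing events per network
  component over a land-unit graph with −50 m-isobath merges, conservative
  exclusion of ambiguous long crossings (automatic rule plus a first-class
  per-event override file), and dispersal-length spectra against reference
  strait widths;
* **maximum-entropy niche models** — occurrence grid-thinning, exact
  maximum-uncorrelated variable-subset selection, hinge (H) or
  hinge+quadratic+product (HQP) feature classes, an L1-regularized Gibbs
  fitter with coordinate descent, logistic output, replicate subsample AUC,
  max-sensitivity-plus-specificity thresholding, percent contribution and
  single-variable jackknife gains, and a cryptic-peer alpha-hull biotic
  layer;
* **synthetic worlds** — an archipelago generator with planted colonization
  events, a climate threshold separating two deeply divergent species, and
  presence points from logistic suitability, so every stage can be checked
  against known truth.

## Command line

Each stage is a subcommand of `straitgen`; every run writes a JSON run
report with input counts, exclusions and selected parameters.

```bash
straitgen simulate  --out world --seed 1
straitgen network   --fasta world/sequences.fasta --localities world/localities.csv --out net
straitgen dispersal --fasta world/sequences.fasta --localities world/localities.csv \
                    --straits world/straits.csv --out disp
straitgen landscape --fasta world/sequences.fasta --localities world/localities.csv \
                    --template world/precip_dry.asc --out land
straitgen sdm       --occurrences world/occurrences.csv --species species_west \
                    --rasters world/precip_dry.asc --rasters world/temp_noise.asc \
                    --out sdm_out
```

## File formats

* sequences: aligned FASTA (ids = first token of the header);
* localities: CSV with `specimen_id,species,lat,lon,locality_name,land_unit`;
* occurrences: CSV with `species,lon,lat`;
* strait config: CSV with `record_type,a,b,km` rows (`unit`, `merge`,
  `distance`); unlisted pairs mean "no direct strait";
* rasters: ESRI ASCII grid (lower-left origin, row 0 = northernmost row);
* dispersal overrides: CSV with `event_id,action,note`
  (`action` ∈ retain/exclude).

Coordinates are WGS84 decimal degrees throughout.

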