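# poolscreen

Multidimensional clone-pool screening toolkit for large-insert (BAC-style)
libraries: combinatorial pool design, simulation of pooled SNP-genotyping
signals, threshold-based pool scoring, clone-coordinate deconvolution and
screening-quality evaluation.

A library of 216 microtiter plates (384 wells each; 82,944 clones) is
conceptually stacked into a 36-layer, 48-row, 48-column cube and pooled along
six coordinate axes — plate pools (PP), row pools (RP), column pools (CP) and
three modular diagonal/side/face axes (DP, SP, FP) — giving 276 pools.  Extra
plate-group dimensions (SA: 36 pools of 6 plates; SB: 27 pools of 8 plates;
SG: 216 single-plate pools) support screens with seven or eight dimensions
(339 pools for the eight-dimension layout).  A clone is *putative* for an
allele when every screened dimension's pool scores positive; intersecting the
dimensions recovers clone coordinates from pool-level signals alone.

## Modules

| module                   | purpose                                                                 |
|--------------------------|-------------------------------------------------------------------------|
| `poolscreen.geometry`    | plate/cube geometry, coordinate conversions, well labels                |
| `poolscreen.design`      | pooling design, clone↔pool membership queries                           |
| `poolscreen.simulate`    | synthetic per-pool (normalized R, normalized Theta) signal tables       |
| `poolscreen.scoring`     | threshold scoring (R ≥ 0.2; Theta ≤ 0.05 / ≥ 0.95), Theta folding, clustering baseline, threshold sweep |
| `poolscreen.deconvolve`  | candidate coordinates by all-dimension intersection                     |
| `poolscreen.evaluate`    | confirmation statistics, pool audit, plate filter, recovery experiments |
| `poolscreen.io` / `cli`  | flat-file formats, run configuration, command-line entry points         |

Scoring rule: pools with normalized R below 0.2 are not scored (`none`);
otherwise Theta ≤ 0.05 → `snp1`, Theta ≥ 0.95 → `snp2`, strictly in between →
`both`.  Boundary Theta values are single-SNP calls.

## CLI

```sh
# build the default design and write its manifest
poolscreen design --plates 216 --layers 36 --dims PP,RP,CP,DP,SP,FP,SA,SB --out design/

# simulate a screen for planted loci, then score and deconvolve
poolscreen simulate --design design/ --loci loci.json --seed 1 --out signals.csv
poolscreen score --signals signals.csv --out calls.tsv
poolscreen deconvolve --design design/ --calls calls.tsv --assays loci.json \
    --mode opa1_8dim --out putative.tsv
poolscreen evaluate --design design/ --calls calls.tsv --putative putative.tsv \
    --truth signals.truth.tsv --assays loci.json --signals signals.csv --out report/

# threshold-sensitivity sweep
poolscreen sweep --signals signals.csv --design design/ --windows 0.05:0.95,0.04:0.96 --out sweep.tsv

# end-to-end pipeline (design → simulate → score → deconvolve → evaluate)
poolscreen run --seed 1 --out run1/
```

`loci.json` holds a `loci` list (`locus_id`, `genome_class`, `copy_number`)
and an `assays` list (`assay_id`, `assay_type` ∈ intergenomic / intragenomic /
non_discriminating, `allele1_loci`, `allele2_loci`, optional
`off_target_loci`).  File conventions: plates are 1-based and wells use
"A1"-style labels at the file boundary; everything is 0-based internally.

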