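# swathpep

Tools for digital immunopeptidome analysis: annotate identified HLA
class I peptides to their allele via a binding-affinity ratio score, compute
target-decoy FDR and the annotation-corrected FDR (cFDR), build HLA
allele-specific consensus spectral libraries, generate SWATH/DIA assay
libraries (b/y transition selection, iRT retention-time normalization,
shuffle-decoy assays) and DIA isolation-window schemes.

No external data is required: a fixtures module generates every pipeline
input (identification tables with decoys, donor typing, fragment spectra
with retention-time landmark peptides, source proteins) with known ground
truth, and a deterministic motif-based mock predictor stands in for an
external peptide→allele IC50 predictor.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(worked annotation-score example, window schemes, transition constraints,
fragment-mass oracle, cFDR behaviour, parameter recovery, determinism).

## CLI

A single entry point with composable subcommands
(`swathpep --help` lists all):

```sh
# generate a synthetic sample directory with ground truth
swathpep fixtures --seed 1 --n-per-allele 100 --outdir sample/

# probability/length filter and target-decoy FDR
swathpep filter sample/identifications.tsv --min-prob 0.7 --out filtered.tsv
swathpep fdr sample/identifications.tsv --target-fdr 0.01 --target-fdr 0.05 --out fdr.json

# annotate peptides to HLA alleles (ratio score, cutoff 3)
swathpep annotate sample/identifications.tsv --alleles A02,A03,B07 --out annotation.tsv

# DIA isolation windows (swaths.txt dialect)
swathpep windows --range 400:1200 --width 25 --overlap 1 --out swaths.txt

# full pipeline: filter -> FDR -> annotate -> cFDR -> consensus library ->
# windows -> assays -> decoys -> reports
swathpep run sample/ --seed 1 --outdir out/
```

`swathpep run` writes `annotation.tsv`, `library.sptxt` (consensus spectral
library), `assays.tsv` (OpenSWATH-style transition list with appended
decoys), `swaths.txt`, `report.json` and a reproducibility `manifest.json`.
Identical seeds produce byte-identical outputs.

The external-predictor contract (peptide list file in, TSV
`peptide  allele  ic50_nM` out) is exposed by `swathpep mock-predict` so any
executable honouring the same interface can be substituted.

## Layout

- `swathpep.masses` — monoisotopic b/y fragment and precursor m/z
- `swathpep.annotation` — annotation score, curation categories, allele
  summaries, heat-map matrix, source-protein percentile ranks
- `swathpep.fdr` — peptide-level target-decoy FDR and cFDR
- `swathpep.library` — iRT fitting, consensus spectra, transition
  selection, decoy assays, library merging
- `swathpep.windows` — DIA isolation-window schemes
- `swathpep.fixtures` — synthetic data generators and the mock predictor
- `swathpep.io_formats` — TSV/FASTA/sptxt/swaths.txt readers and writers,
  run configuration
- `swathpep.pipeline`, `swathpep.cli` — orchestration and the CLI
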