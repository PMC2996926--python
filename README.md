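# bacmap

Toolkit for fingerprint-based BAC physical map construction, built around the
Sulston overlap score: contig assembly from agarose and HICF restriction
fingerprints with hybridization-marker cutoff relaxation, pooled-overgo
deconvolution, genetic-map anchoring, window-based synteny anchoring onto
comparator genomes, and a synthetic genome/library simulator with full ground
truth for end-to-end validation.

## Modules

| module | contents |
|---|---|
| `bacmap.fingerprint` | band matching, exact log-space Sulston tail, minimum-match / minimum-informative-band thresholds, Lander–Waterman expected contig count, denary cutoff relaxation |
| `bacmap.assembly` | single-linkage contig assembly with marker/HICF-aware relaxation, CB-map layout, Q-clone detection, DQ splitting, end-to-end merging, singleton adoption, burying, cross-well and band-count QC, the integrated pipeline |
| `bacmap.overgo` | 24×24 row/column/diagonal pool design, exact minimal-cover deconvolution, probe copy-number classification, overgo candidate design |
| `bacmap.anchoring` | hybridization filtering, genetic-map anchoring with weak-anchor handling, per-group summaries, low-copy/repeat contig classification, organelle flagging |
| `bacmap.synteny` | repetitive-query filtering, single-linkage window anchoring, coverage, gene-density tracks and enrichment |
| `bacmap.simulate` | genome/library/digest/probe/pool/comparator simulators plus truth-based precision/recall/purity evaluation |
| `bacmap.io`, `bacmap.config`, `bacmap.cli` | FPC "sizes" dialect, TSV/BLAST-tabular/BED/GFF3 readers and writers, YAML pipeline configuration, CLI |

## CLI

```sh
# analytic calculators
bacmap analytics --bands 17 --tol 7 --gel 5000 --cutoff 1e-12
bacmap analytics --bands 17 --cutoff 1e-12 --clones 92160 --genome-bp 880e6

# synthetic dataset -> assembly -> anchoring -> synteny
bacmap simulate --genome-bp 5000000 --seed 1 --out demo/
bacmap assemble --sizes demo/library.sizes --out demo/asm
bacmap anchor --contigs demo/asm.contigs.tsv --probes demo/probe_hits.tsv \
    --map demo/genetic_map.tsv --out demo/anchors.tsv
bacmap synteny --hits demo/comparator_hits.tsv --contigs demo/asm.contigs.tsv \
    --chroms demo/chrom_lengths.tsv --out demo/synteny.bed

# full integrated pipeline (QC, preliminary, HICF, integrated, finalization)
bacmap integrate --sizes demo/library.sizes --out demo/final

# simulate + assemble + truth-score in one go
bacmap evaluate --genome-bp 2000000 --seed 1
```

## Notes

- Default parameters are the operating points of a large-insert (~100 kb,
  10×) library fingerprinted on a 5000-unit gel: preliminary assembly
  1e-10/tol 8, HICF 1e-50/tol 3, integrated 1e-12/tol 7, marker relaxation by
  2/3/4 denary intervals, end-merging down to 1e-6, burial at 80%.
- HICF bands use a composite encoding `channel * 2000 + size_unit`, so
  cross-channel bands can never fall within tolerance of each other.
- The simulator draws restriction sites once per genome, which is what makes
  fingerprints of overlapping clones concordant; all randomness is
  deterministic under `(config, seed)`.
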