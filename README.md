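# lutiscan

Discovery and characterization of 5′-extended transcript isoforms —
long undecoded transcript isoforms whose uORF-laden leaders repress the
downstream coding sequence — from six genomic data modalities:

- per-base 5′-end tag counts (stranded bedGraph, two timepoints in replicate)
- long-read transcript spans (BED6)
- gene annotation (GFF3) plus genome (FASTA)
- ribosome-footprint 5′ counts (stranded bedGraph)
- histone-mark fold-enrichment tracks (bedGraph) and TF peak calls (narrowPeak)
- nucleosome dyad counts (bedGraph)

The pipeline covers: TPM normalization and distance-based TSS
clustering (strict and permissive parameter sets), promoter-level
aggregation with dominant-position calling, induction filtering and
long-read-validated 5-way locus classification, leader uORF inventory
with footprint translation calls under a leaky-scanning model,
promoter-window histone-mark scoring and TF-target calling, nucleosome
calling (position / occupancy / fuzziness) with +1/−1 assignment and
between-timepoint shift features, and a Spearman feature-correlation
cluster map with repression classification and a paired signed-rank
test.

A fully seeded synthetic-study generator (`lutiscan.simulate`) plants
loci of all five classes with known parameters — proximal-isoform fold
changes, mark gains, +1 nucleosome shifts and fuzziness increases,
uORF counts and initiation probabilities — so every stage is testable
against exact ground truth with no external data.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence for clustering, planted-truth recovery for discovery,
chromatin, nucleosome and correlation stages, Monte-Carlo agreement
for the uORF model, statistical calibration, fuzzed I/O round trips).

## CLI

```sh
# generate a synthetic study with planted ground truth
lutiscan simulate --outdir study/ --seed 1

# cluster 5'-end tags (strict = discovery, permissive = quantification)
lutiscan cluster --ctss study/tlseq --mode strict --out clusters.tsv

# classify induced promoters (LUTI / canonical / antisense / intergenic / intragenic)
lutiscan discover --ctss study/tlseq --reads study/longreads.bed \
    --gff study/annotation.gff3 \
    --pre pre_rep1,pre_rep2,pre_rep3 --mei mei_rep1,mei_rep2,mei_rep3 \
    --out calls.tsv

# uORF inventory and translation calls for the discovered leaders
lutiscan uorf --genome study/genome.fa --calls calls.tsv \
    --footprints study/footprints --out uorf.tsv

# convert size-selected MNase fragments to dyad counts
lutiscan convert --bedgraph fragments.bed --out dyads.bedgraph
```

Python API: `lutiscan.pipeline` exposes the same stages on in-memory
objects (`run_discovery`, `quantify_isoforms`, `assemble_features`,
…); see the module docstrings.

## Conventions

Internal coordinates are 0-based half-open; the 5′ end of a
minus-strand feature is its last covered base. Stranded tracks are
carried as `<sample>.plus.bedgraph` / `<sample>.minus.bedgraph` pairs;
ChIP and MNase tracks are unstranded. GFF3 input/output is 1-based
inclusive.
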