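# pankit

Bacterial genome assemblies are routinely incomplete: gene products present
in the sequencing reads can be missing from the deposited reference sequence,
and every comparative analysis downstream of that reference silently inherits
the gap.  `pankit` is a two-stage toolkit for working strain panels:

1. **Missing-gene recovery (stage 1).**  Reads are partitioned into
   mapped/unmapped against the reference; the unmapped fraction is assembled
   de novo; assembled contigs are annotated; assembled CDS with no similarity
   to any reference CDS are appended to the end of the genome file as new
   product records, and the updated genome is re-annotated.
2. **Pan-genome comparative analysis (stage 2).**  Genes from all (updated)
   genomes are clustered into families by all-vs-all protein similarity
   (e-value ≤ 1e-10, identity and coverage ≥ 0.70, single-linkage components
   — the GF approach); pan/core/new-gene curves are sampled over random
   genome-addition orders; Heap's law is fitted; unique and shared gene
   counts and Jaccard presence/absence distance trees (NJ and UPGMA) are
   produced.

The openness of a pangenome is read off the new-gene discovery curve

```
n_new(N) = κ · N^(−α)
```

where `N` is the number of genomes considered.  `α ≤ 1` means the pangenome
is **open** (every added genome keeps contributing new families); `α > 1`
means it is effectively **closed**.  The fit is a closed-form least squares
on `(ln N, ln s(N))` for `N ≥ 2`, where `s(N)` is the mean or the median of
`n_new(N)` over sampled orders.

A first-class synthetic-data module generates multi-strain panels with a
known family structure (core + accessory following Heap's law with a chosen
`α`), simulates reads, and builds "planted missing gene" scenarios, so the
entire pipeline is testable without any downloads.

## Worked example

Simulate a 4-strain panel with two genes excised from the first strain's
reference (the genes remain in its reads), then run both stages:

```
pankit simulate --genomes 4 --core 8 --kappa 6 --alpha 0.5 \
    --coverage 20 --plant 2 --seed 3 --outdir demo/sim
```

Write a run config listing the genomes from `demo/sim/manifest.yaml`:

```yaml
outdir: demo/run
seed: 1
n_perms: 50
genomes:
  - {genome_id: G01, fasta: demo/sim/genomes/G01.fasta,
     reads1: demo/sim/reads/G01_1.fastq, reads2: demo/sim/reads/G01_2.fastq}
  # ... G02..G04 likewise
```

```
pankit run --config demo/config.yaml
```

The run log shows one line per step:

```
step partition    done in 0.45s
step repair       done in 0.00s
step assemble     done in 0.02s
...
step fit          done in 0.00s
step reports      done in 2.02s
```

`demo/run/stage1/G01/report.tsv` then holds the stage-1 summary for the
strain with planted genes — for this seed:

```
new_products	hypothetical	total	mean_len_nt
0	6	6	272
```

i.e. six assembled CDS had no similarity to the reference's CDS (all six
unnamed, since no known-protein set was supplied) with a mean length of
272 nt; the two planted genes are among them, each accompanied by short
overlapping reading frames from the same recovered loci.  Stage-2 outputs in
`demo/run/stage2/` include `clusters.tsv`, `curves.tsv`, `heapfit.json` —
for this run

```json
"median": {"alpha": 0.301, "kappa": 13.02, "verdict": "open"}
```

— plus `boxplot.png` (pan/core distributions with both fitted α values),
`barplot_uniques.png`, `barplot.png`, `pie_shared.png`, the newick trees
`PanBased.Neighbor-joining.nwk` / `PanBased.UPGMA.nwk`, and TSV siblings for
every plot.  A run that stops (failure, Ctrl-C) can be continued with
`pankit run --config ... --resume`: steps whose recorded state and parameter
hash still match are skipped, and resumed runs reproduce the tables of an
uninterrupted run byte for byte.

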