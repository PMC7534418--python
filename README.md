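# postasm

Post-assembly genome analytics toolkit: a tested, reusable implementation of
the analytical layer that follows a long-read plant genome assembly —

* **k-mer genome size** — peak-based haploid genome-size estimation from a
  k-mer multiplicity histogram (`postasm.kmer_size`);
* **assembly metrics** — contig splitting on N-run gaps, NX statistics,
  gap census and masked fraction, with per-sequence and totals rows
  (`postasm.assembly_metrics`);
* **repeat context** — genic vs non-genic classification of repeat
  annotations, strand concordance, class composition/fold statistics, and
  windowed coverage tracks (`postasm.repeat_context`);
* **gap permutation test** — observed vs shuffled repeat/GC content in
  gap-flanking windows at configurable distances, empirical p-values as the
  strict-exceedance proportion (`postasm.gap_permutation`);
* **SV population curation** — Delly-dialect VCF parsing, the five-rule
  curation chain (precise, < 5 Mb, PASS, MAPQ > 0, PE >= 5), folded minor
  allele frequencies, type-wise summaries, and a deletion-length vs
  TE-length histogram-overlap comparison (`postasm.sv_population`);
* **gene-set filtration** — AED thresholding, primary-isoform selection,
  isoform TPM aggregation, and the orthogroup-informed final filter
  (`postasm.gene_set_filter`);
* **duplication enrichment** — support-filtered duplication events per tree
  node and hypergeometric term enrichment with Benjamini–Hochberg control
  (`postasm.enrichment`);
* **synthetic data** — a deterministic simulator that generates every input
  (softmasked FASTA, repeat table, gene GFF3, gap BED, population SV VCF,
  k-mer histogram, orthogroup/duplication/annotation tables) with ground
  truth retained (`postasm.synthetic_data`);
* **I/O** — strict readers/writers for all of the above with validating
  round-trips; internal coordinates are 0-based half-open everywhere
  (`postasm.io_formats`).

## CLI

All stages are subcommands of one entry point:

```bash
postasm simulate --seed 1 --outdir sim/           # all inputs + ground truth
postasm kmer-size --histogram sim/sim.kmer_hist.txt
postasm asm-stats --fasta sim/sim.genome.fa --min-gap 10
postasm repeat-context --repeats sim/sim.repeats.tsv --genes sim/sim.genes.gff3
postasm gap-perm --fasta sim/sim.genome.fa --gaps sim/sim.gaps.bed \
    --repeats sim/sim.repeats.tsv --n-perm 1000 --distances 50,100,500,1000,1500 \
    --stat repeat,gc --seed 1
postasm sv-pop --vcf sim/sim.svs.vcf --min-pe 5 --maf 0.01
postasm gene-filter --gff sim/sim.genes.gff3 --tpm sim/sim.tpm.tsv \
    --orthogroups sim/sim.orthogroups.tsv --species focal
postasm enrich --duplications sim/sim.duplications.tsv \
    --annotations sim/sim.annotations.tsv --node N2
postasm run-all --seed 1 --outdir out/            # everything + report.json
```

Outputs are TSV; `run-all` additionally writes a combined JSON report whose
numbers are traceable to the per-stage files. Every stochastic stage is
driven by the single `--seed`; fixed seed means byte-identical outputs.

## Testing notes

`tests/test_acceptance.py` holds the acceptance criteria: published-table
arithmetic, oracle-equivalence checks (NX vs brute force, interval
classification and window coverage vs per-base counting, hypergeometric tail
vs exhaustive enumeration, SV filter vs an independent restatement),
statistical calibration of the permutation test (type-I error over 500 null
genomes) and power checks, parameter recovery, and boundary conformance.
Simulation-heavy checks are scaled down (small chromosomes, n_perm = 200) to
keep the suite fast; thresholds are unchanged.
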