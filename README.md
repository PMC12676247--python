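# phagekit

A tested pipeline package for phage-genome analysis at desk scale:

- **triage** — four-signature viral calling (viral/microbial protein-family
  hits, nucleotide score, strand-switch rate), virus-keyword phage
  identification, BUSCO/VPF false-positive filtering, size/completeness
  gates, and lifestyle assignment (virulent / uncertain / temperate).
- **ani** — gapless seed-and-extend ANI with merged-interval coverage,
  strand-insensitive exact dereplication, greedy centroid species-level
  clustering (95% ANI / ≥85% member coverage) and novelty flagging.
- **codes** — alternative genetic-code detection: ORF scanning under four
  stop-codon sets (11, 15, 90, 91) and size-dependent coding-density gain
  thresholds (>10% below 100 kb, >5% above).
- **phylo** — core-marker selection (prevalence ≥10%, mean copy ≤1.2, mean
  length >100 aa), alignment trimming (<50% gap columns), genome inclusion
  (≥3 markers covering >5% of columns), a five-iteration driver,
  neighbour-joining trees and patristic distances.
- **divergence** — AAI / shared-gene genus graphs, Markov clustering
  (inflation 2.0), and one-tailed Wilcoxon habitat-divergence testing
  (exact enumeration for small samples, tie-corrected normal otherwise).
- **crispr** — CRISPR array detection, full-length ≤1-mismatch spacer
  matching on both strands, host assignment and host-range classes,
  phage–phage targeting networks with single/double-directed pair
  classification, and Cas acquisition-module status.
- **synthetic** — a seeded community generator that plants species/genus
  structure, recoded genomes, CRISPR arrays and interaction links as
  ground truth, so every stage is testable without downloads.
- **report** — headline proportion tables (half-up, two decimals).

## CLI

All stages are exposed as subcommands of a single entry point:

```bash
phagekit simulate --config cfg.yaml --seed 7 --outdir sim/
phagekit triage --genomes sim/genomes.fasta --calls sim/gene_calls.tsv \
    --meta sim/metadata.tsv --out triage.tsv
phagekit cluster-species --genomes sim/genomes.fasta --meta sim/metadata.tsv \
    --ani 95 --cov 85 --out clusters.tsv
phagekit call-codes --genomes sim/genomes.fasta --out codes.tsv
phagekit marker-phylo --families families.tsv --alignments alns/ --outdir phylo/
phagekit genus-divergence --genes genes.tsv --habitats habitats.tsv --outdir div/
phagekit crispr-net --phages sim/genomes.fasta --hosts sim/hosts.fasta --outdir net/
phagekit report --indir results/
```

The simulate config is a YAML mapping of `CommunityConfig` fields
(`n_phages`, `n_hosts`, `within_species_sub_rate`, `frac_recode`,
`frac_phage_with_array`, ...); identical config + seed gives byte-identical
output.

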