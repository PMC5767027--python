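# agame

Analysis toolkit for **pooled functional-metagenomics insert data**.

Expression screening of environmental DNA (eDNA) libraries yields
clones — fosmid or cosmid inserts, typically under 45 kb — whose pooled
sequencing cuts costs but leaves a deconvolution problem: after
assembly, which contig came from which clone? `agame` provides the
bespoke computational pieces around that problem, for people running
functional-metagenomics screens:

- **FosBin binning** — partition pooled-assembly contigs into the known
  number of insert clusters by K-means over canonical tetranucleotide
  frequencies (136 strand-collapsed 4-mer classes) and a coverage
  summary (windowed read depth, or assembler-reported k-mer coverage),
  and score clusterings against truth with the binning notions of
  sensitivity (contig co-clustered with a same-insert companion) and
  specificity (cluster purity).
- **End-tag anchoring** — locate single-pass Sanger reads from insert
  termini at contig ends via Smith–Waterman (or supplied BLAST
  `-outfmt 6` hits), and classify each insert's assembly completeness:
  `complete`, `two_of_two`, `one_of_one`, `partial`, `unassigned`.
- **Assembly evaluation** — N50 and total length of end-tag-bearing
  contigs, percent of a reference assembly covered (interval union),
  and percent of reference proteins recovered as reciprocal best hits.
- **Pool-fragmentation benchmark** — a synthetic-data generator
  (Markov-chain source genomes, random insert fragmentation, Poisson
  coverage with optional ×{2,4,8,16} per-insert multipliers) plus the
  full benchmark grid: pools of 8/12/18 inserts × 2/3/5 fragments ×
  100 replicates, tabulated as mean ± sd sensitivity/specificity.
- **Pfam domain reports** — join PFAMScan hits with `pfamA.txt`
  descriptions, filter proteins with AND/OR/NOT keyword queries, and
  render fasta-like HTML reports (per-cluster pages) with a TSV twin.

See `docs/methods.md` for the models, defaults and their rationale, and
what the synthetic benchmark does and does not demonstrate.

## Worked example

Simulate a small benchmark, keep the first replicate's files, and run
the binning and end-tag stages on it:

```sh
agame simulate --pools 8 --fragments 3 --replicates 5 --mode both \
      --seed 7 --write-fixtures --out bench
head -3 bench/benchmark_table.tsv
```

```
n_inserts  n_fragments  mode        mean_sensitivity  mean_specificity  sd_sensitivity  sd_specificity  n_replicates
8          3            multiplied  0.9750            0.9250            0.0228          0.0685          5
8          3            uniform     0.9833            0.9500            0.0228          0.0685          5
```

Five replicates of 8 inserts cut into 3 fragments each: on average 97–98%
of the 24 contigs land in a cluster containing another contig of the
same insert, and ~93–95% of the 8 clusters are single-insert pure.

```sh
agame features --contigs bench/replicate1_contigs.fasta \
      --depth bench/replicate1_depth.tsv --out features.tsv
agame bin --features features.tsv --k 8 --seed 1 --out bins.tsv
agame bin-score --bins bins.tsv --truth bench/replicate1_truth.tsv
```

```
sensitivity  specificity  n_contigs  n_clusters
1.0000       1.0000       24         8
```

This replicate's 24 contigs are recovered perfectly: every cluster
equals one insert's fragment set.

```sh
agame endtag --contigs bench/replicate1_contigs.fasta \
      --tags bench/replicate1_tags.fasta --out endtag
head -3 endtag.classification.tsv
```

```
insert_id  n_tags_available  category    contigs
s0i0       2                 two_of_two  s0i0.f0,s0i0.f2
s0i1       2                 two_of_two  s0i1.f0,s0i1.f2
```

Each insert was deliberately fragmented into three contigs, so both of
its end-tags anchor — at ~99.5% identity, the tags carry simulated
Sanger errors — but on *different* contigs: category `two_of_two`
(an intact single-contig insert would be `complete`).

The Pfam report side is independent of sequencing data:

```sh
agame report --proteins prots.fa --pfamscan pfam_hits.txt \
      --pfama pfamA.txt --query "lipase OR esterase NOT phage" \
      --out report/
```

writes `report/index.html` (fasta-like pages with Pfam hyperlinks, one
page per cluster if `--clusters` is given) and `report/report.tsv`.

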