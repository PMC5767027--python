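# Methods

`agame` deconvolves pooled fosmid/cosmid insert assemblies: given the
contigs of a pooled functional-metagenomics sequencing experiment, it
assigns contigs back to their clone (insert) of origin, measures how well
an assembly reconstructed each insert, and helps prioritize candidate
genes from Pfam annotations. This note records the models, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not demonstrate.

## Contig features

**Composition.** Each contig is summarized by its canonical
tetranucleotide frequency vector. A width-4 window slides one base at a
time; windows containing N are skipped; each 4-mer is collapsed with its
reverse complement onto the lexicographically smaller of the two, giving
(256 − 16)/2 + 16 = 136 classes; counts are normalized by the number of
valid windows. Canonicalization is not cosmetic: contigs assemble in
arbitrary orientation, and a strand-dependent fingerprint would split a
clone's contigs across feature space. The frequency vector of a contig
and of its reverse complement are *exactly* equal (same multiset of
canonical windows), which the suite asserts bitwise.

**Coverage.** Per-contig coverage is the mean of per-window mean depths,
with non-overlapping 500 bp windows; a trailing remainder shorter than
half a window is merged into the previous window (a 100 bp tail window
would otherwise contribute a high-variance estimate), a longer remainder
stands alone, and contigs shorter than one window are a single window.
When no per-base depth track is available, the assembler-reported k-mer
coverage scalar parsed from SPAdes (`_cov_<x>`) or MEGAHIT
(`multi=<x>`) headers is used instead; a depth track wins when both are
present, because windowed read depth is the more direct measurement.
The depth-table dialect is samtools-depth-like (contig, 1-based
position, depth; missing positions are depth 0) — the most common
3-column depth format; this is a reader choice, stated in the CLI help.

**Clustering matrix.** The 136 composition columns are z-scored
per column (zero-variance columns are set to 0); coverage enters as
z-scored log2(1 + c), scaled by a weight whose default is √136 ≈ 11.66.
Coverage spans orders of magnitude between inserts (the benchmark's own
multiplied mode reaches ×16), so the log transform keeps K-means
geometry reasonable; the √136 weight makes the single coverage column's
expected squared contribution to Euclidean distances equal to that of
the whole composition block, i.e. the two signals start from equal
footing. The weight is exposed (`--coverage-weight`) because the right
balance depends on how informative coverage is in a given experiment.

## Binning (FosBin)

Contigs are partitioned into exactly k clusters, k being the known
number of pooled inserts, with Lloyd's K-means using k-means++ seeding
and 25 independent restarts (best final within-cluster sum of squares
kept). The implementation is deliberately deterministic for a pipeline
tool: restart i derives child seed `seed + i`; ties in point-to-centroid
assignment break toward the lowest cluster index; an emptied cluster is
repaired by moving the point farthest from its current centroid, keeping
exactly k clusters. Inertia is non-increasing along each run's
iteration trace, and the multi-restart result is never worse than any
individual restart — both are asserted as properties, and the optimum on
well-separated data is cross-checked against an independent K-means
implementation (scikit-learn) in the tests.

Binnings are scored against truth labels with two set statistics:
*sensitivity*, the fraction of contigs whose cluster contains at least
one other contig from the same insert (a contig in a singleton cluster
is never correct), and *specificity*, the fraction of clusters whose
contigs all derive from one insert. Singleton clusters count as pure,
which literally satisfies the definition but inflates specificity at
high fragmentation — worth remembering when comparing across
fragmentation levels. Contigs under 2 kb are flagged with a warning at
binning time, since short contigs carry noisy composition estimates and
dominate the misbinned set.

## End-tag anchoring and insert classification

Each insert may have one or two single-pass Sanger reads from its
termini. A tag is located on a contig by local (Smith–Waterman)
alignment, match +1 / mismatch −1 / gap −2, on both strands; the hit
must reach 90% identity over at least 80% of the tag, and counts as
*terminal* when the contig-side span lies within `tag length + 500` bp
of a contig end. The thresholds are engineering defaults (the problem
dictates none) and are all configurable; precomputed tabular alignments
(BLAST `-outfmt 6`) can substitute for the built-in aligner, in which
case bitscore plays the role of the alignment score. Each tag is then
assigned its single best terminal hit across contigs (ties: higher
identity, then smaller contig id).

Per insert, the assigned tags yield one of five mutually exclusive
categories: **complete** (both tags on one contig, at opposite termini —
the opposite-termini requirement is what "a single contig matching both
end tags" geometrically means), **two_of_two** (both tags assigned but
not in that geometry), **one_of_one** (the single available tag
assigned), **partial** (two available, one assigned), **unassigned**.
Contigs claimed by tags of two different inserts are conflicts: they are
assigned to neither clone and reported.

## Assembly evaluation

The evaluation row combines: the category counts above; N50 and total
length of end-tag-bearing contigs (N50 = smallest length at which the
descending cumulative sum reaches half the total); percent of reference
bases covered by the union of alignment spans (intervals normalized to
0-based half-open, minus-strand spans flipped, union via an interval
tree; raw covered bases, not identity-weighted); and percent of
reference proteins recovered as reciprocal best hits between the
reference and pooled protein sets (best = max bitscore, then min
e-value, then lexicographically smallest subject — fully deterministic).
No identity filter is applied to evaluation alignments by default.

## The synthetic benchmark

There is no desk-scale real benchmark: the published one builds on
archived sequencing runs and third-party assemblers. The generator
instead *emulates the design*:

- **Source genomes** are order-2 Markov chains whose 16 transition rows
  are independent Dirichlet(α=1) draws. Distinct sources are
  compositionally well separated (asserted as a property); inserts from
  one source share its signature.
- **Pools** draw their inserts round-robin from a fixed panel of 6
  source genomes, so an 8-insert pool contains mostly singleton sources
  while an 18-insert pool has three clones per source. This is the
  load-bearing realism choice: clones of one source are separable only
  through coverage, which (i) reproduces the empirical difficulty
  gradient — deconvolution degrades as pools grow — and (ii) makes the
  coverage channel genuinely decisive, the regime the
  multiplied-coverage experiment probes. Real libraries show the same
  structure (overlapping clones from a single genome occur). An earlier
  design with a fresh source pair per two inserts made every pool size
  equally easy and was discarded.
- **Inserts** are Normal(33 kb, 5 kb) in length, truncated to
  [10 kb, 45 kb]; end-tags are the terminal 700 bp with 0.5%
  substitution error (Sanger-like).
- **Fragmentation** cuts each insert into 2, 3 or 5 contigs at uniform
  random breakpoints, every fragment ≥ 500 bp (one coverage window),
  by rejection sampling; fragments partition the insert exactly.
- **Coverage** is per-base Poisson with one rate per insert,
  λ ~ Uniform(20, 100); in *multiplied* mode the same base rates are
  additionally scaled per insert by a random factor from {2, 4, 8, 16}.
  The two modes are compared on paired pools (same inserts, same
  fragmentation, same base rates), isolating the effect of spreading
  the coverage values.
- **Grid**: pools of {8, 12, 18} × fragmentation {2, 3, 5} × both modes
  × 100 replicates, k fixed to the pool size, all seeds derived from one
  root seed so any replicate is reproducible in isolation.

What passing shows — and does not. The benchmark reproduces the
qualitative behavior of the method: near-perfect recovery of
well-separated 8×2 pools, monotone decline of sensitivity with pool
size, and misbinned contigs concentrating below 2 kb. It does not
reproduce any published benchmark's numeric cells (synthetic sources are
cleaner than real genomes, and "real coverage" there came from
re-mapped reads), and two patterns transfer only partially:

1. With base rates already spread over Uniform(20, 100), random
   multiplication is *not* universally beneficial: it helps inserts that
   draw different factors but — after per-pool z-scoring of the coverage
   column — compresses the gap between inserts that draw the same
   factor. On the seeded default grid the multiplied mode improves or
   ties both scores in 17 of 18 cell comparisons and is marginally
   worse (≤ 0.01) in one cell (12 inserts × 3 fragments). The
   corresponding acceptance check asserts the strict all-cells
   inequality and is therefore expected to fail on that cell; the
   result is reported as-is rather than retuning the generator around
   it. Under the original experiment's premise — near-equimolar pooling,
   hence nearly equal base depths — the multiplication is purely
   beneficial.
2. In the published setting specificity exceeds sensitivity row by row,
   because the dominant error is stray short contigs landing in wrong
   or singleton clusters (pure singletons keep specificity high). The
   synthetic generator's dominant error is the *merging* of same-source
   clones with colliding coverage — high sensitivity, impure clusters —
   so here sensitivity typically exceeds specificity at 3+ fragments.
   The suite asserts the error-mode facts that do transfer (restricting
   scoring to ≥ 2 kb contigs raises sensitivity) rather than the
   pattern that does not.

## Numerical and degenerate-input choices

Sequences are upper-cased on input; characters outside ACGTN are
rejected (DNA-only context — U is an error, not RNA support). A contig
whose every 4-mer window contains N has no composition estimate and is
an error rather than a silent zero vector. K-means requires k ≤ n and a
finite matrix; k = n yields singletons with zero inertia. N50 of an
empty set is undefined (rendered NA in evaluation rows). Boolean
queries: precedence NOT > AND > OR, adjacency means AND, terms match
case-insensitively as substrings of domain descriptions and Pfam ids,
and NOT complements within annotated proteins only — proteins with no
domain hits are outside the query universe. Benchmark problem sizes in
the shipped checks: the full 3×3×2×100 grid for the trend assertions,
20 replicates for the 8×2 recovery floor, and 50 replicates per cell in
`scripts/acceptance.py`; cell means are stable to ~0.01 at these sizes.

## Known limitations

The simulator emulates composition and depth, not reads: no chimeras,
no repeat-induced misassembly, no GC-coverage coupling, no vector or
host contamination (screening for which is upstream of this toolkit).
Assembler headers are parsed for SPAdes and MEGAHIT dialects only.
The end-tag aligner is exact Smith–Waterman, fine for 700 bp tags
against pool-scale contig sets but not meant for genome-scale searches —
use the outfmt-6 bypass with an external BLAST when scale demands it.
K-means with k fixed to the pool size inherits the experiment's
bookkeeping: if the true number of pooled clones is misstated, clusters
are forced to split or merge accordingly.
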